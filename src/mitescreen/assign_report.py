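"""Family-level taxonomic assignment, contamination rates, family x
host-class distribution and suspect-contaminant flagging.

Contaminated contigs are assigned to a mite family from the lineage of
their top best-score reference hit, requiring a nucleotide identity of at
least 91.4% — the strict similarity threshold reported for family-level
barcode assignment in mites (a per-order alternative of 89.9% for
Sarcoptiformes can be enabled).  Ubiquitous human-associated mites (the
follicle mites *Demodex*, family Demodicidae) turn up in assemblies of
unrelated hosts as fortuitous contamination of the sample rather than a
real host association; a configurable watch-list flags such assignments
so they can be excluded from host-association tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import AlignmentHit, ScoringScheme, search
from .io_formats import SeqRecord
from .screen import AssemblyRecord, ContaminationCall, ScreenConfig
from .taxonomy import (
    MITE_ORDERS,
    Lineage,
    family_of,
    round_half_up,
)

UNASSIGNED = "unassigned"


@dataclass
class FamilyAssignment:
    """Family-level label (or unassigned) for one contamination call."""

    contig_id: str
    family: str
    supporting_hit: AlignmentHit
    identity_pct: float


def assign_family(
    call: ContaminationCall,
    lineages: Mapping[str, Lineage],
    cfg: ScreenConfig | None = None,
    per_order_thresholds: Optional[Mapping[str, float]] = None,
) -> FamilyAssignment:
    """Assign a call to a mite family from its top best-score nt hit.

    The family rank of the best hit's lineage is used when the hit
    identity reaches the similarity threshold (uniform 91.4% by default;
    ``per_order_thresholds`` maps order names to stricter or looser
    values).  Below threshold, or when the lineage lacks a family rank,
    the contig stays unassigned.
    """
    cfg = cfg or ScreenConfig()
    hit = call.nt_best_hit
    lineage = lineages.get(hit.subject_id, call.nt_best_lineage)
    threshold = cfg.family_threshold
    if per_order_thresholds:
        for order in lineage.names:
            if order in per_order_thresholds:
                threshold = per_order_thresholds[order]
                break
    family = family_of(lineage) if lineage is not None else None
    if family is None or hit.identity_pct < threshold:
        family = UNASSIGNED
    return FamilyAssignment(
        contig_id=call.contig_id,
        family=family,
        supporting_hit=hit,
        identity_pct=hit.identity_pct,
    )


def contamination_rate(n_contaminated: int, n_total: int) -> float:
    """100 x contaminated / total, half-up rounded to one decimal."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_contaminated <= n_total:
        raise ValueError("n_contaminated outside [0, n_total]")
    return round_half_up(100 * Decimal(n_contaminated) / n_total, 1)


@dataclass
class DistributionTable:
    """Family x host-class counts and percentages plus per-category rates.

    ``rates`` maps a category (project type, host class, or "overall") to
    ``(contaminated, total, pct)`` over assemblies.  ``family_paths``
    carries each family's lineage path (order, family) for Krona output.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    row_percentages: dict[tuple[str, str], float] = field(default_factory=dict)
    rates: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    family_paths: dict[str, tuple[str, ...]] = field(default_factory=dict)
    unassigned_count: int = 0
    flagged_count: int = 0
    total_calls: int = 0

    def families(self) -> list[str]:
        return sorted({fam for fam, _ in self.counts})

    def host_classes(self) -> list[str]:
        return sorted({hc for _, hc in self.counts})

    def family_total(self, family: str) -> int:
        return sum(
            n for (fam, _), n in self.counts.items() if fam == family
        )

    @property
    def assigned_total(self) -> int:
        return sum(self.counts.values())


def build_distribution(
    calls: Sequence[ContaminationCall],
    assignments: Sequence[FamilyAssignment],
    assemblies: Sequence[AssemblyRecord],
    flagged: Iterable[str] = (),
) -> DistributionTable:
    """Cross-tabulate assigned contigs by (family, host class) and compute
    contamination rates per project type and host class over assemblies.

    Flagged suspect contigs are excluded from the family rows (and from
    the unassigned total) but still count toward assembly contamination.
    """
    flagged_set = set(flagged)
    by_contig = {a.contig_id: a for a in assignments}
    table = DistributionTable(total_calls=len(calls))

    for call in calls:
        if call.contig_id in flagged_set:
            table.flagged_count += 1
            continue
        assignment = by_contig.get(call.contig_id)
        if assignment is None or assignment.family == UNASSIGNED:
            table.unassigned_count += 1
            continue
        key = (assignment.family, call.host_class)
        table.counts[key] = table.counts.get(key, 0) + 1
        if assignment.family not in table.family_paths:
            lineage = call.nt_best_lineage
            order = next(
                (n for n in lineage.names if n in MITE_ORDERS), None
            )
            table.family_paths[assignment.family] = (
                (order, assignment.family) if order else (assignment.family,)
            )

    for family in table.families():
        total = table.family_total(family)
        for (fam, hc), n in table.counts.items():
            if fam == family:
                table.row_percentages[(fam, hc)] = round_half_up(
                    100 * Decimal(n) / total, 1
                )

    contaminated_assemblies = {c.assembly_id for c in calls}
    groups: dict[str, list[AssemblyRecord]] = {"overall": list(assemblies)}
    for assembly in assemblies:
        groups.setdefault(assembly.project_type, []).append(assembly)
        groups.setdefault(assembly.host_class, []).append(assembly)
    for category, members in groups.items():
        if not members:
            continue
        n_cont = sum(
            1 for a in members if a.assembly_id in contaminated_assemblies
        )
        table.rates[category] = (
            n_cont, len(members), contamination_rate(n_cont, len(members))
        )
    return table


@dataclass
class WatchItem:
    """Watch-list entry: a family, its expected host group and reference
    sequences used to confirm the suspect identity."""

    family: str
    expected_host_classes: frozenset[str]
    references: list[SeqRecord] = field(default_factory=list)


#: Default watch-list: Demodicidae (follicle mites) are mammal skin
#: parasites; assignments from non-mammal hosts are candidate fortuitous
#: contaminations.  References must be supplied by the caller.
DEFAULT_WATCHLIST = {
    "Demodicidae": WatchItem("Demodicidae", frozenset({"Mammalia"})),
}


def flag_suspect_assignments(
    assignments: Sequence[FamilyAssignment],
    calls: Sequence[ContaminationCall],
    contigs: Mapping[str, SeqRecord],
    watchlist: Mapping[str, WatchItem] | None = None,
    cfg: ScreenConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> list[str]:
    """Contig ids whose assignment matches the suspect pattern.

    A contig is flagged when its family is on the watch-list, its host
    class falls outside the family's expected host group, and its identity
    to a watch-list reference sequence reaches ``suspect_identity_min``
    (default 96%).  Flagged contigs should be excluded from
    host-association tables but are retained in raw output.
    """
    cfg = cfg or ScreenConfig()
    watchlist = DEFAULT_WATCHLIST if watchlist is None else watchlist
    host_by_contig = {c.contig_id: c.host_class for c in calls}
    flagged: list[str] = []
    for assignment in assignments:
        item = watchlist.get(assignment.family)
        if item is None or not item.references:
            continue
        host = host_by_contig.get(assignment.contig_id)
        if host is None or host in item.expected_host_classes:
            continue
        contig = contigs.get(assignment.contig_id)
        if contig is None:
            continue
        hits = search(
            contig, item.references, scheme,
            max_hits=1, evalue_max=None, method="full",
        )
        if hits and hits[0].identity_pct >= cfg.suspect_identity_min:
            flagged.append(assignment.contig_id)
    return flagged


# --- tabular output ----------------------------------------------------------

def assignments_to_frame(
    assignments: Sequence[FamilyAssignment],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": a.contig_id,
                "family": a.family,
                "nt_subject": a.supporting_hit.subject_id,
                "identity_pct": a.identity_pct,
                "bitscore": a.supporting_hit.bitscore,
            }
            for a in assignments
        ],
        columns=["contig_id", "family", "nt_subject", "identity_pct",
                 "bitscore"],
    )


def distribution_to_frames(
    table: DistributionTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format (family, host_class, count, row_pct) plus rates table."""
    dist = pd.DataFrame(
        [
            {
                "family": fam,
                "host_class": hc,
                "count": n,
                "row_pct": table.row_percentages[(fam, hc)],
            }
            for (fam, hc), n in sorted(table.counts.items())
        ],
        columns=["family", "host_class", "count", "row_pct"],
    )
    rates = pd.DataFrame(
        [
            {
                "category": cat,
                "contaminated": c,
                "total": t,
                "pct": pct,
            }
            for cat, (c, t, pct) in sorted(table.rates.items())
        ],
        columns=["category", "contaminated", "total", "pct"],
    )
    return dist, rates
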