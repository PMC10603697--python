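"""Four-step elimination screen for mite contamination, plus detection of
misidentified reference-database records.

Candidate contigs from non-mite assemblies are eliminated sequentially if
they (1) are longer than 100,000 bp; (2) have no similarity to mite
barcodes (inclusion set); (3) are more similar to non-mite barcodes
(exclusion set) than to mite barcodes; or (4) have a best hit in the
nt-like reference database that lies outside Acari-minus-Ixodida or
aligns at under 80% identity.  A contig surviving all four steps is a
:class:`ContaminationCall`.

Step 4 can be defeated by reference records that are themselves mite
contamination annotated to the host species.  Such records are recognised
by their best-match pattern — 100% identity to themselves under a
non-mite label, with the second-best match to a mite sequence — and
contigs whose best nt hit is such a record are rescued rather than
eliminated, flagged with ``rescued_by_misid_rule``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .align import (
    AlignmentHit,
    ScoringScheme,
    SequenceDatabase,
    search,
)
from .io_formats import BarcodeRecord, SeqRecord
from .taxonomy import Lineage, host_class_of, is_mite_lineage

logger = logging.getLogger("mitescreen")

PROJECT_TYPES = ("WGS", "TSA")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the elimination screen and downstream assignment.

    ``sarcoptiformes_threshold`` records the stricter per-order assignment
    threshold; it is unused unless per-order thresholds are enabled in the
    assignment stage.
    """

    max_contig_len: int = 100_000
    min_nt_identity: float = 80.0
    step2_evalue_cutoff: float = 1e-5
    family_threshold: float = 91.4
    sarcoptiformes_threshold: float = 89.9
    min_coi_aa: int = 80
    suspect_identity_min: float = 96.0
    seed_k: int = 13
    search_method: str = "seeded"
    max_hits: int = 25

    def __post_init__(self) -> None:
        numeric = (
            self.max_contig_len, self.min_nt_identity,
            self.step2_evalue_cutoff, self.family_threshold,
            self.sarcoptiformes_threshold, self.min_coi_aa,
            self.suspect_identity_min,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all thresholds must be positive")
        if self.min_nt_identity > self.family_threshold:
            raise ValueError(
                "min_nt_identity must not exceed family_threshold"
            )


@dataclass
class AssemblyRecord:
    """One WGS or TSA assembly: its contigs plus project metadata."""

    assembly_id: str
    project_type: str
    host_lineage: Lineage
    contigs: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.project_type not in PROJECT_TYPES:
            raise ValueError(
                f"project_type must be one of {PROJECT_TYPES}, "
                f"got {self.project_type!r}"
            )

    @property
    def host_class(self) -> str:
        return host_class_of(self.host_lineage)


class StepVerdict(NamedTuple):
    step: int
    verdict: str  # "pass" | "eliminated"
    detail: str


@dataclass
class ContaminationCall:
    """A contig that survived all four elimination steps, with evidence."""

    contig_id: str
    assembly_id: str
    project_type: str
    host_class: str
    best_mite_hit: AlignmentHit
    nt_best_hit: AlignmentHit
    nt_best_lineage: Lineage
    best_nonmite_hit: Optional[AlignmentHit] = None
    step_trace: tuple[StepVerdict, ...] = ()
    rescued_by_misid_rule: bool = False


@dataclass
class MisidentifiedRecord:
    """A reference record annotated to the host but actually mite-derived."""

    record_id: str
    self_hit: AlignmentHit
    second_hit: AlignmentHit
    second_lineage: Lineage

    def __post_init__(self) -> None:
        if self.self_hit.identity_pct != 100.0:
            raise ValueError("self hit must have identity 100.0")
        if not is_mite_lineage(self.second_lineage):
            raise ValueError("second-best lineage must be mite")


@dataclass
class ScreenResult:
    """Output of :func:`run_screen`: calls plus per-assembly flags and
    per-step elimination counts."""

    calls: list[ContaminationCall]
    assembly_contaminated: dict[str, bool]
    step_counts: dict[str, int]
    misidentified: list[MisidentifiedRecord] = field(default_factory=list)


def _as_database(
    db: Union[SequenceDatabase, Sequence[SeqRecord], Sequence[BarcodeRecord]],
    seed_k: int,
) -> SequenceDatabase:
    if isinstance(db, SequenceDatabase):
        return db
    records = [
        r.to_seqrecord() if isinstance(r, BarcodeRecord) else r for r in db
    ]
    return SequenceDatabase(records, seed_k=seed_k)


# --- the four elimination steps ---------------------------------------------

def step1_length_filter(
    contigs: Iterable[SeqRecord], cfg: ScreenConfig | None = None
) -> list[SeqRecord]:
    """Retain contigs of at most ``max_contig_len`` bp (strictly longer
    contigs are eliminated; the boundary length itself is retained)."""
    cfg = cfg or ScreenConfig()
    return [c for c in contigs if len(c) <= cfg.max_contig_len]


def step2_inclusion_screen(
    contig: SeqRecord,
    inclusion_db: SequenceDatabase,
    cfg: ScreenConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> Optional[AlignmentHit]:
    """Best mite-barcode hit of the contig, or None (-> eliminate).

    "No similarity" is operationalised as no hit at the step-2 E-value
    cutoff (default 1e-5).
    """
    cfg = cfg or ScreenConfig()
    hits = search(
        contig, inclusion_db, scheme,
        max_hits=1, evalue_max=cfg.step2_evalue_cutoff,
        method=cfg.search_method, seed_k=cfg.seed_k,
    )
    return hits[0] if hits else None


def step3_comparative_screen(
    best_mite: AlignmentHit, best_nonmite: Optional[AlignmentHit]
) -> bool:
    """True (keep) unless the best non-mite hit scores strictly higher.

    Elimination requires being *more* similar to non-mite barcodes, so
    bitscore ties keep the contig.
    """
    if best_nonmite is None:
        return True
    return best_nonmite.bitscore <= best_mite.bitscore


def step4_passes(
    identity_pct: float, lineage: Lineage, cfg: ScreenConfig | None = None
) -> bool:
    """The step-4 retention rule on a best nt hit's evidence.

    Keep iff the lineage is mite (Acari exclusive of Ixodida) and the
    identity is at least ``min_nt_identity``; identity of exactly 80.0%
    is retained (the elimination clause is "less than 80%").
    """
    cfg = cfg or ScreenConfig()
    return is_mite_lineage(lineage) and identity_pct >= cfg.min_nt_identity


class Step4Result(NamedTuple):
    keep: bool
    nt_hit: Optional[AlignmentHit]
    nt_lineage: Optional[Lineage]
    rescued: bool
    detail: str


def step4_nt_verify(
    contig: SeqRecord,
    nt_db: SequenceDatabase,
    lineages: dict[str, Lineage],
    cfg: ScreenConfig | None = None,
    scheme: ScoringScheme | None = None,
    misid_cache: Optional[dict] = None,
) -> Step4Result:
    """Verify the candidate against the nt-like reference database.

    Keep iff the best-bitscore hit is mite (Acari exclusive of Ixodida)
    at >= 80% identity.  When the best hit is a non-mite record at
    sufficient identity, the misidentification rescue is attempted: if the
    record itself shows the 100%-self / second-best-mite pattern, the
    contig is kept with ``rescued=True``.
    """
    cfg = cfg or ScreenConfig()
    hits = search(
        contig, nt_db, scheme,
        max_hits=cfg.max_hits, evalue_max=cfg.step2_evalue_cutoff,
        method=cfg.search_method, seed_k=cfg.seed_k,
    )
    if not hits:
        return Step4Result(False, None, None, False, "no nt hit")
    best = hits[0]
    lineage = lineages.get(best.subject_id)
    if lineage is None:
        return Step4Result(
            False, best, None, False,
            f"no lineage for nt record {best.subject_id}",
        )
    if best.identity_pct < cfg.min_nt_identity:
        return Step4Result(
            False, best, lineage, False,
            f"best nt identity {best.identity_pct} < {cfg.min_nt_identity}",
        )
    if is_mite_lineage(lineage):
        return Step4Result(
            True, best, lineage, False,
            f"mite best hit {best.subject_id} at {best.identity_pct}%",
        )
    # best hit outside Acari-minus-Ixodida: try the misidentification rescue
    misid = None
    if misid_cache is not None and best.subject_id in misid_cache:
        misid = misid_cache[best.subject_id]
    else:
        record = next(
            (r for r in nt_db.records if r.id == best.subject_id), None
        )
        if record is not None:
            misid = check_record_misidentified(
                record, nt_db, lineages, cfg, scheme
            )
        if misid_cache is not None:
            misid_cache[best.subject_id] = misid
    if misid is not None:
        return Step4Result(
            True, best, lineage, True,
            f"rescued: nt record {best.subject_id} is misidentified "
            f"(second-best mite {misid.second_hit.subject_id})",
        )
    return Step4Result(
        False, best, lineage, False,
        f"best nt hit {best.subject_id} outside Acari (excl. Ixodida)",
    )


# --- misidentified reference records ----------------------------------------

def detect_nt_misidentification(
    query_hits: Sequence[AlignmentHit],
    lineages: dict[str, Lineage],
    source_lineage: Lineage,
) -> Optional[MisidentifiedRecord]:
    """Recognise the misidentification pattern in a record's ranked hits.

    Flags a record iff its top hit is a 100%-identity match to a non-mite
    record carrying the query's own source lineage (normally the record
    itself) while the second-best hit is a mite sequence.
    """
    if len(query_hits) < 2:
        return None
    top, second = query_hits[0], query_hits[1]
    if top.identity_pct != 100.0:
        return None
    top_lineage = lineages.get(top.subject_id)
    if top_lineage is None or is_mite_lineage(top_lineage):
        return None
    if top_lineage.names != source_lineage.names:
        return None
    second_lineage = lineages.get(second.subject_id)
    if second_lineage is None or not is_mite_lineage(second_lineage):
        return None
    return MisidentifiedRecord(
        record_id=top.query_id,
        self_hit=top,
        second_hit=second,
        second_lineage=second_lineage,
    )


def check_record_misidentified(
    record: SeqRecord,
    nt_db: SequenceDatabase,
    lineages: dict[str, Lineage],
    cfg: ScreenConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> Optional[MisidentifiedRecord]:
    """Search one reference record against its own database and apply
    :func:`detect_nt_misidentification`."""
    cfg = cfg or ScreenConfig()
    source = lineages.get(record.id)
    if source is None:
        return None
    hits = search(
        record, nt_db, scheme,
        max_hits=5, evalue_max=cfg.step2_evalue_cutoff,
        method=cfg.search_method, seed_k=cfg.seed_k,
    )
    return detect_nt_misidentification(hits, lineages, source)


def scan_reference_misidentifications(
    nt_db: Union[SequenceDatabase, Sequence[SeqRecord]],
    lineages: dict[str, Lineage],
    cfg: ScreenConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> list[MisidentifiedRecord]:
    """Scan every record of the reference database for the
    misidentification pattern (self best hit at 100%, mite second best)."""
    cfg = cfg or ScreenConfig()
    db = _as_database(nt_db, cfg.seed_k)
    found: list[MisidentifiedRecord] = []
    for record in db.records:
        misid = check_record_misidentified(record, db, lineages, cfg, scheme)
        if misid is not None:
            found.append(misid)
    return found


# --- the full screen ---------------------------------------------------------

def run_screen(
    assemblies: Sequence[AssemblyRecord],
    inclusion_db,
    exclusion_db,
    nt_db,
    lineages: dict[str, Lineage],
    cfg: ScreenConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> ScreenResult:
    """Apply steps 1-4 to every contig of every assembly.

    Per-contig processing is independent, so results are invariant under
    permutation of assemblies and of contigs within an assembly, and fully
    deterministic for fixed inputs.
    """
    cfg = cfg or ScreenConfig()
    inclusion = _as_database(inclusion_db, cfg.seed_k)
    exclusion = _as_database(exclusion_db, cfg.seed_k)
    nt = _as_database(nt_db, cfg.seed_k)
    if not inclusion.records or not nt.records:
        raise ValueError("inclusion and nt databases must be non-empty")

    counts = {
        "input": 0,
        "step1_eliminated": 0,
        "step2_eliminated": 0,
        "step3_eliminated": 0,
        "step4_eliminated": 0,
        "calls": 0,
        "rescued": 0,
    }
    calls: list[ContaminationCall] = []
    flags: dict[str, bool] = {}
    misid_cache: dict = {}
    misid_seen: dict[str, MisidentifiedRecord] = {}

    for assembly in assemblies:
        if not assembly.contigs:
            logger.warning(
                "assembly %s has zero contigs", assembly.assembly_id
            )
        n_calls_before = len(calls)
        for contig in assembly.contigs:
            counts["input"] += 1
            trace: list[StepVerdict] = []

            if len(contig) > cfg.max_contig_len:
                counts["step1_eliminated"] += 1
                continue
            trace.append(
                StepVerdict(1, "pass", f"length {len(contig)} bp")
            )

            mite_hit = step2_inclusion_screen(contig, inclusion, cfg, scheme)
            if mite_hit is None:
                counts["step2_eliminated"] += 1
                continue
            trace.append(
                StepVerdict(
                    2, "pass",
                    f"mite barcode {mite_hit.subject_id} "
                    f"bits={mite_hit.bitscore:.1f}",
                )
            )

            nonmite_hits = search(
                contig, exclusion, scheme,
                max_hits=1, evalue_max=cfg.step2_evalue_cutoff,
                method=cfg.search_method, seed_k=cfg.seed_k,
            ) if exclusion.records else []
            nonmite_hit = nonmite_hits[0] if nonmite_hits else None
            if not step3_comparative_screen(mite_hit, nonmite_hit):
                counts["step3_eliminated"] += 1
                continue
            trace.append(
                StepVerdict(
                    3, "pass",
                    "no stronger non-mite barcode hit"
                    if nonmite_hit is None
                    else f"non-mite bits={nonmite_hit.bitscore:.1f} "
                         f"<= mite bits={mite_hit.bitscore:.1f}",
                )
            )

            verdict = step4_nt_verify(
                contig, nt, lineages, cfg, scheme, misid_cache
            )
            if not verdict.keep:
                counts["step4_eliminated"] += 1
                continue
            trace.append(StepVerdict(4, "pass", verdict.detail))
            if verdict.rescued:
                counts["rescued"] += 1
                rescue = misid_cache.get(verdict.nt_hit.subject_id)
                if rescue is not None:
                    misid_seen.setdefault(rescue.record_id, rescue)
            counts["calls"] += 1
            calls.append(
                ContaminationCall(
                    contig_id=contig.id,
                    assembly_id=assembly.assembly_id,
                    project_type=assembly.project_type,
                    host_class=assembly.host_class,
                    best_mite_hit=mite_hit,
                    best_nonmite_hit=nonmite_hit,
                    nt_best_hit=verdict.nt_hit,
                    nt_best_lineage=verdict.nt_lineage,
                    step_trace=tuple(trace),
                    rescued_by_misid_rule=verdict.rescued,
                )
            )
        flags[assembly.assembly_id] = len(calls) > n_calls_before

    logger.info("screen elimination funnel: %s", counts)
    return ScreenResult(
        calls=calls,
        assembly_contaminated=flags,
        step_counts=counts,
        misidentified=list(misid_seen.values()),
    )


# --- tabular serialization ---------------------------------------------------

def calls_to_frame(calls: Sequence[ContaminationCall]) -> pd.DataFrame:
    """One row per call, with hit evidence and the step trace flattened."""
    rows = []
    for c in calls:
        rows.append(
            {
                "contig_id": c.contig_id,
                "assembly_id": c.assembly_id,
                "project_type": c.project_type,
                "host_class": c.host_class,
                "mite_subject": c.best_mite_hit.subject_id,
                "mite_bitscore": c.best_mite_hit.bitscore,
                "mite_identity": c.best_mite_hit.identity_pct,
                "nonmite_subject": (
                    c.best_nonmite_hit.subject_id
                    if c.best_nonmite_hit else ""
                ),
                "nonmite_bitscore": (
                    c.best_nonmite_hit.bitscore if c.best_nonmite_hit else ""
                ),
                "nt_subject": c.nt_best_hit.subject_id,
                "nt_identity": c.nt_best_hit.identity_pct,
                "nt_bitscore": c.nt_best_hit.bitscore,
                "nt_aln_len": c.nt_best_hit.aln_len,
                "nt_lineage": c.nt_best_lineage.to_string(),
                "rescued_by_misid_rule": c.rescued_by_misid_rule,
                "step_trace": ";".join(
                    f"{v.step}:{v.verdict}({v.detail})" for v in c.step_trace
                ),
            }
        )
    columns = [
        "contig_id", "assembly_id", "project_type", "host_class",
        "mite_subject", "mite_bitscore", "mite_identity",
        "nonmite_subject", "nonmite_bitscore",
        "nt_subject", "nt_identity", "nt_bitscore", "nt_aln_len",
        "nt_lineage", "rescued_by_misid_rule", "step_trace",
    ]
    return pd.DataFrame(rows, columns=columns)


def calls_from_frame(
    frame: pd.DataFrame, scheme: ScoringScheme | None = None
) -> list[ContaminationCall]:
    """Rebuild calls (with evidence reduced to the recorded hit fields)
    from a calls table, for running the assignment stage separately."""
    scheme = scheme or ScoringScheme()
    calls = []
    for row in frame.itertuples(index=False):
        def _hit(subject, bitscore, identity, aln_len=0):
            return AlignmentHit(
                query_id=row.contig_id,
                subject_id=subject,
                raw_score=scheme.raw_from_bitscore(float(bitscore)),
                bitscore=float(bitscore),
                identity_pct=float(identity),
                aln_len=int(aln_len),
                mismatches=0,
                gapopens=0,
                qstart=1, qend=1, sstart=1, send=1,
            )

        calls.append(
            ContaminationCall(
                contig_id=row.contig_id,
                assembly_id=row.assembly_id,
                project_type=row.project_type,
                host_class=row.host_class,
                best_mite_hit=_hit(
                    row.mite_subject, row.mite_bitscore, row.mite_identity
                ),
                best_nonmite_hit=None,
                nt_best_hit=_hit(
                    row.nt_subject, row.nt_bitscore, row.nt_identity,
                    getattr(row, "nt_aln_len", 0),
                ),
                nt_best_lineage=Lineage.from_string(row.nt_lineage),
                rescued_by_misid_rule=bool(row.rescued_by_misid_rule),
            )
        )
    return calls
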