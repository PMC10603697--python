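"""Lineage model, mite/non-mite partitioning and barcode summary statistics.

Mites are operationally defined as Acari exclusive of the tick order
Ixodida.  Because the four remaining Acari orders — Trombidiformes and
Sarcoptiformes (Acariformes), Mesostigmata and Holothyrida
(Parasitiformes) — are mutually exclusive and jointly exhaustive for
non-tick Acari, membership is decided purely by order names, with no
taxonomy-graph walk.  Lineages are name-based; no numeric taxids are
required, so synthetic taxonomies need no NCBI dump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .io_formats import BarcodeRecord

#: The four Acari orders counted as mites (ticks, i.e. Ixodida, excluded).
MITE_ORDERS = frozenset(
    {"Trombidiformes", "Sarcoptiformes", "Mesostigmata", "Holothyrida"}
)

#: Rank label used when a lineage has no taxon at rank "class".
UNRANKED = "unranked"


def round_half_up(value: float | Decimal, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as printed percentages are."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Lineage:
    """An ordered taxonomic lineage, root first.

    Each entry is a ``(rank, name)`` pair; ``rank`` is ``None`` when the
    source did not annotate it.  The string form joins names with commas,
    with annotated ranks written ``rank:Name`` (e.g.
    ``Animalia,Arthropoda,class:Insecta,Coleoptera,family:Carabidae``).
    """

    ranks: tuple[tuple[Optional[str], str], ...]

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("lineage must have at least one element")
        names = [name for _, name in self.ranks]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate taxon names in lineage: {names}")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        ranks: list[tuple[Optional[str], str]] = []
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            if ":" in token:
                rank, name = token.split(":", 1)
                ranks.append((rank.strip() or None, name.strip()))
            else:
                ranks.append((None, token))
        return cls(tuple(ranks))

    @classmethod
    def of_names(cls, names: Sequence[str]) -> "Lineage":
        return cls(tuple((None, n) for n in names))

    def to_string(self) -> str:
        return ",".join(f"{r}:{n}" if r else n for r, n in self.ranks)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.ranks)

    def name_at_rank(self, rank: str) -> Optional[str]:
        for r, name in self.ranks:
            if r == rank:
                return name
        return None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.names

    def __len__(self) -> int:
        return len(self.ranks)


def is_mite_lineage(lineage: Lineage) -> bool:
    """True iff the lineage falls in Acari exclusive of Ixodida.

    Decided by presence of any of the four mite order names
    (:data:`MITE_ORDERS`); a tick lineage (Ixodida) carries none of them
    and is therefore excluded.
    """
    return any(name in MITE_ORDERS for name in lineage.names)


def host_class_of(lineage: Lineage) -> str:
    """The taxon at rank ``class`` (e.g. Insecta, Magnoliopsida).

    Returns :data:`UNRANKED` when the lineage has no annotated class rank.
    """
    return lineage.name_at_rank("class") or UNRANKED


def family_of(lineage: Lineage) -> Optional[str]:
    """The taxon at rank ``family``, or None when the lineage lacks one.

    Falls back to the zoological family suffix ``-idae`` when ranks are
    unannotated.
    """
    name = lineage.name_at_rank("family")
    if name is not None:
        return name
    for taxon in reversed(lineage.names):
        if taxon.endswith("idae"):
            return taxon
    return None


def partition_barcodes(
    records: Iterable["BarcodeRecord"],
) -> tuple[list["BarcodeRecord"], list["BarcodeRecord"]]:
    """Split barcodes into (inclusion, exclusion) = (mite, non-mite) sets.

    The two lists are a disjoint cover of the input; order is preserved.
    Tick (Ixodida) barcodes land in the exclusion set.
    """
    inclusion: list["BarcodeRecord"] = []
    exclusion: list["BarcodeRecord"] = []
    for rec in records:
        (inclusion if is_mite_lineage(rec.lineage) else exclusion).append(rec)
    return inclusion, exclusion


@dataclass
class BarcodeSummary:
    """Counts of barcodes by Acari order and by marker gene.

    Percentages are derived as 100 x count / total, reported half-up to
    the nearest integer for orders and to one decimal for markers.
    """

    counts_by_order: dict[str, int] = field(default_factory=dict)
    counts_by_marker: dict[str, int] = field(default_factory=dict)
    total: int = 0

    @classmethod
    def from_counts(
        cls, by_order: dict[str, int], by_marker: dict[str, int]
    ) -> "BarcodeSummary":
        t_order, t_marker = sum(by_order.values()), sum(by_marker.values())
        if by_order and by_marker and t_order != t_marker:
            raise ValueError(
                f"order total {t_order} != marker total {t_marker}"
            )
        return cls(dict(by_order), dict(by_marker), max(t_order, t_marker))

    def order_percentages(self) -> dict[str, int]:
        if self.total == 0:
            return {}
        return {
            order: int(round_half_up(100 * Decimal(n) / self.total, 0))
            for order, n in self.counts_by_order.items()
        }

    def marker_percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        return {
            marker: round_half_up(100 * Decimal(n) / self.total, 1)
            for marker, n in self.counts_by_marker.items()
        }

    def marker_share(self, prefix: str) -> float:
        """Combined percentage (1 decimal) of markers named with ``prefix``.

        ``marker_share("COI")`` pools COI-5P and COI-3P into the share of
        COI-related barcodes.
        """
        if self.total == 0:
            return 0.0
        n = sum(
            c for m, c in self.counts_by_marker.items() if m.startswith(prefix)
        )
        return round_half_up(100 * Decimal(n) / self.total, 1)


def summarize_barcodes(records: Iterable["BarcodeRecord"]) -> BarcodeSummary:
    """Tabulate mite barcodes by Acari order and by marker gene."""
    by_order: dict[str, int] = {}
    by_marker: dict[str, int] = {}
    total = 0
    for rec in records:
        total += 1
        for name in rec.lineage.names:
            if name in MITE_ORDERS:
                by_order[name] = by_order.get(name, 0) + 1
                break
        by_marker[rec.marker] = by_marker.get(rec.marker, 0) + 1
    return BarcodeSummary(by_order, by_marker, total)
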