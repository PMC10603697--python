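"""Extraction of COI peptide regions from contaminated contigs for
external phylogenetic analysis.

The region of the contig spanned by its best COI-barcode hit is
translated with the invertebrate mitochondrial genetic code (NCBI
translation table 5) on the hit's strand; the longest stop-free stretch
is kept, and only peptides strictly longer than 80 amino acids are
exported.  This hit-guided translation is a deliberate simplification of
full mitogenome gene annotation: it recovers the barcode-spanning COI
fragment, which is what downstream alignment and tree inference consume,
but does not annotate other mitochondrial genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq

from .align import AlignmentHit, revcomp
from .io_formats import PathLike, SeqRecord
from .screen import ContaminationCall, ScreenConfig

#: NCBI genetic code for invertebrate mitochondria.
INVERTEBRATE_MITO_TABLE = 5


@dataclass
class CoiPeptide:
    """A predicted COI peptide: contig, reading frame and protein sequence.

    ``frame`` is +1..+3 on the hit strand of the contig and -1..-3 on the
    reverse complement.
    """

    contig_id: str
    frame: int
    aa_seq: str
    aa_len: int

    def __post_init__(self) -> None:
        if "*" in self.aa_seq:
            raise ValueError("exported peptides must not contain stops")


def extract_coi_peptide(
    contig: SeqRecord,
    guide_hit: AlignmentHit,
    cfg: ScreenConfig | None = None,
) -> Optional[CoiPeptide]:
    """Translate the barcode-hit region of a contig into a COI peptide.

    The guide hit (the contig's best hit to a COI barcode) provides the
    region and strand.  All three frames of the region are translated with
    the invertebrate mitochondrial code; the longest stop-free stretch
    wins (ties broken by lower frame).  Returns None when that stretch is
    not longer than ``min_coi_aa`` (default 80 aa) or the region is
    shorter than one codon.
    """
    cfg = cfg or ScreenConfig()
    region = contig.seq[guide_hit.qstart - 1 : guide_hit.qend]
    minus = guide_hit.strand == "-"
    if minus:
        region = revcomp(region)
    if len(region) < 3:
        return None
    best: Optional[tuple[int, int, str]] = None  # (-len, frame_idx, peptide)
    for offset in range(3):
        sub = region[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate(table=INVERTEBRATE_MITO_TABLE))
        longest = max(aa.split("*"), key=len, default="")
        candidate = (-len(longest), offset, longest)
        if best is None or candidate < best:
            best = candidate
    if best is None:
        return None
    neg_len, offset, peptide = best
    if len(peptide) <= cfg.min_coi_aa:
        return None
    frame = offset + 1
    return CoiPeptide(
        contig_id=contig.id,
        frame=-frame if minus else frame,
        aa_seq=peptide,
        aa_len=len(peptide),
    )


def extract_call_peptides(
    calls: Iterable[ContaminationCall],
    contigs: Mapping[str, SeqRecord],
    cfg: ScreenConfig | None = None,
) -> list[CoiPeptide]:
    """COI peptides for every contamination call whose barcode-guided
    region yields a clean stretch above the length cutoff."""
    peptides = []
    for call in calls:
        contig = contigs.get(call.contig_id)
        if contig is None:
            continue
        pep = extract_coi_peptide(contig, call.best_mite_hit, cfg)
        if pep is not None:
            peptides.append(pep)
    return peptides


def write_coi_peptides(
    peptides: Iterable[CoiPeptide], path: PathLike
) -> None:
    """Write peptides as protein FASTA (input to external MAFFT/IQ-TREE)."""
    with open(path, "w") as fh:
        for pep in peptides:
            fh.write(f">{pep.contig_id} frame={pep.frame:+d} len={pep.aa_len}\n")
            for i in range(0, len(pep.aa_seq), 70):
                fh.write(pep.aa_seq[i : i + 70] + "\n")
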