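"""On-disk formats: FASTA, BOLD-style barcode headers, tabular hit files,
Krona text, lineage tables and the ground-truth manifest.

FASTA parsing/writing is delegated to Bio.SeqIO; this module adds the
contracts the pipeline relies on (uppercasing, unique non-empty records,
named format errors) and the pipe-delimited barcode-header dialect in
which the lineage is a single comma-joined field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .taxonomy import Lineage

PathLike = Union[str, os.PathLike]


class FastaFormatError(ValueError):
    """A FASTA or barcode-header record violating the format contract."""


@dataclass(frozen=True)
class SeqRecord:
    """One DNA sequence: contig, barcode or reference record."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid record id {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BarcodeRecord:
    """A reference DNA barcode with its marker code and source lineage."""

    id: str
    marker: str
    lineage: Lineage
    seq: str

    def __post_init__(self) -> None:
        if not self.marker:
            raise ValueError(f"barcode {self.id!r} has an empty marker")

    def to_seqrecord(self) -> SeqRecord:
        return SeqRecord(id=self.id, seq=self.seq)


@dataclass(frozen=True)
class BarcodeHeaderSpec:
    """Field layout of a pipe-delimited barcode header.

    BOLD exports vary; the default matches ``id|marker|lineage`` where the
    lineage field is comma-joined, e.g.
    ``X1|COI-5P|Animalia,Arthropoda,Arachnida,Trombidiformes,Tetranychidae``.
    """

    sep: str = "|"
    id_field: int = 0
    marker_field: int = 1
    lineage_field: int = 2


class BarcodePartition(NamedTuple):
    classified: list[BarcodeRecord]
    unclassified: list[SeqRecord]


def read_fasta(path: PathLike) -> list[SeqRecord]:
    """Read a (multi-)FASTA file into uppercased records, order preserved.

    Raises :class:`FastaFormatError` naming the offending record for empty
    sequences or duplicate ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        description = rec.description if rec.description != rec.id else ""
        records.append(
            SeqRecord(
                id=rec.id,
                seq=str(rec.seq).upper(),
                description=description,
            )
        )
    return records


def write_fasta(
    records: Iterable[SeqRecord], path: PathLike, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description if rec.description.startswith(rec.id) \
                    else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_barcode_fasta(
    path: PathLike, header_spec: BarcodeHeaderSpec | None = None
) -> BarcodePartition:
    """Read a barcode library with pipe-delimited, lineage-bearing headers.

    Returns ``(classified, unclassified)``: records whose lineage field is
    empty or missing are not dropped silently but returned as plain
    sequences in the second list.  A header with no field separator at all
    is a format error.
    """
    spec = header_spec or BarcodeHeaderSpec()
    classified: list[BarcodeRecord] = []
    unclassified: list[SeqRecord] = []
    for rec in read_fasta(path):
        header = rec.description or rec.id
        if spec.sep not in header:
            raise FastaFormatError(
                f"barcode header {header!r} has no {spec.sep!r} separator"
            )
        fields = header.split(spec.sep)
        try:
            rec_id = fields[spec.id_field].strip()
            marker = fields[spec.marker_field].strip()
            lineage_text = fields[spec.lineage_field].strip()
        except IndexError:
            rec_id, marker, lineage_text = fields[0].strip(), "", ""
        if not lineage_text or not marker:
            unclassified.append(SeqRecord(id=rec_id or rec.id, seq=rec.seq))
            continue
        classified.append(
            BarcodeRecord(
                id=rec_id,
                marker=marker,
                lineage=Lineage.from_string(lineage_text),
                seq=rec.seq,
            )
        )
    return BarcodePartition(classified, unclassified)


def write_barcode_fasta(
    records: Iterable[BarcodeRecord],
    path: PathLike,
    header_spec: BarcodeHeaderSpec | None = None,
) -> None:
    """Inverse of :func:`read_barcode_fasta` for the default 3-field layout."""
    spec = header_spec or BarcodeHeaderSpec()
    with open(path, "w") as fh:
        for rec in records:
            fields = ["", "", ""]
            fields[spec.id_field] = rec.id
            fields[spec.marker_field] = rec.marker
            fields[spec.lineage_field] = rec.lineage.to_string()
            fh.write(">" + spec.sep.join(fields) + "\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


# --- tabular hit files (BLAST outfmt-6 column order) -----------------------

HITS_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def write_hits_table(hits: Iterable, path: PathLike) -> None:
    """Write hits as 12-column tab-separated rows in BLAST outfmt-6 order.

    Floats are written at full precision (``repr``) so that a
    write-then-read round trip through :func:`read_hits_table` is lossless
    on all 12 fields.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        repr(h.identity_pct),
                        h.aln_len,
                        h.mismatches,
                        h.gapopens,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        repr(h.evalue),
                        repr(h.bitscore),
                    )
                )
                + "\n"
            )


def read_hits_table(path: PathLike, scheme=None) -> list:
    """Read a 12-column outfmt-6 hits table.

    The raw alignment score is not an outfmt-6 column; it is recovered by
    inverting the bitscore under ``scheme`` (default scoring scheme when
    omitted).  Minus-strand hits are recognised by descending subject
    coordinates, as in BLAST.
    """
    from .align import AlignmentHit, ScoringScheme

    scheme = scheme or ScoringScheme()
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FastaFormatError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, "
                    f"got {len(parts)}"
                )
            (qid, sid, pident, length, mism, gapo,
             qs, qe, ss, se, ev, bits) = parts[:12]
            sstart, send = int(ss), int(se)
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    raw_score=scheme.raw_from_bitscore(float(bits)),
                    bitscore=float(bits),
                    identity_pct=float(pident),
                    aln_len=int(length),
                    mismatches=int(mism),
                    gapopens=int(gapo),
                    qstart=int(qs),
                    qend=int(qe),
                    sstart=sstart,
                    send=send,
                    strand="-" if sstart > send else "+",
                    evalue=float(ev),
                )
            )
    return hits


# --- Krona text import format ----------------------------------------------

def write_krona_text(table, path: PathLike) -> None:
    """Write a distribution table in Krona's tab-delimited text dialect.

    One line per leaf taxon: count, then the lineage ranks, all
    tab-separated.  The count column sums to the number of assigned
    contigs in the table.
    """
    with open(path, "w") as fh:
        for family in sorted(table.families()):
            count = table.family_total(family)
            if count <= 0:
                continue
            path_ranks = table.family_paths.get(family, (family,))
            fh.write(str(count) + "\t" + "\t".join(path_ranks) + "\n")


# --- lineage tables ---------------------------------------------------------

def read_lineage_table(path: PathLike) -> dict[str, Lineage]:
    """Read a 2-column TSV mapping sequence id -> comma-joined lineage.

    Rank annotations of the form ``class:Insecta`` are allowed inside the
    lineage field.
    """
    table: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FastaFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            table[parts[0]] = Lineage.from_string(parts[1])
    return table


def write_lineage_table(table: dict[str, Lineage], path: PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id, lineage in table.items():
            fh.write(f"{seq_id}\t{lineage.to_string()}\n")


# --- ground-truth manifest --------------------------------------------------

class TruthRow(NamedTuple):
    """One contig's ground-truth label in a synthetic run."""

    contig_id: str
    assembly_id: str
    label: str  # host | mite-contaminant | ixodida-decoy
    source_family: str = ""


def write_truth_table(rows: Iterable[TruthRow], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tassembly_id\tlabel\tsource_family\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_truth_table(path: PathLike) -> list[TruthRow]:
    rows: list[TruthRow] = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("contig_id\t"):
            raise FastaFormatError(f"{path}: missing truth-table header")
        for line in fh:
            line = line.rstrip("\n")
            if line:
                parts = line.split("\t")
                rows.append(TruthRow(*parts[:4]))
    return rows
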