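"""Synthetic data with known ground truth for exercising the pipeline.

Generates, deterministically from a seed: a barcode library partitioned
into mite (inclusion) and non-mite (exclusion) sets; host assemblies with
mite-derived contaminant contigs injected at a controlled divergence and
per-assembly contamination probability; an nt-like reference database
(barcode-bearing mite records plus unrelated non-mite records, optionally
with planted misidentified records); and a per-contig truth manifest.

The substitution model is i.i.d. per-site replacement with a uniform
choice among the three alternative bases (Jukes–Cantor-like), no indels
by default, which keeps identity ~ 1 - divergence arithmetic exact for
threshold tests.  Host contigs are i.i.d. random sequence rather than
genome-derived: the screen only requires them to be alignment-negative
against the barcode library.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .align import ScoringScheme
from .assign_report import UNASSIGNED, FamilyAssignment, contamination_rate
from .io_formats import (
    BarcodeRecord,
    SeqRecord,
    TruthRow,
    read_barcode_fasta,
    read_fasta,
    read_lineage_table,
    read_truth_table,
    write_barcode_fasta,
    write_fasta,
    write_lineage_table,
    write_truth_table,
)
from .screen import AssemblyRecord, ContaminationCall
from .taxonomy import Lineage

_BASES = np.array(list("ACGT"))

#: (order, family) pairs used for synthetic mite families, cycled when
#: more families are requested.  Names follow common mite families so the
#: synthetic lineages read like real ones.
MITE_FAMILY_POOL = [
    ("Trombidiformes", "Tetranychidae"),
    ("Sarcoptiformes", "Acaridae"),
    ("Mesostigmata", "Phytoseiidae"),
    ("Trombidiformes", "Eriophyidae"),
    ("Mesostigmata", "Macrochelidae"),
    ("Sarcoptiformes", "Pyroglyphidae"),
    ("Trombidiformes", "Trombidiidae"),
    ("Holothyrida", "Allothyridae"),
    ("Sarcoptiformes", "Histiostomatidae"),
    ("Trombidiformes", "Demodicidae"),
]

#: Default host classes with lineages and sampling weights, echoing the
#: host spectrum of public WGS/TSA projects (insects, flowering plants,
#: conifers, bony fishes, corals).
HOST_CLASS_DEFAULTS: list[tuple[str, str, float]] = [
    ("Insecta",
     "Animalia,Arthropoda,class:Insecta,Coleoptera,family:Carabidae", 0.35),
    ("Magnoliopsida",
     "Plantae,Streptophyta,class:Magnoliopsida,Fagales,family:Fagaceae", 0.30),
    ("Pinopsida",
     "Plantae,Streptophyta,class:Pinopsida,Pinales,family:Pinaceae", 0.10),
    ("Actinopteri",
     "Animalia,Chordata,class:Actinopteri,Perciformes,family:Percidae", 0.15),
    ("Anthozoa",
     "Animalia,Cnidaria,class:Anthozoa,Scleractinia,family:Acroporidae", 0.10),
]

TERMITE_LINEAGE = (
    "Animalia,Arthropoda,class:Insecta,Blattodea,family:Termopsidae"
)

IXODIDA_LINEAGE = (
    "Animalia,Arthropoda,class:Arachnida,order:Ixodida,family:Ixodidae"
)

NONMITE_BARCODE_LINEAGES = [
    "Animalia,Arthropoda,class:Insecta,Coleoptera,family:Carabidae",
    "Animalia,Arthropoda,class:Insecta,Lepidoptera,family:Noctuidae",
    "Animalia,Chordata,class:Aves,Passeriformes,family:Turdidae",
    "Animalia,Chordata,class:Actinopteri,Cypriniformes,family:Cyprinidae",
    "Plantae,Streptophyta,class:Magnoliopsida,Rosales,family:Rosaceae",
    "Animalia,Arthropoda,class:Arachnida,Araneae,family:Salticidae",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic study, deterministic given ``seed``."""

    seed: int
    n_mite_families: int = 5
    barcodes_per_family: int = 10
    barcode_len: int = 658  # COI-5P barcode length
    intra_family_div: float = 0.03
    n_nonmite_barcodes: int = 40
    n_ixodida_barcodes: int = 5
    n_assemblies: int = 200
    host_classes: tuple[tuple[str, str, float], ...] = tuple(
        HOST_CLASS_DEFAULTS
    )
    contigs_per_assembly: int = 10
    contig_len_range: tuple[int, int] = (500, 3000)
    contamination_prob: float = 0.2
    contaminant_div: float = 0.05
    contaminant_indel_prob: float = 0.0
    ixodida_decoy_prob: float = 0.0
    plant_misid: bool = False
    n_misid: int = 2
    misid_div: float = 0.03
    n_nonmite_nt: int = 15
    tsa_fraction: float = 0.34

    def __post_init__(self) -> None:
        for p in (self.contamination_prob, self.ixodida_decoy_prob,
                  self.tsa_fraction, self.contaminant_indel_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for d in (self.intra_family_div, self.contaminant_div,
                  self.misid_div):
            if not 0.0 <= d <= 0.35:
                raise ValueError("divergences must lie in [0, 0.35]")
        if self.contig_len_range[0] > self.contig_len_range[1]:
            raise ValueError("contig_len_range must be (min, max)")

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["host_classes"] = [list(h) for h in self.host_classes]
        data["contig_len_range"] = list(self.contig_len_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticDesign":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "host_classes" in data:
            data["host_classes"] = tuple(
                tuple(h) for h in data["host_classes"]
            )
        if "contig_len_range" in data:
            data["contig_len_range"] = tuple(data["contig_len_range"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-contig labels and per-assembly contamination flags."""

    labels: dict[str, str] = field(default_factory=dict)
    source_family: dict[str, str] = field(default_factory=dict)
    assembly_contaminated: dict[str, bool] = field(default_factory=dict)

    @property
    def injected_contigs(self) -> set[str]:
        return {
            cid for cid, label in self.labels.items()
            if label == "mite-contaminant"
        }

    def rows(self, assembly_of: dict[str, str]) -> list[TruthRow]:
        return [
            TruthRow(cid, assembly_of[cid], label,
                     self.source_family.get(cid, ""))
            for cid, label in self.labels.items()
        ]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def mutate_sequence(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    indel_prob: float = 0.0,
) -> str:
    """Substitute each site with probability ``divergence`` (uniform over
    the three alternative bases); optional geometric-length indels."""
    chars = list(seq)
    if divergence > 0:
        hits = np.nonzero(rng.random(len(chars)) < divergence)[0]
        for i in hits:
            alternatives = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alternatives[int(rng.integers(3))]
    if indel_prob > 0:
        out: list[str] = []
        for c in chars:
            r = rng.random()
            if r < indel_prob / 2:  # deletion
                continue
            out.append(c)
            if indel_prob / 2 <= r < indel_prob:  # insertion
                length = int(rng.geometric(0.5))
                out.extend(rng.choice(_BASES, size=length))
        chars = out or ["A"]
    return "".join(chars)


def _family_catalog(design: SyntheticDesign) -> list[tuple[str, str]]:
    catalog = []
    for i in range(design.n_mite_families):
        order, family = MITE_FAMILY_POOL[i % len(MITE_FAMILY_POOL)]
        if i >= len(MITE_FAMILY_POOL):
            family = f"{family}{i}"  # keep family names unique
        catalog.append((order, family))
    return catalog


def _mite_lineage(order: str, family: str) -> Lineage:
    return Lineage.from_string(
        f"Animalia,Arthropoda,class:Arachnida,order:{order},family:{family}"
    )


def simulate_barcode_library(
    design: SyntheticDesign,
) -> tuple[list[BarcodeRecord], list[BarcodeRecord]]:
    """Generate the (inclusion, exclusion) barcode sets.

    Family founders are i.i.d. uniform random sequences; family members
    are founder copies mutated at ``intra_family_div`` per site.  Marker
    codes are drawn with COI-5P dominant, echoing the composition of real
    barcode libraries.  The exclusion set holds non-mite barcodes plus
    Ixodida (tick) decoys, which by definition are not mites.
    """
    rng = np.random.default_rng([1, design.seed])
    inclusion: list[BarcodeRecord] = []
    for fam_idx, (order, family) in enumerate(_family_catalog(design)):
        founder = _random_seq(rng, design.barcode_len)
        lineage = _mite_lineage(order, family)
        for j in range(design.barcodes_per_family):
            seq = mutate_sequence(founder, design.intra_family_div, rng)
            marker = ["COI-5P", "COI-3P", "18S"][
                int(rng.choice(3, p=[0.96, 0.025, 0.015]))
            ]
            inclusion.append(
                BarcodeRecord(
                    id=f"MITE{fam_idx:02d}-{j:03d}",
                    marker=marker,
                    lineage=lineage,
                    seq=seq,
                )
            )
    exclusion: list[BarcodeRecord] = []
    for j in range(design.n_nonmite_barcodes):
        lineage = Lineage.from_string(
            NONMITE_BARCODE_LINEAGES[j % len(NONMITE_BARCODE_LINEAGES)]
        )
        exclusion.append(
            BarcodeRecord(
                id=f"NONMITE-{j:03d}",
                marker="COI-5P",
                lineage=lineage,
                seq=_random_seq(rng, design.barcode_len),
            )
        )
    tick_founder = _random_seq(rng, design.barcode_len)
    for j in range(design.n_ixodida_barcodes):
        exclusion.append(
            BarcodeRecord(
                id=f"IXOD-{j:03d}",
                marker="COI-5P",
                lineage=Lineage.from_string(IXODIDA_LINEAGE),
                seq=mutate_sequence(tick_founder, design.intra_family_div,
                                    rng),
            )
        )
    return inclusion, exclusion


def _embed(
    rng: np.random.Generator,
    insert: str,
    design: SyntheticDesign,
) -> str:
    """Embed an insert in random flanks to a total length drawn from the
    design's contig length range (at least insert + 80 bp of flank)."""
    lo, hi = design.contig_len_range
    total_min = max(lo, len(insert) + 80)
    total_max = max(hi, total_min + 1)
    total = int(rng.integers(total_min, total_max + 1))
    left = int(rng.integers(0, total - len(insert) + 1))
    right = total - len(insert) - left
    return _random_seq(rng, left) + insert + _random_seq(rng, right)


def simulate_assemblies(
    design: SyntheticDesign,
    inclusion: Sequence[BarcodeRecord],
    exclusion: Sequence[BarcodeRecord] = (),
) -> tuple[list[AssemblyRecord], GroundTruth]:
    """Generate host assemblies with injected contaminants and the truth.

    Each assembly draws a host class and project type, gets i.i.d. random
    host contigs, and with probability ``contamination_prob`` receives one
    or more contaminant contigs: a randomly chosen inclusion barcode
    mutated at ``contaminant_div`` per site, embedded in random flanks.
    Optional Ixodida decoy contigs are built the same way from tick
    barcodes in the exclusion set; they are not mite contamination.
    """
    if not inclusion:
        raise ValueError("inclusion set must be non-empty")
    rng = np.random.default_rng([2, design.seed])
    weights = np.array([w for _, _, w in design.host_classes], dtype=float)
    weights = weights / weights.sum()
    ticks = [r for r in exclusion if "Ixodida" in r.lineage.names]

    assemblies: list[AssemblyRecord] = []
    truth = GroundTruth()
    lo, hi = design.contig_len_range
    for a in range(design.n_assemblies):
        assembly_id = f"ASM{a:04d}"
        host_idx = int(rng.choice(len(design.host_classes), p=weights))
        _, host_lineage_text, _ = design.host_classes[host_idx]
        project_type = "TSA" if rng.random() < design.tsa_fraction else "WGS"
        contigs: list[SeqRecord] = []
        for j in range(design.contigs_per_assembly):
            length = int(rng.integers(lo, hi + 1))
            cid = f"{assembly_id}.c{j:04d}"
            contigs.append(SeqRecord(id=cid, seq=_random_seq(rng, length)))
            truth.labels[cid] = "host"
        contaminated = rng.random() < design.contamination_prob
        if contaminated:
            n_cont = 1 + int(rng.poisson(0.3))
            for k in range(n_cont):
                source = inclusion[int(rng.integers(len(inclusion)))]
                insert = mutate_sequence(
                    source.seq, design.contaminant_div, rng,
                    indel_prob=design.contaminant_indel_prob,
                )
                cid = f"{assembly_id}.mite{k:02d}"
                contigs.append(
                    SeqRecord(id=cid, seq=_embed(rng, insert, design))
                )
                truth.labels[cid] = "mite-contaminant"
                truth.source_family[cid] = source.lineage.name_at_rank(
                    "family"
                ) or ""
        if ticks and rng.random() < design.ixodida_decoy_prob:
            source = ticks[int(rng.integers(len(ticks)))]
            insert = mutate_sequence(source.seq, design.contaminant_div, rng)
            cid = f"{assembly_id}.tick00"
            contigs.append(SeqRecord(id=cid, seq=_embed(rng, insert, design)))
            truth.labels[cid] = "ixodida-decoy"
        truth.assembly_contaminated[assembly_id] = contaminated
        assemblies.append(
            AssemblyRecord(
                assembly_id=assembly_id,
                project_type=project_type,
                host_lineage=Lineage.from_string(host_lineage_text),
                contigs=contigs,
            )
        )
    return assemblies, truth


def simulate_reference_db(
    design: SyntheticDesign,
    inclusion: Sequence[BarcodeRecord],
) -> tuple[list[SeqRecord], dict[str, Lineage]]:
    """Generate the nt-like database and its lineage table.

    Every inclusion barcode gets one mitogenome-like record (the barcode
    embedded in random flanks) under its own mite lineage — mirroring the
    fact that barcoded specimens are routinely also deposited in GenBank —
    plus unrelated non-mite records under host lineages.  When
    ``plant_misid`` is set, records whose sequence is mite-derived but
    whose lineage is a non-mite host (the misidentification pattern) are
    planted, one per family for the first ``n_misid`` families.
    """
    rng = np.random.default_rng([3, design.seed])
    records: list[SeqRecord] = []
    lineages: dict[str, Lineage] = {}
    for barcode in inclusion:
        flank_l = _random_seq(rng, int(rng.integers(150, 301)))
        flank_r = _random_seq(rng, int(rng.integers(150, 301)))
        rec_id = f"NTR-{barcode.id}"
        records.append(
            SeqRecord(id=rec_id, seq=flank_l + barcode.seq + flank_r)
        )
        lineages[rec_id] = barcode.lineage
    host_pool = [text for _, text, _ in design.host_classes]
    for j in range(design.n_nonmite_nt):
        rec_id = f"NTX-{j:03d}"
        records.append(
            SeqRecord(
                id=rec_id, seq=_random_seq(rng, int(rng.integers(800, 1501)))
            )
        )
        lineages[rec_id] = Lineage.from_string(
            host_pool[j % len(host_pool)]
        )
    if design.plant_misid:
        per_family = design.barcodes_per_family
        for k in range(design.n_misid):
            basis = inclusion[(k * per_family) % len(inclusion)]
            core = mutate_sequence(basis.seq, design.misid_div, rng)
            flank_l = _random_seq(rng, int(rng.integers(50, 121)))
            flank_r = _random_seq(rng, int(rng.integers(50, 121)))
            rec_id = f"MISID{k:02d}"
            records.append(
                SeqRecord(id=rec_id, seq=flank_l + core + flank_r)
            )
            lineages[rec_id] = Lineage.from_string(TERMITE_LINEAGE)
    return records, lineages


@dataclass
class SyntheticDataset:
    """A complete simulated study: library, assemblies, references, truth."""

    design: SyntheticDesign
    inclusion: list[BarcodeRecord]
    exclusion: list[BarcodeRecord]
    assemblies: list[AssemblyRecord]
    nt_records: list[SeqRecord]
    lineages: dict[str, Lineage]
    truth: GroundTruth

    @property
    def contigs(self) -> dict[str, SeqRecord]:
        return {
            c.id: c for a in self.assemblies for c in a.contigs
        }


def simulate_dataset(design: SyntheticDesign) -> SyntheticDataset:
    """Run all generators for one design (deterministic given the seed)."""
    inclusion, exclusion = simulate_barcode_library(design)
    assemblies, truth = simulate_assemblies(design, inclusion, exclusion)
    nt_records, lineages = simulate_reference_db(design, inclusion)
    return SyntheticDataset(
        design=design,
        inclusion=inclusion,
        exclusion=exclusion,
        assemblies=assemblies,
        nt_records=nt_records,
        lineages=lineages,
        truth=truth,
    )


@dataclass
class RecoveryMetrics:
    """How well the screen recovered the designed ground truth."""

    sensitivity: float
    fdr: float
    family_accuracy: float
    recovered_rate_pct: float
    rate_error: Optional[float]
    n_injected: int
    n_calls: int
    n_assigned_true: int


def evaluate_against_truth(
    calls: Sequence[ContaminationCall],
    assignments: Sequence[FamilyAssignment],
    truth: GroundTruth,
    designed_rate_pct: Optional[float] = None,
) -> RecoveryMetrics:
    """Sensitivity, FDR, family accuracy and rate recovery vs the truth.

    Sensitivity = detected true contaminants / injected contaminants;
    FDR = false calls / all calls (0/0 -> 0); family accuracy is taken
    over assigned true contaminants (vacuously 1.0 when none is
    assigned); the recovered contamination rate is the percentage of
    assemblies with at least one call.
    """
    known = set(truth.labels)
    unknown = [c.contig_id for c in calls if c.contig_id not in known]
    if unknown:
        raise ValueError(f"calls reference contigs not in truth: {unknown[:5]}")
    injected = truth.injected_contigs
    detected = {c.contig_id for c in calls}
    true_hits = detected & injected
    sensitivity = len(true_hits) / len(injected) if injected else 1.0
    fdr = len(detected - injected) / len(detected) if detected else 0.0

    assigned_true = [
        a for a in assignments
        if a.family != UNASSIGNED and a.contig_id in injected
    ]
    if assigned_true:
        correct = sum(
            1 for a in assigned_true
            if a.family == truth.source_family.get(a.contig_id)
        )
        family_accuracy = correct / len(assigned_true)
    else:
        family_accuracy = 1.0

    contaminated_assemblies = {c.assembly_id for c in calls}
    n_assemblies = len(truth.assembly_contaminated)
    recovered = contamination_rate(
        sum(1 for a in truth.assembly_contaminated
            if a in contaminated_assemblies),
        n_assemblies,
    ) if n_assemblies else 0.0
    rate_error = (
        abs(recovered - designed_rate_pct)
        if designed_rate_pct is not None else None
    )
    return RecoveryMetrics(
        sensitivity=sensitivity,
        fdr=fdr,
        family_accuracy=family_accuracy,
        recovered_rate_pct=recovered,
        rate_error=rate_error,
        n_injected=len(injected),
        n_calls=len(calls),
        n_assigned_true=len(assigned_true),
    )


# --- on-disk layout of a simulated run ---------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write a simulated study in the pipeline's on-disk layout:
    inclusion/exclusion FASTA, one FASTA per assembly plus a metadata TSV,
    nt FASTA, lineage TSV and the truth manifest."""
    out = Path(outdir)
    (out / "assemblies").mkdir(parents=True, exist_ok=True)
    write_barcode_fasta(dataset.inclusion, out / "inclusion.fasta")
    write_barcode_fasta(dataset.exclusion, out / "exclusion.fasta")
    write_fasta(dataset.nt_records, out / "nt.fasta")
    write_lineage_table(dataset.lineages, out / "lineages.tsv")
    with open(out / "assemblies" / "assemblies.tsv", "w") as fh:
        fh.write("assembly_id\tproject_type\thost_lineage\n")
        for assembly in dataset.assemblies:
            fh.write(
                f"{assembly.assembly_id}\t{assembly.project_type}\t"
                f"{assembly.host_lineage.to_string()}\n"
            )
            write_fasta(
                assembly.contigs,
                out / "assemblies" / f"{assembly.assembly_id}.fasta",
            )
    assembly_of = {
        c.id: a.assembly_id for a in dataset.assemblies for c in a.contigs
    }
    write_truth_table(dataset.truth.rows(assembly_of), out / "truth.tsv")
    dataset.design.to_yaml(out / "design.yaml")


def load_assemblies(directory) -> list[AssemblyRecord]:
    """Read assemblies written by :func:`write_dataset` (or arranged the
    same way by hand): a metadata TSV plus one FASTA per assembly."""
    directory = Path(directory)
    meta = directory / "assemblies.tsv"
    if not meta.exists():
        raise FileNotFoundError(f"missing metadata table {meta}")
    assemblies = []
    with open(meta) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            assembly_id, project_type, lineage_text = line.split("\t")[:3]
            fasta = directory / f"{assembly_id}.fasta"
            contigs = read_fasta(fasta) if fasta.exists() else []
            assemblies.append(
                AssemblyRecord(
                    assembly_id=assembly_id,
                    project_type=project_type,
                    host_lineage=Lineage.from_string(lineage_text),
                    contigs=contigs,
                )
            )
    return assemblies


def load_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    design = SyntheticDesign.from_yaml(directory / "design.yaml")
    inclusion, _ = read_barcode_fasta(directory / "inclusion.fasta")
    exclusion, _ = read_barcode_fasta(directory / "exclusion.fasta")
    assemblies = load_assemblies(directory / "assemblies")
    nt_records = read_fasta(directory / "nt.fasta")
    lineages = read_lineage_table(directory / "lineages.tsv")
    truth = GroundTruth()
    for row in read_truth_table(directory / "truth.tsv"):
        truth.labels[row.contig_id] = row.label
        if row.source_family:
            truth.source_family[row.contig_id] = row.source_family
    for assembly in assemblies:
        truth.assembly_contaminated[assembly.assembly_id] = any(
            truth.labels.get(c.id) == "mite-contaminant"
            for c in assembly.contigs
        )
    return SyntheticDataset(
        design=design,
        inclusion=inclusion,
        exclusion=exclusion,
        assemblies=assemblies,
        nt_records=nt_records,
        lineages=lineages,
        truth=truth,
    )
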