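import logging

import numpy as np
import pytest

from mitescreen.align import AlignmentHit, ScoringScheme, SequenceDatabase
from mitescreen.io_formats import BarcodeRecord, SeqRecord
from mitescreen.screen import (
    AssemblyRecord,
    ScreenConfig,
    detect_nt_misidentification,
    run_screen,
    step1_length_filter,
    step2_inclusion_screen,
    step3_comparative_screen,
    step4_nt_verify,
    step4_passes,
)
from mitescreen.taxonomy import Lineage, is_mite_lineage

from conftest import mutate, random_seq

MITE_LIN = Lineage.from_string(
    "Animalia,Arthropoda,class:Arachnida,order:Sarcoptiformes,family:Acaridae"
)
TICK_LIN = Lineage.from_string(
    "Animalia,Arthropoda,class:Arachnida,order:Ixodida,family:Ixodidae"
)
TERMITE_LIN = Lineage.from_string(
    "Animalia,Arthropoda,class:Insecta,Blattodea,family:Termopsidae"
)
HOST_LIN = Lineage.from_string(
    "Animalia,Arthropoda,class:Insecta,Coleoptera,family:Carabidae"
)


def mk_hit(query="q", subject="s", bitscore=100.0, identity=95.0,
           raw=80) -> AlignmentHit:
    return AlignmentHit(
        query_id=query, subject_id=subject, raw_score=raw,
        bitscore=bitscore, identity_pct=identity, aln_len=100,
        mismatches=5, gapopens=0, qstart=1, qend=100, sstart=1, send=100,
    )


class TestStep1Length:
    def test_boundary_is_strictly_greater(self):
        contigs = [
            SeqRecord(id="at_limit", seq="A" * 100_000),
            SeqRecord(id="over_limit", seq="A" * 100_001),
            SeqRecord(id="mito_scale", seq="A" * 14_000),
        ]
        survivors = step1_length_filter(contigs)
        assert [c.id for c in survivors] == ["at_limit", "mito_scale"]


@pytest.fixture(scope="module")
def inclusion_db(small_dataset):
    return SequenceDatabase(
        [b.to_seqrecord() for b in small_dataset.inclusion]
    )


class TestStep2Inclusion:
    def test_exact_barcode_copy_retained(self, small_dataset, inclusion_db):
        rng = np.random.default_rng(23)
        barcode = small_dataset.inclusion[4]
        contig = SeqRecord(
            id="c", seq=random_seq(rng, 200) + barcode.seq[:600]
            + random_seq(rng, 200),
        )
        hit = step2_inclusion_screen(contig, inclusion_db)
        assert hit is not None
        assert hit.identity_pct == 100.0

    def test_diverged_copy_retained(self, small_dataset, inclusion_db):
        rng = np.random.default_rng(24)
        barcode = small_dataset.inclusion[11]
        contig = SeqRecord(
            id="c", seq=random_seq(rng, 100)
            + mutate(barcode.seq, 0.05, rng) + random_seq(rng, 100),
        )
        hit = step2_inclusion_screen(contig, inclusion_db)
        assert hit is not None
        assert hit.identity_pct > 90.0

    def test_unrelated_contig_eliminated(self, inclusion_db):
        rng = np.random.default_rng(25)
        contig = SeqRecord(id="c", seq=random_seq(rng, 1500))
        assert step2_inclusion_screen(contig, inclusion_db) is None


class TestStep3Comparative:
    @pytest.mark.parametrize(
        "mite_bits, nonmite_bits, keep",
        [
            (200.0, 150.0, True),   # mite similarity dominates
            (150.0, 200.0, False),  # more similar to non-mite barcodes
            (150.0, 150.0, True),   # tie: elimination needs strict majority
        ],
    )
    def test_bitscore_comparison(self, mite_bits, nonmite_bits, keep):
        assert step3_comparative_screen(
            mk_hit(bitscore=mite_bits), mk_hit(bitscore=nonmite_bits)
        ) is keep

    def test_no_nonmite_hit_keeps(self):
        assert step3_comparative_screen(mk_hit(), None) is True


class TestStep4Rule:
    @pytest.mark.parametrize(
        "identity, lineage, keep",
        [
            (85.0, MITE_LIN, True),     # mite lineage, identity above 80
            (99.0, TICK_LIN, False),    # Ixodida is excluded from Acari
            (79.9, MITE_LIN, False),    # below the 80% identity floor
            (80.0, MITE_LIN, True),     # boundary: "less than 80%" eliminates
            (99.0, HOST_LIN, False),    # best hit outside Acari entirely
        ],
    )
    def test_retention_rule(self, identity, lineage, keep):
        assert step4_passes(identity, lineage) is keep

    def test_verify_keeps_mite_record_match(self):
        rng = np.random.default_rng(31)
        core = random_seq(rng, 800)
        nt = SequenceDatabase([
            SeqRecord(id="ntm", seq=core),
            SeqRecord(id="ntx", seq=random_seq(rng, 800)),
        ])
        lineages = {"ntm": MITE_LIN, "ntx": HOST_LIN}
        contig = SeqRecord(
            id="c", seq=random_seq(rng, 100) + mutate(core, 0.1, rng)
        )
        verdict = step4_nt_verify(contig, nt, lineages)
        assert verdict.keep and not verdict.rescued
        assert verdict.nt_hit.subject_id == "ntm"

    def test_verify_eliminates_tick_record_match(self):
        rng = np.random.default_rng(32)
        core = random_seq(rng, 800)
        nt = SequenceDatabase([SeqRecord(id="tick", seq=core)])
        contig = SeqRecord(id="c", seq=mutate(core, 0.02, rng))
        verdict = step4_nt_verify(contig, nt, {"tick": TICK_LIN})
        assert not verdict.keep


class TestMisidentificationDetector:
    def test_flags_self_top_with_mite_second(self):
        hits = [
            mk_hit(query="XM1", subject="XM1", bitscore=900.0, identity=100.0),
            mk_hit(query="XM1", subject="MN85", bitscore=500.0,
                   identity=80.977),
        ]
        lineages = {"XM1": TERMITE_LIN, "MN85": MITE_LIN}
        record = detect_nt_misidentification(hits, lineages, TERMITE_LIN)
        assert record is not None
        assert record.record_id == "XM1"
        assert record.second_hit.subject_id == "MN85"
        assert is_mite_lineage(record.second_lineage)

    def test_mite_top_hit_is_not_flagged(self):
        hits = [
            mk_hit(subject="m1", bitscore=900.0, identity=100.0),
            mk_hit(subject="m2", bitscore=500.0, identity=90.0),
        ]
        lineages = {"m1": MITE_LIN, "m2": MITE_LIN}
        assert detect_nt_misidentification(hits, lineages, MITE_LIN) is None

    def test_sub_100_top_identity_is_not_flagged(self):
        hits = [
            mk_hit(subject="x1", bitscore=900.0, identity=99.5),
            mk_hit(subject="m2", bitscore=500.0, identity=85.0),
        ]
        lineages = {"x1": TERMITE_LIN, "m2": MITE_LIN}
        assert detect_nt_misidentification(
            hits, lineages, TERMITE_LIN
        ) is None


class TestRunScreen:
    def test_single_injected_contaminant_is_the_only_call(
        self, small_dataset
    ):
        rng = np.random.default_rng(41)
        source = small_dataset.inclusion[17]
        contaminant = SeqRecord(
            id="inj.mite", seq=random_seq(rng, 150)
            + mutate(source.seq, 0.05, rng) + random_seq(rng, 150),
        )
        hosts = [
            SeqRecord(id=f"host{i:02d}", seq=random_seq(
                rng, int(rng.integers(600, 1800))))
            for i in range(50)
        ]
        assembly = AssemblyRecord(
            assembly_id="ONE", project_type="WGS",
            host_lineage=HOST_LIN, contigs=hosts + [contaminant],
        )
        result = run_screen(
            [assembly], small_dataset.inclusion, small_dataset.exclusion,
            small_dataset.nt_records, small_dataset.lineages,
        )
        assert [c.contig_id for c in result.calls] == ["inj.mite"]
        assert result.assembly_contaminated == {"ONE": True}

    def test_tick_derived_contig_yields_no_call(self, small_dataset):
        rng = np.random.default_rng(42)
        tick = next(
            b for b in small_dataset.exclusion
            if "Ixodida" in b.lineage.names
        )
        contig = SeqRecord(
            id="tick.c", seq=random_seq(rng, 100)
            + mutate(tick.seq, 0.05, rng) + random_seq(rng, 100),
        )
        assembly = AssemblyRecord(
            assembly_id="TK", project_type="TSA",
            host_lineage=HOST_LIN, contigs=[contig],
        )
        result = run_screen(
            [assembly], small_dataset.inclusion, small_dataset.exclusion,
            small_dataset.nt_records, small_dataset.lineages,
        )
        assert result.calls == []
        assert result.assembly_contaminated == {"TK": False}

    def test_misidentified_record_rescues_contig(self):
        rng = np.random.default_rng(43)
        barcode = random_seq(rng, 658)
        inclusion = [
            BarcodeRecord(id="MB", marker="COI-5P", lineage=MITE_LIN,
                          seq=barcode)
        ]
        # nt database has no honest mite record for this family: only a
        # mite-derived record annotated to a termite, plus a diverged mite
        # mitogenome that supplies the tell-tale second-best hit
        nt = [
            SeqRecord(id="MISID", seq=random_seq(rng, 80)
                      + mutate(barcode, 0.03, rng) + random_seq(rng, 80)),
            SeqRecord(id="MITEREF", seq=random_seq(rng, 80)
                      + mutate(barcode, 0.08, rng) + random_seq(rng, 80)),
        ]
        lineages = {"MISID": TERMITE_LIN, "MITEREF": MITE_LIN}
        contig = SeqRecord(
            id="c.resc", seq=random_seq(rng, 120) + barcode
            + random_seq(rng, 120),
        )
        assembly = AssemblyRecord(
            assembly_id="RS", project_type="WGS",
            host_lineage=HOST_LIN, contigs=[contig],
        )
        result = run_screen([assembly], inclusion, [], nt, lineages)
        assert len(result.calls) == 1
        call = result.calls[0]
        assert call.rescued_by_misid_rule
        assert call.nt_best_hit.subject_id == "MISID"
        assert result.misidentified[0].record_id == "MISID"

    def test_zero_contig_assembly_warns_and_yields_no_calls(
        self, small_dataset, caplog
    ):
        assembly = AssemblyRecord(
            assembly_id="EMPTY", project_type="WGS",
            host_lineage=HOST_LIN, contigs=[],
        )
        with caplog.at_level(logging.WARNING, logger="mitescreen"):
            result = run_screen(
                [assembly], small_dataset.inclusion, small_dataset.exclusion,
                small_dataset.nt_records, small_dataset.lineages,
            )
        assert result.calls == []
        assert "EMPTY" in caplog.text

    def test_order_invariance(self, small_dataset):
        subset = small_dataset.assemblies[:4]
        kwargs = dict(
            inclusion_db=small_dataset.inclusion,
            exclusion_db=small_dataset.exclusion,
            nt_db=small_dataset.nt_records,
            lineages=small_dataset.lineages,
        )
        forward = run_screen(subset, **kwargs)
        backward = run_screen(list(reversed(subset)), **kwargs)
        assert {c.contig_id for c in forward.calls} \
            == {c.contig_id for c in backward.calls}
        assert forward.assembly_contaminated == backward.assembly_contaminated


class TestScreenInvariants:
    def test_monotone_filtration_on_synthetic_assemblies(self, small_dataset):
        cfg = ScreenConfig()
        inclusion = SequenceDatabase(
            [b.to_seqrecord() for b in small_dataset.inclusion]
        )
        exclusion = SequenceDatabase(
            [b.to_seqrecord() for b in small_dataset.exclusion]
        )
        nt = SequenceDatabase(small_dataset.nt_records)
        contigs = [
            c for a in small_dataset.assemblies[:3] for c in a.contigs
        ]
        s1 = step1_length_filter(contigs, cfg)
        s2, best_mite = [], {}
        for contig in s1:
            hit = step2_inclusion_screen(contig, inclusion, cfg)
            if hit is not None:
                s2.append(contig)
                best_mite[contig.id] = hit
        s3 = []
        for contig in s2:
            from mitescreen.align import search
            nonmite = search(
                contig, exclusion, max_hits=1,
                evalue_max=cfg.step2_evalue_cutoff, method="seeded",
            )
            if step3_comparative_screen(
                best_mite[contig.id], nonmite[0] if nonmite else None
            ):
                s3.append(contig)
        s4 = [
            contig for contig in s3
            if step4_nt_verify(
                contig, nt, small_dataset.lineages, cfg
            ).keep
        ]
        ids = [set(c.id for c in stage) for stage in (contigs, s1, s2, s3, s4)]
        for later, earlier in zip(ids[1:], ids[:-1]):
            assert later <= earlier
        assert ids[-1]  # the contaminated subset is non-empty by design

    def test_step_counts_telescope(self, small_screen):
        counts = small_screen.step_counts
        eliminated = sum(
            counts[f"step{k}_eliminated"] for k in (1, 2, 3, 4)
        )
        assert counts["input"] == eliminated + counts["calls"]
        assert counts["calls"] == len(small_screen.calls)

    def test_call_evidence_invariants(self, small_screen):
        assert small_screen.calls  # the design injects contamination
        for call in small_screen.calls:
            if call.best_nonmite_hit is not None:
                assert call.best_mite_hit.bitscore \
                    >= call.best_nonmite_hit.bitscore
            assert call.nt_best_hit.identity_pct >= 80.0
            assert is_mite_lineage(call.nt_best_lineage) \
                or call.rescued_by_misid_rule
            assert [v.step for v in call.step_trace] == [1, 2, 3, 4]
            assert all(v.verdict == "pass" for v in call.step_trace)
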