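from collections import Counter

import numpy as np
import pytest
from scipy import stats

from riboqc import (
    DigestionParams,
    compute_qc_report,
    emit_fastq,
    footprints_from_truth,
    generate_transcriptome,
    simulate_footprints,
)
from riboqc.read_prep import DEFAULT_ADAPTER
from riboqc.simulate import truth_to_frame, write_truth, read_truth


class TestDigestionParams:
    def test_modal_length_shifts_with_completeness(self):
        assert DigestionParams(completeness=1.0).modal_length == 28
        assert DigestionParams(completeness=0.2).modal_length == 32

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"completeness": 0.0},
            {"completeness": 1.2},
            {"gc_bias_strength": -1},
            {"pcr_dup_rate": 1.0},
            {"frame_fidelity_floor": 0.95, "frame_fidelity_complete": 0.9},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DigestionParams(**kwargs)


class TestSimulateFootprints:
    def test_complete_digestion_modal_length_is_28(self, complete_sample):
        _, truth, _ = complete_sample
        lengths = Counter(t.length for t in truth)
        assert lengths.most_common(1)[0][0] == 28

    def test_no_bias_gc_matches_source(self, transcriptome):
        """With every bias off, read GC must be indistinguishable from the
        GC of uniformly drawn same-length source windows."""
        params = DigestionParams(
            completeness=1.0, gc_bias_strength=0.0, utr_contamination_max=0.0,
            end_bias={}, pcr_dup_rate=0.0, seed=5,
        )
        _, truth = simulate_footprints(transcriptome, params, 10_000)
        seqs = {t.id: t.sequence for t in transcriptome}
        read_gc = np.array(
            [
                (lambda s: (s.count("G") + s.count("C")) / len(s))(
                    seqs[t.transcript][t.start : t.start + t.length]
                )
                for t in truth
            ]
        )
        # oracle: independent uniform re-draw of the CDS codon position for
        # each read's (transcript, length) — the flat-acceptance distribution
        rng = np.random.default_rng(99)
        by_id = {t.id: t for t in transcriptome}
        ref = []
        for rec in truth:
            t = by_id[rec.transcript]
            k_lo = max(-(-max(12 - t.utr5_end, 0) // 3), 0)
            k_hi = min(
                (t.cds_end - 3 - t.utr5_end) // 3,
                (t.length - rec.length + 12 - t.utr5_end) // 3,
            )
            p = t.utr5_end + 3 * int(rng.integers(k_lo, k_hi + 1))
            s = t.sequence[p - 12 : p - 12 + rec.length]
            ref.append((s.count("G") + s.count("C")) / len(s))
        assert stats.mannwhitneyu(read_gc, np.array(ref)).pvalue > 0.01

    def test_incomplete_digestion_is_gc_rich_and_long(
        self, transcriptome, complete_sample, incomplete_sample
    ):
        _, _, fps_complete = complete_sample
        _, _, fps_incomplete = incomplete_sample
        rep_c = compute_qc_report(fps_complete, transcriptome, psite_offsets=12)
        rep_i = compute_qc_report(fps_incomplete, transcriptome, psite_offsets=12)
        assert rep_i.gc_window_mean > rep_c.gc_window_mean
        assert rep_i.length_peak > rep_c.length_peak

    def test_duplicate_truth_conservation(self, transcriptome):
        params = DigestionParams(pcr_dup_rate=0.5, seed=9)
        _, truth = simulate_footprints(transcriptome, params, 5_000)
        originals = sum(t.duplicate_of is None for t in truth)
        distinct = len({(t.transcript, t.start, t.length, t.umi) for t in truth})
        assert originals == distinct

    def test_duplicate_of_references_matching_read(self, transcriptome):
        params = DigestionParams(pcr_dup_rate=0.4, seed=9)
        _, truth = simulate_footprints(transcriptome, params, 2_000)
        by_id = {t.read_id: t for t in truth}
        for t in truth:
            if t.duplicate_of is not None:
                ref = by_id[t.duplicate_of]
                assert (t.transcript, t.start, t.length, t.umi) == (
                    ref.transcript, ref.start, ref.length, ref.umi,
                )

    def test_no_bias_limit_is_pure_cds(self, transcriptome):
        params = DigestionParams(
            completeness=1.0, gc_bias_strength=0.0, utr_contamination_max=0.0, seed=2
        )
        _, truth = simulate_footprints(transcriptome, params, 5_000)
        cds_frac = sum(t.region == "cds" for t in truth) / len(truth)
        assert cds_frac >= 0.99

    def test_frame_fidelity_controls_in_frame_fraction(self, transcriptome):
        for fidelity, lo, hi in [(0.9, 0.87, 0.93), (0.4, 0.37, 0.43)]:
            params = DigestionParams(
                frame_fidelity_complete=fidelity, utr_contamination_max=0.0, seed=4
            )
            _, truth = simulate_footprints(transcriptome, params, 8_000)
            f0 = sum(t.frame == 0 for t in truth) / len(truth)
            assert lo <= f0 <= hi

    def test_determinism_byte_identical(self, tmp_path, transcriptome):
        out = []
        for run in ("a", "b"):
            params = DigestionParams(completeness=0.7, pcr_dup_rate=0.2, seed=42)
            reads, truth = simulate_footprints(transcriptome, params, 1_000)
            fq = tmp_path / f"{run}.fastq"
            tr = tmp_path / f"{run}.tsv"
            emit_fastq(reads, fq, umis=[t.umi for t in truth])
            write_truth(truth, tr)
            out.append((fq.read_bytes(), tr.read_bytes()))
        assert out[0] == out[1]

    def test_contaminant_labels(self, transcriptome):
        params = DigestionParams(seed=1)
        _, truth = simulate_footprints(
            transcriptome, params, 4_000,
            contaminant_fractions={"contaminant_rRNA": 0.1, "contaminant_tRNA": 0.05},
        )
        frac = Counter(t.category for t in truth)
        assert 0.07 < frac["contaminant_rRNA"] / len(truth) < 0.13
        assert 0.03 < frac["contaminant_tRNA"] / len(truth) < 0.07

    def test_abundance_weights_shape_counts(self, transcriptome):
        weights = np.zeros(len(transcriptome))
        weights[0] = 1.0
        params = DigestionParams(utr_contamination_max=0.0, seed=1)
        _, truth = simulate_footprints(transcriptome, params, 500, abundance_model=weights)
        assert {t.transcript for t in truth} == {transcriptome[0].id}

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_footprints([], DigestionParams(), 10)


class TestEmitFastq:
    def test_adapter_follows_insert(self, tmp_path, transcriptome):
        params = DigestionParams(seed=0)
        reads, truth = simulate_footprints(transcriptome, params, 1_000)
        path = tmp_path / "s.fastq"
        emit_fastq(reads, path, umis=[t.umi for t in truth], barcode="AATCG")
        lines = path.read_text().splitlines()
        assert len(lines) == 4 * len(reads)
        for i, read in enumerate(reads):
            seq = lines[4 * i + 1]
            insert_end = 5 + 8 + len(read.sequence)
            assert seq[insert_end:].startswith(DEFAULT_ADAPTER[: len(seq) - insert_end])
            assert seq[insert_end : insert_end + 10] == DEFAULT_ADAPTER[:10]

    def test_empty_read_list_gives_empty_fastq(self, tmp_path):
        path = tmp_path / "empty.fastq"
        emit_fastq([], path)
        assert path.read_text() == ""

    def test_read_length_budget_truncates_adapter_not_insert(self, tmp_path):
        from riboqc import RawRead

        read = RawRead(id="r", sequence="ACGT" * 7, qualities="F" * 28)
        path = tmp_path / "one.fastq"
        emit_fastq([read], path, umis=["ACGTACGT"], read_length=50)
        seq = path.read_text().splitlines()[1]
        assert len(seq) == 50
        assert seq[13:41] == read.sequence  # insert intact
        assert seq[41:] == DEFAULT_ADAPTER[:9]  # adapter truncated

    def test_insert_exceeding_budget_rejected(self, tmp_path):
        from riboqc import RawRead

        read = RawRead(id="r", sequence="A" * 60, qualities="F" * 60)
        with pytest.raises(ValueError, match="exceed"):
            emit_fastq([read], tmp_path / "x.fastq", umis=["ACGTACGT"], read_length=40)


class TestTruthIO:
    def test_roundtrip(self, tmp_path, transcriptome):
        params = DigestionParams(pcr_dup_rate=0.3, seed=6)
        _, truth = simulate_footprints(transcriptome, params, 500)
        path = tmp_path / "truth.tsv"
        write_truth(truth, path)
        assert read_truth(path) == truth

    def test_frame_matches_psite(self, transcriptome, complete_sample):
        _, truth, _ = complete_sample
        utr5 = {t.id: t.utr5_end for t in transcriptome}
        df = truth_to_frame(truth)
        assert (df["frame"] == (df["psite"] - df["transcript"].map(utr5)) % 3).all()
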