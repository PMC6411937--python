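import numpy as np
import pytest

from riboqc import (
    DigestionParams,
    Footprint,
    TranscriptModel,
    assign_regions,
    compute_qc_report,
    estimate_psite_offsets,
    footprints_from_truth,
    frame_preference,
    length_histogram,
    length_peak,
    metagene_profile,
    nucleotide_composition,
    simulate_footprints,
    windowed_gc,
)
from riboqc.qc import smooth_profile


def fp(seq=None, rid="r", ref="t", start=0, length=None, umi="ACGTACGT"):
    return Footprint(
        read_id=rid, reference=ref, start=start,
        length=length or (len(seq) if seq else 28), sequence=seq, umi=umi,
    )


def make_tx(seq="A" * 30 + "ATG" + "CAG" * 20 + "TAA" + "T" * 30, tid="t"):
    return TranscriptModel(tid, seq, 30, 30 + 66)


class TestComposition:
    def test_single_read(self):
        m = nucleotide_composition([fp("ACG")])
        assert m.fractions.loc[1, "A"] == 1.0
        assert m.fractions.loc[2, "C"] == 1.0
        assert m.fractions.loc[3, "G"] == 1.0

    def test_ragged_lengths_use_covering_reads_only(self):
        m = nucleotide_composition([fp("AA", rid="a"), fp("AC", rid="b"), fp("A", rid="c")])
        assert m.fractions.loc[2, "A"] == 0.5 and m.fractions.loc[2, "C"] == 0.5
        assert m.coverage.loc[1] == 3 and m.coverage.loc[2] == 2

    def test_fractions_sum_to_one(self, complete_sample):
        _, _, fps = complete_sample
        m = nucleotide_composition(fps)
        sums = m.fractions.dropna().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_five_prime_A_bias_visible(self, transcriptome):
        params = DigestionParams(
            end_bias={"five_prime": {"A": 8.0}, "three_prime": {}}, seed=3
        )
        _, truth = simulate_footprints(transcriptome, params, 5_000)
        m = nucleotide_composition(footprints_from_truth(truth, transcriptome))
        assert m.fractions.loc[1, "A"] > m.fractions.loc[5, "A"]


class TestWindowedGC:
    def test_all_g_reads(self):
        m = nucleotide_composition([fp("G" * 28, rid=f"r{i}") for i in range(3)])
        assert windowed_gc(m, (10, 20)) == 100.0

    def test_half_gc_half_at(self):
        reads = [fp("GC" * 14, rid="a"), fp("AT" * 14, rid="b")]
        assert windowed_gc(nucleotide_composition(reads), (10, 20)) == 50.0

    def test_window_beyond_reads_rejected(self):
        m = nucleotide_composition([fp("ACGT" * 5)])
        with pytest.raises(ValueError, match="exceeds"):
            windowed_gc(m, (10, 30))

    def test_matches_per_read_gc_oracle_for_uniform_lengths(self, transcriptome):
        params = DigestionParams(seed=13, utr_contamination_max=0.0)
        _, truth = simulate_footprints(transcriptome, params, 2_000)
        fps = [f for f in footprints_from_truth(truth, transcriptome) if f.length == 28]
        got = windowed_gc(nucleotide_composition(fps), (10, 20))
        window_gcs = [
            (f.sequence[9:20].count("G") + f.sequence[9:20].count("C")) / 11 for f in fps
        ]
        assert got == pytest.approx(100 * np.mean(window_gcs), abs=1e-9)

    def test_invariant_under_read_permutation(self, complete_sample):
        _, _, fps = complete_sample
        a = windowed_gc(nucleotide_composition(fps))
        b = windowed_gc(nucleotide_composition(fps[::-1]))
        assert a == pytest.approx(b, abs=1e-12)


class TestLengthPeak:
    @pytest.mark.parametrize("hist,expected", [({28: 10, 29: 3}, 28), ({28: 5, 31: 5}, 28)])
    def test_peak_and_tie_rule(self, hist, expected):
        assert length_peak(hist) == expected

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            length_peak({})

    def test_histogram_counts(self):
        fps = [fp("A" * 28, rid="a"), fp("A" * 28, rid="b"), fp("A" * 30, rid="c")]
        assert length_histogram(fps) == {28: 2, 30: 1}


class TestAssignRegions:
    def test_psite_in_cds(self):
        t = make_tx()
        f = fp(ref="t", start=30, length=28)  # P-site at 42, mid-CDS
        assert assign_regions([f], [t]) == {"utr5": 0.0, "cds": 1.0, "utr3": 0.0}

    def test_psite_past_cds_end_is_utr3(self):
        t = make_tx()
        f = fp(ref="t", start=t.cds_end + 2 - 12, length=28)  # P-site 2 nt past cds_end
        assert assign_regions([f], [t])["utr3"] == 1.0

    def test_utr_contamination_matches_model(self, transcriptome):
        params = DigestionParams(completeness=0.2, utr_contamination_max=0.3, seed=19)
        _, truth = simulate_footprints(transcriptome, params, 20_000)
        fracs = assign_regions(footprints_from_truth(truth, transcriptome), transcriptome, 12)
        assert abs((fracs["utr5"] + fracs["utr3"]) - 0.3 * 0.8) < 0.03

    def test_overlap_mode_counts_spanning_read_in_both(self):
        t = make_tx()
        f = fp(ref="t", start=t.utr5_end - 5, length=28)
        fr = assign_regions([f], [t], mode="overlap")
        assert fr["utr5"] == 0.5 and fr["cds"] == 0.5


class TestPsiteOffsets:
    def _reads_with_offset(self, tx, offset, length, n=300):
        # in-frame reads: P-sites on codons 0..n-1, 5' end offset nt upstream
        out = []
        for i in range(n):
            p = tx.utr5_end + 3 * (i % 15)
            out.append(
                fp(ref=tx.id, start=p - offset, length=length, rid=f"r{i}")
            )
        return out

    def test_recovers_truth_offset_12(self):
        tx = make_tx("A" * 30 + "ATG" + "CAG" * 40 + "TAA" + "T" * 40, "t")
        offsets, conf, low = estimate_psite_offsets(
            self._reads_with_offset(tx, 12, 28), [tx], min_reads=200
        )
        assert offsets[28] == 12 and 28 not in low

    def test_recovers_truth_offset_13_for_L29(self):
        tx = make_tx("A" * 30 + "ATG" + "CAG" * 40 + "TAA" + "T" * 40, "t")
        offsets, _, _ = estimate_psite_offsets(
            self._reads_with_offset(tx, 13, 29), [tx], min_reads=200
        )
        assert offsets[29] == 13

    def test_simulated_sample_recovers_offset(self, transcriptome, complete_sample):
        _, _, fps = complete_sample
        offsets, _, _ = estimate_psite_offsets(fps, transcriptome)
        assert offsets[28] == 12

    def test_uniform_positions_flagged_low_confidence(self):
        tx = make_tx("A" * 30 + "ATG" + "CAG" * 40 + "TAA" + "T" * 40, "t")
        rng = np.random.default_rng(0)
        reads = [
            fp(ref="t", start=int(rng.integers(0, tx.length - 28)), length=28, rid=f"r{i}")
            for i in range(500)
        ]
        _, conf, low = estimate_psite_offsets(reads, [tx], min_reads=200)
        assert 28 in low and conf[28] < 2

    def test_every_observed_length_receives_an_offset(self, transcriptome, complete_sample):
        _, _, fps = complete_sample
        offsets, _, _ = estimate_psite_offsets(fps, transcriptome, min_reads=200)
        assert set(offsets) == {f.length for f in fps}

    def test_no_passing_length_class_errors(self):
        tx = make_tx()
        with pytest.raises(ValueError, match="min_reads"):
            estimate_psite_offsets([fp(ref="t", start=20, length=28)], [tx], min_reads=200)


class TestFramePreference:
    def test_all_in_frame(self):
        tx = make_tx("A" * 30 + "ATG" + "CAG" * 40 + "TAA" + "T" * 40, "t")
        reads = [fp(ref="t", start=tx.utr5_end + 3 * i - 12, length=28, rid=f"r{i}") for i in range(10)]
        res = frame_preference(reads, [tx], 12, min_reads=1)
        assert res.best_fractions["f0"] == 1.0

    def test_uniform_frames_near_third(self):
        tx = make_tx("A" * 30 + "ATG" + "CAG" * 120 + "TAA" + "T" * 40, "t")
        rng = np.random.default_rng(1)
        reads = [
            fp(ref="t", start=int(rng.integers(tx.utr5_end, tx.cds_end - 28)) , length=28, rid=f"r{i}")
            for i in range(10_000)
        ]
        res = frame_preference(reads, [tx], 0, min_reads=1)
        assert res.per_length.loc[28, "f0"] == pytest.approx(1 / 3, abs=0.02)

    def test_fidelity_sweep_orders_f0(self, transcriptome):
        f0 = {}
        for fidelity in (0.9, 0.4):
            params = DigestionParams(
                frame_fidelity_complete=fidelity, utr_contamination_max=0.0, seed=21
            )
            _, truth = simulate_footprints(transcriptome, params, 8_000)
            res = frame_preference(footprints_from_truth(truth, transcriptome), transcriptome, 12)
            f0[fidelity] = res.best_fractions["f0"]
        assert f0[0.9] > f0[0.4]

    def test_best_length_tie_breaks_to_shortest(self):
        tx = make_tx("A" * 30 + "ATG" + "CAG" * 40 + "TAA" + "T" * 40, "t")
        reads = [fp(ref="t", start=tx.utr5_end - 12, length=L, rid=f"r{L}") for L in (28, 29)]
        res = frame_preference(reads, [tx], 12, min_reads=1)
        assert res.best_length == 28


class TestMetagene:
    def test_single_read_delta(self):
        tx = make_tx()
        f = fp(ref="t", start=30, length=28)
        prof = metagene_profile([[f]], tx, smooth_window=0)
        assert prof[42] == 1.0 and prof.sum() == 1.0

    def test_uniform_profile_is_smoothing_fixed_point(self):
        assert np.allclose(smooth_profile(np.full(100, 3.0), 30), 3.0)

    def test_identical_replicates_average_to_themselves(self):
        tx = make_tx()
        reads = [fp(ref="t", start=30 + 3 * i, length=28, rid=f"r{i}") for i in range(5)]
        one = metagene_profile([reads], tx, smooth_window=0)
        two = metagene_profile([reads, list(reads)], tx, smooth_window=0)
        assert np.allclose(one, two)

    def test_counts_conserved_before_smoothing(self):
        tx = make_tx()
        reads = [fp(ref="t", start=30 + 3 * i, length=28, rid=f"r{i}") for i in range(7)]
        prof = metagene_profile([reads], tx, normalization="none", smooth_window=0)
        assert prof.sum() == 7

    def test_smoothing_approximately_conserves_total(self):
        tx = make_tx()
        reads = [fp(ref="t", start=40 + i, length=28, rid=f"r{i}") for i in range(20)]
        raw = metagene_profile([reads], tx, normalization="none", smooth_window=0)
        sm = metagene_profile([reads], tx, normalization="none", smooth_window=30)
        assert sm.sum() == pytest.approx(raw.sum(), rel=0.05)

    def test_cds_mean_density_normalization(self):
        tx = make_tx()
        reads = [fp(ref="t", start=30 + 3 * i, length=28, rid=f"r{i}") for i in range(5)]
        prof = metagene_profile([reads], tx, normalization="cds_mean_density", smooth_window=0)
        cds = prof[tx.utr5_end : tx.cds_end]
        assert cds.mean() == pytest.approx(1.0)


class TestQCReport:
    def test_report_bundles_metrics(self, transcriptome, complete_sample):
        _, _, fps = complete_sample
        rep = compute_qc_report(fps, transcriptome, sample_id="s1")
        assert rep.length_peak == 28
        assert abs(sum(rep.region_fractions.values()) - 1) < 1e-9
        assert abs(sum(rep.frame_fractions.values()) - 1) < 1e-9
        assert rep.psite_offsets[28] == 12
        payload = rep.to_json()
        assert '"length_peak": 28' in payload
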