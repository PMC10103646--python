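"""Synthetic cohort generator: tiling, carrier model, depth model."""

import math

import numpy as np
import pytest

from cnvpop import (
    CnvEvent,
    InvalidArgumentError,
    implant_cnvs,
    simulate_cnvr_cohort,
    simulate_cohort,
    simulate_depth,
    simulate_reference,
    synthetic_gene_model,
)


def small_ref(**kw):
    defaults = dict(n_chrom=1, chrom_length=200_000, window_size=800,
                    step=400, seed=1)
    defaults.update(kw)
    return simulate_reference(**defaults)


class TestReference:
    @pytest.mark.parametrize(
        "length,window,step,expected",
        [(8_000, 800, 800, 10), (8_000, 800, 400, 19)],
    )
    def test_tiling_counts(self, length, window, step, expected):
        ref = simulate_reference(1, length, window, step, seed=0)
        assert ref.n_windows == expected
        win = ref.windows
        assert (win["end"] - win["start"] == window).all()
        assert win["start"].iloc[0] == 0
        assert (np.diff(win["start"]) == step).all()

    def test_same_seed_identical_gc(self):
        a = small_ref(seed=42).windows["gc"]
        b = small_ref(seed=42).windows["gc"]
        assert (a == b).all()
        c = small_ref(seed=43).windows["gc"]
        assert not (a == c).all()

    def test_gc_in_unit_interval_and_smooth(self):
        gc = small_ref(chrom_length=2_000_000).windows["gc"].to_numpy()
        assert gc.min() >= 0.0 and gc.max() <= 1.0
        # AR(1) chain: adjacent windows are much closer than random pairs
        assert np.abs(np.diff(gc)).mean() < 0.25 * gc.std()

    @pytest.mark.parametrize(
        "kw",
        [dict(window_size=0), dict(chrom_length=-5), dict(step=300),
         dict(chrom_length=5_000)],
    )
    def test_invalid_dimensions_rejected(self, kw):
        with pytest.raises(InvalidArgumentError):
            small_ref(**kw)


class TestImplant:
    def test_frequency_extremes(self):
        ref = small_ref()
        ev = CnvEvent("chr1", 40_000, 44_000, "deletion", -1,
                      {"A": 1.0, "B": 0.0})
        truth = implant_cnvs(ref, {"A": 5, "B": 5}, [ev], seed=0)
        win = ref.windows
        span = (win["start"] < 44_000) & (win["end"] > 40_000)
        pops = np.array([truth.populations.population_of(s)
                         for s in truth.sample_ids])
        assert set(np.unique(truth.copy_number[pops == "A"][:, span])) <= {0, 1}
        assert (truth.copy_number[pops == "B"][:, span] == 2).all()
        assert (truth.copy_number[:, ~span.to_numpy()] == 2).all()

    def test_zero_events_all_diploid(self):
        truth = implant_cnvs(small_ref(), {"A": 3}, [], seed=0)
        assert (truth.copy_number == 2).all()

    def test_carrier_fraction_matches_binomial_expectation(self):
        # allele freq 0.5 -> carrier prob 1 - 0.25 = 0.75
        ref = small_ref()
        ev = CnvEvent("chr1", 40_000, 44_000, "deletion", -1, {"A": 0.5})
        truth = implant_cnvs(ref, {"A": 1_000}, [ev], seed=3)
        carriers = (truth.genotypes[:, 0] > 0).mean()
        se = math.sqrt(0.75 * 0.25 / 1_000)
        assert abs(carriers - 0.75) < 5 * se

    def test_overlapping_events_rejected(self):
        ref = small_ref()
        evs = [
            CnvEvent("chr1", 10_000, 20_000, "deletion", -1, {"A": 0.5}),
            CnvEvent("chr1", 15_000, 25_000, "duplication", 1, {"A": 0.5}),
        ]
        with pytest.raises(InvalidArgumentError, match="overlap"):
            implant_cnvs(ref, {"A": 4}, evs, seed=0)

    def test_event_outside_chromosome_rejected(self):
        ref = small_ref()
        ev = CnvEvent("chr1", 190_000, 210_000, "duplication", 1, {"A": 0.5})
        with pytest.raises(InvalidArgumentError, match="bounds"):
            implant_cnvs(ref, {"A": 4}, [ev], seed=0)

    def test_truth_track_consistent_with_genotypes(self):
        # the stored track equals 2 + sum of carried changes, floored at 0
        ref = small_ref()
        evs = [
            CnvEvent("chr1", 10_000, 14_000, "deletion", -1, {"A": 0.6}),
            CnvEvent("chr1", 30_000, 36_000, "duplication", 2, {"A": 0.4}),
            CnvEvent("chr1", 60_000, 61_600, "deletion", -2, {"A": 0.3}),
        ]
        truth = implant_cnvs(ref, {"A": 30}, evs, seed=5)
        win = ref.windows
        expected = np.full_like(truth.copy_number, 2)
        for j, ev in enumerate(evs):
            span = ((win["start"] < ev.end) & (win["end"] > ev.start)).to_numpy()
            expected[:, span] += (truth.genotypes[:, j] * ev.copy_change)[:, None]
        assert (truth.copy_number == np.maximum(expected, 0)).all()


class TestDepth:
    def test_homozygous_deletion_gives_zero_counts(self):
        ref = small_ref()
        ev = CnvEvent("chr1", 40_000, 48_000, "deletion", -1, {"A": 1.0})
        truth = implant_cnvs(ref, {"A": 4}, [ev], seed=0)
        depth = simulate_depth(truth, ref, seed=0)
        span = ((ref.windows["start"] < 48_000)
                & (ref.windows["end"] > 40_000)).to_numpy()
        assert (depth.counts[:, span] == 0).all()

    def test_mean_count_proportional_to_copy_number(self):
        # Poisson limit, no GC bias: mean per CN state within 3 s.e.
        ref = simulate_reference(1, 4_001_000, 800, 400, seed=2)  # ~10k windows
        ev = CnvEvent("chr1", 0, 4_000_000, "duplication", 1, {"A": 1.0})
        truth = implant_cnvs(ref, {"A": 1, "B": 1}, [ev], seed=0)
        depth = simulate_depth(truth, ref, gc_bias_amplitude=0.0,
                               dispersion=math.inf, seed=0)
        mu0 = 12.0 * 800 / 100
        span = (ref.windows["end"] <= 4_000_000).to_numpy()
        n = span.sum()
        for row, cn in ((0, 4), (1, 2)):  # A is homozygous carrier, B diploid
            mean = depth.counts[row, span].mean()
            expect = mu0 * cn / 2
            se = math.sqrt(expect / n)
            assert abs(mean - expect) < 3 * se

    def test_doubling_depth_doubles_counts(self):
        ref = simulate_reference(1, 4_001_000, 800, 400, seed=2)
        truth = implant_cnvs(ref, {"A": 1}, [], seed=0)
        m12 = simulate_depth(truth, ref, mean_depth=12, seed=1).counts.mean()
        m24 = simulate_depth(truth, ref, mean_depth=24, seed=1).counts.mean()
        assert abs(m24 / m12 - 2.0) < 0.02

    def test_negative_binomial_overdispersion(self):
        ref = simulate_reference(1, 4_001_000, 800, 400, seed=2)
        truth = implant_cnvs(ref, {"A": 1}, [], seed=0)
        counts = simulate_depth(truth, ref, gc_bias_amplitude=0.0,
                                dispersion=5.0, seed=1).counts[0]
        assert counts.var() > 1.5 * counts.mean()

    def test_marginal_calibration_one_percent(self):
        # zero events, zero GC amplitude: genome-wide mean == mu0 within 1%
        ref = simulate_reference(1, 4_001_000, 800, 400, seed=2)
        truth = implant_cnvs(ref, {"A": 2}, [], seed=0)
        depth = simulate_depth(truth, ref, gc_bias_amplitude=0.0, seed=4)
        mu0 = 12.0 * 800 / 100
        assert abs(depth.counts.mean() / mu0 - 1.0) < 0.01

    def test_determinism(self):
        depth_a, _ = simulate_cohort(chrom_length=500_000, n_events=5, seed=9)
        depth_b, _ = simulate_cohort(chrom_length=500_000, n_events=5, seed=9)
        assert (depth_a.counts == depth_b.counts).all()
        assert depth_a.windows.equals(depth_b.windows)


class TestCohortHelpers:
    def test_random_events_nonoverlapping_and_snapped(self):
        _, truth = simulate_cohort(chrom_length=2_000_000, n_events=10, seed=3)
        evs = sorted(truth.events, key=lambda e: e.start)
        for ev in evs:
            assert ev.start % 400 == 0 and ev.end % 400 == 0
        for a, b in zip(evs, evs[1:]):
            assert b.start >= a.end

    def test_gene_model_generator_is_deterministic_and_valid(self):
        ref = small_ref(chrom_length=2_000_000)
        m1 = synthetic_gene_model(ref, n_genes=20, seed=5)
        m2 = synthetic_gene_model(ref, n_genes=20, seed=5)
        assert [t.transcript_id for t in m1.transcripts] == \
               [t.transcript_id for t in m2.transcripts]
        assert len(m1.transcripts) > 0
        for tx in m1.transcripts:
            assert tx.start < tx.end  # Transcript validates exons itself

    def test_cnvr_cohort_flags_and_genotypes(self):
        cnvrs, popmap, flags = simulate_cnvr_cohort(
            n_background=20, n_differential=3, seed=0)
        assert flags.sum() == 3 and len(cnvrs) == 23
        assert len(popmap) == 40
        for c in cnvrs:
            assert set(np.unique(c.genotypes)) <= {"loss", "normal", "gain"}
            assert (c.mean_cn >= 0).all()
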