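"""Candidate detection, merging, silhouette, genotyping, and filtering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_samples

from cnvpop import (
    CopyNumberMatrix,
    InvalidArgumentError,
    call_cnvrs,
    detect_candidates,
    filter_cnvrs,
    genotype_cnvr,
    merge_candidates,
    normalize,
    silhouette,
    simulate_cohort,
)
from cnvpop.discovery import CandidateRegion

from conftest import make_cnvr


def cn_matrix(cn, mask=None):
    cn = np.asarray(cn, dtype=float)
    n_windows = cn.shape[1]
    windows = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_windows) * 400,
        "end": np.arange(n_windows) * 400 + 800,
        "gc": 0.45,
    })
    return CopyNumberMatrix(windows=windows, cn=cn,
                            sample_ids=[f"s{i}" for i in range(len(cn))],
                            mask=mask)


def brute_force_silhouette(values, labels):
    """Independent all-pairs implementation of the mean silhouette."""
    values = list(values)
    labels = list(labels)
    n = len(values)
    total = 0.0
    for i in range(n):
        own = [abs(values[i] - values[j]) for j in range(n)
               if j != i and labels[j] == labels[i]]
        if not own:
            continue
        a = sum(own) / len(own)
        b = min(
            sum(abs(values[i] - values[j]) for j in range(n) if labels[j] == lab)
            / sum(1 for j in range(n) if labels[j] == lab)
            for lab in set(labels) if lab != labels[i]
        )
        m = max(a, b)
        total += 0.0 if m == 0 else (b - a) / m
    return total / n


class TestDetectCandidates:
    def test_threshold_arithmetic(self):
        # 40 individuals, f=0.1, h=3 -> need max(3, 4) = 4 deviants
        cn = np.full((40, 3), 2.0)
        cn[:4, 0] = 1.0   # 4 losses -> candidate
        cn[:2, 1] = 0.5   # 2 losses -> not a candidate
        cands = detect_candidates(cn_matrix(cn), f=0.1, h=3)
        assert [c.index for c in cands] == [0]
        assert cands[0].n_loss == 4 and cands[0].n_gain == 0

    def test_all_diploid_no_candidates(self):
        assert detect_candidates(cn_matrix(np.full((40, 10), 2.0))) == []

    def test_masked_windows_excluded(self):
        cn = np.full((40, 2), 2.0)
        cn[:5, :] = 1.0
        mask = np.array([False, True])
        cands = detect_candidates(cn_matrix(cn, mask))
        assert [c.index for c in cands] == [0]

    def test_thresholds_out_of_order_rejected(self):
        with pytest.raises(InvalidArgumentError):
            detect_candidates(cn_matrix(np.full((4, 2), 2.0)),
                              loss_threshold=2.5, gain_threshold=1.5)

    def test_raising_f_or_h_never_adds_candidates(self):
        rng = np.random.default_rng(0)
        cn = rng.normal(2.0, 0.5, (30, 200))
        base = len(detect_candidates(cn_matrix(cn), f=0.1, h=3))
        for f, h in [(0.2, 3), (0.1, 6), (0.5, 10)]:
            assert len(detect_candidates(cn_matrix(cn), f=f, h=h)) <= base


class TestMergeCandidates:
    def test_adjacent_identical_vectors_merge(self):
        cn = np.full((40, 2), 2.0)
        cn[:5, :] = 1.0
        cands = detect_candidates(cn_matrix(cn))
        regions = merge_candidates(cands, r=0.1)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 1_200)

    def test_anticorrelated_vectors_split(self):
        cn = np.full((40, 2), 2.0)
        cn[:5, 0] = 1.0
        cn[5:10, 1] = 1.0
        cn[:5, 1] = 3.0  # second window exactly anticorrelated with first
        cn[5:10, 0] = 3.0
        cands = detect_candidates(cn_matrix(cn))
        assert len(cands) == 2
        regions = merge_candidates(cands, r=0.1, min_windows=1)
        assert len(regions) == 2

    def test_gap_rule_blocks_distant_candidates(self):
        cn = np.full((40, 7), 2.0)
        cn[:5, 0] = 1.0
        cn[:5, 6] = 1.0  # identical pattern but 5 window-steps away
        cands = detect_candidates(cn_matrix(cn))
        regions = merge_candidates(cands, r=0.1, max_gap=1, min_windows=1)
        assert len(regions) == 2

    def test_min_windows_discards_singletons(self):
        cn = np.full((40, 5), 2.0)
        cn[:5, 2] = 1.0
        cands = detect_candidates(cn_matrix(cn))
        assert merge_candidates(cands, min_windows=2) == []
        assert len(merge_candidates(cands, min_windows=1)) == 1


class TestSilhouette:
    def test_perfectly_separated_pairs(self):
        assert silhouette([0, 0, 4, 4], ["A", "A", "B", "B"]) == 1.0

    def test_four_point_exact_value(self):
        # {0,1,2,3} / {A,A,B,B}: s = (0.6 + 1/3 + 1/3 + 0.6)/4 = 7/15
        vals, labs = [0, 1, 2, 3], ["A", "A", "B", "B"]
        expected = brute_force_silhouette(vals, labs)
        assert expected == pytest.approx(7 / 15, abs=1e-15)
        assert silhouette(vals, labs) == pytest.approx(expected, abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(InvalidArgumentError):
            silhouette([1.0, 2.0], ["A", "A"])

    def test_singleton_cluster_contributes_zero(self):
        vals = [0.0, 0.0, 5.0]
        labs = ["A", "A", "B"]
        assert silhouette(vals, labs) == pytest.approx(
            brute_force_silhouette(vals, labs), abs=1e-12)

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            vals = rng.normal(size=n)
            labs = rng.integers(0, 3, size=n)
            if len(np.unique(labs)) < 2:
                continue
            ours = silhouette(vals, labs)
            assert ours == pytest.approx(
                brute_force_silhouette(vals, labs), abs=1e-12)
            sk = silhouette_samples(vals.reshape(-1, 1), labs).mean()
            assert ours == pytest.approx(sk, abs=1e-9)

    def test_random_labels_near_zero_on_average(self):
        rng = np.random.default_rng(12)
        means = []
        for _ in range(100):
            vals = rng.normal(size=200)
            labs = rng.integers(0, 2, size=200)
            means.append(silhouette(vals, labs))
        assert -0.1 < np.mean(means) < 0.1


class TestGenotypeCnvr:
    def region(self, n_windows=1):
        return CandidateRegion("chr1", 0, 400 * (n_windows - 1) + 800,
                               tuple(range(n_windows)))

    def test_two_well_separated_clusters_is_deletion(self):
        cn = np.concatenate([np.full(20, 2.0), np.full(20, 1.0)])
        cnvr = genotype_cnvr(self.region(), cn_matrix(cn.reshape(-1, 1)))
        assert cnvr.kind == "deletion"
        assert cnvr.silhouette > 0.9
        assert (cnvr.genotypes[cn <= 1.5] == "loss").all()
        assert (cnvr.genotypes[cn > 1.5] == "normal").all()

    def test_identical_values_degenerate(self):
        cnvr = genotype_cnvr(self.region(), cn_matrix(np.full((40, 1), 2.0)))
        assert cnvr.silhouette == -1.0
        assert cnvr.kind == "normal"

    def test_three_clusters_is_both(self):
        rng = np.random.default_rng(4)
        cn = np.concatenate([
            rng.normal(1.0, 0.05, 15),
            rng.normal(2.0, 0.05, 15),
            rng.normal(3.0, 0.05, 10),
        ])
        cnvr = genotype_cnvr(self.region(), cn_matrix(cn.reshape(-1, 1)))
        assert cnvr.kind == "both"
        assert cnvr.silhouette > 0.6
        assert (cnvr.genotypes[cn < 1.5] == "loss").all()
        assert (cnvr.genotypes[cn > 2.5] == "gain").all()


class TestFilterCnvrs:
    def test_silhouette_strictly_above_gate(self):
        at_gate = make_cnvr(end=10_000, sil=0.6)
        above = make_cnvr(end=10_000, sil=0.6000001)
        assert filter_cnvrs([at_gate, above]) == [above]

    @pytest.mark.parametrize(
        "kind,length,kept",
        [
            ("deletion", 50_000, True),   # <= 50 kb inclusive
            ("deletion", 50_400, False),
            ("both", 50_000, True),
            ("both", 50_400, False),
            ("duplication", 499_999, True),   # < 500 kb strict
            ("duplication", 500_000, False),
        ],
    )
    def test_length_caps_by_kind(self, kind, length, kept):
        c = make_cnvr(end=length, kind=kind, sil=0.9)
        assert (filter_cnvrs([c]) == [c]) is kept

    def test_raising_gate_never_keeps_more(self):
        cnvrs = [make_cnvr(end=5_000, sil=s) for s in np.linspace(-1, 1, 21)]
        sizes = [len(filter_cnvrs(cnvrs, silhouette_min=m))
                 for m in (0.0, 0.3, 0.6, 0.9)]
        assert sizes == sorted(sizes, reverse=True)


class TestEndToEnd:
    def test_call_is_deterministic(self):
        depth, _ = simulate_cohort(chrom_length=1_000_000, n_events=6,
                                   carrier_freq=0.5, seed=21)
        cn = normalize(depth)
        a, _ = call_cnvrs(cn)
        b, _ = call_cnvrs(cn)
        assert [(c.chrom, c.start, c.end, c.kind, c.silhouette) for c in a] == \
               [(c.chrom, c.start, c.end, c.kind, c.silhouette) for c in b]
        assert len(a) > 0
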