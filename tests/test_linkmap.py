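"""Two-point estimators, linkage grouping, binning, ordering, map comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mapanchor.genotypes import HET, MISSING, P1, P2, HaplotypeMatrix
from mapanchor.linkmap import (
    BinMap,
    GeneticBin,
    assign_bins,
    build_binmap,
    cluster_linkage_groups,
    compare_orders,
    haldane_cm,
    lod_two_point,
    order_bins,
    pairwise_recombinant_fraction,
    phase_normalize,
    ril_correct,
)
from mapanchor.simpop import SimConfig, simulate_ril_population
from tests.conftest import true_chromosome_labels


class TestEstimators:
    @pytest.mark.parametrize("r_hat,expected", [(0.0, 0.0), (0.5, 0.5), (0.15345, 0.09063)])
    def test_ril_correction_examples(self, r_hat, expected):
        assert ril_correct(r_hat) == pytest.approx(expected, abs=1e-5)

    @given(st.floats(min_value=0.0, max_value=0.4999))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_ril_correction_inverts_forward_transform(self, r):
        forward = 2 * r / (1 + 2 * r)
        assert abs(ril_correct(forward) - r) < 1e-12

    def test_ril_correction_domain(self):
        with pytest.raises(ValueError):
            ril_correct(1.0)

    def test_haldane_distance_examples(self):
        assert haldane_cm(0.0) == 0.0
        # r for 10 cM under Haldane: (1 - exp(-0.2)) / 2
        r10 = (1 - math.exp(-0.2)) / 2
        assert haldane_cm(r10) == pytest.approx(10.0, abs=1e-9)
        assert haldane_cm(0.5) == math.inf

    def test_haldane_distance_monotone(self):
        rs = np.linspace(0, 0.49, 50)
        ds = haldane_cm(rs)
        assert (np.diff(ds) > 0).all()

    def test_lod_examples(self):
        assert lod_two_point(0.5, 80) == pytest.approx(0.0, abs=1e-12)
        assert lod_two_point(0.0, 50) == pytest.approx(50 * math.log10(2))

    def test_lod_decreasing_in_r(self):
        rs = np.linspace(0, 0.5, 30)
        lods = lod_two_point(rs, 60)
        assert (np.diff(lods) < 1e-12).all()

    def test_pairwise_fraction_examples(self):
        a = np.array([P1] * 45 + [P2] * 45, dtype=np.int8)
        assert pairwise_recombinant_fraction(a, a) == (0.0, 90)
        comp = (1 - a).astype(np.int8)
        assert pairwise_recombinant_fraction(a, comp) == (1.0, 90)
        empty = np.full_like(a, MISSING)
        r, n = pairwise_recombinant_fraction(a, empty)
        assert math.isnan(r) and n == 0
        with pytest.raises(ValueError):
            pairwise_recombinant_fraction(a, a[:10])


def _matrix(vectors: dict[str, np.ndarray]) -> HaplotypeMatrix:
    ids = list(vectors)
    calls = np.stack([vectors[i] for i in ids]).astype(np.int8)
    n_inf = (calls != MISSING).sum(axis=1, keepdims=True) * np.ones_like(calls, dtype=int)
    return HaplotypeMatrix(ids, calls, np.ones_like(calls, dtype=float), n_inf,
                           [f"R{i}" for i in range(calls.shape[1])])


class TestClustering:
    def test_two_unlinked_blocks_give_two_groups(self):
        rng = np.random.default_rng(0)
        p = rng.integers(0, 2, 60).astype(np.int8)
        q = rng.integers(0, 2, 60).astype(np.int8)
        hap = _matrix({"a1": p, "a2": p.copy(), "b1": q, "b2": q.copy()})
        part = cluster_linkage_groups(hap)
        assert len(part.groups) == 2
        assert {tuple(sorted(m)) for m in part.groups.values()} == {
            ("a1", "a2"),
            ("b1", "b2"),
        }

    def test_degenerate_thresholds_merge_everything(self):
        rng = np.random.default_rng(1)
        vecs = {f"s{i}": rng.integers(0, 2, 40).astype(np.int8) for i in range(6)}
        part = cluster_linkage_groups(_matrix(vecs), lod_min=0.0, r_max=0.5)
        assert len(part.groups) == 1
        assert len(part.groups[1]) == 6

    def test_short_scaffolds_excluded(self):
        rng = np.random.default_rng(2)
        p = rng.integers(0, 2, 60).astype(np.int8)
        hap = _matrix({"long1": p, "long2": p.copy(), "tiny": p.copy()})
        part = cluster_linkage_groups(
            hap, lengths={"long1": 5000, "long2": 5000, "tiny": 500}
        )
        assert part.groups == {1: ["long1", "long2"]}
        assert part.unplaced == ["tiny"]

    def test_preset_recovers_true_chromosome_partition(self, lettuce_run):
        from sklearn.metrics import adjusted_rand_score

        bm = lettuce_run["bin_map"]
        sim = lettuce_run["sim"]
        assert len(bm.lgs) == sim.config.n_chromosomes
        placed = sorted(bm.scaffold_to)
        truth = true_chromosome_labels(sim, placed)
        pred = [bm.scaffold_to[s][0] for s in placed]
        assert adjusted_rand_score(truth, pred) == 1.0


class TestBins:
    def test_identical_vectors_share_one_bin(self):
        v = np.array([P1, P2, P1, P2, P1] * 10, dtype=np.int8)
        bins = assign_bins(_matrix({"x": v, "y": v.copy()}))
        assert len(bins) == 1
        assert sorted(bins[0].members) == ["x", "y"]

    def test_single_informative_mismatch_separates_bins(self):
        v = np.array([P1, P2] * 25, dtype=np.int8)
        w = v.copy()
        w[0] = P2
        bins = assign_bins(_matrix({"x": v, "y": w}), max_mismatch=0)
        assert len(bins) == 2

    def test_missing_data_tolerated_in_cosegregation(self):
        v = np.array([P1, P2] * 25, dtype=np.int8)
        w = v.copy()
        w[:10] = MISSING
        bins = assign_bins(_matrix({"x": v, "y": w}))
        assert len(bins) == 1

    def test_truth_cosegregating_scaffolds_share_bins(self, lettuce_run):
        # Scaffolds with identical noise-free segregation (zero homozygous
        # discordance over many lines) must stay together: same LG, same or
        # immediately adjacent bin (residual heterozygosity at a segment
        # boundary can legitimately split a bin), and mostly the same bin.
        from mapanchor.haplo import consensus_matrix
        from mapanchor.linkmap import pairwise_matrices

        sim = lettuce_run["sim"]
        bm = lettuce_run["bin_map"]
        clean = consensus_matrix(sim.clean_table, min_markers=1)
        keep = [s for s in clean.scaffold_ids if s in bm.scaffold_to]
        sub = clean.subset(keep)
        r, n = pairwise_matrices(sub.calls)
        cose = (r == 0.0) & (n >= 50)
        ii, jj = np.nonzero(np.triu(cose, 1))
        assert len(ii) > 0
        same_bin = 0
        for i, j in zip(ii, jj):
            lg_i, bin_i = bm.scaffold_to[keep[i]]
            lg_j, bin_j = bm.scaffold_to[keep[j]]
            assert lg_i == lg_j
            assert abs(bin_i - bin_j) <= 1
            same_bin += bin_i == bin_j
        assert same_bin > 0


class TestOrdering:
    def _bins_from_loci(self, loci_cm, n_rils=500, seed=0, length=40.0):
        cfg = SimConfig(
            n_chromosomes=1,
            chrom_genetic_lengths=(length,),
            chrom_physical_lengths=(100_000,),
            n_rils=n_rils,
            selfing_generations=7,
        )
        pop = simulate_ril_population(cfg, np.random.default_rng(seed))
        calls = pop.genotype_at(0, np.array(loci_cm, dtype=float))
        return [
            GeneticBin(i, [f"L{i:02d}"], calls[i].astype(np.int8))
            for i in range(len(loci_cm))
        ]

    def test_single_bin_at_origin(self):
        bins = [GeneticBin(0, ["only"], np.array([P1, P2, P1], dtype=np.int8))]
        out = order_bins(bins)
        assert out[0].cm == 0.0

    def test_linear_loci_recovered_in_order(self):
        bins = self._bins_from_loci([0.0, 10.0, 20.0, 30.0])
        out = order_bins(bins)
        members = [b.members[0] for b in out]
        assert members in (["L00", "L01", "L02", "L03"], ["L03", "L02", "L01", "L00"])
        from scipy.stats import spearmanr

        rho = spearmanr(range(4), [int(m[1:]) for m in members]).statistic
        assert abs(rho) == pytest.approx(1.0)
        cms = [b.cm for b in out]
        assert cms[0] == 0.0
        assert all(b2 > b1 for b1, b2 in zip(cms, cms[1:]))

    def test_order_is_deterministic(self):
        bins_a = self._bins_from_loci([0, 7, 14, 21, 28, 35], seed=5)
        bins_b = self._bins_from_loci([0, 7, 14, 21, 28, 35], seed=5)
        out_a = [b.members for b in order_bins(bins_a)]
        out_b = [b.members for b in order_bins(bins_b)]
        assert out_a == out_b

    def test_map_length_tracks_simulated_truth(self, lettuce_run):
        # Cumulative Haldane distance over bins tracks each simulated
        # chromosome's genetic length, but is compressed: lines recombining
        # inside a scaffold often fail the consensus majority and drop out
        # of the informative set, deflating adjacent recombinant fractions.
        # At the preset's scaffold density this compression is ~30-45%.
        bm = lettuce_run["bin_map"]
        glen = lettuce_run["sim"].config.chrom_genetic_lengths[0]
        for bins in bm.lgs.values():
            span = bins[-1].cm
            assert 0.45 * glen < span < 1.1 * glen


class TestPhaseInvariance:
    def test_flipping_one_vector_leaves_binning_invariant(self):
        rng = np.random.default_rng(3)
        cfg = SimConfig(
            n_chromosomes=1,
            chrom_genetic_lengths=(30.0,),
            chrom_physical_lengths=(50_000,),
            n_rils=80,
            selfing_generations=7,
        )
        pop = simulate_ril_population(cfg, rng)
        loci = np.linspace(0, 30, 8)
        calls = pop.genotype_at(0, loci).astype(np.int8)
        vecs = {f"s{i}": calls[i] for i in range(8)}
        hap = _matrix(vecs)
        norm, _ = phase_normalize(hap)
        bins_ref = [sorted(b.members) for b in order_bins(assign_bins(norm))]
        flipped = {k: v.copy() for k, v in vecs.items()}
        hom = flipped["s3"] <= P2
        flipped["s3"][hom] = 1 - flipped["s3"][hom]
        norm2, flips = phase_normalize(_matrix(flipped))
        bins_flip = [sorted(b.members) for b in order_bins(assign_bins(norm2))]
        assert bins_ref == bins_flip
        # the tree is rooted at s0, so the flipped scaffold is flipped back
        assert flips["s3"] is True
        assert not any(v for k, v in flips.items() if k != "s3")


class TestCompareOrders:
    def _map(self, rows):
        return pd.DataFrame(rows, columns=["scaffold_id", "LG", "bin_index", "bin_cM"])

    def test_identical_maps_fully_consistent(self):
        rows = [(f"s{i}", 1, i, float(i)) for i in range(10)]
        frac, rhos = compare_orders(self._map(rows), self._map(rows))
        assert frac == 0.0
        assert rhos[1] == pytest.approx(1.0)

    def test_reversed_map_counts_as_colinear(self):
        rows = [(f"s{i}", 1, i, float(i)) for i in range(10)]
        rev = [(f"s{i}", 1, 9 - i, float(9 - i)) for i in range(10)]
        frac, rhos = compare_orders(self._map(rows), self._map(rev))
        assert frac == 0.0
        assert rhos[1] == pytest.approx(1.0)

    def test_moved_markers_counted_as_inconsistent(self):
        rows = [(f"s{i}", 1, i, float(i)) for i in range(100)]
        moved = [
            (f"s{i}", 2 if i < 2 else 1, i, float(i)) for i in range(100)
        ]
        frac, _ = compare_orders(self._map(rows), self._map(moved))
        assert frac == pytest.approx(0.02)

    def test_disjoint_maps_not_comparable(self):
        a = self._map([("x", 1, 0, 0.0)])
        b = self._map([("y", 1, 0, 0.0)])
        with pytest.raises(ValueError):
            compare_orders(a, b)
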