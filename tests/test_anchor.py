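"""Superscaffold placement, orientation, order refinement and pseudomolecules."""

import itertools
import re

import numpy as np
import pytest

from mapanchor.genotypes import HET, MISSING, P1, P2
from mapanchor.linkmap import BinMap, GeneticBin
from mapanchor.anchor import (
    build_pseudomolecules,
    count_double_recombinants,
    find_telomere_arrays,
    flag_misassembly,
    initial_order,
    orient_superscaffold,
    place_superscaffold,
    refine_order,
    superscaffold_sequence,
)
from mapanchor.seqio import fasta_from_agp, reverse_complement, validate_agp
from mapanchor.simpop import SuperscaffoldLayout


def _bin_map(assignments: dict[str, tuple[int, int]], bins_per_lg: int = 10) -> BinMap:
    """BinMap with the given scaffold -> (LG, bin) and 1-cM bin spacing."""
    lgs: dict[int, list[GeneticBin]] = {}
    by_lg: dict[int, dict[int, list[str]]] = {}
    for sid, (lg, b) in assignments.items():
        by_lg.setdefault(lg, {}).setdefault(b, []).append(sid)
    for lg, bins in by_lg.items():
        lg_bins = []
        for b in range(bins_per_lg):
            lg_bins.append(
                GeneticBin(b, bins.get(b, []), np.empty(0, dtype=np.int8), float(b))
            )
        lgs[lg] = lg_bins
    return BinMap(lgs)


def _layout(ss_id, scaffold_ids, length=1000, strand="+", gap=100):
    return SuperscaffoldLayout.from_parts(
        ss_id, [(sid, length, strand) for sid in scaffold_ids], gap
    )


class TestPlacement:
    def test_components_spanning_bins_are_placed_with_span(self):
        bm = _bin_map({f"s{i}": (2, i) for i in range(3, 8)})
        placement = place_superscaffold(_layout("SS1", [f"s{i}" for i in range(3, 8)]), bm)
        assert placement.status == "placed"
        assert (placement.lg, placement.first_bin, placement.last_bin) == (2, 3, 7)
        assert placement.span_cm == pytest.approx(4.0)
        assert placement.orientation == "forward"

    def test_single_bin_superscaffold_cannot_be_oriented(self):
        bm = _bin_map({"a": (1, 4), "b": (1, 4)})
        placement = place_superscaffold(_layout("SS1", ["a", "b"]), bm)
        assert placement.status == "placed"
        assert placement.span_cm == 0.0
        assert placement.orientation == "unoriented"

    def test_unmapped_superscaffold_is_unplaced(self):
        bm = _bin_map({"elsewhere": (1, 0)})
        placement = place_superscaffold(_layout("SS1", ["x", "y"]), bm)
        assert placement.status == "unplaced"

    def test_descending_bins_give_reverse_orientation(self):
        bm = _bin_map({"a": (1, 7), "b": (1, 5), "c": (1, 3)})
        placement = place_superscaffold(_layout("SS1", ["a", "b", "c"]), bm)
        assert placement.orientation == "reverse"


class TestMisassembly:
    def test_cross_lg_components_flagged_with_split_point(self):
        bm = _bin_map({"a": (1, 0), "b": (1, 1), "c": (5, 2), "d": (5, 3)})
        mis, split_at = flag_misassembly(_layout("SS1", ["a", "b", "c", "d"]), bm)
        assert mis is True
        assert split_at == 2  # between components b and c

    def test_weakly_monotone_bins_are_clean(self):
        bm = _bin_map({"a": (1, 1), "b": (1, 2), "c": (1, 2), "d": (1, 3)})
        mis, _ = flag_misassembly(_layout("SS1", ["a", "b", "c", "d"]), bm)
        assert mis is False

    def test_scrambled_bins_beyond_tolerance_flagged(self):
        order = {
            "a": (1, 9), "b": (1, 0), "c": (1, 8), "d": (1, 1),
            "e": (1, 7), "f": (1, 2), "g": (1, 6), "h": (1, 3),
        }
        mis, _ = flag_misassembly(_layout("SS1", list(order)), _bin_map(order), tolerance=2)
        assert mis is True

    def test_planted_cross_lg_joins_always_flagged(self, lettuce_run):
        # A superscaffold whose placed components truly span more than one
        # chromosome (a planted superscaffold misjoin, or the host of a
        # split cross-chromosome chimera) must be flagged; every other
        # superscaffold must not be.
        from mapanchor.pipeline import _split_layouts
        from tests.conftest import true_chromosome_labels

        sim = lettuce_run["sim"]
        bm = lettuce_run["bin_map"]
        layouts = _split_layouts(sim.layouts, lettuce_run["split_map"])
        n_cross = 0
        for lay in layouts:
            placed = [c.scaffold_id for c in lay.components if c.scaffold_id in bm.scaffold_to]
            cross_chrom = len(set(true_chromosome_labels(sim, placed))) > 1
            n_cross += cross_chrom
            mis, _ = flag_misassembly(lay, bm)
            if cross_chrom:
                assert mis, f"{lay.superscaffold_id} misjoin not flagged"
            else:
                assert not mis, f"{lay.superscaffold_id} falsely flagged"
        assert n_cross >= 2

    def test_orientation_matches_truth_for_orientable_superscaffolds(self, lettuce_run):
        from tests.conftest import lg_directions

        sim = lettuce_run["sim"]
        bm = lettuce_run["bin_map"]
        sst = sim.truth.superscaffolds.set_index("superscaffold_id")
        signs = lg_directions(bm, sim)
        total = correct = 0
        for lay in sim.layouts:
            if sst.loc[lay.superscaffold_id, "is_misjoin"]:
                continue
            p = place_superscaffold(lay, bm)
            if p.status != "placed" or p.orientation == "unoriented":
                continue
            want_fwd = sst.loc[lay.superscaffold_id, "orientation"] == "+"
            if signs[p.lg] < 0:  # LG direction vs chromosome is arbitrary
                want_fwd = not want_fwd
            total += 1
            correct += p.orientation == ("forward" if want_fwd else "reverse")
        assert total > 20
        assert correct / total >= 0.99


def _brute_force_double_recombinants(order, vectors):
    """Independent oracle: per RIL, condense to homozygous calls and scan."""
    n_ril = len(next(iter(vectors.values())))
    total = 0
    for ril in range(n_ril):
        seq = [vectors[u][ril] for u in order]
        hom = [c for c in seq if c in (P1, P2)]
        for k in range(1, len(hom) - 1):
            if hom[k] != hom[k - 1] and hom[k] != hom[k + 1]:
                total += 1
    return total


class TestDoubleRecombinants:
    def test_single_crossover_gradient_has_none(self):
        vectors = {
            "u1": np.array([P1, P1, P1], dtype=np.int8),
            "u2": np.array([P1, P1, P2], dtype=np.int8),
            "u3": np.array([P1, P2, P2], dtype=np.int8),
            "u4": np.array([P2, P2, P2], dtype=np.int8),
        }
        assert count_double_recombinants(["u1", "u2", "u3", "u4"], vectors) == 0

    def test_single_flip_back_pattern_counts_once(self):
        vectors = {
            "u1": np.array([P1], dtype=np.int8),
            "u2": np.array([P2], dtype=np.int8),
            "u3": np.array([P1], dtype=np.int8),
        }
        assert count_double_recombinants(["u1", "u2", "u3"], vectors) == 1

    def test_matches_brute_force_on_all_permutations(self):
        rng = np.random.default_rng(0)
        for n_units in (4, 5, 6):
            units = [f"u{k}" for k in range(n_units)]
            vectors = {
                u: rng.integers(0, 4, size=6).astype(np.int8) for u in units
            }
            for perm in itertools.permutations(units):
                assert count_double_recombinants(perm, vectors) == \
                    _brute_force_double_recombinants(perm, vectors)

    def test_fewer_than_three_units_counts_zero(self):
        v = {"a": np.array([P1], dtype=np.int8), "b": np.array([P2], dtype=np.int8)}
        assert count_double_recombinants(["a", "b"], v) == 0


class TestRefineOrder:
    def _gradient_vectors(self, n_units=10, n_rils=60, seed=2):
        # units on a genetic line: RIL r switches P1->P2 at a random unit
        rng = np.random.default_rng(seed)
        cut = rng.integers(0, n_units + 1, size=n_rils)
        vectors = {}
        for k in range(n_units):
            vectors[f"u{k:02d}"] = np.where(k < cut, P1, P2).astype(np.int8)
        return vectors

    def test_optimal_order_returned_unchanged(self):
        vectors = self._gradient_vectors()
        order = sorted(vectors)
        assert refine_order(order, vectors) == order

    def test_adjacent_swap_relative_to_truth_repaired(self):
        vectors = self._gradient_vectors()
        truth = sorted(vectors)
        scrambled = truth.copy()
        scrambled[4], scrambled[5] = scrambled[5], scrambled[4]
        refined = refine_order(scrambled, vectors)
        assert refined in (truth, truth[::-1])

    def test_objective_never_increases(self):
        rng = np.random.default_rng(9)
        vectors = {f"u{k}": rng.integers(0, 4, size=30).astype(np.int8) for k in range(8)}
        order = list(vectors)
        before = count_double_recombinants(order, vectors)
        after = count_double_recombinants(refine_order(order, vectors), vectors)
        assert after <= before


class TestPseudomolecules:
    def _setup(self, lengths=(1000, 2000, 500), seed=0):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        seqs = {
            f"sc{i}": "".join(rng.choice(bases, size=n)) for i, n in enumerate(lengths)
        }
        layouts = {
            f"ss{i}": _layout(f"ss{i}", [f"sc{i}"], length=n, gap=0)
            for i, n in enumerate(lengths)
        }
        from mapanchor.anchor import Placement

        placements = {
            f"ss{i}": Placement(f"ss{i}", 1, i, i, 0.0, "unoriented", "placed")
            for i in range(len(lengths))
        }
        return seqs, layouts, placements

    def test_spacer_arithmetic_and_n_runs(self):
        seqs, layouts, placements = self._setup()
        fasta, agp = build_pseudomolecules(
            {1: ["ss0", "ss1", "ss2"]}, placements, layouts, seqs, spacer_bp=10_000
        )
        seq = fasta["LG1"]
        assert len(seq) == 1000 + 2000 + 500 + 2 * 10_000
        runs = [len(m.group(0)) for m in re.finditer("N+", seq)]
        assert runs == [10_000, 10_000]

    def test_single_superscaffold_has_no_spacer(self):
        seqs, layouts, placements = self._setup()
        fasta, _ = build_pseudomolecules(
            {1: ["ss1"]}, placements, layouts, seqs, spacer_bp=10_000
        )
        assert len(fasta["LG1"]) == 2000
        assert "N" not in fasta["LG1"]

    def test_agp_fasta_round_trip_byte_identical(self):
        seqs, layouts, placements = self._setup()
        # make one superscaffold multi-component with a '-' strand and
        # reverse placement to exercise both flips
        layouts["ss1"] = SuperscaffoldLayout.from_parts(
            "ss1", [("sc1", 2000, "-"), ("sc0", 1000, "+")], gap_bp=100
        )
        placements["ss1"].orientation = "reverse"
        placements["ss1"].first_bin, placements["ss1"].last_bin = 5, 3
        fasta, agp = build_pseudomolecules(
            {1: ["ss1", "ss2"]}, placements, layouts, seqs, spacer_bp=10_000
        )
        validate_agp(agp)
        rebuilt = fasta_from_agp(agp, seqs)
        assert rebuilt == fasta

    def test_reverse_placement_emits_reverse_complement(self):
        seqs, layouts, placements = self._setup()
        placements["ss0"].orientation = "reverse"
        fasta, _ = build_pseudomolecules(
            {1: ["ss0"]}, placements, layouts, seqs, spacer_bp=0
        )
        assert fasta["LG1"] == reverse_complement(seqs["sc0"])

    def test_missing_component_sequence_is_hard_error(self):
        seqs, layouts, placements = self._setup()
        del seqs["sc1"]
        with pytest.raises(KeyError, match="sc1"):
            build_pseudomolecules(
                {1: ["ss0", "ss1"]}, placements, layouts, seqs, spacer_bp=10
            )


class TestTelomeres:
    def _random_seq(self, n, seed):
        rng = np.random.default_rng(seed)
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    def test_terminal_array_detected_with_copy_count(self):
        seq = self._random_seq(50_000, 0) + "TTTAGGG" * 30
        hits = find_telomere_arrays({"chr1": seq})
        assert len(hits) == 1
        assert (hits[0].end, hits[0].copies) == ("3prime", 30)

    def test_reverse_complement_motif_at_five_prime(self):
        seq = "CCCTAAA" * 30 + self._random_seq(50_000, 1)
        hits = find_telomere_arrays({"chr1": seq})
        assert len(hits) == 1
        assert hits[0].end == "5prime"
        assert hits[0].motif == "CCCTAAA"

    @pytest.mark.parametrize("seed", range(3))
    def test_random_sequence_yields_no_hits(self, seed):
        seq = self._random_seq(1_000_000, 10 + seed)
        assert find_telomere_arrays({"chr1": seq}, min_copies=10) == []

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            find_telomere_arrays({"x": "ACGT"}, motif="")
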