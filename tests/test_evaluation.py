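"""Per-read scoring, L1, precision/sensitivity, UniFrac and rarefaction.

The weighted UniFrac implementation (bottom-up tree EMD) is checked
against an exhaustive min-cost-flow linear program on small random
instances; L1 against a naive element-wise loop.
"""

import numpy as np
import pytest

import metaprof as mp
from metaprof.errors import ValidationError
from metaprof.evaluation import (
    DetectionCounts,
    detection_counts,
    l1_distance,
    precision,
    rarefaction,
    score_read_annotations,
    sensitivity,
    weighted_unifrac,
)
from metaprof.evaluation import _node_masses
from metaprof.integration import ReadAnnotation
from metaprof.profiling import build_profile
from metaprof.simulate import make_taxonomy
from metaprof.taxonomy import EVAL_RANKS

from conftest import emd_lp_oracle, unifrac_node_masses


def ann(read_id, taxon, source="read_direct"):
    if taxon is None:
        source = "unclassified"
    return ReadAnnotation(read_id, taxon, source)


def random_annotations(tree, rng, n, include_internal=True):
    """Random reads annotated at species or (optionally) internal ranks."""
    pool = sorted(
        t for t, nd in tree.nodes.items()
        if nd.rank == "species"
        or (include_internal and nd.rank in ("genus", "family", "order"))
    )
    return [
        ann(f"r{i}", pool[rng.integers(len(pool))]) for i in range(n)
    ]


class TestScoreReadAnnotations:
    def test_perfect_predictions(self, small_tree):
        truth = {"r1": "sA", "r2": "sC"}
        preds = [ann("r1", "sA"), ann("r2", "sC")]
        table = score_read_annotations(preds, truth, small_tree)
        assert table["species"].tpr == 1.0
        assert table["species"].unannotated == 0

    def test_genus_prediction_for_species_truth(self, small_tree):
        table = score_read_annotations([ann("r1", "g1")], {"r1": "sA"}, small_tree)
        # oracle: project both onto each rank and compare
        assert table["species"].unannotated == 1
        assert table["genus"].correct == 1
        assert table["family"].correct == 1

    def test_wrong_species_right_genus(self, small_tree):
        table = score_read_annotations([ann("r1", "sB")], {"r1": "sA"}, small_tree)
        assert table["species"].incorrect == 1
        assert table["genus"].correct == 1

    def test_unclassified_counts_unannotated_everywhere(self, small_tree):
        table = score_read_annotations([ann("r1", None)], {"r1": "sA"}, small_tree)
        assert all(table[r].unannotated == 1 for r in EVAL_RANKS)

    def test_tpr_zero_when_nothing_annotated(self, small_tree):
        table = score_read_annotations([ann("r1", None)], {"r1": "sA"}, small_tree)
        assert table["species"].tpr == 0.0

    def test_missing_truth_is_consistency_error(self, small_tree):
        with pytest.raises(ValidationError):
            score_read_annotations([ann("rX", "sA")], {}, small_tree)

    def test_counts_partition_reads_at_every_rank(self, small_tree):
        rng = np.random.default_rng(0)
        truth = {f"r{i}": ["sA", "sB", "sC", "sD"][rng.integers(4)] for i in range(50)}
        preds = [
            ann(r, ["sA", "sB", "g1", None][rng.integers(4)]) for r in truth
        ]
        table = score_read_annotations(preds, truth, small_tree)
        for rank in EVAL_RANKS:
            assert table[rank].total == 50

    def test_correct_counts_non_increasing_with_depth(self, small_tree):
        rng = np.random.default_rng(5)
        truth = {f"r{i}": ["sA", "sB", "sC", "sD"][rng.integers(4)] for i in range(80)}
        preds = [ann(r, ["sA", "sC", "sD", "g2"][rng.integers(4)]) for r in truth]
        table = score_read_annotations(preds, truth, small_tree)
        corrects = [table[r].correct for r in EVAL_RANKS]
        assert all(a >= b for a, b in zip(corrects, corrects[1:]))


class TestL1Distance:
    def test_identical_profiles_zero(self, small_tree):
        prof = build_profile([ann("r1", "sA"), ann("r2", "sC")], small_tree)
        for rank in EVAL_RANKS:
            assert l1_distance(prof, prof, rank) == 0.0

    def test_disjoint_full_mass_profiles_two(self, two_phylum_tree):
        p1 = build_profile([ann("r1", "sX")], two_phylum_tree)
        p2 = build_profile([ann("r1", "sY")], two_phylum_tree)
        for rank in EVAL_RANKS:
            assert l1_distance(p1, p2, rank) == 2.0

    def test_matches_naive_loop_on_random_profiles(self, small_tree):
        rng = np.random.default_rng(21)
        for _ in range(30):
            p1 = build_profile(random_annotations(small_tree, rng, 40), small_tree)
            p2 = build_profile(random_annotations(small_tree, rng, 40), small_tree)
            for rank in EVAL_RANKS:
                a, b = p1.per_rank[rank], p2.per_rank[rank]
                expected = 0.0
                for t in set(a) | set(b):
                    expected += abs(a.get(t, 0.0) - b.get(t, 0.0))
                got = l1_distance(p1, p2, rank)
                assert got == pytest.approx(expected)
                assert 0.0 <= got <= 2.0


class TestPrecisionSensitivity:
    def test_direct_formulas(self):
        assert precision(DetectionCounts(3, 1, 0)) == 0.75
        assert sensitivity(DetectionCounts(3, 0, 0)) == 1.0
        assert sensitivity(DetectionCounts(3, 0, 1)) == 0.75

    def test_undefined_cases_absent(self):
        assert precision(DetectionCounts(0, 0, 5)) is None
        assert sensitivity(DetectionCounts(0, 5, 0)) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DetectionCounts(-1, 0, 0)

    def test_detection_identity(self, small_tree):
        prof = build_profile([ann("r1", "sA"), ann("r2", "sC")], small_tree)
        c = detection_counts(prof, prof, "species", cutoff=0.0)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_below_cutoff_prediction_not_counted_fp(self, small_tree):
        pred = build_profile(
            [ann("r1", "sB")] + [ann(f"a{i}", "sA") for i in range(999)], small_tree
        )
        ref = build_profile([ann("r1", "sA")], small_tree)
        c = detection_counts(pred, ref, "species", cutoff=0.01)
        # sB at 1e-3 is below the cutoff: thresholding removes the FP
        assert c.fp == 0 and c.tp == 1

    def test_empty_prediction(self, small_tree):
        pred = build_profile([ann("r1", None)], small_tree)
        ref = build_profile([ann("r1", "sA"), ann("r2", "sC")], small_tree)
        c = detection_counts(pred, ref, "species", cutoff=0.0)
        assert c.tp == 0 and c.fn == 2

    def test_raising_cutoff_never_increases_sensitivity(self, small_tree):
        rng = np.random.default_rng(17)
        pred = build_profile(random_annotations(small_tree, rng, 60), small_tree)
        ref = build_profile(random_annotations(small_tree, rng, 60), small_tree)
        prev = 1.0
        for cutoff in (0.0, 0.01, 0.05, 0.2, 0.5):
            s = sensitivity(detection_counts(pred, ref, "species", cutoff))
            if s is not None:
                assert s <= prev + 1e-12
                prev = s


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self, small_tree):
        prof = build_profile([ann("r1", "sA"), ann("r2", "sC")], small_tree)
        assert weighted_unifrac(prof, prof, small_tree) == pytest.approx(0.0)

    def test_sibling_species_mass_move(self, small_tree):
        """Moving 0.2 between sibling species costs 0.4 (one edge up, one down)."""
        p1 = build_profile(
            [ann(f"a{i}", "sA") for i in range(7)] + [ann(f"b{i}", "sB") for i in range(3)],
            small_tree,
        )
        p2 = build_profile(
            [ann(f"a{i}", "sA") for i in range(5)] + [ann(f"b{i}", "sB") for i in range(5)],
            small_tree,
        )
        got = weighted_unifrac(p1, p2, small_tree)
        assert got == pytest.approx(0.4, abs=1e-12)
        # cross-check against the transport LP
        m1 = _node_masses(p1, small_tree, EVAL_RANKS)
        m2 = _node_masses(p2, small_tree, EVAL_RANKS)
        assert got == pytest.approx(emd_lp_oracle(small_tree, m1, m2), abs=1e-9)

    def test_internal_node_mass_stays_on_node(self, small_tree):
        # genus-annotated reads sit on the genus node: distance to a species
        # below it is one rank step
        p1 = build_profile([ann("r1", "g1")], small_tree)
        p2 = build_profile([ann("r1", "sA")], small_tree)
        assert weighted_unifrac(p1, p2, small_tree) == pytest.approx(1.0)

    def test_different_unclassified_fractions_are_renormalised(self, small_tree):
        p1 = build_profile([ann("r1", "sA"), ann("u1", None), ann("u2", None)],
                           small_tree)
        p2 = build_profile([ann("r1", "sA")], small_tree)
        assert weighted_unifrac(p1, p2, small_tree) == pytest.approx(0.0)

    def test_matches_lp_oracle_on_random_instances(self):
        rng = np.random.default_rng(31)
        for trial in range(40):
            tree = make_taxonomy(seed=int(rng.integers(2**31)), n_species=int(rng.integers(2, 7)))
            assert len(tree) <= 30
            a1 = random_annotations(tree, rng, int(rng.integers(5, 40)))
            a2 = random_annotations(tree, rng, int(rng.integers(5, 40)))
            p1 = build_profile(a1, tree)
            p2 = build_profile(a2, tree)
            got = weighted_unifrac(p1, p2, tree)
            expected = emd_lp_oracle(
                tree, unifrac_node_masses(tree, a1), unifrac_node_masses(tree, a2)
            )
            assert got == pytest.approx(expected, abs=1e-9)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(33)
        tree = make_taxonomy(seed=3, n_species=6)
        profs = [
            build_profile(random_annotations(tree, rng, 20), tree) for _ in range(6)
        ]
        for _ in range(20):
            i, j, k = rng.integers(len(profs), size=3)
            dij = weighted_unifrac(profs[i], profs[j], tree)
            dji = weighted_unifrac(profs[j], profs[i], tree)
            assert dij == pytest.approx(dji, abs=1e-12)  # symmetry
            assert weighted_unifrac(profs[i], profs[i], tree) == pytest.approx(0.0)
            dik = weighted_unifrac(profs[i], profs[k], tree)
            dkj = weighted_unifrac(profs[k], profs[j], tree)
            assert dij <= dik + dkj + 1e-9  # triangle inequality

    def test_classified_vs_empty_is_error(self, small_tree):
        p1 = build_profile([ann("r1", "sA")], small_tree)
        p2 = build_profile([ann("r1", None)], small_tree)
        with pytest.raises(ValidationError):
            weighted_unifrac(p1, p2, small_tree)


class TestRarefaction:
    def _annotations(self, tree, n=400, seed=2):
        rng = np.random.default_rng(seed)
        return random_annotations(tree, rng, n, include_internal=False)

    def test_full_fraction_equals_full_data_count(self, small_tree):
        anns = self._annotations(small_tree)
        full = build_profile(anns, small_tree)
        table = rarefaction(anns, small_tree, "species", fractions=(100,), repeats=3)
        assert set(table["n_taxa"]) == {len(full.taxa("species"))}

    def test_deterministic_under_seed(self, small_tree):
        anns = self._annotations(small_tree)
        t1 = rarefaction(anns, small_tree, "species", seed=5)
        t2 = rarefaction(anns, small_tree, "species", seed=5)
        assert t1.equals(t2)

    def test_mean_counts_non_decreasing_in_fraction(self, small_tree):
        anns = self._annotations(small_tree)
        table = rarefaction(anns, small_tree, "species", repeats=10, seed=1)
        means = table.groupby("fraction")["n_taxa"].mean()
        assert (means.diff().dropna() >= -1e-9).all()

    def test_curve_levels_off_with_cutoff_on_saturated_community(self):
        """A community whose taxa are all common saturates early: the last
        two fractions differ by < 5% on average."""
        cfg = mp.SimulationConfig(seed=9, n_species=20, n_reads=3000,
                                  abundance_sigma=0.3, hit_noise=0.0,
                                  novel_fraction=0.0)
        ds = mp.simulate_dataset(cfg)
        res = mp.run_on_dataset(ds)
        table = rarefaction(res.read_annotations, ds.tree, "species",
                            fractions=(50, 90, 100), cutoff=1e-4, seed=0)
        means = table.groupby("fraction")["n_taxa"].mean()
        assert abs(means[100] - means[90]) / means[100] < 0.05

    def test_fraction_out_of_range_rejected(self, small_tree):
        with pytest.raises(ValueError):
            rarefaction(self._annotations(small_tree), small_tree, "species",
                        fractions=(120,))
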