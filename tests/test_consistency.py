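"""Split-half reliability, permutation/sign-flip inference, cumulative curves."""

import numpy as np
import pandas as pd
import pytest

from lepmem import (
    DegenerateDataError,
    StructuralError,
    cumulative_curves,
    make_matrix,
    permutation_test_delta_rho,
    rank_tests,
    spearman_brown,
    split_half_reliability,
)
from lepmem.consistency import (
    CurveSet,
    SplitIterations,
    compute_split_iterations,
    rowwise_spearman,
)

from conftest import make_trials, trials_row


def binary_matrix(rng, p_img, n_participants):
    """Bernoulli participant×image matrix with per-image probabilities."""
    return (rng.random((n_participants, len(p_img))) < p_img).astype(float)


def iterations_from(hj, hk):
    hj = np.atleast_2d(np.asarray(hj, dtype=float))
    hk = np.atleast_2d(np.asarray(hk, dtype=float))
    m = hj.shape[1]
    return SplitIterations(
        image_ids=np.array([f"I{i:02d}" for i in range(m)]),
        participant_ids=np.array(["P0", "P1"]),
        group_j=np.zeros((hj.shape[0], 1), dtype=np.intp),
        group_k=np.ones((hj.shape[0], 1), dtype=np.intp),
        hj=hj,
        hk=hk,
    )


class TestSpearmanBrown:
    @pytest.mark.parametrize("r, expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)])
    def test_values(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected, abs=1e-12)

    def test_strictly_increasing_and_maps_unit_interval(self):
        grid = np.linspace(-0.99, 1.0, 400)
        vals = [spearman_brown(r) for r in grid]
        assert np.all(np.diff(vals) > 0)
        inside = [spearman_brown(r) for r in np.linspace(0, 1, 100)]
        assert all(0.0 <= v <= 1.0 for v in inside)

    def test_undefined_at_minus_one(self):
        with pytest.raises(DegenerateDataError):
            spearman_brown(-1.0)


class TestMakeMatrix:
    def test_shape_and_column_means_match_image_scores(
        self, default_dataset, default_retained, default_scores
    ):
        trials, _ = default_retained
        analysed = trials[trials["image_id"] != "AP_01"]
        matrix, pids, iids = make_matrix(analysed)
        assert matrix.shape == (50, 57)
        scores = default_scores.set_index("image_id")
        np.testing.assert_allclose(
            matrix.mean(axis=0), scores.loc[iids, "hit_rate"].to_numpy(), atol=1e-12
        )

    def test_duplicate_trial_is_structural_error(self):
        rows = [
            trials_row("P1", "A", "recognition", "target", response="old"),
            trials_row("P1", "A", "recognition", "target", response="new"),
        ]
        with pytest.raises(StructuralError, match="duplicated"):
            make_matrix(make_trials(rows))

    def test_missing_cell_is_structural_error(self):
        rows = [
            trials_row("P1", "A", "recognition", "target", response="old"),
            trials_row("P1", "B", "recognition", "target", response="old"),
            trials_row("P2", "A", "recognition", "target", response="new"),
        ]
        with pytest.raises(StructuralError, match="missing"):
            make_matrix(make_trials(rows))


class TestSplitHalfReliability:
    def test_identical_participants_give_perfect_reliability(self):
        pattern = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        matrix = np.tile(pattern, (10, 1))
        classes = np.array(["AP"] * 4 + ["nonAP"] * 4)
        _, rel = split_half_reliability(
            matrix, classes, n_iterations=50, rng=np.random.default_rng(0)
        )
        for scope in ("all", "AP", "nonAP"):
            assert np.allclose(rel[scope].values, 1.0)

    def test_fair_coin_matrices_have_near_zero_reliability(self):
        """Monte-Carlo null: with no true image effects the corrected
        reliability is centred on zero.  A single dataset's value varies
        substantially (chance image effects are shared between halves), so the
        check averages over fresh datasets."""
        rng = np.random.default_rng(8)
        classes = np.array(["AP"] * 15 + ["nonAP"] * 15)
        means = []
        for _ in range(30):
            matrix = binary_matrix(rng, np.full(30, 0.5), 40)
            _, rel = split_half_reliability(
                matrix, classes, n_iterations=200, n_bootstrap=20, rng=rng
            )
            means.append(rel["all"].rho_mean)
        assert abs(np.mean(means)) < 0.1

    def test_identical_halves_have_unit_raw_correlation(self):
        h = np.random.default_rng(2).random((20, 12))
        assert np.allclose(rowwise_spearman(h, h), 1.0)

    def test_split_sizes_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(3)
        matrix = binary_matrix(rng, np.full(9, 0.6), 11)  # odd pool
        its = compute_split_iterations(
            matrix, np.arange(9).astype(str), np.arange(11).astype(str), 25, rng
        )
        assert its.group_j.shape[1] == 5 and its.group_k.shape[1] == 6
        for i in range(25):
            j, k = set(its.group_j[i]), set(its.group_k[i])
            assert j.isdisjoint(k)
            assert j | k == set(range(11))

    def test_invariant_to_simultaneous_image_relabeling(self):
        rng = np.random.default_rng(4)
        p = rng.random(14)
        matrix = binary_matrix(rng, p, 16)
        classes = np.array(["AP"] * 7 + ["nonAP"] * 7)
        _, rel = split_half_reliability(
            matrix, classes, n_iterations=40, rng=np.random.default_rng(10)
        )
        perm = rng.permutation(14)
        _, rel_perm = split_half_reliability(
            matrix[:, perm], classes[perm], n_iterations=40,
            rng=np.random.default_rng(10),
        )
        for scope in ("all", "AP", "nonAP"):
            np.testing.assert_allclose(
                rel[scope].values, rel_perm[scope].values, atol=1e-12
            )

    def test_more_participants_do_not_reduce_reliability(self):
        """Median corrected reliability at 40 participants >= at 20
        (50 seeds, fixed image-level effects)."""
        means = {20: [], 40: []}
        for seed in range(50):
            rng = np.random.default_rng(seed)
            from scipy.special import expit

            p = expit(rng.normal(0.5, 0.8, 16))
            for n in (20, 40):
                matrix = binary_matrix(rng, p, n)
                classes = np.array(["AP"] * 8 + ["nonAP"] * 8)
                _, rel = split_half_reliability(
                    matrix, classes, n_iterations=30, n_bootstrap=20,
                    rng=np.random.default_rng(1000 + seed),
                )
                means[n].append(rel["all"].rho_mean)
        assert np.median(means[40]) >= np.median(means[20])

    def test_bit_for_bit_reproducible_under_fixed_seed(self):
        rng_data = np.random.default_rng(6)
        matrix = binary_matrix(rng_data, rng_data.random(10), 12)
        classes = np.array(["AP"] * 5 + ["nonAP"] * 5)

        def run():
            rng = np.random.default_rng(77)
            its, rel = split_half_reliability(
                matrix, classes, n_iterations=30, rng=rng
            )
            d, p = permutation_test_delta_rho(
                matrix, classes, n_permutations=50, rng=rng, iterations=its
            )
            cs = cumulative_curves(its, classes, rng=rng, n_bootstrap=30)
            rt = rank_tests(cs, n_permutations=50, n_bootstrap=30, rng=rng)
            return rel, d, p, cs, rt

        rel1, d1, p1, cs1, rt1 = run()
        rel2, d2, p2, cs2, rt2 = run()
        assert (d1, p1) == (d2, p2)
        for scope in rel1:
            np.testing.assert_array_equal(rel1[scope].values, rel2[scope].values)
        pd.testing.assert_frame_equal(rt1, rt2)
        pd.testing.assert_frame_equal(cs1.to_frame(), cs2.to_frame())


class TestDeltaRho:
    def test_refuses_tiny_class(self):
        matrix = np.random.default_rng(0).random((10, 5))
        classes = np.array(["AP", "AP", "nonAP", "nonAP", "nonAP"])
        with pytest.raises(DegenerateDataError):
            permutation_test_delta_rho(matrix, classes, n_permutations=10)

    def test_p_has_resolution_floor(self):
        rng = np.random.default_rng(1)
        from scipy.special import expit

        p = np.concatenate([expit(rng.normal(0.6, 1.5, 10)), np.full(10, 0.6)])
        matrix = binary_matrix(rng, p, 30)
        classes = np.array(["AP"] * 10 + ["nonAP"] * 10)
        d, pval = permutation_test_delta_rho(
            matrix, classes, n_permutations=200, rng=rng, n_iterations=60
        )
        assert pval >= 1 / 200
        assert d > 0


class TestCumulativeCurves:
    def test_hand_computed_group_j_curve(self):
        its = iterations_from([1.0, 0.75, 0.5, 0.25], [1.0, 0.75, 0.5, 0.25])
        classes = np.array(["AP"] * 4)
        cs = cumulative_curves(
            its, classes, rng=np.random.default_rng(0), n_bootstrap=10, scopes=("AP",)
        )
        np.testing.assert_allclose(cs.mean_j["AP"][:2], [0.875, 0.75], atol=1e-12)
        assert list(cs.ranks["AP"]) == [2, 3, 4]

    def test_group_k_equal_to_j_gives_identical_curve(self):
        rng = np.random.default_rng(3)
        h = rng.random((40, 10))
        its = iterations_from(h, h.copy())
        classes = np.array(["AP"] * 10)
        cs = cumulative_curves(
            its, classes, rng=rng, n_bootstrap=20, scopes=("AP",)
        )
        np.testing.assert_allclose(cs.mean_j["AP"], cs.mean_k["AP"], atol=1e-12)

    def test_group_j_curve_is_non_increasing(self):
        rng = np.random.default_rng(9)
        its = iterations_from(rng.random((50, 12)), rng.random((50, 12)))
        classes = np.array(["AP"] * 12)
        cs = cumulative_curves(its, classes, rng=rng, n_bootstrap=20, scopes=("AP",))
        assert np.all(np.diff(cs.mean_j["AP"]) <= 1e-12)

    def test_shuffled_curve_stays_at_grand_mean(self):
        rng = np.random.default_rng(10)
        from scipy.special import expit

        p = expit(rng.normal(0.5, 1.0, 12))
        matrix = binary_matrix(rng, p, 30)
        classes = np.array(["AP"] * 6 + ["nonAP"] * 6)
        its = compute_split_iterations(
            matrix, np.arange(12).astype(str), np.arange(30).astype(str), 400, rng
        )
        cs = cumulative_curves(its, classes, rng=rng, n_bootstrap=300)
        for scope in ("all", "AP", "nonAP"):
            # the check runs at every rank of every scope, so use wide
            # (99.9%) bootstrap bands to control the familywise error of the
            # assertion itself
            curves = cs.curves_shuffled[scope]
            idx = rng.integers(0, curves.shape[0], size=(500, curves.shape[0]))
            boot = curves[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [0.05, 99.95], axis=0)
            gm = cs.grand_mean[scope]
            assert np.all(lo <= gm + 1e-9) and np.all(gm - 1e-9 <= hi)


class TestRankTests:
    def _curveset(self, diffs_ap, diffs_non=None):
        diffs_non = diffs_ap if diffs_non is None else diffs_non
        cs = CurveSet({}, {}, {}, {}, {}, {}, {}, {}, {})
        for scope, diffs in (("AP", diffs_ap), ("nonAP", diffs_non)):
            r = diffs.shape[1]
            cs.ranks[scope] = np.arange(2, 2 + r)
            cs.diffs_jk[scope] = diffs
            cs.diffs_ks[scope] = diffs
        return cs

    def test_all_zero_differences_give_p_one(self):
        cs = self._curveset(np.zeros((40, 6)))
        table = rank_tests(cs, n_permutations=100, n_bootstrap=50,
                           rng=np.random.default_rng(0))
        assert (table["p_bonferroni"] == 1.0).all()

    def test_overwhelming_effect_hits_resolution_floor(self):
        rng = np.random.default_rng(1)
        diffs = 1.0 + 0.01 * rng.standard_normal((60, 5))
        cs = self._curveset(diffs, np.zeros((60, 5)))
        table = rank_tests(cs, n_permutations=200, n_bootstrap=50, rng=rng)
        ap = table[(table.scope == "AP") & (table.comparison == "k_vs_shuffled")]
        assert (ap["p_raw"] == 1 / 200).all()

    def test_mismatched_iteration_counts_refused(self):
        cs = self._curveset(np.zeros((40, 5)), np.zeros((30, 5)))
        with pytest.raises(StructuralError, match="mismatched"):
            rank_tests(cs, n_permutations=10, n_bootstrap=10,
                       rng=np.random.default_rng(0))

    def test_surplus_nonap_rank_dropped_in_between_class_family(self):
        cs = self._curveset(np.zeros((20, 5)), np.zeros((20, 6)))
        table = rank_tests(cs, n_permutations=10, n_bootstrap=10,
                           rng=np.random.default_rng(0))
        between = table[table.scope == "between"]
        assert between["rank"].max() == 6  # ranks 2..6 — five common ranks
        assert len(between) == 5
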