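"""synergy: Bliss excess, outcome metrics, hit selection, overlaps."""

import math

import numpy as np
import pandas as pd
import pytest

from synscreen import screen_io, simulate
from synscreen.dose_response import DoseResponseFit, FourPLParams
from synscreen.errors import InsufficientDataError, ValidationError
from synscreen.synergy import (
    CombinationMatrix,
    SynergyMetrics,
    anchored_metrics,
    average_bliss,
    bliss_excess_matrix,
    bliss_expected,
    cross_entity_overlap,
    delta_emax,
    delta_ic50,
    max_effective_synergy,
    score_anchored_screen,
    select_hits,
)


def make_fit(ic50, censor=None):
    params = FourPLParams(1.0, 0.0, max(ic50, 1e-6), 1.0)
    return DoseResponseFit(params=params, converged=True, ic50=ic50,
                           ic50_censor=censor, auc=0.5,
                           dose_range=(0.1, 1e4), residual_sse=0.0)


def make_grid(viability, mono_a, mono_b, doses_a=None, doses_b=None):
    mono_a = np.asarray(mono_a, dtype=float)
    mono_b = np.asarray(mono_b, dtype=float)
    if doses_a is None:
        doses_a = 10.0 ** np.arange(mono_a.size)
    if doses_b is None:
        doses_b = 10.0 ** np.arange(mono_b.size)
    return CombinationMatrix(
        cell_line="L1", compound_a="A", compound_b="B",
        doses_a=doses_a, doses_b=doses_b,
        viability=np.asarray(viability, dtype=float),
        mono_a=mono_a, mono_b=mono_b)


class TestBlissExpected:
    @pytest.mark.parametrize("fa, fb, expected", [
        (0.0, 0.4, 0.4),       # null partner leaves the effect unchanged
        (0.5, 0.5, 0.75),
        (1.0, 0.3, 1.0),       # absorbing at complete inhibition
        (1.0, 0.0, 1.0),
    ])
    def test_values(self, fa, fb, expected):
        assert bliss_expected(fa, fb) == pytest.approx(expected)
        assert bliss_expected(fb, fa) == pytest.approx(expected)  # symmetric

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bliss_expected(1.2, 0.5)
        with pytest.raises(ValidationError):
            bliss_expected(0.5, -0.1)


class TestBlissExcessMatrix:
    def test_independence_null_is_zero(self):
        va = np.array([0.9, 0.6, 0.3])
        vb = np.array([0.8, 0.5, 0.2])
        fa, fb = 1 - va, 1 - vb
        expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
        grid = make_grid(1 - expected, va, vb)
        np.testing.assert_allclose(bliss_excess_matrix(grid), 0.0, atol=1e-12)

    def test_planted_excess_value(self):
        # fa=0.2, fb=0.3, observed inhibition 0.64 -> 0.64 - 0.44 = +0.20
        grid = make_grid([[1 - 0.64]], [0.8], [0.7],
                         doses_a=np.array([1.0]), doses_b=np.array([1.0]))
        assert bliss_excess_matrix(grid)[0, 0] == pytest.approx(0.20)

    def test_missing_margin_undefines_its_cells(self):
        rng = np.random.default_rng(0)
        va = rng.uniform(0.2, 1.0, 9)
        vb = rng.uniform(0.2, 1.0, 9)
        va[2] = np.nan
        grid = make_grid(rng.uniform(0, 1, (9, 9)), va, vb)
        excess = bliss_excess_matrix(grid)
        assert np.isfinite(excess).sum() == 72  # one margin removes one row

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(1)
        grid = make_grid(rng.uniform(0, 1, (4, 6)),
                         rng.uniform(0.1, 1.0, 4), rng.uniform(0.1, 1.0, 6))
        np.testing.assert_allclose(bliss_excess_matrix(grid.transpose()),
                                   bliss_excess_matrix(grid).T)


class TestAverageBliss:
    def test_values(self):
        assert average_bliss(np.zeros((3, 3))) == 0.0
        assert average_bliss(np.array([0.1, -0.1])) == pytest.approx(0.0)
        assert math.isnan(average_bliss(np.full((2, 2), np.nan)))

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(2)
        excess = rng.normal(0, 0.1, (3, 3))
        excess[1, 2] = np.nan
        manual = sum(excess[i, j] for i in range(3) for j in range(3)
                     if not math.isnan(excess[i, j])) / 8
        assert average_bliss(excess) == pytest.approx(manual)


class TestFoldChanges:
    def test_delta_emax_arithmetic(self):
        # mono viability 0.60 -> Emax 0.4; combo 0.10 -> 0.9; ratio 2.25
        assert delta_emax(0.60, 0.10) == pytest.approx(2.25)

    def test_delta_emax_identity_and_zero_cases(self):
        assert delta_emax(0.4, 0.4) == 1.0
        assert delta_emax(1.0, 1.0) == 1.0            # 0/0 convention
        assert math.isinf(delta_emax(1.0, 0.5))       # effect from null baseline
        assert delta_emax(1.0, 0.5) > 5               # satisfies any threshold

    def test_delta_ic50_orientation(self):
        assert delta_ic50(make_fit(10.0), make_fit(2.0)) == pytest.approx(5.0)
        assert delta_ic50(make_fit(10.0), make_fit(10.0)) == 1.0

    def test_delta_ic50_censored_bound_substitution(self):
        mono = make_fit(10000.0, censor=">cmax")
        combo = make_fit(100.0)
        assert delta_ic50(mono, combo) == pytest.approx(100.0)

    def test_delta_ic50_both_censored_same_bound(self):
        a = make_fit(10000.0, censor=">cmax")
        b = make_fit(10000.0, censor=">cmax")
        assert delta_ic50(a, b) == 1.0


class TestAnchoredMetrics:
    def test_average_over_anchors(self):
        m = anchored_metrics({
            "IC15": (1.0, 2.0, 0.02),
            "IC25": (2.0, 4.0, -0.01),
            "IC50": (3.0, 9.0, 0.02),
        })
        assert m.delta_ic50 == pytest.approx(5.0)
        assert m.delta_emax == pytest.approx(2.0)
        assert m.bliss_avg == pytest.approx(0.01)

    def test_single_anchor_passthrough(self):
        m = anchored_metrics({"IC25": (1.5, 2.5, 0.1)})
        assert (m.delta_emax, m.delta_ic50, m.bliss_avg) == (1.5, 2.5, 0.1)

    def test_infinity_propagates(self):
        m = anchored_metrics({"a": (math.inf, 2.0, 0.0), "b": (2.0, 2.0, 0.0)})
        assert math.isinf(m.delta_emax)

    def test_undefined_anchors_excluded(self):
        m = anchored_metrics({"a": (math.nan, 2.0, 0.1), "b": (3.0, 4.0, 0.3)})
        assert m.delta_emax == 3.0
        assert m.delta_ic50 == 3.0

    def test_no_anchors_is_error(self):
        with pytest.raises(InsufficientDataError):
            anchored_metrics({})


class TestSelectHits:
    @pytest.mark.parametrize("de, di, bl, expected", [
        (1.2, 5.1, -0.02, True),    # IC50 fold change above five
        (1.0, 1.0, 0.001, True),    # any positive average Bliss
        (5.0, 5.0, 0.0, False),     # strict inequalities at the boundary
        (6.0, 1.0, -0.5, True),
        (math.nan, math.nan, math.nan, False),
        (math.inf, 1.0, -0.1, True),
    ])
    def test_rule(self, de, di, bl, expected):
        m = SynergyMetrics(delta_emax=de, delta_ic50=di, bliss_avg=bl)
        assert select_hits(m) is expected


class TestMaxEffectiveSynergy:
    def test_only_low_viability_cells_qualify(self):
        viability = np.full((3, 4), 0.9)
        excess = np.full((3, 4), 0.5)
        viability[2, 3] = 0.4
        excess[2, 3] = 0.15
        assert max_effective_synergy(viability, excess) == pytest.approx(0.15)

    def test_no_qualifying_cell(self):
        assert math.isnan(max_effective_synergy(np.full((2, 2), 0.6),
                                                np.ones((2, 2))))

    def test_all_qualifying_reduces_to_max(self):
        rng = np.random.default_rng(3)
        excess = rng.normal(0, 0.2, (5, 5))
        assert max_effective_synergy(np.full((5, 5), 0.1), excess) == excess.max()

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            viability = rng.uniform(0, 1, (10, 10))
            excess = rng.normal(0, 0.2, (10, 10))
            got = max_effective_synergy(viability, excess)
            best = None
            for i in range(10):
                for j in range(10):
                    if viability[i, j] < 0.5:
                        if best is None or excess[i, j] > best:
                            best = excess[i, j]
            if best is None:
                assert math.isnan(got)
            else:
                assert got == best


class TestCrossEntityOverlap:
    def test_intersection(self):
        hits = {"L1": {"A": True, "B": True, "C": True},
                "L2": {"A": False, "B": True, "C": True}}
        assert cross_entity_overlap(hits) == {"B", "C"}

    def test_unscreened_compound_excluded_not_missed(self):
        hits = {f"L{i}": {"X": True} for i in range(1, 5)}
        hits["L5"] = {"Y": False}  # X never screened in L5
        assert "X" in cross_entity_overlap(hits)

    def test_disjoint_sets_empty(self):
        hits = {"L1": {"A": True, "B": False},
                "L2": {"A": False, "B": True}}
        assert cross_entity_overlap(hits) == set()

    def test_requires_two_lines(self):
        with pytest.raises(ValidationError):
            cross_entity_overlap({"L1": {"A": True}})


class TestGeneratorClosure:
    def test_noise_free_independence_gives_exact_zero(self):
        df, _ = simulate.gen_combination_matrix(
            delta=0.0, noise=simulate.NoiseModel(sigma=0.0, replicates=1),
            seed=0)
        points = screen_io.normalize_viability(df)
        grid = _matrix_from_points(points)
        excess = bliss_excess_matrix(grid)
        assert average_bliss(excess) == pytest.approx(0.0, abs=1e-12)

    def test_planted_excess_recovered_noise_free(self):
        df, truth = simulate.gen_combination_matrix(
            delta=0.15, noise=simulate.NoiseModel(sigma=0.0, replicates=1),
            seed=0)
        points = screen_io.normalize_viability(df)
        excess = bliss_excess_matrix(_matrix_from_points(points))
        # clip-limited cells aside, the bulk of the grid carries delta
        assert np.nanmedian(excess) == pytest.approx(0.15, abs=1e-9)


def _matrix_from_points(points: pd.DataFrame) -> CombinationMatrix:
    points = points.copy()
    points["anchor_compound"] = points["anchor_compound"].fillna("")
    combo = points[(points["anchor_dose"] > 0) & (points["dose"] > 0)]
    doses_a = np.sort(combo["anchor_dose"].unique())
    doses_b = np.sort(combo["dose"].unique())
    grid = (combo.pivot(index="anchor_dose", columns="dose",
                        values="viability")
            .loc[doses_a, doses_b].to_numpy())
    mono_a = (points[(points["dose"] == 0) & (points["anchor_dose"] > 0)]
              .set_index("anchor_dose")["viability"].loc[doses_a].to_numpy())
    mono_b = (points[(points["dose"] > 0) & (points["anchor_dose"] == 0)]
              .set_index("dose")["viability"].loc[doses_b].to_numpy())
    return CombinationMatrix(cell_line="L1", compound_a="ANCHOR",
                             compound_b="LIBRARY", doses_a=doses_a,
                             doses_b=doses_b, viability=grid,
                             mono_a=mono_a, mono_b=mono_b)


class TestAnchoredScreenScoring:
    def test_planted_compound_flagged_and_null_mostly_clean(self):
        df, truth = simulate.gen_anchored_library_screen(
            n_compounds=12, n_synergistic=2, delta=0.25,
            noise=simulate.NoiseModel(sigma=0.02, replicates=2), seed=9)
        points = screen_io.normalize_viability(df)
        scores = score_anchored_screen(points)
        assert len(scores) == 12
        assert set(scores["n_anchors"]) == {3}
        planted = set(truth["synergistic_compounds"])
        flagged = set(scores.loc[scores["is_hit"], "library_compound"])
        assert planted <= flagged
        bliss = scores.set_index("library_compound")["bliss_avg"]
        assert all(bliss[c] > 0.1 for c in planted)
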