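"""Aggregate statistics: stratification, OLS, composition, representatives,
ensemble variability, correlations, hydropathy."""

import numpy as np
import pandas as pd
import pytest

import loopbench as lb
from loopbench.benchstats import (
    binned_profile,
    correlate,
    ensemble_variability,
    hydropathy_index,
    linear_fit,
    loop_fraction,
    select_representatives,
    sse_composition,
    stratify_by_length,
)
from loopbench.secstruct import assign_secstruct


def test_loop_fraction_extremes():
    coil = lb.make_ideal_segment("coil", 20, seed=2)
    assert loop_fraction(assign_secstruct(coil)) == 1.0
    helix = lb.make_ideal_segment("alpha_helix", 40)
    frac = loop_fraction(assign_secstruct(helix))
    assert frac == pytest.approx(2 / 40)  # only the two cap residues


def test_stratify_mean_and_se():
    rows = pd.DataFrame({
        "length": [5, 5, 7],
        "rmsd_A": [0.2, 0.4, 1.0],
    })
    bins = stratify_by_length(rows, "rmsd_A")
    assert [b.length for b in bins] == [5, 7]
    b5 = bins[0]
    assert b5.mean == pytest.approx(0.3)
    assert b5.se == pytest.approx(0.1)  # sd = 0.1414 / sqrt(2)
    assert bins[1].se == 0.0            # singleton convention
    assert b5.min <= b5.mean <= b5.max


def test_stratify_unknown_field():
    rows = pd.DataFrame({"length": [3], "rmsd_A": [0.1]})
    with pytest.raises(KeyError):
        stratify_by_length(rows, "nope")


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        fit = linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_r2_zero(self):
        fit = linear_fit([1, 2, 3], [4, 4, 4])
        assert fit.r_squared == 0.0

    def test_closed_form_example(self):
        """x={1,2,3}, y={1,3,2}: slope 0.5, intercept 1, R^2 0.25 (hand OLS)."""
        fit = linear_fit([1, 2, 3], [1, 3, 2])
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(0.25)

    def test_identical_x_errors(self):
        with pytest.raises(ValueError):
            linear_fit([2, 2, 2], [1, 2, 3])

    def test_bin_means_variant(self):
        x = np.array([1, 1, 2, 2], dtype=float)
        y = np.array([0.0, 2.0, 3.0, 5.0])
        fit = linear_fit(x, y, on_bin_means=True)
        assert fit.slope == pytest.approx(3.0)  # means 1.0 and 4.0
        assert fit.n == 2


def test_composition_experimental_is_pure_loop(bench_result):
    comp = sse_composition({
        "experimental": bench_result.exp_loops,
        "predicted": bench_result.pred_fragments,
    })
    assert comp.loc["regular_ss_fraction", "experimental"] == 0.0
    core = comp.loc[["none", "turn", "bend", "parallel_sheet",
                     "antiparallel_sheet", "alpha_helix", "pi_helix",
                     "three_ten_helix"]]
    np.testing.assert_allclose(core.sum(axis=0), 1.0, atol=1e-9)


def test_composition_manual_counts():
    from loopbench.loops import LoopRegion
    loop = LoopRegion(parent_id="x", chain="A", start=0, end=5, sequence="AAAAA",
                      residues=[], classes="CCTTH", sense=np.zeros(5),
                      source="predicted")
    comp = sse_composition({"predicted": [loop]})
    assert comp.loc["none", "predicted"] == pytest.approx(0.4)
    assert comp.loc["turn", "predicted"] == pytest.approx(0.4)
    assert comp.loc["alpha_helix", "predicted"] == pytest.approx(0.2)


class TestRepresentatives:
    def frame(self):
        return pd.DataFrame({
            "pair_id": ["a", "b", "c", "d", "e"],
            "length": [5, 5, 5, 9, 7],
            "rmsd_A": [0.1, 0.3, 0.5, 1.0, 0.7],
        })

    def test_closest_to_mean(self):
        reps = select_representatives(self.frame(), [5])
        assert reps[5] == "b"  # mean 0.3, b sits on it

    def test_singleton_and_absent(self):
        reps = select_representatives(self.frame(), [9, 11])
        assert reps == {9: "d"}

    def test_tie_breaks_to_smaller_pair_id(self):
        df = pd.DataFrame({
            "pair_id": ["z", "a"],
            "length": [4, 4],
            "rmsd_A": [0.2, 0.4],  # mean 0.3, both 0.1 away
        })
        assert select_representatives(df, [4])[4] == "a"


class TestEnsembleVariability:
    def test_identical_copies_all_zero(self, bench_manifest):
        import copy
        exp = lb.read_structure(bench_manifest.exp_path[0], "experimental")
        reps = [exp, copy.deepcopy(exp), copy.deepcopy(exp)]
        pred = lb.read_structure(bench_manifest.pred_path[0], "predicted")
        res = ensemble_variability(reps, pred)
        assert np.allclose(res["exp_exp"], 0.0, atol=1e-9)
        # k=3 structures -> 3 pairwise values per loop
        assert len(res["exp_exp"]) == 3 * res["n_loops"]
        assert len(res["pred_exp"]) == 3 * res["n_loops"]

    def test_prediction_equal_to_reference_gives_zeros(self, bench_manifest):
        import copy
        exp = lb.read_structure(bench_manifest.exp_path[0], "experimental")
        rng = np.random.default_rng(0)
        from loopbench.synthetic_data import perturb_coordinates
        reps = [exp, perturb_coordinates(exp, 0.1, rng)]
        pred_twin = copy.deepcopy(exp)
        pred_twin.source = "predicted"
        res = ensemble_variability(reps, pred_twin)
        assert np.isclose(res["pred_exp"], 0.0, atol=1e-9).any()

    def test_requires_two_structures(self, bench_manifest):
        exp = lb.read_structure(bench_manifest.exp_path[0], "experimental")
        pred = lb.read_structure(bench_manifest.pred_path[0], "predicted")
        with pytest.raises(ValueError):
            ensemble_variability([exp], pred)


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        r_manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        r, r2 = correlate(x, y)
        assert r == pytest.approx(r_manual, abs=1e-12)
        assert r2 == pytest.approx(r_manual ** 2, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            r, _ = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)


def test_binned_profile_counts_sum():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1, 200)
    y = rng.normal(size=200)
    prof = binned_profile(x, y, width=0.05, x_range=(0.0, 1.0))
    assert prof["n"].sum() == 200
    assert (prof["min"] <= prof["mean"]).all() and (prof["mean"] <= prof["max"]).all()


class TestHydropathy:
    @pytest.mark.parametrize("seq,expected", [
        ("IIII", 4.5), ("RRR", -4.5), ("IR", 0.0),
    ])
    def test_scale_values(self, seq, expected):
        assert hydropathy_index(seq) == pytest.approx(expected)

    def test_nonstandard_excluded(self):
        assert hydropathy_index("IXI") == pytest.approx(4.5)
        with pytest.raises(ValueError):
            hydropathy_index("XXX")
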