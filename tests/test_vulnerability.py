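import numpy as np
import pandas as pd
import pytest
from scipy import stats
from shapely.geometry import box

from epeagree.classification import PERCENTILE_99
from epeagree.errors import CollinearityError
from epeagree.types import DistanceProfile, EPEMatrix, GridSpec
from epeagree.vulnerability import (
    categorize_units,
    confusion_counts,
    distance_regression,
    match_units,
    one_way_anova,
    prominence_from_elevation,
)

from conftest import square_unit


def unit_with(uid, **attrs):
    base = dict(
        pct_minority=30.0, pct_black=10.0, pct_native_american=1.0,
        pct_asian=3.0, pct_hispanic=8.0, pct_poverty=12.0, svi=0.5,
        urbanicity="urban", pop_density=1.0, prominence_km=0.2,
    )
    base.update(attrs)
    return square_unit(uid, 0, 0, **base)


class TestCategorize:
    def test_exactly_fifty_percent_not_majority(self):
        df = categorize_units([unit_with("u", pct_native_american=50.0)])
        assert df.loc["u", "majority_native_american"] == False  # noqa: E712

    def test_just_over_fifty_is_majority(self):
        df = categorize_units([unit_with("u", pct_black=50.01)])
        assert df.loc["u", "majority_black"] == True  # noqa: E712

    @pytest.mark.parametrize(
        "svi,bin_", [(0.0, "very low"), (0.25, "very low"), (0.2500001, "low"),
                     (0.5, "low"), (0.75, "high"), (0.9, "very high")]
    )
    def test_svi_bins_right_closed(self, svi, bin_):
        df = categorize_units([unit_with("u", svi=svi)])
        assert df.loc["u", "svi_bin"] == bin_

    def test_poverty_threshold_strict_by_default(self):
        df = categorize_units([unit_with("u", pct_poverty=20.0)])
        assert df.loc["u", "low_income"] == False  # noqa: E712
        df2 = categorize_units(
            [unit_with("u", pct_poverty=20.0)], poverty_op=">="
        )
        assert df2.loc["u", "low_income"] == True  # noqa: E712

    def test_missing_attribute_unclassifiable_only_there(self):
        df = categorize_units([unit_with("u", pct_poverty=np.nan)])
        assert pd.isna(df.loc["u", "low_income"])
        assert df.loc["u", "svi_bin"] == "low"

    def test_schemes_are_exclusive_and_total(self):
        units = [unit_with(f"u{i}", svi=(i + 0.5) / 10) for i in range(10)]
        df = categorize_units(units)
        assert df["svi_bin"].notna().all()
        assert set(df["svi_bin"]) <= {"very low", "low", "high", "very high"}


class TestProminence:
    def spec(self, n, d=0.5):
        return GridSpec(0, 0, d, d, n, n)

    def test_flat_raster_zero(self):
        elev = np.full((8, 8), 0.3)
        assert prominence_from_elevation(box(0, 0, 4, 4), elev, self.spec(8)) == 0.0

    def test_range_of_intersected_cells(self):
        elev = np.array([[0.1, 0.5], [0.9, 0.5]])
        spec = GridSpec(0, 0, 1, 1, 2, 2)
        p = prominence_from_elevation(box(0, 0, 2, 2), elev, spec, target_cell_km=1.0)
        assert p == pytest.approx(0.8)

    def test_block_aggregation_matches_mean_oracle(self):
        # checkerboard at 0.25 km aggregated to 0.5 km -> every block mean 0.5
        n = 8
        elev = np.indices((n, n)).sum(axis=0) % 2
        spec = GridSpec(0, 0, 0.25, 0.25, n, n)
        p = prominence_from_elevation(
            box(0, 0, 2, 2), elev.astype(float), spec, target_cell_km=0.5
        )
        assert p == pytest.approx(0.0)


class TestMatching:
    def test_identical_covariates_all_matched(self):
        units = [unit_with(f"u{i}") for i in range(6)]
        flags = {"u0": True, "u1": True}
        ms = match_units(units, flags)
        assert sorted(ms.referent) == ["u0", "u1"]
        assert sorted(ms.matched) == ["u2", "u3", "u4", "u5"]
        assert ms.unmatched == []

    def test_boundary_exactly_one_sd_is_matched(self):
        units = [
            unit_with("r1", pop_density=1.0, prominence_km=0.2),
            unit_with("r2", pop_density=3.0, prominence_km=0.2),
            # referent: mean 2.0, sd sqrt(2); candidate exactly at mu+sd
            unit_with("c", pop_density=2.0 + np.sqrt(2.0), prominence_km=0.2),
        ]
        ms = match_units(units, {"r1": True, "r2": True})
        assert ms.matched == ["c"]

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        units = [
            unit_with(f"u{i}", pop_density=float(rng.gamma(2, 1)),
                      prominence_km=float(rng.gamma(1, 0.3)))
            for i in range(30)
        ]
        flags = {f"u{i}": True for i in range(5)}
        ms = match_units(units, flags)
        assert len(ms.referent) + len(ms.matched) + len(ms.unmatched) == 30

    def test_referent_too_small_raises(self):
        units = [unit_with("a"), unit_with("b")]
        with pytest.raises(ValueError):
            match_units(units, {"a": True})


class TestRegression:
    def profiles(self, units, dists):
        return {
            u.unit_id: DistanceProfile(u.unit_id, d) for u, d in zip(units, dists)
        }

    def test_exact_fit_through_points(self):
        units = [
            unit_with("a", pct_native_american=0.0),
            unit_with("b", pct_native_american=100.0),
            unit_with("c", pct_native_american=50.0),
        ]
        profs = self.profiles(units, [5.0, 25.0, 15.0])
        out = distance_regression(profs, units, models=(1,))
        slope = out[out.term == "native_american_share"].iloc[0]
        assert slope.coef == pytest.approx(20.0)

    def test_parameter_recovery_small_noise(self, rng):
        shares = rng.uniform(0, 100, 120)
        units = [
            unit_with(f"u{i}", pct_native_american=float(s),
                      prominence_km=float(rng.gamma(1, 0.3)),
                      pop_density=float(rng.gamma(2, 1)))
            for i, s in enumerate(shares)
        ]
        dists = 7.0 + 20.0 * shares / 100.0 + rng.normal(0, 1e-6, 120)
        out = distance_regression(self.profiles(units, dists), units)
        for m in (1, 2, 3, 4):
            slope = out[(out.model == m) & (out.term == "native_american_share")]
            assert slope.iloc[0].coef == pytest.approx(20.0, abs=1e-3)

    def test_orthogonal_covariate_leaves_slope(self, rng):
        n = 200
        shares = np.tile([0.0, 100.0], n // 2)
        orth = np.repeat([0.0, 1.0], n // 2)  # orthogonal to share by design
        orth = orth - orth.mean()
        shares_c = shares - shares.mean()
        assert abs(np.dot(orth, shares_c)) < 1e-9
        units = [
            unit_with(f"u{i}", pct_native_american=float(s),
                      prominence_km=float(o + 1.0))
            for i, (s, o) in enumerate(zip(shares, orth))
        ]
        d = 3.0 + 10.0 * shares / 100.0 + rng.normal(0, 0.5, n)
        out = distance_regression(self.profiles(units, d), units, models=(1, 2))
        c1 = out[(out.model == 1) & (out.term == "native_american_share")].iloc[0]
        c2 = out[(out.model == 2) & (out.term == "native_american_share")].iloc[0]
        assert c1.coef == pytest.approx(c2.coef, abs=1e-9)

    def test_collinear_design_raises(self):
        units = [unit_with(f"u{i}", pct_native_american=5.0) for i in range(10)]
        profs = self.profiles(units, list(np.arange(10.0)))
        with pytest.raises(CollinearityError):
            distance_regression(profs, units, models=(1,))


class TestAnova:
    def test_two_groups_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 15)
        vals = {f"a{i}": float(v) for i, v in enumerate(x)}
        vals.update({f"b{i}": float(v) for i, v in enumerate(y)})
        groups = {k: k[0] for k in vals}
        res = one_way_anova(vals, groups)
        t, _ = stats.ttest_ind(x, y)
        assert res.f_stat == pytest.approx(t**2)

    def test_matches_scipy_f_oneway(self, rng):
        samples = [rng.normal(m, 1, 20) for m in (0, 0.3, 1.0)]
        vals, groups = {}, {}
        for g, s in enumerate(samples):
            for i, v in enumerate(s):
                vals[f"{g}_{i}"] = float(v)
                groups[f"{g}_{i}"] = str(g)
        res = one_way_anova(vals, groups)
        f, p = stats.f_oneway(*samples)
        assert res.f_stat == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_label_permutation_invariance(self, rng):
        vals = {f"u{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 30))}
        groups = {f"u{i}": ["a", "b", "c"][i % 3] for i in range(30)}
        relabel = {"a": "z", "b": "x", "c": "y"}
        res1 = one_way_anova(vals, groups)
        res2 = one_way_anova(vals, {k: relabel[v] for k, v in groups.items()})
        assert res1.f_stat == pytest.approx(res2.f_stat)

    def test_degenerate_zero_within_variance(self):
        vals = {"a1": 1.0, "a2": 1.0, "b1": 2.0, "b2": 2.0}
        groups = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        res = one_way_anova(vals, groups)
        assert res.degenerate and np.isinf(res.f_stat) and res.p_value == 0.0

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": 1.0, "b": 2.0}, {"a": "g", "b": "g"})


class TestConfusion:
    def mat(self, ind, source):
        ind = np.asarray(ind, float)
        dates = pd.date_range("2011-01-01", periods=ind.shape[1], freq="D")
        ids = [f"u{i}" for i in range(ind.shape[0])]
        return EPEMatrix(ids, dates, source, PERCENTILE_99, ind)

    def test_identical_matrices_zero(self):
        a = self.mat([[1, 0, 1]], "ref")
        b = self.mat([[1, 0, 1]], "cmp")
        c = confusion_counts(a, b, ["u0"])
        assert c.false_positives == 0 and c.false_negatives == 0

    def test_miss_is_false_negative(self):
        ref = self.mat([[1, 0, 1]], "ref")
        cmp_ = self.mat([[0, 0, 1]], "cmp")
        c = confusion_counts(ref, cmp_, ["u0"])
        assert c.false_negatives == 1 and c.false_positives == 0
        assert c.reference_epe_count == 2

    def test_matches_brute_force(self, rng):
        ref_i = (rng.random((6, 200)) < 0.1).astype(float)
        cmp_i = (rng.random((6, 200)) < 0.1).astype(float)
        ref_i[rng.random((6, 200)) < 0.05] = np.nan
        ref = self.mat(ref_i, "ref")
        cmp_ = self.mat(cmp_i, "cmp")
        subset = ["u1", "u3", "u4"]
        c = confusion_counts(ref, cmp_, subset)
        fp = fn = 0
        for uid in subset:
            k = ref.unit_ids.index(uid)
            for d in range(200):
                r, m = ref_i[k, d], cmp_i[k, d]
                if np.isnan(r) or np.isnan(m):
                    continue
                fp += int(m == 1 and r == 0)
                fn += int(m == 0 and r == 1)
        assert (c.false_positives, c.false_negatives) == (fp, fn)
        assert c.fp_per_unit == pytest.approx(fp / 3)

    def test_empty_subset_raises(self):
        a = self.mat([[1.0]], "ref")
        with pytest.raises(ValueError):
            confusion_counts(a, self.mat([[1.0]], "cmp"), [])
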