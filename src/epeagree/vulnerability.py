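"""Sociodemographic stratification and station-proximity analyses.

Builds the strata used to modify the agreement analysis (majority
race/ethnicity flags, low-income class, SVI quartile bins, urbanicity,
distance-to-station bands), the covariate-matched tract subsets, the
distance regressions and ANOVA, and the local-example false
positive/negative counts against a designated reference source.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from shapely.geometry.base import BaseGeometry

from .errors import CollinearityError, EpeAgreeError
from .gridded_exposure import intersection_weights
from .types import (
    DistanceProfile,
    EPEMatrix,
    ExposureUnit,
    GridSpec,
    MatchedStrata,
)

__all__ = [
    "categorize_units",
    "prominence_from_elevation",
    "match_units",
    "distance_regression",
    "one_way_anova",
    "confusion_counts",
]

SVI_BINS = ("very low", "low", "high", "very high")


def _svi_bin(svi: float) -> str:
    """Right-closed quartile bins: [0,0.25], (0.25,0.5], (0.5,0.75], (0.75,1]."""
    if svi <= 0.25:
        return SVI_BINS[0]
    if svi <= 0.50:
        return SVI_BINS[1]
    if svi <= 0.75:
        return SVI_BINS[2]
    return SVI_BINS[3]


def categorize_units(
    units: list[ExposureUnit],
    poverty_threshold: float = 20.0,
    poverty_op: str = ">",
) -> pd.DataFrame:
    """Stratification table per unit.

    Majority flags use strict > 50% of the relevant share; low income is
    > 20% poverty (the Treasury definition; set ``poverty_op='>='`` for
    the inclusive reading); SVI quartile bins are right-closed.  A unit
    missing an attribute is NaN (unclassifiable) for that scheme only.
    """
    op = {">": operator.gt, ">=": operator.ge}[poverty_op]
    rows = []
    for u in units:
        def flag(v):
            return np.nan if np.isnan(v) else bool(v > 50.0)

        rows.append(
            {
                "unit_id": u.unit_id,
                "majority_minority": flag(u.pct_minority),
                "majority_black": flag(u.pct_black),
                "majority_native_american": flag(u.pct_native_american),
                "majority_asian": flag(u.pct_asian),
                "majority_hispanic": flag(u.pct_hispanic),
                "low_income": (
                    np.nan if np.isnan(u.pct_poverty)
                    else bool(op(u.pct_poverty, poverty_threshold))
                ),
                "svi_bin": np.nan if np.isnan(u.svi) else _svi_bin(u.svi),
                "urbanicity": u.urbanicity if u.urbanicity else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("unit_id")


def prominence_from_elevation(
    polygon: BaseGeometry,
    elevation: np.ndarray,
    spec: GridSpec,
    target_cell_km: float = 0.5,
) -> float:
    """Topographic prominence: elevation range within the polygon.

    The raster is first block-aggregated (block mean) to the configured
    coarse resolution when that is coarser than the native one, then the
    max minus min over intersecting cells is returned (km).
    """
    factor = max(1, int(round(target_cell_km / spec.dx)))
    if factor > 1:
        nr = (spec.n_rows // factor) * factor
        nc = (spec.n_cols // factor) * factor
        agg = elevation[:nr, :nc].reshape(
            nr // factor, factor, nc // factor, factor
        ).mean(axis=(1, 3))
        agg_spec = GridSpec(
            spec.x0, spec.y0, spec.dx * factor, spec.dy * factor,
            nr // factor, nc // factor,
        )
    else:
        agg, agg_spec = elevation, spec
    rows, cols, _ = intersection_weights(polygon, agg_spec)
    if rows.size == 0:
        raise EpeAgreeError("polygon does not intersect the elevation raster")
    vals = agg[rows, cols]
    return float(vals.max() - vals.min())


def match_units(
    units: list[ExposureUnit], referent_flag: dict[str, bool]
) -> MatchedStrata:
    """Partition units into referent / covariate-matched / unmatched sets.

    Matched units are non-referent units whose population density AND
    topographic prominence both lie within one sample standard deviation
    (closed interval) of the referent-group mean.
    """
    ref = [u for u in units if referent_flag.get(u.unit_id)]
    non = [u for u in units if not referent_flag.get(u.unit_id)]
    if len(ref) < 2:
        raise ValueError("referent group must contain >= 2 units (SD undefined)")
    dens = np.array([u.pop_density for u in ref])
    prom = np.array([u.prominence_km for u in ref])
    d_lo, d_hi = dens.mean() - dens.std(ddof=1), dens.mean() + dens.std(ddof=1)
    p_lo, p_hi = prom.mean() - prom.std(ddof=1), prom.mean() + prom.std(ddof=1)
    matched, unmatched = [], []
    for u in non:
        if d_lo <= u.pop_density <= d_hi and p_lo <= u.prominence_km <= p_hi:
            matched.append(u.unit_id)
        else:
            unmatched.append(u.unit_id)
    return MatchedStrata(
        referent=[u.unit_id for u in ref], matched=matched, unmatched=unmatched
    )


_MODEL_TERMS = {
    1: ["native_american_share"],
    2: ["native_american_share", "prominence_km"],
    3: ["native_american_share", "pop_density"],
    4: ["native_american_share", "prominence_km", "pop_density"],
}


def distance_regression(
    profiles: dict[str, DistanceProfile],
    units: list[ExposureUnit],
    models: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """OLS of mean daily station distance on sociogeographic covariates.

    Model 1 regresses distance (km) on Native American share alone;
    models 2–4 add topographic prominence and/or population density.
    The share enters as a proportion (0–1), so its coefficient is the km
    change from a 0% -> 100% Native American tract.  Returns a tidy
    coefficient table with classical 95% CIs.
    """
    df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "native_american_share": [u.pct_native_american / 100.0 for u in units],
            "prominence_km": [u.prominence_km for u in units],
            "pop_density": [u.pop_density for u in units],
        }
    ).set_index("unit_id")
    df["distance_km"] = pd.Series(
        {uid: p.mean_daily_distance_km for uid, p in profiles.items()}
    )
    df = df.dropna(subset=["distance_km"])

    rows = []
    for m in models:
        terms = _MODEL_TERMS[m]
        if len(df) < len(terms) + 2:
            raise ValueError(f"model {m}: need at least {len(terms) + 2} units")
        X = sm.add_constant(df[terms], has_constant="add")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise CollinearityError(
                f"model {m}: design matrix rank-deficient over terms {terms}"
            )
        fit = sm.OLS(df["distance_km"], X).fit()
        ci = fit.conf_int(alpha=0.05)
        for term in ["const"] + terms:
            rows.append(
                {
                    "model": m,
                    "term": term,
                    "coef": float(fit.params[term]),
                    "ci_lo": float(ci.loc[term, 0]),
                    "ci_hi": float(ci.loc[term, 1]),
                    "p_value": float(fit.pvalues[term]),
                    "n": int(fit.nobs),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def one_way_anova(values: dict[str, float], groups: dict[str, str]) -> AnovaResult:
    """Classical one-way ANOVA of per-unit values across group labels.

    ``values`` and ``groups`` are keyed by unit_id.  A degenerate design
    with zero within-group variance but distinct group means reports an
    infinite F with p = 0 and ``degenerate=True`` rather than raising.
    """
    by_group: dict[str, list[float]] = {}
    for uid, v in values.items():
        g = groups.get(uid)
        if g is None or (isinstance(v, float) and np.isnan(v)):
            continue
        by_group.setdefault(g, []).append(float(v))
    if len(by_group) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [np.asarray(v) for v in by_group.values()]
    n = sum(len(s) for s in samples)
    k = len(samples)
    if n <= k:
        raise ValueError("ANOVA needs total observations > number of groups")
    grand = np.concatenate(samples).mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(float("nan"), float("nan"), df_b, df_w, True)
        return AnovaResult(float("inf"), 0.0, df_b, df_w, True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


@dataclass
class ConfusionCounts:
    """False positive/negative EPE counts of a comparator against a
    designated reference source.

    The reference is a comparison baseline only — no claim is made that
    it is actually the most accurate measurement of precipitation.
    """

    reference: str
    comparator: str
    n_units: int
    reference_epe_count: int
    false_positives: int
    false_negatives: int
    fp_per_unit: float
    fn_per_unit: float
    disclaimer: str = (
        "reference source is a comparison baseline, not ground truth"
    )


def confusion_counts(
    reference: EPEMatrix, comparator: EPEMatrix, unit_subset: list[str]
) -> ConfusionCounts:
    """FP/FN unit-day counts over a subset of units, total and per unit.

    FP: comparator flags an EPE where the reference does not; FN: the
    reference flags an EPE the comparator misses.  Pairs with a missing
    rating on either side are excluded.
    """
    reference.aligned_with(comparator)
    if not unit_subset:
        raise ValueError("unit_subset must be non-empty")
    idx = [reference.unit_ids.index(u) for u in unit_subset]
    r = reference.indicator[idx]
    c = comparator.indicator[idx]
    ok = ~np.isnan(r) & ~np.isnan(c)
    fp = int(np.count_nonzero(ok & (c == 1.0) & (r == 0.0)))
    fn = int(np.count_nonzero(ok & (c == 0.0) & (r == 1.0)))
    ref_n = int(np.count_nonzero(ok & (r == 1.0)))
    k = len(unit_subset)
    return ConfusionCounts(
        reference=reference.source,
        comparator=comparator.source,
        n_units=k,
        reference_epe_count=ref_n,
        false_positives=fp,
        false_negatives=fn,
        fp_per_unit=fp / k,
        fn_per_unit=fn / k,
    )
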