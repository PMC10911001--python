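"""Cohen's kappa agreement analysis.

Agreement between two binary EPE classifications is summarised by
Cohen's kappa, kappa = (p_o - p_e) / (1 - p_e), with p_o the observed
proportion of agreeing unit-days and p_e the chance-agreement
proportion from the marginal products.  The standard error is the
Fleiss–Cohen–Everitt large-sample variance and the 95% CI the normal
approximation.  Pooled, per-year, and per-stratum variants all collapse
unit-days into a single 2x2 table (the convention implied by the very
narrow CIs that pooled national comparisons produce); a per-unit mode
is available for sensitivity analyses.

Kappa is interpreted on the Landis–Koch bands: < 0 poor, 0–0.20 slight,
0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.00
almost perfect (intervals closed on the right).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .types import Contingency2x2, EPEMatrix, KappaResult

__all__ = [
    "contingency",
    "cohen_kappa",
    "interpret",
    "matrix_kappa",
    "annual_kappa",
    "stratified_kappa",
    "per_unit_kappa",
]

_Z95 = 1.959963984540054


def contingency(a: np.ndarray, b: np.ndarray) -> Contingency2x2:
    """2x2 counts over pairwise-complete observations.

    Pairs where either rating is missing are dropped; raises if no
    complete pair remains.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    if not ok.any():
        raise ValueError("no complete pairs")
    a, b = a[ok] > 0.5, b[ok] > 0.5
    return Contingency2x2(
        n11=int(np.count_nonzero(a & b)),
        n10=int(np.count_nonzero(a & ~b)),
        n01=int(np.count_nonzero(~a & b)),
        n00=int(np.count_nonzero(~a & ~b)),
    )


def cohen_kappa(t: Contingency2x2) -> KappaResult:
    """Cohen's kappa with asymptotic SE and 95% CI from a 2x2 table.

    Undefined (kappa = NaN) only when chance agreement p_e = 1, i.e.
    both raters are constant on the same class.
    """
    n = t.n
    p = t.as_array() / n  # p[i, j]: rater A class (1,0) x rater B class (1, 0)
    pa = p.sum(axis=1)  # A marginals (class 1, class 0)
    pb = p.sum(axis=0)  # B marginals
    p_o = float(p[0, 0] + p[1, 1])
    p_e = float(pa @ pb)
    if abs(1.0 - p_e) < 1e-15:
        return KappaResult(
            kappa=float("nan"), p_o=p_o, p_e=p_e, se=float("nan"),
            ci95=(float("nan"), float("nan")), n=n, label="undefined",
            defined=False, table=t,
        )
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss-Cohen-Everitt (1969) large-sample variance
    om = 1.0 - kappa
    term_diag = sum(
        p[i, i] * (1.0 - (pa[i] + pb[i]) * om) ** 2 for i in range(2)
    )
    term_off = om**2 * sum(
        p[i, j] * (pb[i] + pa[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    term_c = (kappa - p_e * om) ** 2
    var = (term_diag + term_off - term_c) / (n * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    ci = (kappa - _Z95 * se, kappa + _Z95 * se)
    return KappaResult(
        kappa=float(kappa), p_o=p_o, p_e=p_e, se=float(se), ci95=ci,
        n=n, label=interpret(kappa), defined=True, table=t,
    )


def interpret(kappa: float) -> str:
    """Landis–Koch qualitative band for a kappa value."""
    if kappa is None or (isinstance(kappa, float) and math.isnan(kappa)):
        return "undefined"
    # band edges are right-closed; the small tolerance keeps values that
    # are exactly on an edge up to float rounding in the lower band
    eps = 1e-12
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.20 + eps:
        return "slight"
    if kappa <= 0.40 + eps:
        return "fair"
    if kappa <= 0.60 + eps:
        return "moderate"
    if kappa <= 0.80 + eps:
        return "substantial"
    return "almost perfect"


def _undefined(n: int = 0) -> KappaResult:
    return KappaResult(
        kappa=float("nan"), p_o=float("nan"), p_e=float("nan"),
        se=float("nan"), ci95=(float("nan"), float("nan")), n=n,
        label="undefined", defined=False,
    )


def matrix_kappa(
    a: EPEMatrix, b: EPEMatrix, unit_subset: list[str] | None = None
) -> KappaResult:
    """Pooled kappa over all (or a subset of) unit-days of two matrices."""
    a.aligned_with(b)
    ia, ib = a.indicator, b.indicator
    if unit_subset is not None:
        idx = [a.unit_ids.index(u) for u in unit_subset]
        ia, ib = ia[idx], ib[idx]
    return cohen_kappa(contingency(ia, ib))


def annual_kappa(a: EPEMatrix, b: EPEMatrix) -> dict[int, KappaResult]:
    """Kappa restricted to each calendar year's unit-days."""
    a.aligned_with(b)
    years = a.dates.year
    out = {}
    for yr in sorted(set(years)):
        cols = np.flatnonzero(years == yr)
        try:
            t = contingency(a.indicator[:, cols], b.indicator[:, cols])
        except ValueError:
            out[int(yr)] = _undefined()
            continue
        out[int(yr)] = cohen_kappa(t)
    return out


def stratified_kappa(
    a: EPEMatrix, b: EPEMatrix, strata: dict[str, str]
) -> dict[str, KappaResult]:
    """Kappa per stratum of units, pooling each stratum's unit-days.

    ``strata`` maps unit_id -> stratum label; units absent from the map
    are excluded.  Empty strata (no complete pair) are flagged undefined.
    """
    a.aligned_with(b)
    labels = sorted(set(strata.values()))
    out = {}
    for lab in labels:
        idx = [k for k, u in enumerate(a.unit_ids) if strata.get(u) == lab]
        if not idx:
            out[lab] = _undefined()
            continue
        try:
            t = contingency(a.indicator[idx], b.indicator[idx])
        except ValueError:
            out[lab] = _undefined()
            continue
        out[lab] = cohen_kappa(t)
    return out


def per_unit_kappa(a: EPEMatrix, b: EPEMatrix) -> pd.Series:
    """Optional per-unit kappa (one 2x2 per unit), NaN where undefined."""
    a.aligned_with(b)
    vals = {}
    for k, uid in enumerate(a.unit_ids):
        try:
            r = cohen_kappa(contingency(a.indicator[k], b.indicator[k]))
            vals[uid] = r.kappa
        except ValueError:
            vals[uid] = float("nan")
    return pd.Series(vals, name="kappa")


def kappa_table(results: dict[str, KappaResult]) -> pd.DataFrame:
    """Flatten {label: KappaResult} into a tidy results table."""
    rows = []
    for key, r in results.items():
        rows.append(
            {
                "stratum": key,
                "kappa": r.kappa,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "n": r.n,
                "label": r.label,
            }
        )
    return pd.DataFrame(rows)
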