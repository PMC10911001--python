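"""Binary extreme-precipitation-event (EPE) classification.

An EPE day is one whose assigned precipitation strictly exceeds the
applicable threshold — either the locally derived 99th-percentile
wet-day threshold or the absolute more-than-one-inch (25.4 mm) cut.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .types import EPEDefinition, EPEMatrix, PrecipSeries

__all__ = ["classify", "build_epe_matrix", "build_epe_matrices"]

logger = logging.getLogger(__name__)

PERCENTILE_99 = EPEDefinition("percentile_99")
ONE_INCH = EPEDefinition("absolute", 25.4)


def classify(series: PrecipSeries, threshold_mm: float) -> np.ndarray:
    """1.0 where value > threshold (strict), 0.0 otherwise, NaN missing."""
    v = series.values
    out = np.where(v > threshold_mm, 1.0, 0.0)
    out[np.isnan(v)] = np.nan
    return out


def build_epe_matrix(
    unit_series: dict[str, PrecipSeries],
    thresholds: dict[str, float] | float,
    source: str,
    definition: EPEDefinition,
) -> EPEMatrix:
    """Unit x day indicator matrix for one source and one definition.

    ``thresholds`` is a per-unit map for the percentile definition or a
    single absolute value; all series must share one date index.
    """
    unit_ids = sorted(unit_series)
    dates: pd.DatetimeIndex | None = None
    rows = []
    for uid in unit_ids:
        s = unit_series[uid]
        if dates is None:
            dates = s.dates
        elif not dates.equals(s.dates):
            raise AlignmentError(f"{uid}: date index differs from other units")
        thr = thresholds if np.isscalar(thresholds) else thresholds[uid]
        rows.append(classify(s, float(thr)))
    indicator = np.vstack(rows)
    mat = EPEMatrix(unit_ids, dates, source, definition, indicator)
    n_epe = int(np.nansum(indicator))
    logger.info("%s/%s: %d EPE unit-days of %d", source, definition.kind,
                n_epe, indicator.size)
    return mat


def build_epe_matrices(
    series_by_source: dict[str, dict[str, PrecipSeries]],
    thresholds_by_source: dict[str, dict[str, float]],
    definitions: tuple[EPEDefinition, ...] = (PERCENTILE_99, ONE_INCH),
) -> list[EPEMatrix]:
    """One matrix per (source, definition) pair."""
    out = []
    for source, series in series_by_source.items():
        for definition in definitions:
            if definition.kind == "absolute":
                thr: dict[str, float] | float = definition.absolute_threshold_mm
            else:
                thr = thresholds_by_source[source]
            out.append(build_epe_matrix(series, thr, source, definition))
    return out
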