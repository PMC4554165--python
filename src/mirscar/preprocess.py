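"""Raw intensities -> analysis-ready log2 expression.

Steps: background subtraction (floored so the log stays finite), log2
transform, MA-lowess normalization of every array against a median
pseudo-array reference, and a detection filter removing rows that never
rise above a signal threshold.

Normalization works in MA coordinates: for array a with log2 values x_a
and reference r (the per-miRNA median over all arrays),

    A = (x_a + r) / 2,    M = x_a - r,

a robust locally weighted regression Mhat(A) is fitted and subtracted,
x_a <- x_a - Mhat(A). This removes smooth intensity-dependent per-array
bias while leaving rank structure intact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Raw-scale floor applied after background subtraction (keeps log2 finite).
DEFAULT_FLOOR = 1.0


@dataclass(frozen=True)
class LowessParams:
    """Span (fraction of points per local window) and robustness iterations."""

    span: float = 0.3
    iterations: int = 3

    def validate(self) -> None:
        if not 0.0 < self.span <= 1.0:
            raise ConfigurationError("span must lie in (0, 1]")
        if self.iterations < 0:
            raise ConfigurationError("iterations must be >= 0")


def subtract_background(matrix: pd.DataFrame, background,
                        floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Subtract a global or per-array background, clamped at ``floor``.

    ``background`` is a scalar, or a mapping/Series keyed by array id.
    Returns a new matrix; the input is not modified.
    """
    if np.isscalar(background):
        if background < 0:
            raise ConfigurationError("background must be non-negative")
        bg = pd.Series(float(background), index=matrix.columns)
    else:
        bg = pd.Series(background).astype(float)
        missing = set(matrix.columns) - set(bg.index)
        if missing:
            raise ConfigurationError(
                f"background missing arrays: {sorted(missing)[:5]}")
        if (bg < 0).any():
            raise ConfigurationError("background must be non-negative")
        bg = bg.reindex(matrix.columns)
    out = matrix.sub(bg, axis=1).clip(lower=floor)
    n_floored = int((matrix.sub(bg, axis=1) < floor).to_numpy().sum())
    if n_floored:
        logger.info("background subtraction floored %d values at %g",
                    n_floored, floor)
    return out


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; raises naming the first offending cell if <= 0."""
    values = matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        r, c = np.argwhere(values <= 0)[0]
        raise InputError(
            f"non-positive intensity at row {matrix.index[r]!r}, "
            f"array {matrix.columns[c]!r}; subtract background with a "
            "positive floor first")
    out = pd.DataFrame(np.log2(values), index=matrix.index,
                       columns=matrix.columns)
    out.attrs = dict(matrix.attrs)
    return out


def _median_reference(matrix: pd.DataFrame) -> pd.Series:
    return matrix.median(axis=1)


def lowess_normalize(matrix: pd.DataFrame,
                     params: LowessParams | None = None) -> pd.DataFrame:
    """MA-lowess normalize each array against the median pseudo-array.

    Requires at least 2 arrays and 10 miRNAs (local regression needs
    points). Each array receives one robust fit-and-subtract pass; the
    smoother is not a projection, so re-applying the operation refits
    residual noise at a much smaller scale rather than reproducing the
    output exactly. After normalization each array's median M against
    the recomputed reference is approximately zero.
    """
    params = params or LowessParams()
    params.validate()
    if matrix.shape[1] < 2:
        raise InputError("lowess normalization needs at least 2 arrays")
    if matrix.shape[0] < 10:
        raise InputError("lowess normalization needs at least 10 miRNAs")

    x = matrix.to_numpy(dtype=float)
    reference = np.median(x, axis=1)
    out = np.empty_like(x)
    for a in range(x.shape[1]):
        m = x[:, a] - reference
        avg = 0.5 * (x[:, a] + reference)
        fitted = sm_lowess(m, avg, frac=params.span, it=params.iterations,
                           return_sorted=False)
        # constant-A windows make lowess return NaN; nothing to correct
        fitted = np.where(np.isfinite(fitted), fitted, 0.0)
        out[:, a] = x[:, a] - fitted
    normalized = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    normalized.attrs = dict(matrix.attrs)
    prov = normalized.attrs.setdefault("provenance", {})
    prov["lowess"] = {"span": params.span, "iterations": params.iterations,
                      "reference": "median pseudo-array"}
    return normalized


def detection_filter(matrix: pd.DataFrame, min_signal: float,
                     min_fraction: float) -> pd.DataFrame:
    """Keep rows exceeding ``min_signal`` in >= ceil(min_fraction * n_arrays)
    arrays; removed rows are logged, never NA-filled."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ConfigurationError("min_fraction must lie in [0, 1]")
    required = math.ceil(min_fraction * matrix.shape[1])
    n_detected = (matrix > min_signal).sum(axis=1)
    keep = n_detected >= required
    removed = int((~keep).sum())
    if removed:
        logger.info("detection filter removed %d of %d miRNAs "
                    "(min_signal=%g, min_fraction=%g)",
                    removed, matrix.shape[0], min_signal, min_fraction)
    out = matrix.loc[keep].copy()
    out.attrs = dict(matrix.attrs)
    prov = out.attrs.setdefault("provenance", {})
    prov["detection_filter"] = {"min_signal": min_signal,
                                "min_fraction": min_fraction,
                                "removed": removed}
    return out


def preprocess_pipeline(matrix: pd.DataFrame, background: float = 0.0,
                        floor: float = DEFAULT_FLOOR,
                        params: LowessParams | None = None,
                        min_signal: float | None = None,
                        min_fraction: float = 0.5) -> pd.DataFrame:
    """subtract -> log2 -> lowess -> filter, with the module defaults.

    ``min_signal`` defaults to ``log2(2 * floor)``, i.e. one doubling
    above the background floor.
    """
    if min_signal is None:
        min_signal = math.log2(2.0 * floor)
    out = subtract_background(matrix, background, floor=floor)
    out = log2_transform(out)
    out = lowess_normalize(out, params)
    out = detection_filter(out, min_signal=min_signal,
                           min_fraction=min_fraction)
    prov = out.attrs.setdefault("provenance", {})
    prov["background"] = {"level": background, "floor": floor}
    return out
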