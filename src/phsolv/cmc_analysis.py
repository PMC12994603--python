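"""Critical micelle concentration from conductometric titration curves.

The classical construction: fit ordinary-least-squares lines to the pre-
and post-break segments (exhaustive search over split positions, minimum
total SSE), take the CMC as the intersection of the two lines, and get its
SD from a nonparametric bootstrap over points (the split index is discrete,
so a delta-method SD would be inappropriate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InputError

__all__ = ["ConductivityCurve", "CMCEstimate", "fit_segmented"]

MIN_POINTS = 6
MIN_SEGMENT = 3


@dataclass(frozen=True)
class ConductivityCurve:
    """Specific conductivity vs surfactant concentration."""

    concentrations: np.ndarray  # ascending
    kappa: np.ndarray
    conc_unit: str = "mmol/L"
    kappa_unit: str = "uS/cm"
    medium: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        k = np.asarray(self.kappa, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "kappa", k)
        if c.size < MIN_POINTS:
            raise InputError(f"need at least {MIN_POINTS} points, got {c.size}")
        if c.shape != k.shape:
            raise InputError("concentration and kappa arrays differ in length")
        if np.any(np.diff(c) <= 0):
            raise InputError("concentrations must be strictly increasing")


@dataclass(frozen=True)
class CMCEstimate:
    cmc: float
    cmc_sd: float
    pre_slope: float
    post_slope: float
    pre_slope_sd: float
    post_slope_sd: float
    pre_intercept: float
    post_intercept: float
    split_index: int
    sse: float
    n_boot: int = 0
    seed: int | None = None


def _ols(x, y):
    """Return (intercept, slope, sse, slope_var)."""
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise DegenerateFitError("segment has no spread in concentration")
    b = float(np.sum((x - xm) * (y - ym)) / sxx)
    a = ym - b * xm
    resid = y - a - b * x
    sse = float(resid @ resid)
    dof = len(x) - 2
    slope_var = (sse / dof / sxx) if dof > 0 else 0.0
    return a, b, sse, slope_var


def _two_line_fit(x, y, min_segment=MIN_SEGMENT):
    n = len(x)
    if n < 2 * min_segment:
        raise InputError(
            f"need {min_segment} points per segment, got {n} total")
    best = None
    for i in range(min_segment, n - min_segment + 1):
        a1, b1, sse1, v1 = _ols(x[:i], y[:i])
        a2, b2, sse2, v2 = _ols(x[i:], y[i:])
        sse = sse1 + sse2
        if best is None or sse < best[0]:
            best = (sse, i, a1, b1, v1, a2, b2, v2)
    sse, i, a1, b1, v1, a2, b2, v2 = best
    span = max(abs(b1), abs(b2), 1e-30)
    if abs(b1 - b2) < 1e-6 * span or abs(b1 - b2) < 1e-300:
        raise DegenerateFitError(
            f"segments are (near-)parallel: slopes {b1:.6g}, {b2:.6g}")
    cmc = (a2 - a1) / (b1 - b2)
    return cmc, i, a1, b1, v1, a2, b2, v2, sse


def fit_segmented(curve: ConductivityCurve, n_boot: int = 1000,
                  seed: int | None = None,
                  min_segment: int = MIN_SEGMENT) -> CMCEstimate:
    """Two-segment fit of a conductivity curve; CMC at the intersection.

    Raises :class:`DegenerateFitError` when the best split yields
    (near-)parallel segments (e.g. a single straight line) and
    :class:`InputError` when either segment would have < ``min_segment``
    points.
    """
    x = curve.concentrations
    y = curve.kappa
    cmc, i, a1, b1, v1, a2, b2, v2, sse = _two_line_fit(x, y, min_segment)

    boots = []
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(x)
        for _ in range(n_boot):
            idx = np.sort(rng.integers(0, n, size=n))
            xb, yb = x[idx], y[idx]
            # drop duplicate x so each segment keeps spread
            keep = np.concatenate([[True], np.diff(xb) > 0])
            xb, yb = xb[keep], yb[keep]
            if len(xb) < 2 * min_segment:
                continue
            try:
                boots.append(_two_line_fit(xb, yb, min_segment)[0])
            except DegenerateFitError:
                continue
    cmc_sd = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")

    return CMCEstimate(
        cmc=float(cmc), cmc_sd=cmc_sd,
        pre_slope=float(b1), post_slope=float(b2),
        pre_slope_sd=float(np.sqrt(v1)), post_slope_sd=float(np.sqrt(v2)),
        pre_intercept=float(a1), post_intercept=float(a2),
        split_index=int(i), sse=float(sse), n_boot=len(boots), seed=seed)
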