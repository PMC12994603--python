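"""Weighted nonlinear least-squares refinement of equilibrium constants.

Selected constants are refined (in log units) against log S-pcH
observations by Levenberg-Marquardt with a central-difference Jacobian.
Zero-weight (flagged) observations are excluded.  The goodness of fit is
``GOF = sqrt(chi2_min / (n - m))`` with ``n`` weighted points and ``m``
free constants; per-constant SDs come from the GOF-scaled inverse of the
Gauss-Newton normal matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .activity_ph import ActivityModel
from .errors import DomainError, InputError, RefineError, UnderdeterminedError
from .model_registry import MediumRecipe, ModelConstants
from .speciation import EquilibriumState, SolubilityObservation, solve_equilibrium

logger = logging.getLogger("phsolv.refinement")

__all__ = ["TitrationSet", "RefinedConstants", "refine", "pool_weighted_mean"]


@dataclass
class TitrationSet:
    """A suspension series: recipe, observations and the free-constant mask."""

    name: str
    recipe: MediumRecipe
    observations: list[SolubilityObservation]
    free_mask: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.observations:
            raise InputError(f"titration set {self.name!r} has no observations")
        if self.free_mask and not any(o.weight > 0 for o in self.observations):
            logger.warning("set %s: free constants but no weighted observations",
                           self.name)

    @property
    def weighted(self) -> list[SolubilityObservation]:
        return [o for o in self.observations if o.weight > 0]


@dataclass
class RefinedConstants:
    """Refinement result mirroring the per-set summary-table layout."""

    estimates: dict[str, float]
    sds: dict[str, float]
    gof: float
    n: int
    i_avg: float
    chi2: float = 0.0
    model: ModelConstants | None = None
    chi2_trace: list[float] = field(default_factory=list)


def _forward_logS(sets, model, activity, cache):
    out = []
    for si, tset in enumerate(sets):
        for oi, obs in enumerate(tset.observations):
            if obs.weight <= 0:
                continue
            warm = cache.get((si, oi))
            st = solve_equilibrium(tset.recipe, model, obs.pcH, activity, warm=warm)
            cache[(si, oi)] = st
            out.append((np.log10(st.s_dissolved), obs, st))
    return out


def refine(sets: TitrationSet | list[TitrationSet], model: ModelConstants,
           free: tuple[str, ...] | None = None,
           activity: ActivityModel | None = None,
           max_nfev: int = 400) -> RefinedConstants:
    """Refine the union of the sets' free constants against their data.

    Passing several sets refines them jointly (concatenated residual
    vectors, one recipe per set).  Constants not in the free mask are held
    at their ``model`` values and excluded from ``m`` and from pooling.
    """
    if isinstance(sets, TitrationSet):
        sets = [sets]
    if activity is None:
        activity = ActivityModel()
    if free is None:
        seen: list[str] = []
        for ts in sets:
            for k in ts.free_mask:
                if k not in seen:
                    seen.append(k)
        free = tuple(seen)
    if not free:
        raise InputError("no free constants to refine")
    for k in free:
        if k not in model.values:
            raise InputError(f"unknown constant {k!r}")
        if k in model.fixed:
            raise InputError(f"constant {k!r} is marked fixed")

    n = sum(len(ts.weighted) for ts in sets)
    m = len(free)
    if n <= m:
        raise UnderdeterminedError(f"{n} weighted points for {m} free constants")

    cache: dict[tuple[int, int], EquilibriumState] = {}
    trace: list[float] = []

    # Trial values outside +/-40 log units are physically meaningless and
    # can defeat the equilibrium solver; the surface is flat there, so
    # clamping lets LM retract oversized steps for unidentifiable constants.
    CLAMP = 40.0

    def residuals(theta):
        mod = model.updated(dict(zip(free, np.clip(theta, -CLAMP, CLAMP))))
        rows = _forward_logS(sets, mod, activity, cache)
        r = np.array([(obs.logS - calc) / obs.sigma for calc, obs, _ in rows])
        trace.append(float(r @ r))
        return r

    x0 = np.array([model.values[k] for k in free], dtype=float)
    try:
        res = least_squares(residuals, x0, method="lm",
                            diff_step=1e-4, max_nfev=max_nfev)
    except Exception as exc:  # solver blow-up inside an LM trial step
        raise RefineError(f"refinement failed: {exc}", trace=trace) from exc
    if not res.success:
        raise RefineError(f"refinement did not converge: {res.message}", trace=trace)

    chi2 = float(res.fun @ res.fun)
    gof = float(np.sqrt(chi2 / (n - m)))
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    sds = {k: float(gof * np.sqrt(max(cov[i, i], 0.0)))
           for i, k in enumerate(free)}
    estimates = dict(zip(free, (float(v) for v in np.clip(res.x, -CLAMP, CLAMP))))

    final_model = model.updated(estimates)
    rows = _forward_logS(sets, final_model, activity, cache)
    i_avg = float(np.mean([st.I for _, _, st in rows]))
    logger.info("refined %s: chi2=%.4g gof=%.3f n=%d", free, chi2, gof, n)
    return RefinedConstants(estimates=estimates, sds=sds, gof=gof, n=n,
                            i_avg=i_avg, chi2=chi2, model=final_model,
                            chi2_trace=trace)


def pool_weighted_mean(values, sds) -> tuple[float, float]:
    """Inverse-variance pooled mean: weights 1/SD^2, SD_mean = 1/sqrt(sum w)."""
    values = np.asarray(values, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if values.size == 0:
        raise DomainError("cannot pool an empty list")
    if values.shape != sds.shape:
        raise InputError("values and SDs must have equal length")
    if np.any(sds <= 0):
        raise InputError("SDs must be > 0 (exclude fixed entries)")
    w = 1.0 / sds**2
    mean = float(np.sum(w * values) / np.sum(w))
    sd_mean = float(1.0 / np.sqrt(np.sum(w)))
    return mean, sd_mean
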