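"""Ionic-strength bookkeeping, activity coefficients and pH-scale conversion.

The shipped activity model is the Davies equation for charged species plus a
linear salting-out term for the neutral drug::

    log10 gamma(z)   = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I)     (z != 0)
    log10 gamma(0)   = +Ks I                                     (neutral drug)

All equilibrium constants are stored at a reference ionic strength
(``I_ref``, default 0.15 mol/L) and rescaled to the working ionic strength
through the reaction stoichiometry.  Operational pH-meter readings are
converted to the concentration scale (pcH) by inverting the four-parameter
electrode map ``pH = alpha + ks*pcH + jH*10^-pcH + jOH*10^(pcH-pKw)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, InputError

logger = logging.getLogger("phsolv.activity")

__all__ = [
    "ActivityModel",
    "ElectrodeParams",
    "ionic_strength",
    "log_gamma",
    "scale_logK",
    "operational_to_pcH",
    "pcH_to_operational",
]

DAVIES_RANGE_MAX = 0.5  # nominal validity limit of the Davies equation


@dataclass(frozen=True)
class ActivityModel:
    """Davies-type activity model with neutral-drug salting-out.

    ``form='off'`` disables all corrections (every log gamma is zero).
    """

    form: str = "davies"
    A_DH: float = 0.509  # Debye-Hueckel slope at 25 degC
    Ks_neutral: float = 0.42  # salting-out coefficient of the neutral drug
    I_ref: float = 0.15  # mol/L

    def __post_init__(self):
        if self.form not in ("davies", "off"):
            raise InputError(f"unknown activity model form {self.form!r}")
        if self.I_ref <= 0:
            raise InputError("I_ref must be > 0")
        if self.Ks_neutral < 0:
            raise InputError("Ks_neutral must be >= 0")

    @classmethod
    def off(cls) -> "ActivityModel":
        return cls(form="off", A_DH=0.0, Ks_neutral=0.0)

    @property
    def is_off(self) -> bool:
        return self.form == "off"


def ionic_strength(concentrations, charges=None) -> float:
    """``I = 0.5 * sum(c_i z_i^2)`` over charged species.

    Accepts either an ``EquilibriumState``-like object exposing ``ions()``
    (returning parallel concentration/charge arrays) or two parallel
    sequences of concentrations and integer charges.
    """
    if charges is None:
        c, z = concentrations.ions()
    else:
        c, z = concentrations, charges
    c = np.asarray(c, dtype=float)
    z = np.asarray(z, dtype=float)
    if c.shape != z.shape:
        raise InputError("concentrations and charges must have equal length")
    if np.any(c < 0):
        raise InputError("negative concentration in ionic strength sum")
    return 0.5 * float(np.sum(c * z * z))


_warned_davies = False


def log_gamma(z: int, I: float, model: ActivityModel) -> float:
    """log10 activity coefficient of a species with charge ``z`` at ``I``.

    ``z == 0`` is interpreted as the neutral drug: the salting-out term
    ``+Ks*I`` is returned, so the neutral's effective activity rises with I.
    """
    if I < 0:
        raise InputError("ionic strength must be >= 0")
    if model.is_off:
        return 0.0
    if z == 0:
        return model.Ks_neutral * I
    global _warned_davies
    if I > DAVIES_RANGE_MAX and not _warned_davies:
        logger.warning(
            "Davies equation applied at I=%.3f mol/L, beyond its nominal "
            "validity range (I <= %.1f); substitute coefficients via the "
            "[activity] config section if needed", I, DAVIES_RANGE_MAX)
        _warned_davies = True
    sqrt_i = math.sqrt(I)
    return -model.A_DH * z * z * (sqrt_i / (1.0 + sqrt_i) - 0.3 * I)


def scale_logK(
    logK_at_Iref: float,
    stoichiometry: Iterable[tuple[int, float]],
    I_target: float,
    model: ActivityModel,
    salting: Sequence[bool] | None = None,
) -> float:
    """Rescale a concentration-scale constant from I_ref to ``I_target``.

    ``stoichiometry`` is an iterable of ``(charge, nu)`` pairs with ``nu``
    positive for species in the numerator of the mass-action quotient.
    ``salting`` optionally marks, per pair, whether a neutral entry is the
    salting-out drug (defaults to True for every z == 0 entry, matching
    :func:`log_gamma`).

    Satisfies the round-trip identity
    ``scale_logK(scale_logK(K, s, I, m, Iref->I), s, Iref, m) == K``.
    """
    if I_target < 0:
        raise InputError("I_target must be >= 0")
    if model.is_off:
        return logK_at_Iref
    pairs = list(stoichiometry)
    if salting is None:
        salting = [True] * len(pairs)

    def _lg(z, I, salts):
        if z == 0 and not salts:
            return 0.0
        return log_gamma(z, I, model)

    shift = sum(
        nu * (_lg(z, I_target, s) - _lg(z, model.I_ref, s))
        for (z, nu), s in zip(pairs, salting)
    )
    # K_c(I) = K_thermo / prod(gamma^nu)  =>  logK shifts by -delta(log gammas)
    return logK_at_Iref - shift


@dataclass(frozen=True)
class ElectrodeParams:
    """Four-parameter electrode standardisation map."""

    alpha: float = 0.0  # intercept, pH units
    ks: float = 1.0  # actual-to-Nernst slope ratio
    jH: float = 0.0  # acidic junction coefficient
    jOH: float = 0.0  # alkaline junction coefficient
    pKw: float = 13.764

    def __post_init__(self):
        if not 0.8 < self.ks < 1.2:
            raise InputError(f"electrode slope ratio ks={self.ks} outside (0.8, 1.2)")
        if not (math.isfinite(self.jH) and math.isfinite(self.jOH)):
            raise InputError("junction coefficients must be finite")


def pcH_to_operational(pcH: float, params: ElectrodeParams) -> float:
    """Forward electrode map: concentration-scale pcH -> meter reading."""
    return (params.alpha + params.ks * pcH
            + params.jH * 10.0 ** (-pcH)
            + params.jOH * 10.0 ** (pcH - params.pKw))


def operational_to_pcH(
    pH_reading: float,
    params: ElectrodeParams,
    bracket: tuple[float, float] = (-2.0, 16.0),
) -> float:
    """Invert the electrode map by safeguarded 1-D root finding."""
    if not -1.0 < pH_reading < 15.0:
        raise InputError(f"pH reading {pH_reading} outside (-1, 15)")

    def f(pcH):
        return pcH_to_operational(pcH, params) - pH_reading

    # The four-parameter map can be non-monotone for large junction
    # coefficients; scan the bracket and take the sign change closest to the
    # junction-free estimate (the physical branch).
    guess = (pH_reading - params.alpha) / params.ks
    lo, hi = bracket
    grid = np.linspace(lo, hi, 181)
    vals = np.array([f(g) for g in grid])
    signs = np.sign(vals)
    crossings = np.nonzero(signs[:-1] * signs[1:] <= 0)[0]
    if crossings.size == 0:
        raise CalibrationError(
            f"no pcH root in bracket {bracket} for reading {pH_reading}")
    mid = 0.5 * (grid[crossings] + grid[crossings + 1])
    k = int(crossings[np.argmin(np.abs(mid - guess))])
    return float(brentq(f, grid[k], grid[k + 1], xtol=1e-12, rtol=8.9e-16))
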