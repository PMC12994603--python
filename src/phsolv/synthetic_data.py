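"""Synthetic titration sets and conductivity curves.

Generates data with the statistical structure the analysis assumes:
log S-pcH observations are forward-simulated with the speciation solver
and perturbed with independent Gaussian noise (default SD 0.05 log units);
conductivity curves are two continuous line segments with multiplicative
Gaussian noise.  Every generator takes a seed and is bit-reproducible.

Bundled suspension designs ``set1_2 ... set6`` reconstruct the shipped
drug model's suspension recipes from weighed masses (molar masses computed
from the drug formulas at runtime, e.g. 52 mg of hydrochloride in 1 mL of
0.15 mol/L NaCl -> 0.164 mol/L total drug).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity_ph import ActivityModel
from .cmc_analysis import ConductivityCurve, MIN_POINTS
from .errors import InputError
from .model_registry import MediumRecipe, ModelConstants, build_default_model
from .refinement import TitrationSet
from .speciation import (
    ObservationFlag,
    SolubilityObservation,
    simulate_logS_curve,
)

__all__ = [
    "SyntheticDesign",
    "builtin_design",
    "make_titration_set",
    "make_conductivity_curve",
    "BUILTIN_DESIGN_NAMES",
]


@dataclass
class SyntheticDesign:
    """Recipe + grid + ground-truth constants for one synthetic set."""

    name: str
    recipe: MediumRecipe
    grid: np.ndarray
    truth: ModelConstants
    noise_sd: float = 0.05
    seed: int | None = None
    degradation_above: float | None = None
    free_mask: tuple[str, ...] = ()

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.noise_sd <= 0:
            raise InputError("noise SD must be > 0")


def _set_truth(overrides: dict[str, float]) -> ModelConstants:
    return build_default_model().updated(overrides)


def _builtin_designs() -> dict[str, SyntheticDesign]:
    salt = "salt_BHCl"
    base = "free_base"
    designs = {}
    designs["set1_2"] = SyntheticDesign(
        name="set1_2",
        recipe=MediumRecipe.from_weighed_solid(
            0.057, 1.0, salt, background_NaH2PO4=0.14, c_strong_acid=0.049),
        grid=np.linspace(3.82, 11.43, 17),
        truth=_set_truth({"logK141": 3.039, "pKsp_BH2HPO4": 6.699,
                          "logK310": 8.735, "logK750": 8.165}),
        free_mask=("logK141", "pKsp_BH2HPO4", "logK310", "logK750"),
    )
    designs["set3"] = SyntheticDesign(
        name="set3",
        recipe=MediumRecipe.from_weighed_solid(
            0.052, 1.0, salt, background_NaCl=0.15),
        grid=np.linspace(7.4, 11.87, 8),
        truth=_set_truth({"logK310": 8.816, "logK750": 9.981}),
        free_mask=("pS0", "logK310", "logK750"),
    )
    designs["set4"] = SyntheticDesign(
        name="set4",
        recipe=MediumRecipe.from_weighed_solid(
            0.068, 1.0, base, background_NaH2PO4=1.69, c_strong_base=0.46),
        grid=np.linspace(2.67, 6.27, 7),
        truth=_set_truth({"logK141": 0.364, "pKsp_BHH2PO4": 2.672,
                          "pKsp_BH2HPO4": 7.045, "logK310": 8.816,
                          "logK750": 9.981}),
        free_mask=("logK141", "pKsp_BHH2PO4", "pKsp_BH2HPO4"),
    )
    designs["set5"] = SyntheticDesign(
        name="set5",
        recipe=MediumRecipe.from_weighed_solid(
            0.071, 1.0, base, background_NaCl=1.70),
        grid=np.linspace(2.62, 8.00, 7),
        truth=_set_truth({"logK310": 8.332, "logK750": 9.816}),
        free_mask=("pKsp_BHCl", "logK310", "logK750"),
    )
    designs["set6"] = SyntheticDesign(
        name="set6",
        recipe=MediumRecipe.from_weighed_solid(
            0.069, 1.0, base, background_NaH2PO4=1.4, background_H3PO4=0.6),
        grid=np.linspace(2.50, 6.37, 9),
        truth=_set_truth({"logK141": 0.324, "pKsp_BHH2PO4": 2.829,
                          "pKsp_BH2HPO4": 6.801, "logK310": 8.816,
                          "logK750": 9.981}),
        free_mask=("logK141", "pKsp_BHH2PO4", "pKsp_BH2HPO4"),
    )
    return designs


BUILTIN_DESIGN_NAMES = ("set1_2", "set3", "set4", "set5", "set6")


def builtin_design(name: str, seed: int | None = None) -> SyntheticDesign:
    """One of the bundled suspension designs (``set1_2``..``set6``)."""
    designs = _builtin_designs()
    if name not in designs:
        raise InputError(f"unknown design {name!r}; choose from {BUILTIN_DESIGN_NAMES}")
    d = designs[name]
    d.seed = seed
    return d


def make_titration_set(design: SyntheticDesign,
                       activity: ActivityModel | None = None) -> TitrationSet:
    """Forward-simulate a design and add Gaussian noise on log S.

    Grid points where no solid forms are kept but flagged subsaturated
    (zero weight); points above the degradation cutoff are flagged
    degraded (zero weight).  The flags do not perturb the values.
    """
    rng = np.random.default_rng(design.seed)
    points = simulate_logS_curve(design.recipe, design.truth, design.grid, activity)
    noise = rng.normal(0.0, design.noise_sd, size=len(points))
    observations = []
    for pt, eps in zip(points, noise):
        flag = ObservationFlag.OK
        if pt.subsaturated:
            flag = ObservationFlag.SUBSATURATED
        elif (design.degradation_above is not None
                and pt.pcH > design.degradation_above):
            flag = ObservationFlag.DEGRADED
        observations.append(SolubilityObservation(
            pcH=pt.pcH, logS=pt.logS + eps, sigma=design.noise_sd, flag=flag))
    return TitrationSet(name=design.name, recipe=design.recipe,
                        observations=observations, free_mask=design.free_mask)


def make_conductivity_curve(
    true_cmc: float,
    pre_slope: float,
    post_slope: float,
    intercept: float,
    n_points: int = 16,
    rel_noise: float = 0.01,
    seed: int | None = None,
    span: tuple[float, float] = (0.3, 2.0),
    medium: str = "synthetic",
) -> ConductivityCurve:
    """Two-line kappa(c) curve, continuous at the breakpoint, with
    multiplicative Gaussian noise; points span ``span`` times the CMC."""
    if not pre_slope > post_slope > 0:
        raise InputError("need pre_slope > post_slope > 0")
    if n_points < MIN_POINTS:
        raise InputError(f"need at least {MIN_POINTS} points, got {n_points}")
    if true_cmc <= 0:
        raise InputError("true_cmc must be > 0")
    rng = np.random.default_rng(seed)
    conc = np.linspace(span[0] * true_cmc, span[1] * true_cmc, n_points)
    kappa = np.where(
        conc <= true_cmc,
        intercept + pre_slope * conc,
        intercept + pre_slope * true_cmc + post_slope * (conc - true_cmc))
    if rel_noise > 0:
        kappa = kappa * (1.0 + rng.normal(0.0, rel_noise, size=n_points))
    return ConductivityCurve(concentrations=conc, kappa=kappa, medium=medium)
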