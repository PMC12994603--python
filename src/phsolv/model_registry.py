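"""Domain types and the default imipramine equilibrium model.

The model describes a monoprotic base B (the drug) in media containing
chloride and/or phosphate.  Aqueous species are written in terms of three
stoichiometric indices (B units, bound protons, phosphate units); solution
constants are formation constants from the master species B, H3PO4, Cl- and
H+ on the concentration scale at the reference ionic strength.

Aggregation constants use the documented step convention::

    K_trimer   = [B2(BH+)]  / ([B]^2 [BH+])
    K_heptamer = [B2(BH+)5] / ([B]^2 [BH+]^5)
    K_complex  = [BH+.H3PO4] / ([BH+] [H3PO4])

The ``reference_convention`` tag on each species records this choice so an
alternative convention can be swapped in without touching the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import yaml

from . import elements
from .errors import InputError

__all__ = [
    "ReferenceConvention",
    "AqueousSpecies",
    "SolidPhase",
    "ModelConstants",
    "MediumRecipe",
    "build_default_model",
    "validate_model",
    "default_species",
    "default_solids",
    "DEFAULT_SET_ESTIMATES",
    "CONSTANT_KEYS",
    "SPECIES_CONSTANT_KEYS",
    "SOLID_CONSTANT_KEYS",
]


class ReferenceConvention(str, Enum):
    FROM_B_AND_BH = "from_B_and_BH"
    FROM_BH_AND_H3PO4 = "from_BH_and_H3PO4"
    MASS_ACTION_CORE = "mass_action_core"


@dataclass(frozen=True)
class AqueousSpecies:
    """A solution species with (B, H, PO4) stoichiometry.

    ``n_h`` counts protons relative to the cores B and PO4(3-); the charge
    bookkeeping invariant is ``charge == n_h - 3 * n_p`` (halide/alkali cores
    Cl- and Na+ are exempt, they carry their own fixed charge).
    ``logK_ref`` is the log10 formation constant from the masters
    (B, H3PO4, Cl-, H+) on the concentration scale at I_ref.
    """

    name: str
    n_b: int
    n_h: int
    n_p: int
    charge: int
    logK_ref: float
    reference_convention: ReferenceConvention = ReferenceConvention.MASS_ACTION_CORE
    n_cl: int = 0
    salting_out: bool = False  # neutral-drug salting-out applies

    @property
    def nu_h(self) -> int:
        """Protons consumed when forming the species from the masters."""
        return self.n_h - 3 * self.n_p


@dataclass(frozen=True)
class SolidPhase:
    """A precipitate with formula-unit stoichiometry and pKsp.

    ``iap_definition`` lists (free-species name, exponent) pairs defining
    the ion-activity product; for the free base solid it is ``[("B", 1)]``
    and ``pKsp_ref`` equals pS0.
    """

    name: str
    n_b: int
    n_h: int
    n_p: int
    n_cl: int
    pKsp_ref: float
    iap_definition: tuple[tuple[str, int], ...]

    @property
    def net_charge(self) -> int:
        return self.n_h - 3 * self.n_p - self.n_cl


SPECIES_CONSTANT_KEYS = (
    "pKa",
    "pKw",
    "pKa1_H3PO4",
    "pKa2_H3PO4",
    "pKa3_H3PO4",
    "logK310",
    "logK750",
    "logK141",
)
SOLID_CONSTANT_KEYS = (
    "pS0",
    "pKsp_BHCl",
    "pKsp_BHH2PO4",
    "pKsp_BH2HPO4",
)
CONSTANT_KEYS = SPECIES_CONSTANT_KEYS + SOLID_CONSTANT_KEYS

# Constants that are background bookkeeping, never refined by default.
BACKGROUND_KEYS = ("pKa", "pKw", "pKa1_H3PO4", "pKa2_H3PO4", "pKa3_H3PO4")


@dataclass(frozen=True)
class ModelConstants:
    """Bag of equilibrium constants with per-constant SD and free/fixed flag.

    ``values`` may map an aggregation constant to ``None`` (species absent,
    equivalent to log K = -inf).
    """

    values: Mapping[str, float | None]
    sd: Mapping[str, float] = field(default_factory=dict)
    fixed: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "sd", dict(self.sd))
        object.__setattr__(self, "fixed", frozenset(self.fixed))

    def __getitem__(self, key: str) -> float | None:
        return self.values[key]

    def updated(self, changes: Mapping[str, float | None] | None = None, **kw):
        """Return a copy with some constant values replaced."""
        vals = dict(self.values)
        vals.update(changes or {})
        vals.update(kw)
        return replace(self, values=vals)

    def without_aggregates(self) -> "ModelConstants":
        """Copy with trimer/heptamer/phosphate-complex species switched off."""
        return self.updated(logK310=None, logK750=None, logK141=None)

    # -- serialisation ----------------------------------------------------
    def to_yaml(self) -> str:
        """Canonical YAML (sorted keys) so round-trips are byte-identical."""
        doc = {
            "constants": {k: self.values.get(k) for k in sorted(SPECIES_CONSTANT_KEYS)},
            "solids": {k: self.values.get(k) for k in sorted(SOLID_CONSTANT_KEYS)},
            "sd": {k: self.sd[k] for k in sorted(self.sd)},
            "fixed": sorted(self.fixed),
        }
        return yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConstants":
        doc = yaml.safe_load(text)
        values = {}
        values.update(doc.get("constants") or {})
        values.update(doc.get("solids") or {})
        return cls(
            values=values,
            sd=doc.get("sd") or {},
            fixed=frozenset(doc.get("fixed") or ()),
        )


class StartingMaterial(str, Enum):
    SALT_BHCL = "salt_BHCl"
    FREE_BASE = "free_base"


@dataclass(frozen=True)
class MediumRecipe:
    """Per-litre-of-suspension totals for one suspension series.

    The hydrochloride starting material contributes one chloride per drug
    unit; ``c_cl_total`` must already include that contribution (use
    :meth:`from_weighed_solid` to get the bookkeeping right).
    """

    c_b_total: float
    c_p_total: float = 0.0
    c_cl_total: float = 0.0
    c_na_total: float = 0.0
    c_strong_acid: float = 0.0
    c_strong_base: float = 0.0
    starting_material: StartingMaterial = StartingMaterial.SALT_BHCL

    def __post_init__(self):
        object.__setattr__(self, "starting_material",
                           StartingMaterial(self.starting_material))
        for name in ("c_b_total", "c_p_total", "c_cl_total", "c_na_total",
                     "c_strong_acid", "c_strong_base"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0, got {getattr(self, name)}")
        if (self.starting_material is StartingMaterial.SALT_BHCL
                and self.c_cl_total < self.c_b_total - 1e-12):
            raise InputError(
                "salt_BHCl starting material contributes 1 Cl per B; "
                f"c_cl_total={self.c_cl_total} < c_b_total={self.c_b_total}"
            )

    @classmethod
    def from_weighed_solid(
        cls,
        mass_g: float,
        volume_mL: float,
        starting_material: StartingMaterial | str = StartingMaterial.SALT_BHCL,
        background_NaCl: float = 0.0,
        background_NaH2PO4: float = 0.0,
        background_H3PO4: float = 0.0,
        c_strong_acid: float = 0.0,
        c_strong_base: float = 0.0,
    ) -> "MediumRecipe":
        """Build a recipe from a weighed solid in a background electrolyte.

        Molar masses are computed from the drug formulas at call time.
        """
        starting_material = StartingMaterial(starting_material)
        if starting_material is StartingMaterial.SALT_BHCL:
            mm = elements.molar_mass(elements.HYDROCHLORIDE_FORMULA)
        else:
            mm = elements.molar_mass(elements.FREE_BASE_FORMULA)
        c_b = mass_g / mm / (volume_mL * 1e-3)
        c_cl = background_NaCl + c_strong_acid
        if starting_material is StartingMaterial.SALT_BHCL:
            c_cl += c_b
        return cls(
            c_b_total=c_b,
            c_p_total=background_NaH2PO4 + background_H3PO4,
            c_cl_total=c_cl,
            c_na_total=background_NaCl + background_NaH2PO4,
            c_strong_acid=c_strong_acid,
            c_strong_base=c_strong_base,
            starting_material=starting_material,
        )


def build_default_model() -> ModelConstants:
    """The shipped imipramine model (pooled constants at I_ref = 0.15 M).

    Background constants (water ionisation and phosphoric acid pKa's at
    25 degC, I = 0.15 M) are configuration defaults and may be overridden
    via the bundled YAML file.
    """
    values = {
        "pKa": 9.52,
        "pKw": 13.764,
        "pKa1_H3PO4": 1.95,
        "pKa2_H3PO4": 6.74,
        "pKa3_H3PO4": 11.60,
        "logK310": 8.728,
        "logK750": 9.970,
        "logK141": 0.374,
        "pS0": 4.602,
        "pKsp_BHCl": 2.338,
        "pKsp_BHH2PO4": 2.823,
        "pKsp_BH2HPO4": 6.812,
    }
    sd = {
        "logK310": 0.0017,
        "logK750": 0.0040,
        "logK141": 0.016,
        "pS0": 0.02,
        "pKsp_BHCl": 0.02,
        "pKsp_BHH2PO4": 0.00010,
        "pKsp_BH2HPO4": 0.00009,
    }
    return ModelConstants(values=values, sd=sd, fixed=frozenset(BACKGROUND_KEYS))


# Published per-suspension-set estimates for the default drug model:
# constant -> list of (set label, value, SD); SD None means held fixed in
# that set (excluded from pooling).  These are the pooling inputs behind
# the weighted means in build_default_model().
DEFAULT_SET_ESTIMATES: dict[str, list[tuple[str, float, float | None]]] = {
    "logK141": [("set1_2", 3.039, 0.94), ("set4", 0.364, 0.58), ("set6", 0.324, 0.13)],
    "pKsp_BHH2PO4": [("set4", 2.672, 0.05), ("set6", 2.829, 0.01)],
    "pKsp_BH2HPO4": [("set1_2", 6.699, 0.06), ("set4", 7.045, 0.04), ("set6", 6.801, 0.01)],
    "logK310": [("set1_2", 8.735, 0.06), ("set3", 8.816, 0.06), ("set5", 8.332, 0.13),
                ("set4", 8.816, None), ("set6", 8.816, None)],
    "logK750": [("set1_2", 8.165, 0.94), ("set3", 9.981, 0.06), ("set5", 9.816, 0.47),
                ("set4", 9.981, None), ("set6", 9.981, None)],
    "pKsp_BHCl": [("set3", 2.338, None), ("set5", 2.338, 0.02)],
    "pS0": [("set1_2", 4.602, None), ("set3", 4.602, None), ("set4", 4.602, None),
            ("set5", 4.602, None), ("set6", 4.602, None)],
}


def default_species(model: ModelConstants) -> list[AqueousSpecies]:
    """Instantiate the species list for a constants bag.

    Aggregate species whose constant is ``None``/-inf are omitted.
    """
    v = model.values
    core = ReferenceConvention.MASS_ACTION_CORE
    agg = ReferenceConvention.FROM_B_AND_BH
    out = [
        AqueousSpecies("B", 1, 0, 0, 0, 0.0, core, salting_out=True),
        AqueousSpecies("BH+", 1, 1, 0, +1, v["pKa"], core),
        AqueousSpecies("H3PO4", 0, 3, 1, 0, 0.0, core),
        AqueousSpecies("H2PO4-", 0, 2, 1, -1, -v["pKa1_H3PO4"], core),
        AqueousSpecies("HPO4-2", 0, 1, 1, -2, -(v["pKa1_H3PO4"] + v["pKa2_H3PO4"]), core),
        AqueousSpecies("PO4-3", 0, 0, 1, -3,
                       -(v["pKa1_H3PO4"] + v["pKa2_H3PO4"] + v["pKa3_H3PO4"]), core),
        AqueousSpecies("Cl-", 0, 0, 0, -1, 0.0, core, n_cl=1),
        AqueousSpecies("OH-", 0, -1, 0, -1, -v["pKw"], core),
    ]

    def _on(key):
        val = v.get(key)
        return val is not None and math.isfinite(val)

    if _on("logK310"):
        out.append(AqueousSpecies("B2(BH+)", 3, 1, 0, +1, v["logK310"] + v["pKa"], agg))
    if _on("logK750"):
        out.append(AqueousSpecies("B2(BH+)5", 7, 5, 0, +5, v["logK750"] + 5 * v["pKa"], agg))
    if _on("logK141"):
        out.append(AqueousSpecies(
            "BH+.H3PO4", 1, 4, 1, +1, v["logK141"] + v["pKa"],
            ReferenceConvention.FROM_BH_AND_H3PO4))
    return out


def default_solids(model: ModelConstants) -> list[SolidPhase]:
    """Candidate precipitates in their tie-break (acid-to-base) order."""
    v = model.values
    return [
        SolidPhase("BHCl(s)", 1, 1, 0, 1, v["pKsp_BHCl"],
                   (("BH+", 1), ("Cl-", 1))),
        SolidPhase("BHH2PO4(s)", 1, 3, 1, 0, v["pKsp_BHH2PO4"],
                   (("BH+", 1), ("H2PO4-", 1))),
        SolidPhase("BH2HPO4(s)", 2, 3, 1, 0, v["pKsp_BH2HPO4"],
                   (("BH+", 2), ("HPO4-2", 1))),
        SolidPhase("B(s)", 1, 0, 0, 0, v["pS0"],
                   (("B", 1),)),
    ]


_CHARGE_EXEMPT = {"Cl-", "Na+"}


def validate_model(model: ModelConstants) -> list[str]:
    """Return a list of invariant violations (empty list means valid)."""
    violations: list[str] = []
    for key in CONSTANT_KEYS:
        if key not in model.values:
            violations.append(f"missing constant {key}")
    for key, val in model.values.items():
        if key not in CONSTANT_KEYS:
            violations.append(f"orphan constant {key} maps to no species or solid")
        elif val is not None and not math.isfinite(val) and not (
                key in ("logK310", "logK750", "logK141") and val == -math.inf):
            violations.append(f"constant {key} is not finite")
    for key, s in model.sd.items():
        if s is not None and s < 0:
            violations.append(f"negative SD for {key}")
        if key in model.fixed:
            violations.append(f"fixed constant {key} carries an SD")
    if violations:
        return violations

    for sp in default_species(model):
        if sp.name in _CHARGE_EXEMPT or sp.n_cl:
            continue
        if sp.charge != sp.n_h - 3 * sp.n_p:
            violations.append(
                f"species {sp.name}: charge {sp.charge} != n_h - 3 n_p "
                f"= {sp.n_h - 3 * sp.n_p}")
        if min(sp.n_b, sp.n_h, sp.n_p) < 0 and sp.name != "OH-":
            violations.append(f"species {sp.name}: negative stoichiometry")
    for solid in default_solids(model):
        if solid.net_charge != 0:
            violations.append(
                f"solid {solid.name}: formula unit has net charge {solid.net_charge}")
        if not math.isfinite(solid.pKsp_ref):
            violations.append(f"solid {solid.name}: pKsp not finite")
    return violations


def validate_solids(solids: Iterable[SolidPhase]) -> list[str]:
    """Electroneutrality check for a custom solid list."""
    out = []
    for so in solids:
        if so.net_charge != 0:
            out.append(f"solid {so.name}: formula unit has net charge {so.net_charge}")
    return out


def validate_species(species: Iterable[AqueousSpecies]) -> list[str]:
    """Charge-bookkeeping check for a custom species list."""
    out = []
    for sp in species:
        if sp.name in _CHARGE_EXEMPT or sp.n_cl:
            continue
        if sp.charge != sp.n_h - 3 * sp.n_p:
            out.append(f"species {sp.name}: charge {sp.charge} != n_h - 3 n_p")
    return out
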