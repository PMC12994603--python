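"""Theoretical elemental composition of candidate solid forms.

Builds candidate salt/base hydrates, computes their C/H mass percentages
from standard atomic weights, and assigns the nearest candidate to an
observed (C%, H%) pair by Euclidean distance.  The hydrochloride salt and
the base dihydrate have near-identical C% (~72 %), so ranking always uses
C and H jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import elements
from .errors import InputError

__all__ = [
    "CandidateComposition",
    "elemental_percentages",
    "assign_composition",
    "default_candidates",
]


@dataclass(frozen=True)
class CandidateComposition:
    label: str
    formula: str
    element_counts: dict[str, int]
    n_waters: int
    molar_mass: float
    c_pct: float
    h_pct: float


def elemental_percentages(formula: str) -> tuple[float, float, float]:
    """(C%, H%, molar mass g/mol) of a formula from standard atomic weights."""
    counts = elements.parse_formula(formula)
    fractions = elements.mass_fractions(counts)
    return (fractions.get("C", 0.0), fractions.get("H", 0.0),
            elements.molar_mass(counts))


def make_candidate(label: str, anhydrous_formula: str, n_waters: int) -> CandidateComposition:
    formula = anhydrous_formula if n_waters == 0 else (
        f"{anhydrous_formula}·{n_waters}H2O")
    counts = elements.parse_formula(formula)
    c, h, mass = elemental_percentages(formula)
    return CandidateComposition(label=label, formula=formula,
                                element_counts=counts, n_waters=n_waters,
                                molar_mass=mass, c_pct=c, h_pct=h)


# Anhydrous parents of the shipped drug model.
_BASE = ("Imp", elements.FREE_BASE_FORMULA)
_HCL_SALT = ("ImpHCl", elements.HYDROCHLORIDE_FORMULA)
_HPO4_SALT = ("(ImpH)2HPO4", f"({elements.CATION_FORMULA})2·HPO4")
_H2PO4_SALT = ("ImpH·H2PO4", f"{elements.CATION_FORMULA}·H2PO4")

HYDRATION_NUMBERS = (0, 1, 2, 4)


def default_candidates(medium: str) -> list[CandidateComposition]:
    """Candidate list for a medium: chloride-free media exclude the
    hydrochloride; phosphate-free media exclude phosphate salts."""
    medium = medium.lower()
    known = {"phosphate", "chloride", "phosphate+chloride"}
    if medium not in known:
        raise InputError(f"medium must be one of {sorted(known)}")
    parents = [_BASE]
    if "phosphate" in medium:
        parents += [_HPO4_SALT, _H2PO4_SALT]
    if "chloride" in medium:
        parents += [_HCL_SALT]
    out = []
    for label, formula in parents:
        for n in HYDRATION_NUMBERS:
            suffix = "" if n == 0 else f"·{n}H2O"
            out.append(make_candidate(f"{label}{suffix}", formula, n))
    return out


def assign_composition(
    observed_c: float, observed_h: float,
    candidates: list[CandidateComposition],
) -> list[tuple[CandidateComposition, float]]:
    """Rank candidates by Euclidean distance in (C%, H%) space.

    Returns the full ranking as (candidate, distance) pairs, best first.
    """
    if not candidates:
        raise InputError("candidate list is empty")
    ranked = sorted(
        ((cand, ((cand.c_pct - observed_c) ** 2
                 + (cand.h_pct - observed_h) ** 2) ** 0.5)
         for cand in candidates),
        key=lambda cd: cd[1])
    return ranked
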