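"""Chemical formula parsing and molar masses from standard atomic weights.

Formulas may contain parenthesised groups with multipliers and hydrate /
adduct parts separated by ``·``, ``×``, ``*`` or ``.``, each with an optional
leading integer multiplier, e.g. ``"(C19H25N2)2·HPO4·2H2O"``.
"""

from __future__ import annotations

import re

from .errors import FormulaParseError

# IUPAC 2021 abridged standard atomic weights (g/mol).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)|(\()|(\))(\d*)")
_PART_SEP = re.compile(r"[·×*.]")


def _parse_part(part: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    stack: list[dict[str, int]] = [counts]
    pos = 0
    while pos < len(part):
        m = _TOKEN.match(part, pos)
        if m is None:
            raise FormulaParseError(f"cannot parse formula near {part[pos:]!r}")
        pos = m.end()
        if m.group(1):  # element symbol
            sym, num = m.group(1), int(m.group(2) or 1)
            if sym not in ATOMIC_WEIGHTS:
                raise FormulaParseError(f"unknown element {sym!r}")
            stack[-1][sym] = stack[-1].get(sym, 0) + num
        elif m.group(3):  # "("
            stack.append({})
        else:  # ")" with optional multiplier
            if len(stack) == 1:
                raise FormulaParseError(f"unbalanced ')' in {part!r}")
            group = stack.pop()
            mult = int(m.group(5) or 1)
            for sym, n in group.items():
                stack[-1][sym] = stack[-1].get(sym, 0) + n * mult
    if len(stack) != 1:
        raise FormulaParseError(f"unbalanced '(' in {part!r}")
    return counts


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``formula`` into a mapping element symbol -> atom count."""
    total: dict[str, int] = {}
    for raw in _PART_SEP.split(formula.strip()):
        part = raw.strip()
        if not part:
            continue
        m = re.match(r"(\d+)(.*)", part)
        mult = 1
        if m and m.group(2):
            mult, part = int(m.group(1)), m.group(2)
        counts = _parse_part(part)
        for sym, n in counts.items():
            total[sym] = total.get(sym, 0) + n * mult
    if not total:
        raise FormulaParseError(f"empty formula {formula!r}")
    return total


def molar_mass(formula: str | dict[str, int]) -> float:
    """Molar mass (g/mol) of a formula string or element-count mapping."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ATOMIC_WEIGHTS[sym] * n for sym, n in counts.items())


def mass_fractions(formula: str | dict[str, int]) -> dict[str, float]:
    """Mass percentage of each element; values sum to 100."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    mass = molar_mass(counts)
    return {sym: 100.0 * ATOMIC_WEIGHTS[sym] * n / mass for sym, n in counts.items()}


# Formulas of the shipped drug model (imipramine); molar masses are always
# derived from these at runtime, never stored as numbers.
FREE_BASE_FORMULA = "C19H24N2"
HYDROCHLORIDE_FORMULA = "C19H25N2·Cl"
CATION_FORMULA = "C19H25N2"
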