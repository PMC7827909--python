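"""Elemental formulas, monoisotopic masses, and adduct-ion arithmetic.

Monoisotopic masses are sums of the most abundant isotope masses of the
constituent atoms.  Observed MALDI ions are singly charged adducts of a
neutral species M; their m/z is an affine transform of the neutral
monoisotopic mass::

    m/z = n * M + delta

where ``n`` counts the M units in cluster ions (``2M+Na``) and ``delta``
is the signed mass of the attached/lost atoms (``+K``, ``-H``, ``-H2O-H``
...).  By default the *atomic-mass* convention is used: protonation adds
the mass of a hydrogen atom (1.00783 Da), not of a bare proton, and no
electron-mass correction is applied.  The ion-physics convention (proton
mass plus electron bookkeeping) is available via ``electron_correction``;
the two differ by at most ~0.0011 Da, far below the 0.025 Da matching
tolerance used throughout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

__all__ = [
    "ElementMassTable",
    "AdductRule",
    "FormulaError",
    "AdductParseError",
    "load_element_masses",
    "parse_formula",
    "monoisotopic_mass",
    "parse_adduct",
    "adduct_mz",
    "neutral_mass",
    "default_rules",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "WATER_MASS",
]


class FormulaError(ValueError):
    """Raised for empty formulas or unknown element symbols."""


class AdductParseError(ValueError):
    """Raised when an adduct name does not follow the ``n?M(+/-species)*`` grammar."""


ElementMassTable = Mapping[str, float]
Formula = Mapping[str, int]


def load_element_masses() -> dict[str, float]:
    """Load the bundled monoisotopic element mass table (CODATA/IUPAC values).

    The table also carries the proton and electron masses under the
    pseudo-symbols ``proton`` and ``electron``.
    """
    path = resources.files("smearmsi.data").joinpath("element_masses.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return {r["symbol"]: float(r["monoisotopic_mass_Da"]) for r in rows}


ELEMENT_MASSES: dict[str, float] = load_element_masses()
PROTON_MASS = ELEMENT_MASSES["proton"]
ELECTRON_MASS = ELEMENT_MASSES["electron"]
WATER_MASS = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula like ``C10H16N5O13P3``.

    Counts default to 1.  Repeated symbols accumulate.  Raises
    :class:`FormulaError` for empty input, unknown symbols, or trailing
    garbage.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    s = formula.strip()
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENT_MASSES or sym in ("proton", "electron"):
            raise FormulaError(f"unknown element symbol {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    if not counts:
        raise FormulaError("empty formula")
    return counts


def monoisotopic_mass(formula: str | Formula, masses: ElementMassTable | None = None) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula.

    ``formula`` may be a string (parsed with :func:`parse_formula`) or a
    symbol→count mapping.
    """
    if masses is None:
        masses = ELEMENT_MASSES
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts or all(c == 0 for c in counts.values()):
        raise FormulaError("empty formula")
    total = 0.0
    for sym, cnt in counts.items():
        if sym not in masses:
            raise FormulaError(f"unknown element symbol {sym!r}")
        if cnt < 0:
            raise FormulaError(f"negative count for {sym!r}")
        total += masses[sym] * cnt
    return total


@dataclass(frozen=True)
class AdductRule:
    """A singly charged adduct transform: m/z = n * M + delta.

    polarity is +1 for positive-mode ions, -1 for negative-mode ions.
    """

    name: str
    n: int
    delta: float
    polarity: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("multiplier n must be a positive integer")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


# species masses and their single-ion charge contribution when *added*
_SPECIES = {
    "H": (ELEMENT_MASSES["H"], +1),
    "Na": (ELEMENT_MASSES["Na"], +1),
    "K": (ELEMENT_MASSES["K"], +1),
    "Cl": (ELEMENT_MASSES["Cl"], -1),
    "H2O": (WATER_MASS, 0),
}

_ADDUCT_RE = re.compile(r"^(\d*)M((?:[+-]\d?(?:H2O|H20|Na|K|Cl|H))*)$")
_TERM_RE = re.compile(r"([+-])(\d?)(H2O|H20|Na|K|Cl|H)")


def parse_adduct(name: str) -> AdductRule:
    """Parse an adduct name such as ``M-H``, ``2M+Na`` or ``M+H-2H2O``.

    Grammar: ``n?M(+species|-species)*`` with species in {H, Na, K, Cl,
    H2O}, each optionally preceded by a small count (``2H2O``).  The
    historical spelling ``H20`` (digit zero) is accepted as an alias of
    ``H2O``.  Polarity is the net charge of the attached/lost species; the
    bare radical ion ``M`` is positive by convention.
    """
    s = name.strip()
    m = _ADDUCT_RE.match(s)
    if m is None:
        raise AdductParseError(
            f"cannot parse adduct {name!r}; expected n?M(+/-species)* with "
            "species in {H, Na, K, Cl, H2O}, e.g. 'M-H', '2M+Na', 'M+H-2H2O'"
        )
    n = int(m.group(1)) if m.group(1) else 1
    delta = 0.0
    charge = 0
    for sign, cnt, sp in _TERM_RE.findall(m.group(2)):
        sp = "H2O" if sp == "H20" else sp
        k = int(cnt) if cnt else 1
        mass, q = _SPECIES[sp]
        sgn = 1 if sign == "+" else -1
        delta += sgn * k * mass
        charge += sgn * k * q
    if charge == 0:
        polarity = +1  # bare [M]+ radical cation, e.g. oxidized heme
    elif charge in (+1, -1):
        polarity = charge
    else:
        raise AdductParseError(f"adduct {name!r} implies charge {charge:+d}; only singly charged ions are supported")
    return AdductRule(name=s, n=n, delta=delta, polarity=polarity)


def adduct_mz(neutral: float, rule: AdductRule | str, electron_correction: bool = False) -> float:
    """m/z of the singly charged adduct ion of a neutral mass (Da).

    With ``electron_correction`` the electron mass is subtracted for
    positive ions and added for negative ions (ion-physics convention).
    """
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    if isinstance(rule, str):
        rule = parse_adduct(rule)
    mz = rule.n * neutral + rule.delta
    if electron_correction:
        mz -= rule.polarity * ELECTRON_MASS
    return mz


def neutral_mass(mz: float, rule: AdductRule | str, electron_correction: bool = False) -> float:
    """Invert :func:`adduct_mz`: recover the neutral mass from an ion m/z."""
    if isinstance(rule, str):
        rule = parse_adduct(rule)
    if electron_correction:
        mz = mz + rule.polarity * ELECTRON_MASS
    return (mz - rule.delta) / rule.n


def _load_registry() -> list[AdductRule]:
    path = resources.files("smearmsi.data").joinpath("adducts.csv")
    rules = []
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rules.append(
                AdductRule(
                    name=row["name"],
                    n=int(row["n"]),
                    delta=float(row["delta_Da"]),
                    polarity=int(row["polarity"]),
                )
            )
    return rules


def default_rules(polarity: int | None = None) -> list[AdductRule]:
    """The bundled adduct registry (every adduct string used in the study),
    optionally filtered to one polarity."""
    rules = _load_registry()
    if polarity is not None:
        rules = [r for r in rules if r.polarity == polarity]
    return rules
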