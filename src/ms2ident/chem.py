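"""Elemental formulas, monoisotopic masses, adduct arithmetic and formula decomposition.

Masses of the most abundant isotopes are taken from the NIST table shipped
with :mod:`pyteomics.mass`.  All ions are treated as singly charged; adduct
mass shifts follow the proton-mass convention (the electron mass is ignored,
an error well below 1 ppm at metabolite masses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mass as _pt_mass

__all__ = [
    "ELEMENTS",
    "PROTON_MASS",
    "Formula",
    "Adduct",
    "Molecule",
    "ADDUCTS",
    "get_adduct",
    "load_adduct_table",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_from_mz",
    "rdbe",
    "decompose_mass",
    "ChemError",
]

#: Supported elements, heaviest first (DFS order for decomposition).
ELEMENTS = ("I", "Br", "Cl", "S", "P", "F", "O", "N", "C", "H")

#: Monoisotopic mass of the most abundant isotope of each element, in Da.
ELEMENT_MASS = {el: _pt_mass.nist_mass[el][0][0] for el in ELEMENTS}

PROTON_MASS = 1.007276
H_MASS = ELEMENT_MASS["H"]

# Standard valences used for the ring-plus-double-bond-equivalent filter.
_VALENCE = {"C": 4, "H": 1, "N": 3, "O": 2, "P": 5, "S": 6,
            "F": 1, "Cl": 1, "Br": 1, "I": 1}


class ChemError(ValueError):
    """Invalid formula, adduct or decomposition request."""


@dataclass(frozen=True)
class Formula:
    """Elemental composition over C, H, N, O, P, S and the halogens."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for el, n in self.counts:
            if el not in ELEMENT_MASS:
                raise ChemError(f"unsupported element {el!r}")
            if n < 0:
                raise ChemError(f"negative count for {el}")
        if not any(n > 0 for _, n in self.counts):
            raise ChemError("empty formula")

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "Formula":
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return cls(items)

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``C6H12O6``."""
        import re

        counts: dict[str, int] = {}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if m.start() != pos:
                raise ChemError(f"cannot parse formula {text!r}")
            if not m.group(0):
                break
            pos = m.end()
            el, n = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(n) if n else 1)
        if pos != len(text) or not counts:
            raise ChemError(f"cannot parse formula {text!r}")
        return cls.from_dict(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    @property
    def mass(self) -> float:
        return sum(ELEMENT_MASS[el] * n for el, n in self.counts)

    def add_hydrogens(self, k: int) -> "Formula":
        """Return the formula with *k* hydrogens added (k may be negative)."""
        counts = self.as_dict()
        counts["H"] = counts.get("H", 0) + k
        if counts["H"] < 0:
            raise ChemError("hydrogen count would be negative")
        return Formula.from_dict(counts)

    def is_subformula_of(self, other: "Formula", h_slack: int = 0) -> bool:
        """True if every element count fits within *other* (H up to *h_slack* over)."""
        oc = other.as_dict()
        for el, n in self.counts:
            allowed = oc.get(el, 0) + (h_slack if el == "H" else 0)
            if n > allowed:
                return False
        return True

    def __str__(self) -> str:  # Hill order: C, H, then alphabetical
        d = self.as_dict()
        parts = []
        for el in ["C", "H"] + sorted(set(d) - {"C", "H"}):
            n = d.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def monoisotopic_mass(formula: Formula) -> float:
    """Monoisotopic (most-abundant-isotope) mass of *formula* in Da."""
    return formula.mass


@dataclass(frozen=True)
class Adduct:
    """A singly charged ESI adduct: label, polarity and neutral-mass shift."""

    label: str
    polarity: int          # +1 or -1
    mass_shift: float      # Da added to the neutral monoisotopic mass

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ChemError("polarity must be +1 or -1")


# Built-in table; standard singly-charged shifts (proton-mass convention).
_ADDUCT_ROWS = [
    ("[M+H]+", +1, PROTON_MASS),
    ("[M+Na]+", +1, 22.989218),
    ("[M+NH4]+", +1, 18.033823),
    ("[M-H]-", -1, -PROTON_MASS),
    ("[M+Cl]-", -1, 34.969402),
    ("[M+FA-H]-", -1, 44.998201),
]

ADDUCTS: dict[str, Adduct] = {lbl: Adduct(lbl, pol, sh) for lbl, pol, sh in _ADDUCT_ROWS}

# Unicode minus occasionally appears in copy-pasted labels.
_LABEL_ALIASES = {"[M−H]−": "[M-H]-", "[M−H]-": "[M-H]-"}


def get_adduct(label: str) -> Adduct:
    label = _LABEL_ALIASES.get(label, label)
    try:
        return ADDUCTS[label]
    except KeyError:
        known = ", ".join(ADDUCTS)
        raise ChemError(f"unknown adduct {label!r}; known adducts: {known}") from None


def load_adduct_table(path: str | Path) -> dict[str, Adduct]:
    """Load extra adducts from a whitespace-separated config file.

    Each non-comment line holds ``label polarity mass_shift``; entries are
    merged into (and may override) the built-in table.
    """
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            label, pol, shift = line.split()
            ADDUCTS[label] = Adduct(label, int(pol), float(shift))
        except (ValueError, ChemError) as exc:
            raise ChemError(f"{path}:{lineno}: bad adduct row: {exc}") from None
    return ADDUCTS


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of the singly charged adduct ion of a neutral of *neutral_mass* Da."""
    if neutral_mass <= 0:
        raise ChemError("neutral mass must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return neutral_mass + adduct.mass_shift


def neutral_from_mz(precursor_mz: float, adduct: Adduct | str) -> float:
    """Exact inverse of :func:`adduct_mz`."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return precursor_mz - adduct.mass_shift


@dataclass(frozen=True)
class Molecule:
    """A neutral small molecule: structure line notation + formula + mass."""

    structure: str
    formula: Formula
    neutral_monoisotopic_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.neutral_monoisotopic_mass == 0.0:
            object.__setattr__(self, "neutral_monoisotopic_mass", self.formula.mass)
        elif abs(self.neutral_monoisotopic_mass - self.formula.mass) > 1e-6:
            raise ChemError(
                f"mass {self.neutral_monoisotopic_mass} inconsistent with formula "
                f"{self.formula} ({self.formula.mass:.6f})"
            )

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemError(f"unparsable SMILES {smiles!r}")
        counts: dict[str, int] = {}
        for atom in mol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
            counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
        return cls(structure=smiles, formula=Formula.from_dict(counts))


def rdbe(formula: Formula) -> float:
    """Ring-plus-double-bond equivalents, 1 + sum(n_i (v_i - 2)) / 2."""
    return 1.0 + sum(n * (_VALENCE[el] - 2) for el, n in formula.counts) / 2.0


DEFAULT_BOUNDS = {"C": 40, "H": 80, "N": 10, "O": 20, "P": 5, "S": 5}

_MAX_STATES = 10**7


def decompose_mass(
    target_mass: float,
    tol_ppm: float = 5.0,
    element_bounds: dict[str, int] | None = None,
) -> list[Formula]:
    """All formulas within *tol_ppm* of a neutral *target_mass*, RDBE-filtered.

    Candidates must have RDBE >= 0 and integer RDBE (the consistency condition
    for neutral even-electron species).  Results are sorted by absolute mass
    error, ties by formula string.

    Heavy elements are enumerated depth-first with mass pruning; the hydrogen
    count is then solved directly from the residual mass, so the search space
    is the product of heavy-element ranges only.
    """
    if target_mass <= 0:
        raise ChemError("target mass must be positive")
    if tol_ppm <= 0:
        raise ChemError("tolerance must be positive")
    bounds = dict(DEFAULT_BOUNDS if element_bounds is None else element_bounds)
    for el in bounds:
        if el not in ELEMENT_MASS:
            raise ChemError(f"unsupported element {el!r} in bounds")

    tol_da = target_mass * tol_ppm * 1e-6
    heavy = [el for el in ELEMENTS if el != "H" and bounds.get(el, 0) > 0]
    h_max = bounds.get("H", 0)

    states = 1
    for el in heavy:
        states *= min(bounds[el], int(target_mass / ELEMENT_MASS[el])) + 1
        if states > _MAX_STATES:
            raise ChemError(
                f"element bounds allow > {_MAX_STATES:.0e} enumeration states; "
                "tighten the per-element bounds"
            )

    out: list[tuple[float, Formula]] = []
    counts: dict[str, int] = {}

    def recurse(i: int, mass_so_far: float) -> None:
        if mass_so_far > target_mass + tol_da:
            return
        if i == len(heavy):
            # Solve the hydrogen count from the residual mass.
            resid = target_mass - mass_so_far
            h = int(round(resid / H_MASS))
            for hh in (h - 1, h, h + 1):
                if hh < 0 or hh > h_max:
                    continue
                err = mass_so_far + hh * H_MASS - target_mass
                if abs(err) > tol_da:
                    continue
                trial = {**counts, "H": hh}
                if not any(trial.values()):
                    continue
                f = Formula.from_dict(trial)
                r = rdbe(f)
                if r < -1e-9 or abs(r - round(r)) > 1e-9:
                    continue
                out.append((abs(err), f))
            return
        el = heavy[i]
        m = ELEMENT_MASS[el]
        top = min(bounds[el], int((target_mass + tol_da - mass_so_far) / m))
        for n in range(top + 1):
            if n:
                counts[el] = n
            elif el in counts:
                del counts[el]
            recurse(i + 1, mass_so_far + n * m)
        counts.pop(el, None)

    recurse(0, 0.0)
    out.sort(key=lambda t: (t[0], str(t[1])))
    return [f for _, f in out]
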