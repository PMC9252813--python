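"""Combinatorial bond-breaking fragment enumeration and peak assignment.

Fragments are the connected components left after deleting up to ``max_depth``
breakable bonds from the molecular graph (every cut costs one depth unit, so
splitting a ring costs two cuts).  A bond is breakable if it is a single bond
or lies in a ring; acyclic multiple bonds are kept intact.  Each fragment is
emitted with hydrogen-rearrangement variants (h_shift in [-2, +2]) and
deduplicated by (formula, h_shift), keeping the fewest broken bonds.

Ion m/z values follow the even-electron convention: fragment monoisotopic
mass + h_shift x m(H) +/- m(proton) for positive/negative mode.  Following
the precursor-only adduct rule, non-protonated adducts shift only the intact
precursor ion; daughter ions are always computed as [M+H]+ / [M-H]- species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem

from .chem import H_MASS, PROTON_MASS, ChemError, Formula, Molecule, adduct_mz, get_adduct
from .spectra import Spectrum

__all__ = [
    "FragmentIon",
    "PeakAnnotation",
    "AnnotatedSpectrum",
    "enumerate_fragments",
    "assign_peaks",
    "write_annotation",
    "read_annotation",
    "H_SHIFT_RANGE",
]

#: Hydrogen rearrangement allowance for fragment ions.
H_SHIFT_RANGE = (-2, -1, 0, 1, 2)

DEFAULT_MAX_DEPTH = 2


@dataclass(frozen=True)
class FragmentIon:
    """A connected substructure of the parent with a hydrogen shift applied."""

    parent_structure: str
    substructure: str            # SMILES of the connected fragment
    formula: Formula             # composition after the hydrogen shift
    broken_bonds: int
    h_shift: int
    theoretical_mz: float

    def __str__(self) -> str:
        sign = "+" if self.h_shift >= 0 else ""
        return f"{self.substructure} ({self.formula}, {sign}{self.h_shift}H, {self.theoretical_mz:.4f})"


def _mol_from_structure(structure: str) -> Chem.Mol:
    if structure.startswith("InChI="):
        mol = Chem.MolFromInchi(structure)
    else:
        mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ChemError(f"unparsable structure {structure!r}")
    return mol


def _component_atoms(n_atoms: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    """Connected components of an atom graph given the surviving edges."""
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    seen = [False] * n_atoms
    comps = []
    for start in range(n_atoms):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _fragment_formula(mol: Chem.Mol, atoms: list[int]) -> Formula:
    counts: dict[str, int] = {}
    for idx in atoms:
        atom = mol.GetAtomWithIdx(idx)
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        counts["H"] = counts.get("H", 0) + atom.GetTotalNumHs()
    return Formula.from_dict(counts)


def _ion_mz(neutral_fragment_mass: float, h_shift: int, ion_mode: str) -> float:
    charge = PROTON_MASS if ion_mode == "positive" else -PROTON_MASS
    return neutral_fragment_mass + h_shift * H_MASS + charge


def enumerate_fragments(
    molecule: Molecule | str,
    max_depth: int = DEFAULT_MAX_DEPTH,
    ion_mode: str = "positive",
) -> list[FragmentIon]:
    """Enumerate candidate fragment ions of *molecule* up to *max_depth* bond breaks.

    Returns fragments (including the intact molecule at 0 breaks) deduplicated
    by (formula, h_shift); deterministic order (ascending theoretical m/z,
    then substructure SMILES).
    """
    if max_depth not in (0, 1, 2, 3):
        raise ValueError("max_depth must be in {1, 2, 3}")
    if isinstance(molecule, str):
        molecule = Molecule.from_smiles(molecule)
    mol = _mol_from_structure(molecule.structure)
    n_atoms = mol.GetNumAtoms()
    bonds = [(b.GetIdx(), b.GetBeginAtomIdx(), b.GetEndAtomIdx())
             for b in mol.GetBonds()
             if b.GetBondType() == Chem.BondType.SINGLE or b.IsInRing()]

    best: dict[tuple[Formula, int], FragmentIon] = {}

    def emit(atoms: list[int], n_broken: int) -> None:
        base = _fragment_formula(mol, atoms)
        smiles = Chem.MolFragmentToSmiles(mol, atomsToUse=atoms, canonical=True)
        for h in H_SHIFT_RANGE:
            if base["H"] + h < 0:
                continue
            formula = base.add_hydrogens(h)
            key = (formula, h)
            prev = best.get(key)
            if prev is not None and prev.broken_bonds <= n_broken:
                continue
            best[key] = FragmentIon(
                parent_structure=molecule.structure,
                substructure=smiles,
                formula=formula,
                broken_bonds=n_broken,
                h_shift=h,
                theoretical_mz=_ion_mz(base.mass, h, ion_mode),
            )

    all_atoms = list(range(n_atoms))
    for depth in range(max_depth + 1):
        for cut in itertools.combinations(bonds, depth):
            cut_ids = {b[0] for b in cut}
            edges = [(a, b) for idx, a, b in
                     [(bd.GetIdx(), bd.GetBeginAtomIdx(), bd.GetEndAtomIdx()) for bd in mol.GetBonds()]
                     if idx not in cut_ids]
            comps = _component_atoms(n_atoms, edges) if cut else [all_atoms]
            for comp in comps:
                emit(comp, depth)

    return sorted(best.values(), key=lambda f: (f.theoretical_mz, f.substructure))


@dataclass(frozen=True)
class PeakAnnotation:
    fragment: FragmentIon | None
    ppm_error: float | None

    @property
    def matched(self) -> bool:
        return self.fragment is not None


@dataclass(frozen=True)
class AnnotatedSpectrum:
    spectrum: Spectrum
    annotations: tuple[PeakAnnotation, ...]

    @property
    def n_matched(self) -> int:
        return sum(a.matched for a in self.annotations)


def assign_peaks(
    spectrum: Spectrum,
    molecule: Molecule | str,
    tol_ppm: float = 10.0,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> AnnotatedSpectrum:
    """Annotate each peak with the best-matching enumerated fragment ion.

    Best = smallest |ppm error|, ties broken by fewer broken bonds, then
    smaller |h_shift|, then substructure SMILES.  The precursor peak (if the
    spectrum's adduct is known) is matched against the intact adduct ion,
    which for non-protonated adducts is the only ion carrying the adduct
    shift.  Peaks with no fragment within tolerance stay unannotated.
    """
    if spectrum.ion_mode is None:
        raise ValueError("spectrum ion_mode must be known for peak assignment")
    if isinstance(molecule, str):
        molecule = Molecule.from_smiles(molecule)
    fragments = enumerate_fragments(molecule, max_depth=max_depth, ion_mode=spectrum.ion_mode)
    if spectrum.adduct is not None:
        adduct = get_adduct(spectrum.adduct)
        precursor_ion = FragmentIon(
            parent_structure=molecule.structure,
            substructure=molecule.structure,
            formula=molecule.formula,
            broken_bonds=0,
            h_shift=0,
            theoretical_mz=adduct_mz(molecule.neutral_monoisotopic_mass, adduct),
        )
        fragments = fragments + [precursor_ion]

    annotations = []
    for peak in spectrum.peaks:
        tol_da = peak.mz * tol_ppm * 1e-6
        candidates = [f for f in fragments if abs(f.theoretical_mz - peak.mz) <= tol_da]
        if not candidates:
            annotations.append(PeakAnnotation(None, None))
            continue
        frag = min(
            candidates,
            key=lambda f: (abs(f.theoretical_mz - peak.mz), f.broken_bonds,
                           abs(f.h_shift), f.substructure),
        )
        ppm = (peak.mz - frag.theoretical_mz) / frag.theoretical_mz * 1e6
        annotations.append(PeakAnnotation(frag, ppm))
    return AnnotatedSpectrum(spectrum=spectrum, annotations=tuple(annotations))


def write_annotation(annotated: AnnotatedSpectrum, path: str | Path) -> None:
    """Write the annotated peak list as TSV: mz, intensity, SMILES, formula, ppm."""
    with open(path, "w") as fh:
        fh.write("mz\tintensity\tfragment\tformula\tppm_error\n")
        for peak, ann in zip(annotated.spectrum.peaks, annotated.annotations):
            if ann.matched:
                fh.write(f"{peak.mz:.6f}\t{peak.relative_intensity:.4f}\t"
                         f"{ann.fragment.substructure}\t{ann.fragment.formula}\t"
                         f"{ann.ppm_error:.4f}\n")
            else:
                fh.write(f"{peak.mz:.6f}\t{peak.relative_intensity:.4f}\t-\t-\t-\n")


def read_annotation(path: str | Path) -> list[dict[str, object]]:
    """Read an annotation TSV back into a list of row dicts (round-trip check)."""
    rows = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        vals = line.split("\t")
        row: dict[str, object] = dict(zip(header, vals))
        row["mz"] = float(row["mz"])
        row["intensity"] = float(row["intensity"])
        row["ppm_error"] = None if row["ppm_error"] == "-" else float(row["ppm_error"])
        rows.append(row)
    return rows
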