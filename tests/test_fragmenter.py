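"""Bond-breaking fragment enumeration and peak assignment."""

import itertools

import pytest
from rdkit import Chem

from ms2ident.chem import PROTON_MASS, ChemError, Molecule
from ms2ident.fragmenter import (assign_peaks, enumerate_fragments,
                                 read_annotation, write_annotation)
from ms2ident.spectra import make_spectrum

# A seeded set of small molecules (<= 10 heavy atoms) for oracle comparison.
SMALL_MOLECULES = [
    "CCO", "CC(=O)O", "CCN", "OCC(O)CO", "CC(C)C", "c1ccccc1", "C1CCCCC1",
    "CC(N)C(=O)O", "OC(=O)CC(=O)O", "c1ccncc1", "CC(=O)C", "CCOC(=O)C",
    "NCCO", "CSC", "OCC=O", "CC#N", "C1CC1", "C1COC1", "Oc1ccccc1",
    "CNC(=O)C", "CC(O)C(=O)O", "NC(=O)N", "CCCC", "OCCO", "C1CCNC1",
]


def oracle_depth1_formulas(smiles):
    """Independent depth-1 oracle: per-bond component split via raw atom walks.

    Deliberately avoids the implementation's helpers: components are found by
    a set-growing loop over RDKit's bond list, and formulas are plain counted
    dicts (element -> count including implicit H).
    """
    mol = Chem.MolFromSmiles(smiles)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    breakable = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE or b.IsInRing()
    ]
    n = mol.GetNumAtoms()

    def formula_of(atom_ids):
        counts = {}
        for i in atom_ids:
            a = mol.GetAtomWithIdx(i)
            counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
            counts["H"] = counts.get("H", 0) + a.GetTotalNumHs()
        return tuple(sorted((k, v) for k, v in counts.items() if v))

    def components(excluded):
        remaining_edges = [e for e in bonds if e != excluded]
        comps, unseen = [], set(range(n))
        while unseen:
            grow = {unseen.pop()}
            changed = True
            while changed:
                changed = False
                for a, b in remaining_edges:
                    if a in grow and b not in grow and b in unseen:
                        grow.add(b); unseen.discard(b); changed = True
                    elif b in grow and a not in grow and a in unseen:
                        grow.add(a); unseen.discard(a); changed = True
            comps.append(grow)
        return comps

    out = {(formula_of(range(n)), 0)}
    for e in breakable:
        for comp in components(e):
            out.add((formula_of(comp), 1 if len(comp) < n else 1))
    # collapse to formula set with h-shifts applied the same way
    shifted = set()
    for (formula, _), h in itertools.product(out, (-2, -1, 0, 1, 2)):
        d = dict(formula)
        if d.get("H", 0) + h < 0:
            continue
        d["H"] = d.get("H", 0) + h
        shifted.add(tuple(sorted((k, v) for k, v in d.items() if v)))
    return shifted


class TestEnumerateFragments:
    def test_ethanol_depth1_bond_breaks(self):
        frags = enumerate_fragments("CCO", max_depth=1)
        formulas = {str(f.formula) for f in frags if f.broken_bonds == 1}
        # C-C break: CH3 / CH2OH sides; C-O break: C2H5 / OH sides
        assert {"CH3", "CH3O", "C2H5", "HO"} <= formulas

    def test_methane_depth1_intact_only(self):
        frags = enumerate_fragments("C", max_depth=1)
        assert all(f.broken_bonds == 0 for f in frags)
        assert {str(f.formula) for f in frags} == {"CH2", "CH3", "CH4", "CH5", "CH6"}

    def test_benzene_ring_needs_two_cuts(self):
        depth1 = enumerate_fragments("c1ccccc1", max_depth=1)
        # a single ring cut leaves the molecule connected: only C6 compositions
        assert {f.formula["C"] for f in depth1} == {6}
        depth2 = enumerate_fragments("c1ccccc1", max_depth=2)
        assert {f.formula["C"] for f in depth2} > {6}

    def test_theoretical_mz_protonation_rule(self):
        pos = {(str(f.formula), f.h_shift): f.theoretical_mz
               for f in enumerate_fragments("CCO", 1, ion_mode="positive")}
        neg = {(str(f.formula), f.h_shift): f.theoretical_mz
               for f in enumerate_fragments("CCO", 1, ion_mode="negative")}
        for key, mz in pos.items():
            assert neg[key] == pytest.approx(mz - 2 * PROTON_MASS, abs=1e-9)

    def test_unparsable_structure(self):
        with pytest.raises(ChemError):
            enumerate_fragments("][", max_depth=1)

    @pytest.mark.parametrize("smiles", SMALL_MOLECULES)
    def test_depth1_matches_exhaustive_oracle(self, smiles):
        got = {tuple(sorted(f.formula.counts)) for f in enumerate_fragments(smiles, 1)}
        assert got == oracle_depth1_formulas(smiles)

    @pytest.mark.parametrize("smiles", ["CC(=O)O", "c1ccccc1", "OCC(O)CO"])
    def test_depth_monotonicity(self, smiles):
        keys = lambda frags: {(f.formula, f.h_shift) for f in frags}
        d1, d2, d3 = (keys(enumerate_fragments(smiles, d)) for d in (1, 2, 3))
        assert d1 <= d2 <= d3

    def test_fragment_formula_within_parent(self):
        parent = Molecule.from_smiles("CC(N)C(=O)O")
        for f in enumerate_fragments(parent, 2):
            assert f.formula.is_subformula_of(parent.formula, h_slack=2)


class TestAssignPeaks:
    def _mol_and_spectrum(self):
        mol = Molecule.from_smiles("CC(N)C(=O)O")  # alanine, 6 heavy atoms
        frags = enumerate_fragments(mol, 2, ion_mode="positive")
        chosen = [f for f in frags if f.broken_bonds == 1][:3]
        pairs = [(f.theoretical_mz, 50.0) for f in chosen]
        spectrum = make_spectrum(pairs, ion_mode="positive")
        return mol, spectrum

    def test_constructed_peaks_all_annotated(self):
        mol, spectrum = self._mol_and_spectrum()
        ann = assign_peaks(spectrum, mol, tol_ppm=10)
        assert ann.n_matched == len(spectrum)
        for a in ann.annotations:
            assert abs(a.ppm_error) <= 10

    def test_offset_peak_unannotated(self):
        mol, spectrum = self._mol_and_spectrum()
        pairs = [(p.mz, p.relative_intensity) for p in spectrum.peaks]
        pairs.append((spectrum.peaks[0].mz + 0.5, 30.0))
        spectrum2 = make_spectrum(pairs, ion_mode="positive")
        ann = assign_peaks(spectrum2, mol, tol_ppm=10)
        unmatched = [a for a in ann.annotations if not a.matched]
        assert len(unmatched) == 1

    def test_annotation_count_matches_brute_force(self):
        import numpy as np

        mol = Molecule.from_smiles("CC(=O)Nc1ccc(O)cc1")  # paracetamol
        frags = enumerate_fragments(mol, 2, ion_mode="positive")
        mzs = sorted({f.theoretical_mz for f in frags})
        rng = np.random.default_rng(17)
        pairs = [(float(rng.uniform(20, 160)), 50.0) for _ in range(12)]
        spectrum = make_spectrum(pairs, ion_mode="positive")
        ann = assign_peaks(spectrum, mol, tol_ppm=10)
        expected = sum(
            any(abs(p.mz - m) <= p.mz * 1e-5 for m in mzs) for p in spectrum.peaks
        )
        assert ann.n_matched == expected

    def test_precursor_annotated_as_adduct_ion(self):
        mol = Molecule.from_smiles("OCC(O)CO")
        precursor = mol.neutral_monoisotopic_mass + 22.989218  # [M+Na]+
        spectrum = make_spectrum([(precursor, 100.0)], ion_mode="positive",
                                 adduct="[M+Na]+", precursor_mz=precursor)
        ann = assign_peaks(spectrum, mol, tol_ppm=5)
        assert ann.n_matched == 1
        assert ann.annotations[0].fragment.formula == mol.formula

    def test_annotation_tsv_roundtrip(self, tmp_path):
        mol, spectrum = self._mol_and_spectrum()
        pairs = [(p.mz, p.relative_intensity) for p in spectrum.peaks]
        pairs.append((spectrum.peaks[-1].mz + 0.5, 30.0))
        ann = assign_peaks(make_spectrum(pairs, ion_mode="positive"), mol)
        path = tmp_path / "ann.tsv"
        write_annotation(ann, path)
        rows = read_annotation(path)
        assert len(rows) == len(ann.annotations)
        for row, a, peak in zip(rows, ann.annotations, ann.spectrum.peaks):
            assert row["mz"] == pytest.approx(peak.mz, abs=1e-6)
            if a.matched:
                assert row["fragment"] == a.fragment.substructure
                assert row["formula"] == str(a.fragment.formula)
            else:
                assert row["fragment"] == "-"
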