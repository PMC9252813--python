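"""Synthetic spectral libraries with ground truth, for testing and benchmarking.

The simulator draws real small-molecule structures from a packaged list,
fragments each one combinatorially, and turns the fragment ions into
per-energy spectra with the qualitative behaviour of collision-induced
dissociation: at low collision energy the precursor ion dominates and few
fragments appear; at high energy the precursor is depleted and the intensity
distribution moves toward low-mass fragments.  Queries are noised copies of
the library spectra — Gaussian ppm-scale m/z jitter plus uniformly placed
spurious peaks — with the generating compound as ground truth.

Everything is driven by one integer seed through numpy's Generator, so a
given (seed, parameters) pair reproduces the library byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._compounds import COMPOUNDS
from .chem import ELEMENT_MASS, Formula, Molecule, adduct_mz, get_adduct, rdbe
from .fragmenter import enumerate_fragments
from .identify import CandidateRecord, SpectralLibrary
from .spectra import ENERGIES, Spectrum, SpectrumSet, make_spectrum

__all__ = ["NoiseModel", "simulate_library", "simulate_spectrum_set",
           "shifted_analog", "random_formula", "OXYGEN_MASS"]

#: Monoisotopic mass of one oxygen atom — the canonical analog modification
#: (hydroxylation) used in neutral-loss search demonstrations.
OXYGEN_MASS = ELEMENT_MASS["O"]

#: m/z decay scale (Da) of fragment survival per collision energy: smaller
#: scale at higher energy pushes intensity toward low-mass fragments.
_ENERGY_DECAY = {10: 400.0, 20: 180.0, 40: 80.0}
#: Relative precursor-ion intensity per energy (precursor survives low CID).
_PRECURSOR_INTENSITY = {10: 100.0, 20: 40.0, 40: 8.0}
#: Fragment peaks drawn per spectrum (at most; fewer for small molecules).
_N_FRAGMENT_PEAKS = 8


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to query spectra.

    jitter_ppm: standard deviation of Gaussian m/z error, ppm.
    n_spurious: count of random contaminant peaks added per spectrum.
    spurious_intensity: upper bound of the uniform spurious intensity, percent.
    """

    jitter_ppm: float = 2.0
    n_spurious: int = 2
    spurious_intensity: float = 20.0

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(jitter_ppm=0.0, n_spurious=0)


def simulate_spectrum_set(
    molecule: Molecule,
    rng: np.random.Generator,
    adduct: str = "[M+H]+",
    fragment_depth: int = 2,
    energies: tuple[int, ...] = ENERGIES,
) -> SpectrumSet:
    """Per-energy in-silico spectra of *molecule* from its fragment ions."""
    add = get_adduct(adduct)
    ion_mode = "positive" if add.polarity > 0 else "negative"
    precursor = adduct_mz(molecule.neutral_monoisotopic_mass, add)
    # Daughter ions as [M+H]+/[M-H]- species; only the precursor carries a
    # non-protonated adduct shift.
    fragments = [
        f for f in enumerate_fragments(molecule, max_depth=fragment_depth, ion_mode=ion_mode)
        if f.broken_bonds > 0 and 10.0 < f.theoretical_mz < precursor - 1.0
    ]
    spectra = []
    for energy in energies:
        pairs = [(precursor, _PRECURSOR_INTENSITY[energy])]
        if fragments:
            weights = np.array([np.exp(-f.theoretical_mz / _ENERGY_DECAY[energy])
                                for f in fragments])
            weights /= weights.sum()
            k = min(_N_FRAGMENT_PEAKS, len(fragments))
            chosen = rng.choice(len(fragments), size=k, replace=False, p=weights)
            for idx in sorted(chosen):
                intensity = float(rng.uniform(5.0, 100.0))
                pairs.append((fragments[idx].theoretical_mz, intensity))
        spectra.append(make_spectrum(
            pairs,
            precursor_mz=precursor,
            ion_mode=ion_mode,
            adduct=adduct,
            collision_energy=energy,
        ))
    return SpectrumSet.from_spectra(spectra)


def _noised_copy(spectrum_set: SpectrumSet, noise: NoiseModel,
                 rng: np.random.Generator) -> SpectrumSet:
    if noise.jitter_ppm == 0 and noise.n_spurious == 0:
        return SpectrumSet.from_spectra(replace(s) for s in spectrum_set)
    out = []
    for spec in spectrum_set:
        pairs = []
        for p in spec.peaks:
            mz = p.mz * (1.0 + 1e-6 * noise.jitter_ppm * rng.standard_normal()) \
                if noise.jitter_ppm > 0 else p.mz
            pairs.append((mz, p.relative_intensity))
        for _ in range(noise.n_spurious):
            mz = float(rng.uniform(30.0, spec.precursor_mz or 500.0))
            pairs.append((mz, float(rng.uniform(0.5, noise.spurious_intensity))))
        out.append(make_spectrum(
            pairs,
            precursor_mz=spec.precursor_mz,
            ion_mode=spec.ion_mode,
            adduct=spec.adduct,
            collision_energy=spec.collision_energy,
            source_id=spec.source_id,
        ))
    return SpectrumSet.from_spectra(out)


def simulate_library(
    n_compounds: int,
    seed: int,
    fragment_depth: int = 2,
    noise_model: NoiseModel | None = None,
    adduct: str = "[M+H]+",
    energies: tuple[int, ...] = ENERGIES,
) -> tuple[SpectralLibrary, list[tuple[SpectrumSet, str]]]:
    """Build a seeded synthetic library and a matched query test set.

    Compounds are drawn (without replacement) from the packaged structure
    list; each gets per-energy spectra via :func:`simulate_spectrum_set`.
    The test set holds one noised query per compound with its identifier as
    ground truth.  Fully reproducible: the same arguments give identical
    output.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    if n_compounds > len(COMPOUNDS):
        raise ValueError(f"at most {len(COMPOUNDS)} packaged compounds available")
    noise = NoiseModel() if noise_model is None else noise_model
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(COMPOUNDS), size=n_compounds, replace=False)
    records = []
    testset = []
    for idx in sorted(picks):
        name, smiles = COMPOUNDS[idx]
        molecule = Molecule.from_smiles(smiles)
        spectra = simulate_spectrum_set(
            molecule, rng, adduct=adduct, fragment_depth=fragment_depth,
            energies=energies,
        )
        records.append(CandidateRecord(identifier=name, molecule=molecule, spectra=spectra))
        query = _noised_copy(spectra, noise, rng)
        query = SpectrumSet.from_spectra(
            replace(s, source_id=name) for s in query
        )
        testset.append((query, name))
    return SpectralLibrary(records), testset


def shifted_analog(spectrum_set: SpectrumSet, delta_mass: float = OXYGEN_MASS) -> SpectrumSet:
    """Spectra of a structural analog: precursor and every product peak
    shifted by *delta_mass*, intensities kept.

    This models a chemical modification (default: +O, hydroxylation) that is
    retained in every fragment, so all neutral losses are preserved while the
    parent mass moves outside any ppm retrieval window.
    """
    out = []
    for spec in spectrum_set:
        peaks = tuple(
            replace(p, mz=p.mz + delta_mass) for p in spec.peaks
        )
        out.append(replace(
            spec, peaks=peaks,
            precursor_mz=(spec.precursor_mz or 0.0) + delta_mass,
        ))
    return SpectrumSet.from_spectra(out)


def random_formula(rng: np.random.Generator, max_mass: float = 500.0) -> Formula:
    """A random valid CHNOPS formula (integer RDBE >= 0) below *max_mass* Da.

    Heavy-atom counts are drawn uniformly at modest ranges, then the hydrogen
    count is drawn with the parity and ceiling that keep the ring-plus-double-
    bond equivalent a non-negative integer, mimicking real molecular formulas.
    """
    while True:
        c = int(rng.integers(1, 25))
        n = int(rng.integers(0, 5))
        o = int(rng.integers(0, 9))
        p = int(rng.integers(0, 3))
        s = int(rng.integers(0, 3))
        h_cap = 2 + 2 * c + n + 3 * p + 4 * s
        parity = (n + p) % 2
        choices = [h for h in range(parity, h_cap + 1, 2)]
        h = int(choices[rng.integers(0, len(choices))])
        counts = {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s}
        f = Formula.from_dict(counts)
        if f.mass >= max_mass:
            continue
        r = rdbe(f)
        assert r >= 0 and abs(r - round(r)) < 1e-9
        return f
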