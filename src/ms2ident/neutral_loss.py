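"""Neutral-loss spectra and the neutral-loss analog search.

A neutral-loss spectrum replaces each product peak's m/z by the mass lost
from the precursor (precursor m/z - product m/z), inheriting intensities.
Losses are invariant to any chemical modification that shifts the precursor
and all fragments by the same mass, which is what makes neutral-loss search
able to find structural analogs (e.g. a hydroxylated form, +15.9949 Da) that
a precursor-mass-filtered product-ion search can never retrieve.

Accordingly the search here applies NO precursor-mass filter: every library
record is scored by count-based Dice similarity between neutral-loss spectra,
averaged over the query's collision energies, with an absolute-Da matching
tolerance (losses are mass differences, so a ppm window makes no sense).
"""

from __future__ import annotations

from dataclasses import dataclass

from .identify import CandidateRecord, RankedHit, SpectralLibrary, _rank_scored
from .scoring import SimilarityScore, dice_score
from .spectra import Peak, Spectrum, SpectrumSet, SpectrumError

__all__ = [
    "MIN_LOSS_DA",
    "NL_TOL_DA",
    "neutral_loss_spectrum",
    "neutral_loss_set",
    "nl_search",
]

#: Minimum loss mass (Da); drops the precursor's own ~0 Da self-loss.
MIN_LOSS_DA = 0.5
#: Default absolute matching tolerance between losses, Da.
NL_TOL_DA = 0.01


def neutral_loss_spectrum(spectrum: Spectrum, min_loss: float = MIN_LOSS_DA) -> Spectrum:
    """The spectrum of losses (precursor m/z - product m/z) >= *min_loss*.

    Returned as a Spectrum whose "m/z" axis is loss mass, sorted ascending,
    intensities inherited from the product peaks and renormalized; the
    original precursor m/z is kept as provenance.  Raises if the spectrum has
    no precursor m/z, or if every peak sits within *min_loss* of it (an empty
    loss spectrum).
    """
    if spectrum.precursor_mz is None:
        raise SpectrumError("neutral-loss spectrum requires a precursor m/z")
    losses = [
        (spectrum.precursor_mz - p.mz, p.relative_intensity)
        for p in spectrum.peaks
        if spectrum.precursor_mz - p.mz >= min_loss
    ]
    if not losses:
        raise SpectrumError("no losses above min_loss: spectrum holds only the precursor")
    top = max(i for _, i in losses)
    peaks = tuple(Peak(loss, 100.0 * (i / top)) for loss, i in sorted(losses))
    return Spectrum(
        peaks=peaks,
        precursor_mz=spectrum.precursor_mz,
        ion_mode=spectrum.ion_mode,
        adduct=spectrum.adduct,
        collision_energy=spectrum.collision_energy,
        source_id=spectrum.source_id,
    )


def neutral_loss_set(spectrum_set: SpectrumSet, min_loss: float = MIN_LOSS_DA) -> SpectrumSet:
    """Per-energy neutral-loss spectra; energies with no losses are dropped."""
    out = {}
    for energy, spec in spectrum_set.spectra.items():
        try:
            out[energy] = neutral_loss_spectrum(spec, min_loss)
        except SpectrumError:
            continue
    if not out:
        raise SpectrumError("no energy level yields a non-empty loss spectrum")
    return SpectrumSet(out)


def _nl_multi_energy_dice(
    query_nl: SpectrumSet, candidate_nl: SpectrumSet, tol_abs_da: float
) -> SimilarityScore:
    # Mean Dice over the query's energies; ppm tolerance 0 so the absolute
    # window governs (losses are differences).
    energies = query_nl.energies
    total = 0.0
    for energy in energies:
        cand = candidate_nl.spectra.get(energy)
        if cand is not None:
            total += dice_score(query_nl.spectra[energy], cand,
                                tol_ppm=0.0, tol_abs_da=tol_abs_da).value
    return SimilarityScore(total / len(energies), "dice")


def nl_search(
    query: SpectrumSet,
    library: SpectralLibrary,
    tol_abs_da: float = NL_TOL_DA,
    top_n: int | None = 10,
    min_loss: float = MIN_LOSS_DA,
) -> list[RankedHit]:
    """Rank all library records by neutral-loss Dice similarity to the query.

    No precursor-mass filter is applied: analogs whose parent mass differs
    from the query's are exactly the intended matches.  Candidate neutral-
    loss spectra are computed on the fly; records with no usable losses score
    0.  Ties are broken by candidate identifier.
    """
    if len(query) == 0:
        raise ValueError("query must contain at least one spectrum")
    query_nl = neutral_loss_set(query, min_loss)
    scored: list[tuple[float, CandidateRecord]] = []
    for rec in library.records:
        try:
            cand_nl = neutral_loss_set(rec.spectra, min_loss)
        except SpectrumError:
            scored.append((0.0, rec))
            continue
        scored.append((_nl_multi_energy_dice(query_nl, cand_nl, tol_abs_da).value, rec))
    return list(_rank_scored(scored, top_n))
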