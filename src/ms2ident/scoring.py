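"""Peak matching across two spectra and the Dice / dot-product similarities.

Peaks of two spectra are paired one-to-one by minimum-cost assignment over
candidate pairs, each within the combined tolerance
max(tol_ppm * mz * 1e-6, tol_abs_da).  The Dice score is the
count-based set overlap 2*|matched| / (|a| + |b|); the dot-product score is
the cosine of peak-weight vectors w = mz^p * intensity^q aligned on the
matched pairs and normalised by the full vector norms, so unmatched peaks
dilute the score.  Both are symmetric and live in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "MatchResult",
    "SimilarityScore",
    "match_peaks",
    "dice_score",
    "dot_product_score",
    "multi_energy_score",
    "get_scorer",
    "SCORERS",
    "TOL_ABS_DA",
]

#: Absolute floor of the matching tolerance, Da (avoids vanishing ppm windows
#: at low m/z).
TOL_ABS_DA = 0.001

MZ_POWER = 0.5
INTENSITY_POWER = 0.5


@dataclass(frozen=True)
class MatchResult:
    """One-to-one peak pairing between a query and a reference spectrum."""

    pairs: tuple[tuple[int, int], ...]   # (index in a, index in b)
    n_unmatched_a: int
    n_unmatched_b: int


@dataclass(frozen=True)
class SimilarityScore:
    value: float
    method: str

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"similarity {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


def _tol_da(mz: float, tol_ppm: float, tol_abs_da: float) -> float:
    return max(tol_ppm * mz * 1e-6, tol_abs_da)


def match_peaks(
    a: Spectrum,
    b: Spectrum,
    tol_ppm: float = 10.0,
    tol_abs_da: float = TOL_ABS_DA,
) -> MatchResult:
    """Optimal one-to-one peak matching within tolerance.

    Among all one-to-one pairings of peaks within tolerance, returns one with
    the maximum number of pairs and, among those, minimum total |delta m/z|
    (Hungarian assignment).  On well-separated peaks this coincides with the
    simple greedy smallest-difference-first pass, but unlike greedy it cannot
    drop a pair in chained near-tolerance configurations, it is symmetric in
    its arguments, and it matches exhaustive enumeration exactly.
    Deterministic for fixed inputs.
    """
    candidates: list[tuple[float, int, int]] = []
    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            d = abs(pa.mz - pb.mz)
            if d <= _tol_da(min(pa.mz, pb.mz), tol_ppm, tol_abs_da):
                candidates.append((d, i, j))
    pairs: list[tuple[int, int]] = []
    if candidates:
        import numpy as np
        from scipy.optimize import linear_sum_assignment

        # Forbidden pairs get a cost that dwarfs any feasible total, so the
        # assignment maximises pair count first, total |dmz| second.
        big = 1.0 + sum(d for d, _, _ in candidates)
        cost = np.full((len(a), len(b)), big)
        for d, i, j in candidates:
            cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        pairs = sorted(
            (int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < big
        )
    return MatchResult(
        pairs=tuple(pairs),
        n_unmatched_a=len(a) - len(pairs),
        n_unmatched_b=len(b) - len(pairs),
    )


def dice_score(
    a: Spectrum,
    b: Spectrum,
    tol_ppm: float = 10.0,
    tol_abs_da: float = TOL_ABS_DA,
) -> SimilarityScore:
    """Count-based Dice set-overlap: 2 * matched / (|a| + |b|)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Dice score requires non-empty spectra")
    m = len(match_peaks(a, b, tol_ppm, tol_abs_da).pairs)
    return SimilarityScore(2.0 * m / (len(a) + len(b)), "dice")


def _weights(spectrum: Spectrum, mz_power: float, intensity_power: float) -> list[float]:
    return [p.mz ** mz_power * p.relative_intensity ** intensity_power
            for p in spectrum.peaks]


def dot_product_score(
    a: Spectrum,
    b: Spectrum,
    tol_ppm: float = 10.0,
    tol_abs_da: float = TOL_ABS_DA,
    mz_power: float = MZ_POWER,
    intensity_power: float = INTENSITY_POWER,
) -> SimilarityScore:
    """Weighted cosine over matched peak pairs, normalised by full norms."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("dot-product score requires non-empty spectra")
    match = match_peaks(a, b, tol_ppm, tol_abs_da)
    wa = _weights(a, mz_power, intensity_power)
    wb = _weights(b, mz_power, intensity_power)
    num = sum(wa[i] * wb[j] for i, j in match.pairs)
    den = math.sqrt(sum(w * w for w in wa)) * math.sqrt(sum(w * w for w in wb))
    value = min(num / den, 1.0) if den > 0 else 0.0
    return SimilarityScore(value, "dot_product")


SCORERS = {"dice": dice_score, "dotproduct": dot_product_score}


def get_scorer(method: str):
    try:
        return SCORERS[method]
    except KeyError:
        raise ValueError(
            f"unknown scorer {method!r}; supported scorers: {', '.join(SCORERS)}"
        ) from None


def multi_energy_score(
    query: SpectrumSet,
    candidate: SpectrumSet,
    method: str = "dotproduct",
    tol_ppm: float = 10.0,
    tol_abs_da: float = TOL_ABS_DA,
) -> SimilarityScore:
    """Mean per-energy similarity over the energies present in the query.

    An energy level missing from the candidate contributes 0 to the mean, so
    a candidate library entry lacking half the query's energies can score at
    most 0.5 even on perfect matches.
    """
    scorer = get_scorer(method)
    energies = query.energies
    if not energies:
        raise ValueError("query spectrum set is empty")
    total = 0.0
    for energy in energies:
        cand = candidate.spectra.get(energy)
        if cand is not None:
            total += scorer(query.spectra[energy], cand, tol_ppm, tol_abs_da).value
    return SimilarityScore(total / len(energies), method)
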