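"""The compound-identification pipeline and its rank-based evaluation harness.

Identification retrieves library candidates whose adduct ion m/z falls within
a ppm window of the query precursor, scores each candidate's per-energy
spectra against the query (Dice or weighted cosine, averaged over the query's
collision energies), and returns a deterministically ranked hit table.

Evaluation replays a test set of (query, true-identifier) pairs and reports
the rank<=k accuracies and the fraction of queries whose top hit carries the
correct molecular formula, the headline metrics of library-search benchmarks.
The rank of the true compound is pessimistic under score ties: it counts
every tied candidate, so a reported rank-1 means the true compound was the
unique best.
"""

from __future__ import annotations

import bisect
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem import Adduct, Formula, Molecule, adduct_mz, get_adduct
from .scoring import TOL_ABS_DA, multi_energy_score
from .spectra import Spectrum, SpectrumSet, read_msp, write_msp

__all__ = [
    "CandidateRecord",
    "SpectralLibrary",
    "RankedHit",
    "IdentificationResult",
    "EvaluationReport",
    "retrieve_candidates",
    "identify",
    "evaluate",
    "load_library",
    "save_library",
]


@dataclass(frozen=True)
class CandidateRecord:
    """One library compound: structure, formula, mass and per-energy spectra."""

    identifier: str
    molecule: Molecule
    spectra: SpectrumSet

    @property
    def neutral_mass(self) -> float:
        return self.molecule.neutral_monoisotopic_mass


class SpectralLibrary:
    """A searchable collection of candidate records, indexed by neutral mass."""

    def __init__(self, records: Iterable[CandidateRecord] = ()):
        self._records: dict[str, CandidateRecord] = {}
        for rec in records:
            self.add(rec)
        self._reindex()

    def add(self, record: CandidateRecord) -> None:
        if record.identifier in self._records:
            raise ValueError(f"duplicate identifier {record.identifier!r}")
        self._records[record.identifier] = record
        self._index = None

    def _reindex(self) -> None:
        ordered = sorted(self._records.values(), key=lambda r: (r.neutral_mass, r.identifier))
        self._index = ([r.neutral_mass for r in ordered], ordered)

    @property
    def records(self) -> list[CandidateRecord]:
        return list(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._records

    def __getitem__(self, identifier: str) -> CandidateRecord:
        return self._records[identifier]

    def remove(self, identifier: str) -> CandidateRecord:
        rec = self._records.pop(identifier)
        self._index = None
        return rec

    def mass_window(self, lo: float, hi: float) -> list[CandidateRecord]:
        """All records with neutral monoisotopic mass in [lo, hi] (bisect index)."""
        if self._index is None:
            self._reindex()
        masses, ordered = self._index
        i = bisect.bisect_left(masses, lo)
        j = bisect.bisect_right(masses, hi)
        return ordered[i:j]


def retrieve_candidates(
    library: SpectralLibrary,
    precursor_mz: float,
    adduct: Adduct | str,
    mass_tol_ppm: float = 10.0,
) -> list[CandidateRecord]:
    """Records whose adduct ion m/z lies within *mass_tol_ppm* of the precursor."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    tol_da = precursor_mz * mass_tol_ppm * 1e-6
    lo = precursor_mz - tol_da - adduct.mass_shift
    hi = precursor_mz + tol_da - adduct.mass_shift
    hits = library.mass_window(lo, hi)
    # The index bounds are exact for single-adduct search, but re-check in m/z
    # space so the contract holds for any future index layout.
    return [r for r in hits if abs(adduct_mz(r.neutral_mass, adduct) - precursor_mz) <= tol_da]


@dataclass(frozen=True)
class RankedHit:
    rank: int
    candidate: CandidateRecord
    score: float
    formula: Formula
    molecular_weight: float

    @property
    def identifier(self) -> str:
        return self.candidate.identifier


@dataclass(frozen=True)
class IdentificationResult:
    """Ranked hits plus a status distinguishing 'no candidates in window'."""

    hits: tuple[RankedHit, ...]
    status: str            # "ok" | "no-candidates"
    n_candidates: int      # candidates scored before truncation

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def _rank_scored(
    scored: list[tuple[float, CandidateRecord]],
    top_n: int | None,
) -> tuple[RankedHit, ...]:
    scored.sort(key=lambda t: (-t[0], t[1].identifier))
    if top_n is not None:
        scored = scored[:top_n]
    return tuple(
        RankedHit(
            rank=i + 1,
            candidate=rec,
            score=score,
            formula=rec.molecule.formula,
            molecular_weight=rec.neutral_mass,
        )
        for i, (score, rec) in enumerate(scored)
    )


def identify(
    query: SpectrumSet,
    library: SpectralLibrary,
    method: str = "dotproduct",
    tol_ppm: float = 10.0,
    top_n: int | None = 10,
    mass_tol_ppm: float = 10.0,
    adduct: Adduct | str | None = None,
    tol_abs_da: float = TOL_ABS_DA,
) -> IdentificationResult:
    """Retrieve, score and rank library candidates for a query spectrum set.

    The adduct defaults to the one recorded on the query spectra.  Ties are
    broken by candidate identifier, so output is fully deterministic.
    """
    if len(query) == 0:
        raise ValueError("query must contain at least one spectrum")
    if adduct is None:
        adduct = next(iter(query)).adduct
        if adduct is None:
            raise ValueError("no adduct on the query spectra; pass adduct=...")
    precursor = query.precursor_mz
    if precursor is None:
        raise ValueError("query spectra carry no precursor m/z")
    candidates = retrieve_candidates(library, precursor, adduct, mass_tol_ppm)
    if not candidates:
        return IdentificationResult(hits=(), status="no-candidates", n_candidates=0)
    scored = [
        (multi_energy_score(query, rec.spectra, method, tol_ppm, tol_abs_da).value, rec)
        for rec in candidates
    ]
    hits = _rank_scored(scored, top_n)
    return IdentificationResult(hits=hits, status="ok", n_candidates=len(candidates))


@dataclass(frozen=True)
class EvaluationReport:
    """Rank-based accuracy summary over a query test set."""

    n_queries: int
    frac_rank1: float
    frac_rank_le5: float
    frac_rank_le10: float
    frac_correct_formula_top1: float
    median_candidates: float

    def __post_init__(self) -> None:
        assert 0 <= self.frac_rank1 <= self.frac_rank_le5 <= self.frac_rank_le10 <= 1

    def as_dict(self) -> dict[str, float]:
        return {
            "n_queries": self.n_queries,
            "frac_rank1": self.frac_rank1,
            "frac_rank_le5": self.frac_rank_le5,
            "frac_rank_le10": self.frac_rank_le10,
            "frac_correct_formula_top1": self.frac_correct_formula_top1,
            "median_candidates": self.median_candidates,
        }

    def summary(self) -> str:
        return (
            f"n = {self.n_queries}\n"
            f"rank = 1        : {100 * self.frac_rank1:6.2f}%\n"
            f"rank <= 5       : {100 * self.frac_rank_le5:6.2f}%\n"
            f"rank <= 10      : {100 * self.frac_rank_le10:6.2f}%\n"
            f"correct formula : {100 * self.frac_correct_formula_top1:6.2f}%  (top hit)\n"
            f"median candidates per query: {self.median_candidates:g}"
        )


def true_compound_rank(
    result: IdentificationResult, true_identifier: str
) -> int | None:
    """Pessimistic rank of the true compound: counts all score-tied candidates."""
    true_score = None
    for hit in result.hits:
        if hit.identifier == true_identifier:
            true_score = hit.score
            break
    if true_score is None:
        return None
    return sum(1 for h in result.hits if h.score >= true_score - 1e-12)


def evaluate(
    testset: Sequence[tuple[SpectrumSet, str]],
    library: SpectralLibrary,
    method: str = "dotproduct",
    tol_ppm: float = 10.0,
    mass_tol_ppm: float = 10.0,
    tol_abs_da: float = TOL_ABS_DA,
) -> EvaluationReport:
    """Replay a (query, true identifier) test set and tally rank accuracies.

    Every true identifier must exist in the library; a query whose true
    compound is not retrieved (outside the mass window) counts as a miss at
    every rank cutoff.
    """
    if not testset:
        raise ValueError("empty test set")
    n_r1 = n_r5 = n_r10 = n_formula = 0
    n_candidates: list[int] = []
    for query, true_id in testset:
        if true_id not in library:
            raise ValueError(f"true identifier {true_id!r} not in library")
        result = identify(
            query, library, method=method, tol_ppm=tol_ppm, top_n=None,
            mass_tol_ppm=mass_tol_ppm, tol_abs_da=tol_abs_da,
        )
        n_candidates.append(result.n_candidates)
        rank = true_compound_rank(result, true_id)
        if rank is not None:
            n_r1 += rank == 1
            n_r5 += rank <= 5
            n_r10 += rank <= 10
        if result.hits and result.hits[0].formula == library[true_id].molecule.formula:
            n_formula += 1
    n = len(testset)
    return EvaluationReport(
        n_queries=n,
        frac_rank1=n_r1 / n,
        frac_rank_le5=n_r5 / n,
        frac_rank_le10=n_r10 / n,
        frac_correct_formula_top1=n_formula / n,
        median_candidates=float(statistics.median(n_candidates)),
    )


# ---------------------------------------------------------------------------
# Library persistence (MSP)

def save_library(library: SpectralLibrary, path: str | Path) -> None:
    """Write a library as MSP, one block per (compound, collision energy)."""
    entries = []
    for rec in sorted(library.records, key=lambda r: r.identifier):
        for energy in rec.spectra.energies:
            spec = rec.spectra.spectra[energy]
            meta = {
                "name": rec.identifier,
                "id": rec.identifier,
                "smiles": rec.molecule.structure,
                "formula": str(rec.molecule.formula),
                "mw": f"{rec.neutral_mass:.6f}",
            }
            entries.append((meta, spec))
    write_msp(entries, path)


def load_library(path: str | Path) -> SpectralLibrary:
    """Read an MSP file written by :func:`save_library` back into a library."""
    groups: dict[str, list[tuple[dict[str, str], Spectrum]]] = {}
    for meta, spec in read_msp(path):
        ident = meta.get("id") or meta.get("name") or "unknown"
        groups.setdefault(ident, []).append((meta, spec))
    records = []
    for ident, entries in groups.items():
        meta0 = entries[0][0]
        if "smiles" in meta0:
            molecule = Molecule.from_smiles(meta0["smiles"])
        elif "formula" in meta0:
            molecule = Molecule(structure="", formula=Formula.from_string(meta0["formula"]))
        else:
            raise ValueError(f"record {ident!r} has neither SMILES nor formula")
        spectra = SpectrumSet.from_spectra(s for _, s in entries)
        records.append(CandidateRecord(identifier=ident, molecule=molecule, spectra=spectra))
    return SpectralLibrary(records)


def load_queries(path: str | Path) -> list[tuple[SpectrumSet, str]]:
    """Read query MSP into (SpectrumSet, source identifier) pairs."""
    groups: dict[str, list[Spectrum]] = {}
    for meta, spec in read_msp(path):
        ident = meta.get("id") or meta.get("name") or "unknown"
        groups.setdefault(ident, []).append(spec)
    return [(SpectrumSet.from_spectra(specs), ident) for ident, specs in groups.items()]
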