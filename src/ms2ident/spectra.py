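"""Reading, validating, normalizing and writing product-ion MS/MS spectra.

Supported dialects: plain two-column peak lists (``#`` comments), NIST-style
MSP library blocks, and MGF (via :mod:`pyteomics.mgf`).  Intensities are kept
internally as relative percent of the base peak (base = 100); raw counts are
accepted on input and rescaled.  Peaks closer than the merge tolerance are
merged (intensity-weighted m/z, intensities summed) so each spectrum is a
strictly m/z-sorted centroid list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumSet",
    "SpectrumError",
    "FormatError",
    "MERGE_TOL_DA",
    "NOISE_THRESHOLD",
    "ENERGIES",
    "make_spectrum",
    "read_peaklist",
    "write_peaklist",
    "read_msp",
    "write_msp",
    "read_mgf",
    "write_mgf",
    "normalize",
    "denoise",
]

#: Default within-spectrum peak merge tolerance in Da.
MERGE_TOL_DA = 0.001
#: Default noise-removal threshold, percent of base peak.
NOISE_THRESHOLD = 0.1
#: Collision energies (eV) a spectrum set may hold.
ENERGIES = (10, 20, 40)


class SpectrumError(ValueError):
    """Malformed spectrum content (parse error, empty spectrum, ...)."""


class FormatError(SpectrumError):
    """Structural error in a library file (MSP/MGF block)."""


@dataclass(frozen=True, order=True)
class Peak:
    mz: float
    relative_intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise SpectrumError(f"non-positive m/z {self.mz}")
        if self.relative_intensity <= 0:
            raise SpectrumError(f"non-positive intensity at m/z {self.mz}")


@dataclass(frozen=True)
class Spectrum:
    """A centroided product-ion spectrum with precursor metadata.

    ``peaks`` are strictly sorted by m/z, merged within ``MERGE_TOL_DA`` and
    normalized so the base peak has relative intensity 100.
    """

    peaks: tuple[Peak, ...]
    precursor_mz: float | None = None
    ion_mode: str | None = None          # "positive" | "negative"
    adduct: str | None = None
    collision_energy: int | None = None  # 10 | 20 | 40 | None (unknown)
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.ion_mode not in (None, "positive", "negative"):
            raise SpectrumError(f"ion mode must be positive/negative, got {self.ion_mode!r}")
        if self.collision_energy is not None and self.collision_energy not in ENERGIES:
            raise SpectrumError(f"collision energy must be one of {ENERGIES}")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.relative_intensity for p in self.peaks]

    @property
    def base_peak(self) -> Peak:
        return max(self.peaks, key=lambda p: p.relative_intensity)


def _merge_sort(pairs: Iterable[tuple[float, float]], merge_tol: float) -> list[tuple[float, float]]:
    """Sort (mz, intensity) pairs and merge neighbours within *merge_tol* Da."""
    pts = sorted(pairs)
    merged: list[tuple[float, float]] = []
    for mz, inten in pts:
        if merged and mz - merged[-1][0] <= merge_tol:
            pmz, pint = merged[-1]
            tot = pint + inten
            merged[-1] = ((pmz * pint + mz * inten) / tot, tot)
        else:
            merged.append((mz, inten))
    return merged


def make_spectrum(
    pairs: Iterable[tuple[float, float]],
    merge_tol: float = MERGE_TOL_DA,
    **meta,
) -> Spectrum:
    """Build a validated, sorted, merged, normalized Spectrum from raw pairs."""
    merged = _merge_sort(pairs, merge_tol)
    if not merged:
        raise SpectrumError("empty spectrum")
    top = max(i for _, i in merged)
    peaks = tuple(Peak(mz, 100.0 * (i / top)) for mz, i in merged)
    return Spectrum(peaks=peaks, **meta)


def normalize(spectrum: Spectrum) -> Spectrum:
    """Rescale intensities so the base peak is exactly 100 (idempotent)."""
    if not spectrum.peaks:
        raise SpectrumError("cannot normalize an empty spectrum")
    top = max(p.relative_intensity for p in spectrum.peaks)
    peaks = tuple(Peak(p.mz, 100.0 * (p.relative_intensity / top)) for p in spectrum.peaks)
    return replace(spectrum, peaks=peaks)


def denoise(spectrum: Spectrum, min_rel_intensity: float = NOISE_THRESHOLD) -> Spectrum:
    """Drop peaks below *min_rel_intensity* percent and renormalize.

    The base peak always survives (threshold <= 100).
    """
    kept = tuple(p for p in spectrum.peaks if p.relative_intensity >= min_rel_intensity)
    if not kept:  # threshold > 100: keep at least the base peak
        kept = (spectrum.base_peak,)
    return normalize(replace(spectrum, peaks=kept))


_DIRECTIVE = re.compile(r"^#\s*(\w+)\s*[:=]\s*(.+)$")


def read_peaklist(text: str, merge_tol: float = MERGE_TOL_DA, **meta) -> Spectrum:
    """Parse a plain two-column peak list.

    Lines starting with ``#`` are comments; ``# key: value`` comments set
    precursor/energy metadata (keys: precursor_mz, ion_mode, adduct,
    collision_energy, source_id).  Keyword arguments override directives.
    """
    pairs: list[tuple[float, float]] = []
    parsed_meta: dict[str, object] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _DIRECTIVE.match(line)
            if m:
                key, val = m.group(1).lower(), m.group(2).strip()
                if key in ("precursor_mz", "precursormz", "pepmass"):
                    parsed_meta["precursor_mz"] = float(val)
                elif key == "ion_mode":
                    parsed_meta["ion_mode"] = val
                elif key == "adduct":
                    parsed_meta["adduct"] = val
                elif key in ("collision_energy", "energy"):
                    parsed_meta["collision_energy"] = int(float(val))
                elif key == "source_id":
                    parsed_meta["source_id"] = val
            continue
        fields = line.split()
        if len(fields) != 2:
            raise SpectrumError(f"line {lineno}: expected 'm/z intensity', got {raw!r}")
        try:
            mz, inten = float(fields[0]), float(fields[1])
        except ValueError:
            raise SpectrumError(f"line {lineno}: non-numeric value in {raw!r}") from None
        pairs.append((mz, inten))
    if not pairs:
        raise SpectrumError("empty spectrum: no peak lines found")
    parsed_meta.update(meta)
    return make_spectrum(pairs, merge_tol=merge_tol, **parsed_meta)


def write_peaklist(spectrum: Spectrum) -> str:
    lines = []
    if spectrum.precursor_mz is not None:
        lines.append(f"# precursor_mz: {spectrum.precursor_mz:.6f}")
    for key in ("ion_mode", "adduct", "collision_energy", "source_id"):
        val = getattr(spectrum, key)
        if val is not None:
            lines.append(f"# {key}: {val}")
    lines += [f"{p.mz:.6f} {p.relative_intensity:.4f}" for p in spectrum.peaks]
    return "\n".join(lines) + "\n"


@dataclass
class SpectrumSet:
    """The spectra of one compound (or one query), keyed by collision energy."""

    spectra: dict[int | None, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        modes = {s.ion_mode for s in self.spectra.values()}
        adducts = {s.adduct for s in self.spectra.values()}
        if len(modes) > 1 or len(adducts) > 1:
            raise SpectrumError("all spectra in a set must share ion mode and adduct")
        for energy, s in self.spectra.items():
            if s.collision_energy != energy:
                raise SpectrumError("spectrum keyed under wrong collision energy")

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum]) -> "SpectrumSet":
        d: dict[int | None, Spectrum] = {}
        for s in spectra:
            if s.collision_energy in d:
                raise SpectrumError(f"duplicate spectrum at energy {s.collision_energy}")
            d[s.collision_energy] = s
        return cls(d)

    @property
    def energies(self) -> list[int | None]:
        return sorted(self.spectra, key=lambda e: (e is None, e))

    @property
    def precursor_mz(self) -> float | None:
        for s in self.spectra.values():
            if s.precursor_mz is not None:
                return s.precursor_mz
        return None

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra.values())

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# MSP (NIST dialect)

_MSP_KNOWN = {
    "name": "name", "id": "id", "smiles": "smiles", "formula": "formula",
    "mw": "mw", "exactmass": "mw", "precursormz": "precursor_mz",
    "precursor_mz": "precursor_mz", "ion_mode": "ion_mode", "ionmode": "ion_mode",
    "adduct": "adduct", "precursortype": "adduct",
    "collision_energy": "collision_energy", "collisionenergy": "collision_energy",
}


def _msp_blocks(text: str) -> Iterator[list[str]]:
    block: list[str] = []
    for line in text.splitlines():
        if not line.strip():
            if block:
                yield block
                block = []
        else:
            block.append(line.rstrip("\n"))
    if block:
        yield block


def _parse_msp_block(block: list[str]) -> tuple[dict[str, str], Spectrum]:
    meta: dict[str, str] = {}
    extra: dict[str, str] = {}
    n_declared: int | None = None
    i = 0
    for i, line in enumerate(block):
        m = re.match(r"^([\w ./-]+):\s*(.*)$", line)
        if m is None:
            break
        key = m.group(1).strip().lower().replace(" ", "_")
        if key == "num_peaks":
            n_declared = int(m.group(2))
            i += 1
            break
        if key in _MSP_KNOWN:
            meta[_MSP_KNOWN[key]] = m.group(2).strip()
        else:
            extra[m.group(1).strip()] = m.group(2).strip()
    if n_declared is None:
        raise FormatError("MSP block missing 'Num Peaks'")
    pairs: list[tuple[float, float]] = []
    for line in block[i:]:
        fields = line.replace(";", " ").split()
        if len(fields) < 2:
            raise FormatError(f"bad MSP peak line {line!r}")
        pairs.append((float(fields[0]), float(fields[1])))
    if len(pairs) != n_declared:
        raise FormatError(
            f"'Num Peaks: {n_declared}' disagrees with {len(pairs)} peak lines "
            f"in record {meta.get('name', '?')!r}"
        )
    smeta: dict[str, object] = {}
    if "precursor_mz" in meta:
        smeta["precursor_mz"] = float(meta["precursor_mz"])
    if "ion_mode" in meta:
        mode = meta["ion_mode"].lower()
        smeta["ion_mode"] = {"p": "positive", "n": "negative"}.get(mode[:1], mode)
    if "adduct" in meta:
        smeta["adduct"] = meta["adduct"]
    if "collision_energy" in meta:
        smeta["collision_energy"] = int(float(meta["collision_energy"].rstrip("eV ")))
    smeta["source_id"] = meta.get("id") or meta.get("name")
    meta.update(extra)
    return meta, make_spectrum(pairs, **smeta)


def read_msp(path: str | Path) -> list[tuple[dict[str, str], Spectrum]]:
    """Read an MSP library file into (metadata, Spectrum) pairs.

    Metadata keys are lower-cased canonical names for the known NIST-style
    fields; unknown keys are preserved verbatim.
    """
    text = Path(path).read_text()
    return [_parse_msp_block(b) for b in _msp_blocks(text)]


def write_msp(entries: Iterable[tuple[dict[str, str], Spectrum]], path: str | Path) -> None:
    """Write (metadata, Spectrum) pairs as NIST-style MSP blocks."""
    known_order = ["name", "id", "smiles", "formula", "mw"]
    with open(path, "w") as fh:
        for meta, spec in entries:
            name = meta.get("name") or spec.source_id or "unknown"
            fh.write(f"Name: {name}\n")
            for key in known_order[1:]:
                if key in meta:
                    fh.write(f"{key.upper() if key in ('id', 'mw') else key.capitalize()}: {meta[key]}\n")
            if spec.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {spec.precursor_mz:.6f}\n")
            if spec.ion_mode:
                fh.write(f"Ion_mode: {spec.ion_mode[0].upper()}\n")
            if spec.adduct:
                fh.write(f"Precursortype: {spec.adduct}\n")
            if spec.collision_energy is not None:
                fh.write(f"Collision_energy: {spec.collision_energy}\n")
            for key, val in meta.items():
                if key not in known_order and key not in _MSP_KNOWN:
                    fh.write(f"{key}: {val}\n")
            fh.write(f"Num Peaks: {len(spec)}\n")
            for p in spec.peaks:
                fh.write(f"{p.mz:.6f} {p.relative_intensity:.4f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# MGF (via pyteomics)

def read_mgf(path: str | Path) -> list[Spectrum]:
    from pyteomics import mgf

    out: list[Spectrum] = []
    with mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            meta: dict[str, object] = {}
            if "pepmass" in params:
                meta["precursor_mz"] = float(params["pepmass"][0])
            if "charge" in params:
                meta["ion_mode"] = "positive" if int(params["charge"][0]) > 0 else "negative"
            if "ion_mode" in params:
                meta["ion_mode"] = str(params["ion_mode"]).lower()
            if "adduct" in params:
                meta["adduct"] = str(params["adduct"])
            if "collision_energy" in params:
                meta["collision_energy"] = int(float(params["collision_energy"]))
            if "title" in params:
                meta["source_id"] = str(params["title"])
            pairs = list(zip(entry["m/z array"], entry["intensity array"]))
            out.append(make_spectrum(pairs, **meta))
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    from pyteomics import mgf

    entries = []
    for s in spectra:
        params: dict[str, object] = {}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.ion_mode is not None:
            params["charge"] = [1 if s.ion_mode == "positive" else -1]
            params["ion_mode"] = s.ion_mode
        if s.adduct is not None:
            params["adduct"] = s.adduct
        if s.collision_energy is not None:
            params["collision_energy"] = s.collision_energy
        if s.source_id is not None:
            params["title"] = s.source_id
        entries.append({
            "m/z array": s.mzs,
            "intensity array": s.intensities,
            "params": params,
        })
    mgf.write(entries, str(path), file_mode="w")
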