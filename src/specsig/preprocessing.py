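"""Spectrum conditioning chain and cross-library m/z harmonization.

The fixed pipeline is: deisotope -> reduce_concurrent ->
remove_precursor_region -> normalize -> compute_losses -> harmonize.
Harmonization pools m/z values of one kind (fragment or neutral loss)
across the whole library, clusters them within the matching tolerance and
produces a spectra x signals occurrence matrix of normalized intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral_io import Peak, SpectralLibrary, Spectrum

__all__ = [
    "Tolerance",
    "Signal",
    "BinnedSignalMatrix",
    "deisotope",
    "reduce_concurrent",
    "remove_precursor_region",
    "normalize",
    "compute_losses",
    "harmonize",
    "preprocess_spectrum",
    "preprocess_library",
    "build_signal_matrix",
    "round_half_away",
]

#: charge-1 carbon isotopologue spacings (Da)
C13_SPACING = 1.00336
C13_SPACING_2 = 2.00671


@dataclass(frozen=True)
class Tolerance:
    """m/z matching tolerance: max of an absolute (Da) and a relative (ppm) term.

    The two components coincide at m/z 400 Th for the defaults (10 mDa, 25 ppm);
    the permissive `max` combination is used as the effective window.
    """

    absolute: float = 0.010
    ppm: float = 25.0

    def __post_init__(self) -> None:
        if self.absolute <= 0 or self.ppm <= 0:
            raise ValueError("tolerance components must be strictly positive")

    def window(self, mz: float) -> float:
        """Effective half-window (Da) at the given m/z."""
        return max(self.absolute, self.ppm * mz * 1e-6)

    def matches(self, a: float, b: float) -> bool:
        return abs(a - b) <= self.window(max(a, b))


def round_half_away(x: float, decimals: int = 4) -> float:
    """Round half away from zero (not banker's rounding)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True, order=True)
class Signal:
    """A diagnostic feature: a fragment or neutral-loss m/z at 4 decimals."""

    kind: str  # "fragment" | "loss"
    mz: float

    def __post_init__(self) -> None:
        if self.kind not in ("fragment", "loss"):
            raise ValueError(f"signal kind must be 'fragment' or 'loss', got {self.kind!r}")
        if not self.mz > 0:
            raise ValueError(f"signal m/z must be positive, got {self.mz}")

    @property
    def label(self) -> str:
        prefix = "F" if self.kind == "fragment" else "L"
        return f"{prefix}:{self.mz:.4f}"

    @classmethod
    def from_label(cls, label: str) -> "Signal":
        prefix, _, mz = label.partition(":")
        kind = {"F": "fragment", "L": "loss"}[prefix]
        return cls(kind=kind, mz=float(mz))


class BinnedSignalMatrix:
    """Spectra x signals occurrence matrix of normalized intensities in [0, 1]."""

    def __init__(self, row_ids: list[str], signals: list[Signal], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(row_ids), len(signals)):
            raise ValueError("matrix shape does not match row/column labels")
        self.row_ids = list(row_ids)
        self.signals = list(signals)
        self.values = values
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._col_index = {s: j for j, s in enumerate(self.signals)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell(self, spectrum_id: str, signal: Signal) -> float:
        return float(self.values[self._row_index[spectrum_id], self._col_index[signal]])

    def column(self, signal: Signal) -> np.ndarray:
        return self.values[:, self._col_index[signal]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_ids, columns=[s.label for s in self.signals]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @staticmethod
    def concat(a: "BinnedSignalMatrix", b: "BinnedSignalMatrix") -> "BinnedSignalMatrix":
        """Column-wise concatenation of matrices sharing identical rows."""
        if a.row_ids != b.row_ids:
            raise ValueError("matrices have different row ids")
        return BinnedSignalMatrix(
            a.row_ids, a.signals + b.signals, np.hstack([a.values, b.values])
        )


def deisotope(spectrum: Spectrum, tol: Tolerance) -> Spectrum:
    """Remove charge-1 carbon isotopologue peaks.

    A peak j is dropped when a retained peak i below it satisfies
    |mz_j - mz_i - spacing| <= window for the 1x or 2x 13C spacing and
    intensity_i > intensity_j (the putative monoisotopic peak must be the
    more intense one).  Single low-to-high pass.
    """
    kept: list[Peak] = []
    for peak in spectrum.peaks:
        is_isotope = False
        for prev in reversed(kept):
            delta = peak.mz - prev.mz
            if delta > C13_SPACING_2 + tol.window(peak.mz):
                break
            for spacing in (C13_SPACING, C13_SPACING_2):
                if abs(delta - spacing) <= tol.window(peak.mz) and prev.intensity > peak.intensity:
                    is_isotope = True
                    break
            if is_isotope:
                break
        if not is_isotope:
            kept.append(peak)
    return spectrum.copy_with(peaks=kept)


def reduce_concurrent(spectrum: Spectrum, tol: Tolerance) -> Spectrum:
    """Merge peaks chained within the tolerance window, keeping the most intense.

    Ties at equal intensity keep the lower m/z.  The result has no two peaks
    within the effective window of each other.
    """
    peaks = spectrum.peaks
    if not peaks:
        return spectrum.copy_with(peaks=[])
    kept: list[Peak] = []
    cluster: list[Peak] = [peaks[0]]
    for peak in peaks[1:]:
        if peak.mz - cluster[-1].mz <= tol.window(peak.mz):
            cluster.append(peak)
        else:
            kept.append(max(cluster, key=lambda p: (p.intensity, -p.mz)))
            cluster = [peak]
    kept.append(max(cluster, key=lambda p: (p.intensity, -p.mz)))
    return spectrum.copy_with(peaks=kept)


def remove_precursor_region(spectrum: Spectrum) -> Spectrum:
    """Drop all fragments at or above the precursor m/z (inclusive removal)."""
    kept = [p for p in spectrum.peaks if p.mz < spectrum.precursor_mz]
    return spectrum.copy_with(peaks=kept)


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the base peak equals 1.0."""
    if not spectrum.peaks:
        return spectrum.copy_with(peaks=[])
    top = max(p.intensity for p in spectrum.peaks)
    if top <= 0:
        raise ValueError(f"spectrum {spectrum.spectrum_id}: all intensities are zero")
    kept = [Peak(p.mz, p.intensity / top) for p in spectrum.peaks]
    return spectrum.copy_with(peaks=kept)


def compute_losses(spectrum: Spectrum) -> list[tuple[float, float]]:
    """Neutral losses (precursor - fragment) with intensities inherited.

    Only fragments below the precursor contribute (the precursor region must
    already have been removed).  Returns (loss m/z, intensity) pairs.
    """
    out = []
    for p in spectrum.peaks:
        loss = spectrum.precursor_mz - p.mz
        if loss > 0:
            out.append((loss, p.intensity))
    return out


def preprocess_spectrum(
    spectrum: Spectrum, tol: Tolerance, deisotope_enabled: bool = True
) -> Spectrum:
    """Apply the fixed conditioning chain up to normalization."""
    s = deisotope(spectrum, tol) if deisotope_enabled else spectrum
    s = reduce_concurrent(s, tol)
    s = remove_precursor_region(s)
    if s.peaks:
        s = normalize(s)
    return s


def preprocess_library(
    library: SpectralLibrary, tol: Tolerance, deisotope_enabled: bool = True
) -> tuple[dict[str, Spectrum], list[str]]:
    """Condition every spectrum; spectra emptied by filtering are flagged.

    Returns (id -> processed spectrum for surviving spectra, flagged ids).
    Flagged spectra are excluded from the occurrence matrices and from group
    sizes downstream (logged by the caller).
    """
    processed: dict[str, Spectrum] = {}
    flagged: list[str] = []
    for spec in library:
        s = preprocess_spectrum(spec, tol, deisotope_enabled)
        if s.peaks:
            processed[spec.spectrum_id] = s
        else:
            flagged.append(spec.spectrum_id)
    return processed, flagged


def _cluster_sorted(values: np.ndarray, tol: Tolerance) -> list[slice]:
    """Single-linkage greedy scan over a sorted pool: break where the gap
    between consecutive values exceeds the effective window."""
    breaks = [0]
    for i in range(1, len(values)):
        if values[i] - values[i - 1] > tol.window(values[i]):
            breaks.append(i)
    breaks.append(len(values))
    return [slice(breaks[i], breaks[i + 1]) for i in range(len(breaks) - 1)]


def harmonize(
    library: SpectralLibrary,
    tol: Tolerance,
    kind: str,
    *,
    processed: dict[str, Spectrum] | None = None,
    deisotope_enabled: bool = True,
) -> BinnedSignalMatrix:
    """Pool m/z values of one kind across the library and bin them.

    Each cluster of the greedy single-linkage scan becomes one signal whose
    representative m/z is the intensity-weighted mean of its members, rounded
    half-away-from-zero to 4 decimals.  Matrix cells hold the contributing
    spectrum's normalized intensity (the most intense member wins if a
    spectrum contributes twice to a cluster).
    """
    if kind not in ("fragment", "loss"):
        raise ValueError(f"kind must be 'fragment' or 'loss', got {kind!r}")
    if processed is None:
        processed, _ = preprocess_library(library, tol, deisotope_enabled)
    row_ids = [sid for sid in library.ids if sid in processed]

    entries: list[tuple[float, float, str]] = []  # (mz, intensity, spectrum_id)
    for sid in row_ids:
        spec = processed[sid]
        if kind == "fragment":
            pool = [(p.mz, p.intensity) for p in spec.peaks]
        else:
            pool = compute_losses(spec)
        entries.extend((mz, inten, sid) for mz, inten in pool)

    if not entries:
        return BinnedSignalMatrix(row_ids, [], np.zeros((len(row_ids), 0)))

    entries.sort(key=lambda e: e[0])
    mzs = np.array([e[0] for e in entries])
    row_index = {sid: i for i, sid in enumerate(row_ids)}

    signals: list[Signal] = []
    columns: list[np.ndarray] = []
    for sl in _cluster_sorted(mzs, tol):
        members = entries[sl]
        weights = sum(inten for _, inten, _ in members)
        if weights > 0:
            rep = sum(mz * inten for mz, inten, _ in members) / weights
        else:  # degenerate all-zero intensities: plain mean
            rep = sum(mz for mz, _, _ in members) / len(members)
        col = np.zeros(len(row_ids))
        for _, inten, sid in members:
            i = row_index[sid]
            col[i] = max(col[i], inten)
        signals.append(Signal(kind=kind, mz=round_half_away(rep, 4)))
        columns.append(col)

    return BinnedSignalMatrix(row_ids, signals, np.column_stack(columns))


def build_signal_matrix(
    library: SpectralLibrary,
    tol: Tolerance,
    deisotope_enabled: bool = True,
) -> tuple[BinnedSignalMatrix, list[str]]:
    """Run the full chain once and return the pooled fragment+loss matrix
    together with the ids of spectra emptied by filtering."""
    processed, flagged = preprocess_library(library, tol, deisotope_enabled)
    frag = harmonize(library, tol, "fragment", processed=processed)
    loss = harmonize(library, tol, "loss", processed=processed)
    return BinnedSignalMatrix.concat(frag, loss), flagged
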