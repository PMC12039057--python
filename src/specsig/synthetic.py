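"""Ground-truthed synthetic spectral libraries and extract-level datasets.

Each skeleton group shares planted diagnostic fragments and neutral losses;
noise peaks, m/z jitter, dropout and decoy overlap are parameterized so that
every pipeline stage can be exercised offline with a known answer.  No
attempt is made to imitate real fragmentation chemistry — only the
statistical structure the extraction algorithm consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import Signal, Tolerance, round_half_away
from .spectral_io import Peak, SpectralLibrary, Spectrum

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ExtractDataset",
    "simulate_library",
    "simulate_extract",
]

# planted values are kept far apart (and away from isotope spacings) so that
# binning and deisotoping never merge them in the clean regime
_MIN_PLANTED_SEPARATION = 2.5  # Da
_NOISE_EXCLUSION = 2.2  # Da around planted fragments (covers 2x 13C spacing)


@dataclass(frozen=True)
class SimulationConfig:
    n_groups: int = 4
    members_per_group: int = 8
    planted_fragments_per_group: int = 2
    planted_losses_per_group: int = 1
    noise_peaks_per_spectrum: int = 30
    mz_range: tuple[float, float] = (100.0, 800.0)
    loss_range: tuple[float, float] = (30.0, 95.0)
    jitter_sd: float = 0.003
    dropout_rate: float = 0.0
    decoy_overlap_rate: float = 0.0
    seed: int = 0
    tolerance: Tolerance = field(default_factory=Tolerance)

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.members_per_group < 1:
            raise ValueError("need at least one group with one member")
        if not 0 <= self.dropout_rate <= 1 or not 0 <= self.decoy_overlap_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        window = self.tolerance.window(self.mz_range[1])
        if self.jitter_sd > window / 3:
            raise ValueError(
                f"jitter_sd {self.jitter_sd} exceeds tolerance/3 ({window / 3:.4g})"
            )


@dataclass
class GroundTruth:
    """Planted signals per skeleton and realized per-spectrum presence."""

    planted: dict[str, tuple[Signal, ...]]
    realized: dict[str, set[Signal]]
    config: SimulationConfig


def _draw_separated(
    rng: np.random.Generator,
    count: int,
    low: float,
    high: float,
    taken: list[float],
    min_sep: float,
) -> list[float]:
    out: list[float] = []
    for _ in range(count):
        for _attempt in range(10_000):
            x = float(rng.uniform(low, high))
            if all(abs(x - t) > min_sep for t in taken + out):
                out.append(x)
                break
        else:
            raise ValueError(
                "cannot place planted signals with the required separation; "
                "widen the m/z range or reduce their number"
            )
    return out


def _noise_peak(
    rng: np.random.Generator,
    low: float,
    high: float,
    precursor: float,
    avoid_fragments: list[float],
    avoid_losses: list[float],
) -> float:
    for _attempt in range(10_000):
        x = float(rng.uniform(low, high))
        if any(abs(x - f) < _NOISE_EXCLUSION for f in avoid_fragments):
            continue
        if any(abs((precursor - x) - l) < _NOISE_EXCLUSION for l in avoid_losses):
            continue
        return x
    raise ValueError("noise sampling failed; exclusion zones cover the m/z range")


def simulate_library(config: SimulationConfig) -> tuple[SpectralLibrary, GroundTruth]:
    """Generate a labelled library with planted group-specific signals.

    Reproducible for a fixed seed.  Planted fragments appear at their group
    value (jittered) in every member unless dropped out; planted losses are
    realized as fragments at precursor - loss.  Noise peaks avoid the
    neighborhoods of all planted values.  Intensities are exponential for
    noise and uniform-high for planted peaks, so the base peak is planted
    only part of the time and normalization stays nontrivial.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mz_range

    frag_values: list[float] = []
    loss_values: list[float] = []
    planted: dict[str, tuple[Signal, ...]] = {}
    group_frags: dict[str, list[float]] = {}
    group_losses: dict[str, list[float]] = {}
    for g in range(config.n_groups):
        skeleton = f"skeleton-{g}"
        frags = _draw_separated(
            rng, config.planted_fragments_per_group, lo, hi,
            frag_values, _MIN_PLANTED_SEPARATION,
        )
        losses = _draw_separated(
            rng, config.planted_losses_per_group, *config.loss_range,
            loss_values, _MIN_PLANTED_SEPARATION,
        )
        frag_values.extend(frags)
        loss_values.extend(losses)
        group_frags[skeleton] = frags
        group_losses[skeleton] = losses
        planted[skeleton] = tuple(
            [Signal("fragment", round_half_away(f)) for f in sorted(frags)]
            + [Signal("loss", round_half_away(l)) for l in sorted(losses)]
        )

    spectra: list[Spectrum] = []
    realized: dict[str, set[Signal]] = {}
    for g in range(config.n_groups):
        skeleton = f"skeleton-{g}"
        for m in range(config.members_per_group):
            sid = f"G{g}S{m}"
            precursor = float(rng.uniform(hi + 100.0, hi + 200.0))
            peaks: list[Peak] = []
            present: set[Signal] = set()

            own = [(f, Signal("fragment", round_half_away(f))) for f in group_frags[skeleton]]
            own += [(l, Signal("loss", round_half_away(l))) for l in group_losses[skeleton]]
            # decoy overlap: out-group planted signals leaking into this spectrum
            leak = []
            for other in planted:
                if other == skeleton:
                    continue
                for f in group_frags[other]:
                    if rng.random() < config.decoy_overlap_rate:
                        leak.append((f, Signal("fragment", round_half_away(f))))
                for l in group_losses[other]:
                    if rng.random() < config.decoy_overlap_rate:
                        leak.append((l, Signal("loss", round_half_away(l))))

            for value, signal in own:
                if rng.random() < config.dropout_rate:
                    continue
                jitter = float(rng.normal(0.0, config.jitter_sd))
                mz = value + jitter if signal.kind == "fragment" else precursor - value - jitter
                peaks.append(Peak(mz, float(rng.uniform(0.5, 1.0))))
                present.add(signal)
            for value, signal in leak:
                jitter = float(rng.normal(0.0, config.jitter_sd))
                mz = value + jitter if signal.kind == "fragment" else precursor - value - jitter
                peaks.append(Peak(mz, float(rng.uniform(0.3, 0.9))))
                present.add(signal)

            avoid_frags = frag_values
            avoid_losses = loss_values
            for _ in range(config.noise_peaks_per_spectrum):
                mz = _noise_peak(rng, lo, hi, precursor, avoid_frags, avoid_losses)
                inten = float(np.clip(rng.exponential(0.3), 0.01, 1.5))
                peaks.append(Peak(mz, inten))

            scale = 1000.0  # raw (un-normalized) units
            peaks = [Peak(p.mz, p.intensity * scale) for p in peaks]
            spectra.append(
                Spectrum(
                    spectrum_id=sid,
                    precursor_mz=precursor,
                    peaks=peaks,
                    compound_name=f"compound-{sid}",
                    skeleton=skeleton,
                )
            )
            realized[sid] = present

    library = SpectralLibrary(spectra)
    return library, GroundTruth(planted=planted, realized=realized, config=config)


@dataclass
class ExtractDataset:
    """Feature-level dataset with planted signature-bearing features."""

    library: SpectralLibrary
    source_table: pd.DataFrame  # rows: feature ids; columns: (plant, genus)
    spiked: dict[str, list[str]]  # skeleton -> spiked feature ids


def simulate_extract(
    truth: GroundTruth,
    n_background_features: int = 100,
    n_spiked_per_group: int = 5,
    seed: int = 0,
    genera: tuple[str, ...] = ("GenusA", "GenusB"),
) -> ExtractDataset:
    """Feature-level MGF stand-in for a plant-extract dataset.

    Spiked features carry the full signature of their group; background
    features avoid all signature neighborhoods, so a conjunctive query for
    any planted signal set retrieves exactly the spiked features.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    lo, hi = config.mz_range
    all_frags = [s.mz for sig in truth.planted.values() for s in sig if s.kind == "fragment"]
    all_losses = [s.mz for sig in truth.planted.values() for s in sig if s.kind == "loss"]

    spectra: list[Spectrum] = []
    rows: list[tuple[str, str, str, float]] = []  # feature, plant, genus, intensity
    spiked: dict[str, list[str]] = {}
    counter = 0

    for gi, skeleton in enumerate(sorted(truth.planted)):
        spiked[skeleton] = []
        for k in range(n_spiked_per_group):
            counter += 1
            fid = f"X{counter}"
            precursor = float(rng.uniform(hi + 100.0, hi + 200.0))
            peaks = []
            for signal in truth.planted[skeleton]:
                jitter = float(rng.normal(0.0, config.jitter_sd))
                mz = (
                    signal.mz + jitter
                    if signal.kind == "fragment"
                    else precursor - signal.mz - jitter
                )
                peaks.append(Peak(mz, float(rng.uniform(500.0, 1000.0))))
            for _ in range(10):
                mz = _noise_peak(rng, lo, hi, precursor, all_frags, all_losses)
                peaks.append(Peak(mz, float(rng.uniform(10.0, 300.0))))
            genus = genera[(gi + k) % len(genera)]
            plant = f"{genus}-plant-{(gi + k) % len(genera)}"
            spectra.append(Spectrum(spectrum_id=fid, precursor_mz=precursor, peaks=peaks))
            rows.append((fid, plant, genus, float(sum(p.intensity for p in peaks))))
            spiked[skeleton].append(fid)

    for _ in range(n_background_features):
        counter += 1
        fid = f"X{counter}"
        precursor = float(rng.uniform(hi + 100.0, hi + 200.0))
        peaks = [
            Peak(
                _noise_peak(rng, lo, hi, precursor, all_frags, all_losses),
                float(rng.uniform(10.0, 500.0)),
            )
            for _ in range(15)
        ]
        genus = genera[counter % len(genera)]
        plant = f"{genus}-plant-{counter % len(genera)}"
        spectra.append(Spectrum(spectrum_id=fid, precursor_mz=precursor, peaks=peaks))
        rows.append((fid, plant, genus, float(sum(p.intensity for p in peaks))))

    feature_ids = [r[0] for r in rows]
    plants = sorted({(r[1], r[2]) for r in rows})
    table = pd.DataFrame(
        0.0,
        index=feature_ids,
        columns=pd.MultiIndex.from_tuples(plants, names=["plant", "genus"]),
    )
    for fid, plant, genus, intensity in rows:
        table.loc[fid, (plant, genus)] = intensity

    return ExtractDataset(
        library=SpectralLibrary(spectra), source_table=table, spiked=spiked
    )
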