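"""MGF spectral library I/O and skeleton metadata handling.

Reads and writes Mascot Generic Format (MGF) files, attaches skeleton
(scaffold class) labels to spectra, and exposes the library as a uniform
in-memory collection grouped by skeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Peak",
    "Spectrum",
    "SpectralLibrary",
    "MgfParseError",
    "AmbiguousKeyError",
    "read_mgf",
    "write_mgf",
    "attach_skeletons",
    "read_skeleton_table",
]

#: m/z values are serialized at 4 decimal places (harmonized representation).
MZ_DECIMALS = 4


class MgfParseError(ValueError):
    """Raised when an MGF block cannot be parsed; names the block index."""


class AmbiguousKeyError(KeyError):
    """Raised when a compound name resolves to more than one spectrum."""


@dataclass(frozen=True, order=True)
class Peak:
    """One centroided fragment ion: m/z (Th) and abundance (arbitrary units)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass
class Spectrum:
    """One MS2 record: precursor, peak list and compound metadata."""

    spectrum_id: str
    precursor_mz: float
    peaks: list[Peak] = field(default_factory=list)
    charge: int = 1
    compound_name: str | None = None
    smiles: str | None = None
    skeleton: str | None = None

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor m/z must be positive, got {self.precursor_mz}")
        self.peaks = sorted(self.peaks, key=lambda p: (p.mz, -p.intensity))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def copy_with(self, **kw) -> "Spectrum":
        out = Spectrum(
            spectrum_id=self.spectrum_id,
            precursor_mz=self.precursor_mz,
            peaks=list(self.peaks),
            charge=self.charge,
            compound_name=self.compound_name,
            smiles=self.smiles,
            skeleton=self.skeleton,
        )
        for k, v in kw.items():
            setattr(out, k, v)
        if "peaks" in kw:
            out.peaks = sorted(out.peaks, key=lambda p: (p.mz, -p.intensity))
        return out


class SpectralLibrary:
    """A collection of spectra partitioned into skeleton groups.

    Each spectrum belongs to at most one group (monomeric-subset assumption);
    spectra without a skeleton label are kept but assigned to no group.
    """

    def __init__(self, spectra: Iterable[Spectrum]):
        self.spectra: list[Spectrum] = list(spectra)
        ids = [s.spectrum_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate spectrum ids: {dup}")
        self._by_id = {s.spectrum_id: s for s in self.spectra}

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, spectrum_id: str) -> Spectrum:
        return self._by_id[spectrum_id]

    def __contains__(self, spectrum_id: str) -> bool:
        return spectrum_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [s.spectrum_id for s in self.spectra]

    @property
    def groups(self) -> dict[str, set[str]]:
        """Mapping skeleton label -> set of member spectrum ids."""
        out: dict[str, set[str]] = {}
        for s in self.spectra:
            if s.skeleton is not None:
                out.setdefault(s.skeleton, set()).add(s.spectrum_id)
        return out

    def group_members(self, skeleton: str) -> set[str]:
        members = self.groups.get(skeleton)
        if members is None:
            raise KeyError(f"unknown skeleton label: {skeleton!r}")
        return members


def _parse_block(lines: list[str], index: int) -> tuple[Spectrum, dict[str, str]]:
    meta: dict[str, str] = {}
    peaks: list[Peak] = []
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            meta[key.strip().upper()] = value.strip()
            continue
        parts = line.split()
        try:
            mz = float(parts[0])
            inten = float(parts[1]) if len(parts) > 1 else 0.0
        except (ValueError, IndexError) as exc:
            raise MgfParseError(
                f"block {index}: cannot parse peak row {line!r}"
            ) from exc
        peaks.append(Peak(mz=mz, intensity=inten))
    if "PEPMASS" not in meta:
        raise MgfParseError(f"block {index}: missing PEPMASS")
    # PEPMASS may carry "mz" or "mz intensity"
    try:
        precursor_mz = float(meta["PEPMASS"].split()[0])
    except ValueError as exc:
        raise MgfParseError(
            f"block {index}: non-numeric PEPMASS {meta['PEPMASS']!r}"
        ) from exc
    charge = 1
    if "CHARGE" in meta:
        text = meta["CHARGE"].rstrip("+").lstrip("+")
        try:
            charge = abs(int(text))
        except ValueError:
            charge = 1
    spectrum = Spectrum(
        spectrum_id=str(index),
        precursor_mz=precursor_mz,
        peaks=peaks,
        charge=charge,
    )
    return spectrum, meta


DEFAULT_METADATA_KEYS: dict[str, str] = {
    "TITLE": "spectrum_id",
    "NAME": "compound_name",
    "SMILES": "smiles",
    "SKELETON": "skeleton",
}


def read_mgf(
    path: str | Path,
    metadata_keys: Mapping[str, str] | None = None,
) -> SpectralLibrary:
    """Read an MGF file into a :class:`SpectralLibrary`.

    Parameters
    ----------
    path:
        MGF file (``BEGIN IONS``/``END IONS`` blocks with ``PEPMASS`` and
        peak rows).
    metadata_keys:
        Mapping of MGF header key -> spectrum field (``spectrum_id``,
        ``compound_name``, ``smiles``, ``skeleton``).  Defaults accept
        ``TITLE``/``NAME``/``SMILES``/``SKELETON``.  The skeleton key is
        configurable because deposited libraries differ.
    """
    path = Path(path)
    keys = dict(DEFAULT_METADATA_KEYS if metadata_keys is None else metadata_keys)
    field_of = {k.upper(): v for k, v in keys.items()}

    text = path.read_text()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.upper() == "BEGIN IONS":
            current = []
        elif stripped.upper() == "END IONS":
            if current is not None:
                blocks.append(current)
            current = None
        elif current is not None:
            current.append(line)
    if not blocks:
        raise MgfParseError(f"{path}: no spectra found (empty library)")

    spectra = []
    for i, block in enumerate(blocks, start=1):
        spec, meta = _parse_block(block, i)
        kwargs: dict[str, str] = {}
        for header, value in meta.items():
            field_name = field_of.get(header)
            if field_name is not None:
                kwargs[field_name] = value
        spec.spectrum_id = kwargs.get("spectrum_id", str(i))
        spec.compound_name = kwargs.get("compound_name")
        spec.smiles = kwargs.get("smiles")
        spec.skeleton = kwargs.get("skeleton")
        spectra.append(spec)
    return SpectralLibrary(spectra)


def write_mgf(
    library: SpectralLibrary,
    path: str | Path,
    metadata_keys: Mapping[str, str] | None = None,
) -> None:
    """Write a library to MGF; round-trips with :func:`read_mgf`.

    m/z values are written at 4 decimals, intensities at 6 significant
    digits.  An empty library is an error.
    """
    if len(library) == 0:
        raise ValueError("refusing to write an empty library")
    keys = dict(DEFAULT_METADATA_KEYS if metadata_keys is None else metadata_keys)
    header_of = {v: k for k, v in keys.items()}
    lines: list[str] = []
    for spec in library:
        lines.append("BEGIN IONS")
        lines.append(f"{header_of.get('spectrum_id', 'TITLE')}={spec.spectrum_id}")
        lines.append(f"PEPMASS={spec.precursor_mz:.{MZ_DECIMALS}f}")
        lines.append(f"CHARGE={spec.charge}+")
        if spec.compound_name is not None:
            lines.append(f"{header_of.get('compound_name', 'NAME')}={spec.compound_name}")
        if spec.smiles is not None:
            lines.append(f"{header_of.get('smiles', 'SMILES')}={spec.smiles}")
        if spec.skeleton is not None:
            lines.append(f"{header_of.get('skeleton', 'SKELETON')}={spec.skeleton}")
        for peak in spec.peaks:
            lines.append(f"{peak.mz:.{MZ_DECIMALS}f} {peak.intensity:.6g}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def attach_skeletons(
    library: SpectralLibrary,
    table: Mapping[str, str],
) -> SpectralLibrary:
    """Return a new library with skeleton labels assigned from ``table``.

    Keys are resolved first as spectrum ids, then as compound names.  A
    compound name matching several spectra raises :class:`AmbiguousKeyError`;
    unmatched keys are reported as warnings; spectra absent from the table
    keep no group.
    """
    by_name: dict[str, list[Spectrum]] = {}
    for s in library:
        if s.compound_name is not None:
            by_name.setdefault(s.compound_name, []).append(s)

    assignment: dict[str, str] = {}
    for key, skeleton in table.items():
        if key in library:
            assignment[key] = skeleton
        elif key in by_name:
            matches = by_name[key]
            if len(matches) > 1:
                raise AmbiguousKeyError(
                    f"compound name {key!r} matches several spectra: "
                    f"{sorted(s.spectrum_id for s in matches)}"
                )
            assignment[matches[0].spectrum_id] = skeleton
        else:
            warnings.warn(f"skeleton table key {key!r} matches no spectrum", stacklevel=2)

    # keep a prior label only where the table does not cover the spectrum
    out = []
    for s in library:
        out.append(s.copy_with(skeleton=assignment.get(s.spectrum_id, s.skeleton)))
    return SpectralLibrary(out)


def read_skeleton_table(path: str | Path) -> dict[str, str]:
    """Read a TSV with columns (id | compound_name, skeleton, ...) into a mapping."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    key_col = cols.get("id") or cols.get("compound_name")
    skel_col = cols.get("skeleton")
    if key_col is None or skel_col is None:
        raise ValueError("skeleton table needs an 'id' or 'compound_name' column and a 'skeleton' column")
    return {
        str(row[key_col]): str(row[skel_col])
        for _, row in df.iterrows()
        if pd.notna(row[key_col]) and pd.notna(row[skel_col])
    }
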