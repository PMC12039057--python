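from __future__ import annotations

import pytest

from specsig import Peak, SpectralLibrary, Spectrum, Tolerance


def make_spectrum(
    spectrum_id: str,
    precursor_mz: float,
    peaks: list[tuple[float, float]],
    skeleton: str | None = None,
    compound_name: str | None = None,
    smiles: str | None = None,
) -> Spectrum:
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        peaks=[Peak(mz, inten) for mz, inten in peaks],
        skeleton=skeleton,
        compound_name=compound_name,
        smiles=smiles,
    )


@pytest.fixture
def tol() -> Tolerance:
    return Tolerance()


@pytest.fixture
def tiny_library() -> SpectralLibrary:
    return SpectralLibrary(
        [
            make_spectrum("s1", 353.19, [(144.0808, 100.0), (200.0, 40.0)], "alpha", "cpd-a"),
            make_spectrum("s2", 351.17, [(144.0810, 80.0), (210.0, 20.0)], "alpha", "cpd-b"),
            make_spectrum("s3", 400.20, [(150.0, 60.0), (300.1, 10.0)], "beta", "cpd-c"),
            make_spectrum("s4", 420.25, [(150.0, 70.0)], None, "cpd-d"),
        ]
    )
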