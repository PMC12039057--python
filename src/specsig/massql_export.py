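"""MassQL serialization of skeleton queries and desk-scale query execution.

Queries are emitted as conjunctions of MS2PROD (fragment presence) and MS2NL
(neutral loss) clauses.  ``run_query`` interprets exactly that dialect
natively against an MGF feature dataset, with semantics identical to
:func:`specsig.signature_extraction.match_query` by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .preprocessing import Signal, Tolerance
from .signature_extraction import SkeletonQuery, match_query
from .spectral_io import SpectralLibrary

__all__ = ["MassQLQuery", "to_massql", "parse_massql", "run_query"]

_PREFIX = "QUERY scaninfo(MS2DATA) WHERE "
_CLAUSE_RE = re.compile(
    r"(MS2PROD|MS2NL)=(\d+(?:\.\d+)?):TOLERANCEMZ=(\d+(?:\.\d+)?)"
)


@dataclass(frozen=True)
class MassQLQuery:
    """A MassQL statement plus its native-execution ingredients."""

    text: str
    signals: tuple[Signal, ...]
    tolerance: Tolerance


def to_massql(query: SkeletonQuery, tol: Tolerance) -> MassQLQuery:
    """Serialize a skeleton query as a MassQL statement.

    One MS2PROD clause per fragment, one MS2NL clause per loss; m/z at
    4 decimals; fragments ascending then losses ascending.  Only the
    absolute tolerance component is emitted (clause-level ppm qualifiers
    vary across engine versions); the internal matcher remains the ground
    truth.
    """
    if not query.signals:
        raise ValueError("cannot serialize a query with no signals")
    ordered = sorted(query.signals, key=lambda s: (0 if s.kind == "fragment" else 1, s.mz))
    clauses = []
    for s in ordered:
        keyword = "MS2PROD" if s.kind == "fragment" else "MS2NL"
        clauses.append(f"{keyword}={s.mz:.4f}:TOLERANCEMZ={tol.absolute:g}")
    return MassQLQuery(
        text=_PREFIX + " AND ".join(clauses),
        signals=tuple(ordered),
        tolerance=tol,
    )


def parse_massql(text: str, ppm: float = 25.0) -> MassQLQuery:
    """Parse the emitted MS2PROD/MS2NL conjunction dialect back into signals."""
    matches = _CLAUSE_RE.findall(text)
    if not matches:
        raise ValueError(f"no MS2PROD/MS2NL clauses found in {text!r}")
    signals = tuple(
        Signal(kind="fragment" if kw == "MS2PROD" else "loss", mz=float(mz))
        for kw, mz, _ in matches
    )
    tol_abs = float(matches[0][2])
    return MassQLQuery(text=text, signals=signals, tolerance=Tolerance(tol_abs, ppm))


def run_query(query: MassQLQuery | SkeletonQuery, dataset: SpectralLibrary,
              tol: Tolerance | None = None) -> list[str]:
    """Apply a query to a feature-level MGF dataset; returns matched ids.

    Identical to applying :func:`match_query` with the source query's signal
    set (internal consistency contract).
    """
    if isinstance(query, SkeletonQuery):
        if tol is None:
            raise ValueError("a Tolerance is required when passing a SkeletonQuery")
        signals, tolerance = query.signals, tol
    else:
        signals, tolerance = query.signals, tol or query.tolerance
    return [
        spec.spectrum_id
        for spec in dataset
        if match_query(signals, spec, tolerance)
    ]
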