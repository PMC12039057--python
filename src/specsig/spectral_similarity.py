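"""Pairwise MS/MS similarity: classic cosine and modified cosine.

The modified cosine additionally allows peak matches offset by the precursor
mass difference.  Assignment of matched peak pairs is greedy by descending
intensity product with a one-to-one constraint (the documented contract); an
exact maximum-weight assignment variant is available.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .preprocessing import Tolerance, normalize
from .skeleton_similarity import SimilarityMatrix
from .spectral_io import SpectralLibrary, Spectrum

__all__ = [
    "COSINE_TOLERANCE",
    "cosine_score",
    "modified_cosine",
    "similarity_heatmap",
]

#: networking-style default for cosine matching (0.02 Da)
COSINE_TOLERANCE = Tolerance(absolute=0.02, ppm=1e-6)


def _window(tol: Tolerance | float, mz: float) -> float:
    if isinstance(tol, Tolerance):
        return tol.window(mz)
    return float(tol)


def _candidate_pairs(
    a: Spectrum, b: Spectrum, tol: Tolerance | float, shift: float | None
) -> list[tuple[int, int, float, str]]:
    """(index in a, index in b, intensity product, direct|shifted) pairs."""
    pairs: list[tuple[int, int, float, str]] = []
    offsets = [(0.0, "direct")]
    if shift is not None and abs(shift) > 0:
        offsets.append((shift, "shifted"))
    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            for offset, kind in offsets:
                if abs(pa.mz - (pb.mz + offset)) <= _window(tol, max(pa.mz, pb.mz)):
                    pairs.append((i, j, pa.intensity * pb.intensity, kind))
    return pairs


def _greedy_assignment(pairs: list[tuple[int, int, float, str]]) -> list[tuple[int, int, float, str]]:
    ordered = sorted(pairs, key=lambda p: (-p[2], p[0], p[1], p[3] != "direct"))
    used_a: set[int] = set()
    used_b: set[int] = set()
    chosen = []
    for i, j, product, kind in ordered:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        chosen.append((i, j, product, kind))
    return chosen


def _exact_assignment(pairs: list[tuple[int, int, float, str]]) -> list[tuple[int, int, float, str]]:
    from scipy.optimize import linear_sum_assignment

    if not pairs:
        return []
    ai = sorted({p[0] for p in pairs})
    bj = sorted({p[1] for p in pairs})
    a_pos = {v: k for k, v in enumerate(ai)}
    b_pos = {v: k for k, v in enumerate(bj)}
    weight = np.zeros((len(ai), len(bj)))
    best_kind: dict[tuple[int, int], str] = {}
    for i, j, product, kind in pairs:
        if product > weight[a_pos[i], b_pos[j]]:
            weight[a_pos[i], b_pos[j]] = product
            best_kind[(i, j)] = kind
    rows, cols = linear_sum_assignment(-weight)
    chosen = []
    for r, c in zip(rows, cols):
        if weight[r, c] > 0:
            i, j = ai[r], bj[c]
            chosen.append((i, j, float(weight[r, c]), best_kind[(i, j)]))
    return chosen


def _score(a: Spectrum, b: Spectrum, pairs, exact: bool) -> tuple[float, int]:
    if not a.peaks or not b.peaks:
        return 0.0, 0
    chosen = _exact_assignment(pairs) if exact else _greedy_assignment(pairs)
    if not chosen:
        return 0.0, 0
    norm = math.sqrt(sum(p.intensity ** 2 for p in a.peaks)) * math.sqrt(
        sum(p.intensity ** 2 for p in b.peaks)
    )
    if norm == 0:
        return 0.0, 0
    score = sum(product for _, _, product, _ in chosen) / norm
    return min(score, 1.0), len(chosen)


def cosine_score(
    a: Spectrum, b: Spectrum, tol: Tolerance | float = COSINE_TOLERANCE,
    exact: bool = False,
) -> tuple[float, int]:
    """Classic cosine: direct m/z matches only.  Returns (score, n matched)."""
    return _score(a, b, _candidate_pairs(a, b, tol, shift=None), exact)


def modified_cosine(
    a: Spectrum, b: Spectrum, tol: Tolerance | float = COSINE_TOLERANCE,
    exact: bool = False,
) -> tuple[float, int]:
    """Cosine allowing matches offset by the precursor m/z difference."""
    shift = a.precursor_mz - b.precursor_mz
    return _score(a, b, _candidate_pairs(a, b, tol, shift=shift), exact)


def similarity_heatmap(
    library: SpectralLibrary,
    method: str = "modified_cosine",
    order: Sequence[str] | None = None,
    tol: Tolerance | float = COSINE_TOLERANCE,
    threshold: float | None = None,
    exact: bool = False,
) -> SimilarityMatrix:
    """Full pairwise similarity matrix, rows ordered for heatmap rendering.

    Spectra are sorted by their skeleton's position in the dendrogram leaf
    ``order`` (then by spectrum id); spectra with a skeleton missing from the
    order — or no skeleton — fall into a trailing unassigned block.  An
    optional ``threshold`` masks (zeroes) values below the floor.
    """
    scorers = {"modified_cosine": modified_cosine, "cosine": cosine_score}
    if method not in scorers:
        raise ValueError(f"unknown method {method!r}; use one of {sorted(scorers)}")
    scorer = scorers[method]

    position = {skeleton: k for k, skeleton in enumerate(order)} if order else {}
    unassigned = len(position)

    def sort_key(spec: Spectrum):
        pos = position.get(spec.skeleton, unassigned) if spec.skeleton else unassigned
        return (pos, spec.spectrum_id)

    ordered = sorted(library, key=sort_key)
    prepared = [normalize(s) if s.peaks else s for s in ordered]
    n = len(prepared)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            score, _ = scorer(prepared[i], prepared[j], tol, exact=exact)
            values[i, j] = values[j, i] = score
    if threshold is not None:
        masked = values.copy()
        masked[masked < threshold] = 0.0
        np.fill_diagonal(masked, 1.0)
        values = masked
    labels = [s.spectrum_id for s in ordered]
    return SimilarityMatrix(
        labels=labels,
        values=values,
        leaf_order=labels,
        metadata={"method": method, "threshold": threshold},
    )
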