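"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (exhaustive
enumeration, exact rational arithmetic) and must stay independent of the
code paths they validate.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations


def fbeta_oracle(precision: float, recall: float, beta: float) -> float:
    """Direct transcription of the F-beta definition."""
    if precision == 0 and recall == 0:
        return 0.0
    return (1 + beta**2) * (precision * recall) / ((beta**2 * precision) + recall)


def cluster_oracle(values: list[float], window: float) -> list[list[float]]:
    """Brute-force single-linkage clustering: repeatedly merge the two
    clusters whose closest members are within the window."""
    clusters = [[v] for v in sorted(values)]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                gap = min(
                    abs(a - b) for a in clusters[i] for b in clusters[j]
                )
                if gap <= window:
                    clusters[i] = sorted(clusters[i] + clusters[j])
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    return sorted(clusters)


def _signal_matches(signal_kind: str, signal_mz: float, spectrum, abs_tol: float, ppm: float) -> bool:
    window = max(abs_tol, ppm * signal_mz * 1e-6)
    for peak in spectrum.peaks:
        if signal_kind == "fragment":
            if abs(peak.mz - signal_mz) <= window:
                return True
        else:
            if peak.mz < spectrum.precursor_mz and abs(
                (spectrum.precursor_mz - peak.mz) - signal_mz
            ) <= window:
                return True
    return False


def brute_force_queries(
    skeleton: str,
    signals: list,
    library,
    abs_tol: float,
    ppm: float,
    max_signals: int,
    beta: Fraction,
) -> tuple[Fraction, set[frozenset]]:
    """Enumerate every subset of candidate signals up to max_signals and
    score it with exact rational F-beta; returns (best score, tied subsets)."""
    group = {
        s.spectrum_id for s in library if s.skeleton == skeleton
    }
    hits = {
        s: {
            spec.spectrum_id
            for spec in library
            if _signal_matches(s.kind, s.mz, spec, abs_tol, ppm)
        }
        for s in signals
    }
    best = Fraction(-1)
    ties: set[frozenset] = set()
    for k in range(1, min(max_signals, len(signals)) + 1):
        for subset in combinations(signals, k):
            retrieved = set.intersection(*(hits[s] for s in subset))
            tp = len(retrieved & group)
            precision = Fraction(tp, len(retrieved)) if retrieved else Fraction(0)
            recall = Fraction(tp, len(group)) if group else Fraction(0)
            if precision == 0 and recall == 0:
                score = Fraction(0)
            elif beta**2 * precision + recall == 0:
                score = Fraction(0)
            else:
                score = (
                    (1 + beta**2)
                    * precision
                    * recall
                    / (beta**2 * precision + recall)
                )
            if score > best:
                best = score
                ties = {frozenset(subset)}
            elif score == best:
                ties.add(frozenset(subset))
    return best, ties
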