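"""Skeleton-specific spectrometric signature extraction.

Per skeleton group, candidate signals (fragments and neutral losses pooled)
are scored with an F2 statistic favouring recall; retained candidates are
combined exhaustively (up to 10 signals per query) and every combination is
evaluated back against the raw, non-processed library under conjunctive
matching.  Combinations are ranked by F0.5 and all tied-best queries kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .preprocessing import (
    BinnedSignalMatrix,
    Signal,
    Tolerance,
    build_signal_matrix,
)
from .spectral_io import SpectralLibrary, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "SignatureCandidate",
    "SkeletonQuery",
    "ExtractionConfig",
    "fbeta",
    "score_candidates",
    "match_query",
    "enumerate_and_score",
    "extract_signatures",
    "queries_to_records",
]


def fbeta(precision: float, recall: float, beta: float) -> float:
    """F-beta score: (1 + beta^2) P R / (beta^2 P + R).

    Returns 0.0 when precision and recall are both zero (convention).
    """
    if beta <= 0:
        raise ValueError(f"beta must be strictly positive, got {beta}")
    if precision == 0 and recall == 0:
        return 0.0
    b2 = beta * beta
    return (1 + b2) * precision * recall / (b2 * precision + recall)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def group_size(self) -> int:
        return self.tp + self.fn

    @property
    def retrieved(self) -> int:
        return self.tp + self.fp

    @property
    def precision(self) -> float:
        return self.tp / self.retrieved if self.retrieved else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.group_size if self.group_size else 0.0


@dataclass(frozen=True)
class SignatureCandidate:
    """A signal scored against one skeleton group."""

    skeleton: str
    signal: Signal
    tp: int
    fp: int
    group_size: int
    universal: bool = False  # present in every group member

    @property
    def occurrence(self) -> int:
        return self.tp + self.fp

    @property
    def precision(self) -> float:
        return self.tp / self.occurrence if self.occurrence else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.group_size if self.group_size else 0.0

    @property
    def f2(self) -> float:
        return fbeta(self.precision, self.recall, 2.0)


@dataclass(frozen=True)
class SkeletonQuery:
    """A conjunctive signal set for one skeleton with library-level scores."""

    skeleton: str
    signals: tuple[Signal, ...]
    counts: ConfusionCounts
    f05: float

    @property
    def precision(self) -> float:
        return self.counts.precision

    @property
    def recall(self) -> float:
        return self.counts.recall


def _candidate_sort_key(c: SignatureCandidate):
    # F2 descending, then m/z ascending, fragments before losses
    return (-c.f2, c.signal.mz, 0 if c.signal.kind == "fragment" else 1)


def score_candidates(
    matrix: BinnedSignalMatrix,
    groups: Mapping[str, Iterable[str]],
    min_occurrence: int = 3,
    min_score: float = 0.0,
    top_k: int = 10,
) -> dict[str, list[SignatureCandidate]]:
    """Score every signal against every skeleton group.

    A signal qualifies as a candidate for a group when it occurs (cell > 0)
    in at least ``min_occurrence`` spectra library-wide and in at least one
    group member.  Signals found in *all* group members are retained
    unconditionally, as are specificity-1 signals (no out-group occurrence);
    the remainder are ranked by F2 and the ``top_k`` best kept, dropping any
    below ``min_score``.
    """
    present = matrix.values > 0
    occurrence = present.sum(axis=0)
    row_index = {r: i for i, r in enumerate(matrix.row_ids)}

    out: dict[str, list[SignatureCandidate]] = {}
    for skeleton, member_ids in groups.items():
        rows = [row_index[m] for m in member_ids if m in row_index]
        group_size = len(rows)
        if group_size == 0:
            out[skeleton] = []
            continue
        in_group = present[rows, :].sum(axis=0)

        universal: list[SignatureCandidate] = []
        specific: list[SignatureCandidate] = []
        ranked: list[SignatureCandidate] = []
        for j, signal in enumerate(matrix.signals):
            occ = int(occurrence[j])
            tp = int(in_group[j])
            if occ < min_occurrence or tp == 0:
                continue
            cand = SignatureCandidate(
                skeleton=skeleton,
                signal=signal,
                tp=tp,
                fp=occ - tp,
                group_size=group_size,
                universal=tp == group_size,
            )
            if cand.universal:
                universal.append(cand)
            elif cand.fp == 0:
                specific.append(cand)
            else:
                ranked.append(cand)

        ranked.sort(key=_candidate_sort_key)
        ranked = [c for c in ranked[:top_k] if c.f2 >= min_score]
        merged = universal + specific + ranked
        merged.sort(key=_candidate_sort_key)
        out[skeleton] = merged
    return out


def match_query(
    signals: Sequence[Signal] | SkeletonQuery,
    spectrum: Spectrum,
    tol: Tolerance,
) -> bool:
    """Conjunctive match of a signal set against a raw spectrum.

    Fragment signals match any peak within the effective window; loss
    signals match when precursor_mz minus some peak below the precursor
    falls within the window.  True only if every signal matches.
    """
    if isinstance(signals, SkeletonQuery):
        signals = signals.signals
    signals = tuple(signals)
    if not signals:
        raise ValueError("a query must contain at least one signal")
    for signal in signals:
        window = tol.window(signal.mz)
        if signal.kind == "fragment":
            hit = any(abs(p.mz - signal.mz) <= window for p in spectrum.peaks)
        else:
            hit = any(
                p.mz < spectrum.precursor_mz
                and abs((spectrum.precursor_mz - p.mz) - signal.mz) <= window
                for p in spectrum.peaks
            )
        if not hit:
            return False
    return True


def _signal_order(s: Signal):
    return (0 if s.kind == "fragment" else 1, s.mz)


def _query_tie_key(q: SkeletonQuery):
    return (len(q.signals), tuple((s.mz, s.kind) for s in q.signals))


def _exact_f(beta: Fraction, tp: int, retrieved: int, group_size: int) -> Fraction:
    """F-beta on confusion counts in exact rational arithmetic.

    Algebraically (1+b^2) tp / (b^2 g + retrieved) for tp > 0; ties between
    combinations are decided on these exact values.
    """
    if tp == 0 or retrieved == 0 or group_size == 0:
        return Fraction(0)
    b2 = beta * beta
    return (1 + b2) * tp / (b2 * group_size + retrieved)


def enumerate_and_score(
    skeleton: str,
    candidates: Sequence[SignatureCandidate],
    library: SpectralLibrary,
    tol: Tolerance,
    max_signals: int = 10,
    beta: float = 0.5,
    min_group: int = 5,
    exclude_ids: Iterable[str] = (),
) -> list[SkeletonQuery]:
    """Exhaustively evaluate additive signal combinations for one skeleton.

    Every non-empty subset of the candidate signals up to ``max_signals`` is
    matched against the raw library; subsets whose retrieved set is empty are
    pruned (supersets can only stay empty, a loss-free cut because every
    candidate singleton scores > 0).  Returns all queries tied at the best
    F-beta, sorted by (score desc, size asc, signal m/z lexicographic).
    """
    if not candidates:
        return []
    exclude = set(exclude_ids)
    group = {m for m in library.group_members(skeleton) if m not in exclude}
    if len(group) < min_group:
        logger.info(
            "skeleton %r has %d members (< %d); skipping query generation",
            skeleton, len(group), min_group,
        )
        return []

    eval_ids = [sid for sid in library.ids if sid not in exclude]
    n = len(eval_ids)
    group_size = len(group)
    group_mask = 0
    for i, sid in enumerate(eval_ids):
        if sid in group:
            group_mask |= 1 << i

    signals = sorted({c.signal for c in candidates}, key=_signal_order)
    masks: list[int] = []
    for signal in signals:
        mask = 0
        for i, sid in enumerate(eval_ids):
            if match_query((signal,), library[sid], tol):
                mask |= 1 << i
        masks.append(mask)

    frac_beta = Fraction(beta)
    best: Fraction = Fraction(-1)
    best_subsets: list[tuple[tuple[int, ...], int]] = []

    def evaluate(chosen: tuple[int, ...], mask: int) -> None:
        nonlocal best, best_subsets
        tp = (mask & group_mask).bit_count()
        score = _exact_f(frac_beta, tp, mask.bit_count(), group_size)
        if score > best:
            best = score
            best_subsets = [(chosen, mask)]
        elif score == best:
            best_subsets.append((chosen, mask))

    def dfs(start: int, chosen: tuple[int, ...], mask: int) -> None:
        for j in range(start, len(signals)):
            new_mask = mask & masks[j]
            new_chosen = chosen + (j,)
            evaluate(new_chosen, new_mask)
            if new_mask and len(new_chosen) < max_signals:
                dfs(j + 1, new_chosen, new_mask)

    dfs(0, (), (1 << n) - 1 if n else 0)

    queries = []
    for chosen, mask in best_subsets:
        tp = (mask & group_mask).bit_count()
        retrieved = mask.bit_count()
        counts = ConfusionCounts(
            tp=tp,
            fp=retrieved - tp,
            fn=group_size - tp,
            tn=n - retrieved - (group_size - tp),
        )
        queries.append(
            SkeletonQuery(
                skeleton=skeleton,
                signals=tuple(signals[j] for j in chosen),
                counts=counts,
                f05=float(best),
            )
        )
    queries.sort(key=_query_tie_key)
    return queries


@dataclass
class ExtractionConfig:
    """Thresholds of the end-to-end extraction pipeline (library defaults)."""

    tolerance: Tolerance = field(default_factory=Tolerance)
    min_occurrence: int = 3
    min_score: float = 0.0
    top_k_candidates: int = 10
    max_signals: int = 10
    min_group: int = 5
    beta_query: float = 0.5
    deisotope_enabled: bool = True


def extract_signatures(
    library: SpectralLibrary,
    config: ExtractionConfig | None = None,
) -> dict[str, list[SkeletonQuery]]:
    """Full chain: preprocess, harmonize, score candidates, enumerate queries.

    Returns the tied-best query list per eligible skeleton (group size >=
    ``config.min_group`` after excluding spectra emptied by preprocessing).
    """
    config = config or ExtractionConfig()
    matrix, flagged = build_signal_matrix(
        library, config.tolerance, config.deisotope_enabled
    )
    if flagged:
        logger.info("%d spectra emptied by preprocessing were excluded: %s",
                    len(flagged), flagged)
    groups = library.groups
    candidates = score_candidates(
        matrix,
        groups,
        min_occurrence=config.min_occurrence,
        min_score=config.min_score,
        top_k=config.top_k_candidates,
    )
    out: dict[str, list[SkeletonQuery]] = {}
    flagged_set = set(flagged)
    for skeleton in sorted(groups):
        effective = {m for m in groups[skeleton] if m not in flagged_set}
        if len(effective) < config.min_group:
            logger.info("skeleton %r below minimum group size, skipped", skeleton)
            continue
        queries = enumerate_and_score(
            skeleton,
            candidates.get(skeleton, []),
            library,
            config.tolerance,
            max_signals=config.max_signals,
            beta=config.beta_query,
            min_group=config.min_group,
            exclude_ids=flagged_set,
        )
        if queries:
            out[skeleton] = queries
    if not out:
        logger.info("no eligible skeleton group produced queries")
    return out


def queries_to_records(queries: Mapping[str, Sequence[SkeletonQuery]]) -> list[dict]:
    """Flatten query results to serializable records (one row per query)."""
    records = []
    for skeleton in sorted(queries):
        for q in queries[skeleton]:
            records.append(
                {
                    "skeleton": skeleton,
                    "signals": [s.label for s in q.signals],
                    "tp": q.counts.tp,
                    "fp": q.counts.fp,
                    "fn": q.counts.fn,
                    "tn": q.counts.tn,
                    "precision": q.precision,
                    "recall": q.recall,
                    "f05": q.f05,
                }
            )
    return records
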