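from __future__ import annotations

import json
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specsig import (
    ExtractionConfig,
    SimulationConfig,
    SpectralLibrary,
    Tolerance,
    enumerate_and_score,
    extract_signatures,
    fbeta,
    match_query,
    queries_to_records,
    score_candidates,
    simulate_library,
)
from specsig.preprocessing import BinnedSignalMatrix, Signal
from specsig.signature_extraction import SignatureCandidate

from conftest import make_spectrum
from oracles import brute_force_queries, fbeta_oracle


class TestFbeta:
    def test_worked_example(self):
        # 11/16 precision, 11/12 recall at beta=2 evaluates to 0.859375
        value = fbeta(11 / 16, 11 / 12, 2.0)
        assert value == pytest.approx(0.859375, abs=1e-12)
        assert value == pytest.approx(fbeta_oracle(11 / 16, 11 / 12, 2.0), abs=1e-12)

    def test_perfect(self):
        for beta in (0.5, 1.0, 2.0, 7.3):
            assert fbeta(1.0, 1.0, beta) == pytest.approx(1.0)

    def test_zero_convention(self):
        assert fbeta(0.0, 0.0, 2.0) == 0.0

    def test_harmonic_mean_identity(self):
        for x in (0.1, 0.5, 0.9):
            assert fbeta(x, x, 1.0) == pytest.approx(x)

    def test_bad_beta(self):
        with pytest.raises(ValueError):
            fbeta(0.5, 0.5, 0.0)

    @settings(max_examples=1000, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.01, max_value=10.0),
    )
    def test_matches_independent_formula(self, p, r, beta):
        assert fbeta(p, r, beta) == pytest.approx(fbeta_oracle(p, r, beta), abs=1e-12)


def _matrix(columns: dict[Signal, list[str]], row_ids: list[str]) -> BinnedSignalMatrix:
    signals = sorted(columns, key=lambda s: (s.kind, s.mz))
    values = np.zeros((len(row_ids), len(signals)))
    for j, s in enumerate(signals):
        for sid in columns[s]:
            values[row_ids.index(sid), j] = 1.0
    return BinnedSignalMatrix(row_ids, signals, values)


class TestScoreCandidates:
    def test_paper_style_worked_example(self):
        # a fragment in 16 spectra, 11 of them inside a 12-member group
        rows = [f"g{i}" for i in range(12)] + [f"o{i}" for i in range(18)]
        signal = Signal("fragment", 124.0429)
        present = [f"g{i}" for i in range(11)] + [f"o{i}" for i in range(5)]
        m = _matrix({signal: present}, rows)
        out = score_candidates(m, {"ajm-oxi": [f"g{i}" for i in range(12)]})
        (cand,) = out["ajm-oxi"]
        assert cand.tp == 11 and cand.fp == 5
        assert cand.precision == pytest.approx(11 / 16)
        assert cand.recall == pytest.approx(11 / 12)
        assert cand.f2 == pytest.approx(0.859375, abs=1e-12)

    def test_min_occurrence_filter(self):
        rows = [f"g{i}" for i in range(5)] + ["o0"]
        signal = Signal("fragment", 200.0)
        m = _matrix({signal: ["g0", "g1"]}, rows)
        out = score_candidates(m, {"g": [f"g{i}" for i in range(5)]})
        assert out["g"] == []

    def test_universal_signal_retained_despite_low_precision(self):
        rows = [f"g{i}" for i in range(5)] + [f"o{i}" for i in range(40)]
        signal = Signal("fragment", 150.0)
        m = _matrix({signal: rows}, rows)  # present everywhere
        out = score_candidates(m, {"g": [f"g{i}" for i in range(5)]})
        (cand,) = out["g"]
        assert cand.universal
        assert cand.precision == pytest.approx(5 / 45)

    def test_top_10_cap(self):
        group = [f"g{i}" for i in range(12)]
        rows = group + [f"o{i}" for i in range(20)]
        columns = {}
        for k in range(12):
            # non-universal candidates (at most 11 of 12 members) with distinct F2
            present = group[: min(k + 1, 11)] + [f"o{i}" for i in range(3 if k < 11 else 8)]
            columns[Signal("fragment", 100.0 + k)] = present
        m = _matrix(columns, rows)
        out = score_candidates(m, {"g": group})
        assert len(out["g"]) == 10
        f2s = [c.f2 for c in out["g"]]
        assert f2s == sorted(f2s, reverse=True)

    def test_min_score_drops_ranked_candidates(self):
        group = [f"g{i}" for i in range(12)]
        rows = group + [f"o{i}" for i in range(20)]
        weak = Signal("fragment", 100.0)
        m = _matrix({weak: group[:1] + [f"o{i}" for i in range(10)]}, rows)
        assert score_candidates(m, {"g": group}, min_score=0.5)["g"] == []
        assert len(score_candidates(m, {"g": group}, min_score=0.0)["g"]) == 1


class TestMatchQuery:
    def test_conjunction_satisfied(self, tol):
        spec = make_spectrum("x", 400.0, [(144.0808, 1.0), (249.8, 0.5)])
        q = (Signal("fragment", 144.0808), Signal("loss", 150.2))
        assert match_query(q, spec, tol)

    def test_missing_loss_fails(self, tol):
        spec = make_spectrum("x", 400.0, [(144.0808, 1.0)])
        q = (Signal("fragment", 144.0808), Signal("loss", 150.2))
        assert not match_query(q, spec, tol)

    def test_empty_query_is_error(self, tol):
        with pytest.raises(ValueError):
            match_query((), make_spectrum("x", 400.0, [(100.0, 1.0)]), tol)

    def test_loss_ignores_peaks_above_precursor(self, tol):
        # fragment above precursor cannot realize a loss
        spec = make_spectrum("x", 200.0, [(350.2, 1.0)])
        assert not match_query((Signal("loss", 150.2),), spec, tol)


def _candidate(skeleton: str, signal: Signal) -> SignatureCandidate:
    return SignatureCandidate(skeleton=skeleton, signal=signal, tp=1, fp=0, group_size=5)


def _random_instance(rng: np.random.Generator):
    """Small random library + candidate set with exact-m/z peaks."""
    alphabet = [float(m) for m in range(100, 300, 10)]
    n_spectra = int(rng.integers(8, 16))
    group_size = int(rng.integers(5, min(8, n_spectra) + 1))
    spectra = []
    for i in range(n_spectra):
        skeleton = "target" if i < group_size else None
        k = int(rng.integers(2, 7))
        mzs = rng.choice(alphabet, size=k, replace=False)
        peaks = [(float(m), float(rng.uniform(0.1, 1.0))) for m in mzs]
        spectra.append(make_spectrum(f"s{i}", 500.0, peaks, skeleton))
    library = SpectralLibrary(spectra)
    group_peaks = sorted({m for s in spectra[:group_size] for m in s.mzs})
    n_cand = int(rng.integers(3, min(7, len(group_peaks)) + 1))
    chosen = rng.choice(group_peaks, size=n_cand, replace=False)
    signals = [Signal("fragment", float(m)) for m in sorted(chosen)]
    return library, signals


class TestEnumerateAndScore:
    def test_perfect_single_candidate(self, tol):
        group = [make_spectrum(f"g{i}", 500.0, [(150.0, 1.0)], "sk") for i in range(6)]
        others = [make_spectrum(f"o{i}", 500.0, [(200.0, 1.0)]) for i in range(6)]
        lib = SpectralLibrary(group + others)
        queries = enumerate_and_score("sk", [_candidate("sk", Signal("fragment", 150.0))], lib, tol)
        (q,) = queries
        assert q.precision == 1.0 and q.recall == 1.0 and q.f05 == 1.0

    def test_disjoint_halves_and_semantics(self, tol):
        # A covers one half of the group, B the other: {A,B} retrieves nothing
        half_a = [make_spectrum(f"a{i}", 500.0, [(150.0, 1.0)], "sk") for i in range(3)]
        half_b = [make_spectrum(f"b{i}", 500.0, [(160.0, 1.0)], "sk") for i in range(3)]
        lib = SpectralLibrary(half_a + half_b)
        cands = [_candidate("sk", Signal("fragment", 150.0)),
                 _candidate("sk", Signal("fragment", 160.0))]
        queries = enumerate_and_score("sk", cands, lib, tol)
        expected = (1.25 * 1.0 * 0.5) / (0.25 * 1.0 + 0.5)
        assert queries[0].f05 == pytest.approx(expected)  # 0.8333...
        assert {frozenset(q.signals) for q in queries} == {
            frozenset({Signal("fragment", 150.0)}),
            frozenset({Signal("fragment", 160.0)}),
        }

    def test_max_signals_cap(self, tol):
        group = [make_spectrum(f"g{i}", 500.0, [(float(100 + 10 * k), 1.0) for k in range(12)], "sk")
                 for i in range(5)]
        lib = SpectralLibrary(group + [make_spectrum("o", 500.0, [(90.0, 1.0)])])
        cands = [_candidate("sk", Signal("fragment", float(100 + 10 * k))) for k in range(12)]
        queries = enumerate_and_score("sk", cands, lib, tol, max_signals=10)
        assert all(len(q.signals) <= 10 for q in queries)

    def test_small_group_skipped(self, tol):
        lib = SpectralLibrary(
            [make_spectrum(f"g{i}", 500.0, [(150.0, 1.0)], "sk") for i in range(4)]
        )
        assert enumerate_and_score("sk", [_candidate("sk", Signal("fragment", 150.0))], lib, tol) == []

    def test_matches_brute_force_on_random_instances(self, tol):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            library, signals = _random_instance(rng)
            cands = [_candidate("target", s) for s in signals]
            result = enumerate_and_score("target", cands, library, tol, max_signals=8)
            best, ties = brute_force_queries(
                "target", signals, library, tol.absolute, tol.ppm, 8, Fraction(1, 2)
            )
            assert result, "implementation returned no queries"
            assert result[0].f05 == pytest.approx(float(best), abs=1e-15)
            assert {frozenset(q.signals) for q in result} == ties

    def test_monotonicity_nested_queries(self, tol):
        rng = np.random.default_rng(99)
        library, signals = _random_instance(rng)
        for _ in range(30):
            k = int(rng.integers(1, len(signals)))
            base = list(rng.choice(len(signals), size=k, replace=False))
            extra = int(rng.integers(0, len(signals)))
            small = [signals[i] for i in base]
            large = list({*small, signals[extra]})
            retrieved_small = {s.spectrum_id for s in library if match_query(small, s, tol)}
            retrieved_large = {s.spectrum_id for s in library if match_query(large, s, tol)}
            assert retrieved_large <= retrieved_small


class TestExtractSignatures:
    def test_planted_recovery(self, tol):
        lib, truth = simulate_library(
            SimulationConfig(n_groups=3, members_per_group=6, noise_peaks_per_spectrum=15, seed=7)
        )
        queries = extract_signatures(lib)
        assert set(queries) == set(truth.planted)
        for skeleton, qs in queries.items():
            planted = truth.planted[skeleton]
            for q in qs:
                assert q.f05 == 1.0
                for signal in q.signals:
                    assert any(
                        signal.kind == p.kind and abs(signal.mz - p.mz) <= tol.window(p.mz)
                        for p in planted
                    )

    def test_identical_spectra_precision_is_group_ratio(self):
        peaks = [(150.0, 1.0), (250.0, 0.5)]
        group = [make_spectrum(f"g{i}", 500.0, peaks, "sk") for i in range(5)]
        others = [make_spectrum(f"o{i}", 500.0, peaks) for i in range(5)]
        lib = SpectralLibrary(group + others)
        queries = extract_signatures(lib)
        for q in queries["sk"]:
            assert q.recall == 1.0
            assert q.precision == pytest.approx(0.5)  # group / library ratio

    def test_ungrouped_only_library_is_empty(self):
        lib = SpectralLibrary([make_spectrum(f"s{i}", 500.0, [(150.0, 1.0)]) for i in range(6)])
        assert extract_signatures(lib) == {}

    def test_determinism_byte_identical(self):
        lib, _ = simulate_library(
            SimulationConfig(n_groups=2, members_per_group=5, noise_peaks_per_spectrum=10, seed=13)
        )
        a = json.dumps(queries_to_records(extract_signatures(lib)))
        b = json.dumps(queries_to_records(extract_signatures(lib)))
        assert a == b
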