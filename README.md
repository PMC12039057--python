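# specsig

Skeleton-specific MS/MS spectral signature extraction and MassQL query
generation, with supporting structural (Tanimoto) and spectral (modified
cosine) similarity analyses.

Given an MGF spectral library in which each MS2 spectrum carries a skeleton
(scaffold class) label, `specsig`:

1. **Conditions** each spectrum: deisotoping (charge-1 ¹³C spacings),
   concurrent-fragment reduction, removal of fragments at/above the
   precursor, base-peak normalization, and neutral-loss computation
   (precursor − fragment). The matching tolerance is `max(10 mDa, 25 ppm)`.
2. **Harmonizes** fragment and loss m/z values across the library into
   binned occurrence matrices (representative m/z = intensity-weighted mean,
   4 decimals).
3. **Scores candidate signals** per skeleton group with an F₂ statistic
   (recall-weighted): signals occurring in ≥ 3 spectra qualify; signals
   found in every group member or in no out-group spectrum are retained
   unconditionally; the rest are ranked by F₂ and the top 10 kept.
4. **Enumerates conjunctive queries** — every additive combination of up to
   10 candidate signals — evaluates each against the *raw* library, ranks by
   F₀.₅ (precision-weighted) and keeps all tied-best queries per skeleton
   (groups need ≥ 5 members).
5. **Emits MassQL** statements (`MS2PROD` / `MS2NL` conjunctions) and can run
   them natively against feature-level MGF datasets.
6. Computes **retrieval metrics** (precision/recall over reference-annotated
   features) and **genus-level source attribution**, plus Morgan-fingerprint
   Tanimoto skeleton dendrograms and modified-/classic-cosine similarity
   heatmap matrices.

A fully ground-truthed synthetic-library generator (`specsig.synthetic`)
makes every stage testable offline: groups share planted diagnostic
fragments/losses with configurable noise, jitter, dropout, and decoy
overlap.

## CLI

```bash
# generate a ground-truthed synthetic library
specsig simulate --seed 42 --out lib.mgf --truth truth.json

# extract best skeleton queries (thresholds shown at their defaults)
specsig extract --library lib.mgf --min-occurrence 3 --max-signals 10 \
    --min-group 5 --min-score 0 --out queries.json

# serialize queries as MassQL and run one against a feature dataset
specsig export-massql --queries queries.json --tol 0.01 --out-dir massql/
specsig query --massql massql/skeleton-0_1.massql.txt --dataset extracts.mgf
```

The skeleton label is read from the `SKELETON` MGF header by default
(`--skeleton-key` to change it), or attached from a TSV table
(`--skeleton-table`, columns `id`/`compound_name` and `skeleton`).

## Library API

```python
import specsig as ss

library = ss.read_mgf("library.mgf")
queries = ss.extract_signatures(library, ss.ExtractionConfig())
for skeleton, qs in queries.items():
    best = qs[0]
    print(skeleton, best.f05, [s.label for s in best.signals])
    print(ss.to_massql(best, ss.Tolerance()).text)
```

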