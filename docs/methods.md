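# Methods

## Model

The package computes a convolution string kernel on protein sequences.
Residue-level similarity is a kernel `K1 = SM2^β` (entrywise power), where
`SM2(i,j) = SM(i,j)/(P(i)P(j))` normalizes a symmetric table of raw
substitution counts by its row sums `P(i)`. Writing both denominator
factors as the same row-sum function is the only reading that keeps `SM2`
symmetric, which the kernel property requires; `K1` is a valid kernel iff
`SM2` is symmetric positive definite and `β > 0`.

Sequence-level similarity sums, over every k-mer length `k` from 1 to
`p = min(k_max, n, m)`, the products of `K1` across all gap-free k-mer
pairs of the two sequences. The sum over `k` is unweighted; gaps and
weighted-degree-style weights are deliberately out of scope. The
normalized (correlation) kernel `K̂3 = K3(S,T)/√(K3(S,S)K3(T,T))` has unit
diagonal and induces the metric `D = √(2 − 2K̂3)`, bounded by `√2`.

Two implementations coexist on purpose. `k3_naive` enumerates every k-mer
pair (cost `O(nmk_max²)`) and serves as the reference oracle; the
production route `k3_recursive` uses the factorization
`K2ᵏ(u,v) = K2ᵏ⁻¹ · K1(u_k, v_k)` as a dynamic programme over start
positions (cost `O(nmk_max)`, two layers of memory). The suite asserts
agreement to 1e−9 relative on hundreds of randomized instances.

## Parameters

- **β (default 0.2)** — Hadamard exponent, unitless, any positive real.
  Small β flattens `K1` toward the all-ones matrix: in the exact β → 0
  limit `K3 = Σₖ (n−k+1)(m−k+1)` depends on the lengths only, and `K̂3 = 1`
  for any equal-length pair. That limit is *not* a kernel (the all-ones
  matrix is rank one) and is exposed only through the explicit `ones`
  matrix mode, never by silently passing a tiny β.
- **k_max (default 10)** — largest k-mer length, residues. The per-pair
  cap is `p = min(k_max, n, m)`: the sum cannot extend past the shorter
  sequence, and `k_max` truncates it for cost. Runtime grows linearly in
  `k_max`.
- **Substitution matrix** — accepted as raw counts (normalized here), as a
  ready ratio matrix, as an NCBI-format integer log-odds file
  (back-transformed entrywise by `2^BL`, flagged as approximate because of
  the rounding), or as the identity matrix (exact k-mer matching). The
  default β and k_max follow the setting recommended for fold
  recognition; β near 0.1–0.2 has been the customary choice for this
  kernel family.

## Numerical choices

- Positive definiteness is checked on the symmetric eigenvalues with a
  relative tolerance: definite iff `λ_min > 1e−8·λ_max`. The threshold is
  strictly positive so that rank-deficient matrices (the all-ones limit
  has a zero eigenvalue of multiplicity 19) are reported as not definite,
  while eigensolver backward error on a genuinely definite matrix passes.
- Accumulation is in double precision, per-k layers summed in increasing
  k; a non-finite accumulation raises instead of returning `inf`, with
  advice to lower β or k_max.
- `K̂3` values in `(1, 1 + 1e−9]` are round-off and are clamped to 1;
  values beyond that raise (a broken kernel upstream). Values within
  1e−12 *below* 1 are also snapped to 1 so that self-comparisons are
  machine-exact regardless of how `√(K3(S,S)²)` rounds.
- Nonstandard residues: `strict` (default) rejects with sequence id and
  position; `map` substitutes B→D, Z→E, J→L, U→C, O→K. `X` always errors —
  any numeric stand-in would bias the kernel silently.
- Alphabet order is fixed (ACDEFGHIKLMNPQRSTVWY) and written into every
  matrix file.

## Packaged matrix

No raw-count substitution table is shipped with the kernel's sources, so
the package includes a *synthetic* BLOSUM-like integer count matrix
(`data/synthetic_counts.txt`), generated once with a diagonally dominant
layout: dominance survives the row-sum normalization by congruence, so the
resulting `SM2` is provably positive definite. It behaves sensibly
(match/mismatch contrast ≈ 20:1 in odds, ≈ 1.8:1 after β = 0.2) but is not
derived from real alignments; substitute a real count or log-odds matrix
for production comparisons.

## Evaluation machinery

- **ROC analysis.** Pairs are ranked by distance; a sweeping threshold
  calls pairs below it positive. Pooled mode treats any same-group pair as
  positive; per-group mode restricts positives to one named group, all
  other pairs (including same-group pairs of other groups) counting
  negative. The AUC is the Mann–Whitney rank statistic with midrank tie
  handling, which the tests verify equals the trapezoidal area under the
  tie-grouped curve to 1e−9 and matches scikit-learn's implementation.
- **Pearson correlation** against externally computed per-pair scores
  (e.g. structural-alignment SAS values read from a three-column table)
  delegates to `scipy.stats.pearsonr` after validating lengths and
  variance.
- **Classification experiments.** Each repeat splits every group in half
  at random (the extra member of an odd group goes to training) and
  assigns each test sequence to the group with the smallest *arithmetic
  mean* of its (already length-normalized) kernel distances to the
  group's training members — the mean is the natural reading of a "mean
  normalized distance", as no further normalization is defined. Ties
  break to the lexicographically smallest group label, making runs
  bit-reproducible under a fixed seed. The default is 1,000 repeats
  (configurable; the tests use ≤ 100).
- **RANDOM baseline.** Symmetric iid uniform(0,1) distances; its expected
  AUC is 0.5 and its expected classification efficiency with G balanced
  groups is 1/G, which the acceptance suite verifies.

## Synthetic data

`synthdata.make_families` emulates sets of structurally related,
sequence-divergent protein families: one uniform random ancestor per
family (lengths 60–180 by default, matching single-domain proteins),
members derived by independent point substitutions (default rate 0.5 per
position) and single-residue indels (default 0.05). Members of one family
are therefore related only through the ancestor: two members at
substitution rate `s` share expected identity `(1−s)² + s²/19`, ≈ 26% at
the 0.5 default, decaying to the ≈ 5% unrelated background by rate 0.9.

What the generator does **not** emulate: real residue composition (the
background is uniform, not BLOSUM-frequency weighted), domain
architecture, secondary-structure periodicity, or the heavy-tailed length
spread of real fold classes. Passing tests therefore demonstrate the
kernel's internal consistency and its ability to recover controlled
divergence signal — not performance on real structural classifications.

## Problem sizes and known limitations

The test and acceptance workloads use 40–50 sequences of 30–300 residues,
hundreds of randomized kernel instances, and 50–100 evaluation replicates
— sizes chosen so the whole suite runs in well under a minute while still
exercising every code path at realistic sequence lengths.

At the default conditions (substitution rate 0.5, 4 families × 10
members) the pooled-AUC margin of the kernel over the RANDOM baseline is
modest — roughly 0.1–0.2 depending on the generator seed — because at
≈ 26% pairwise identity the k = 1 composition term dominates `K3` and the
discriminative long-k terms are rare. This mirrors the kernel's reported
behaviour on real remote-homolog benchmarks, where pooled AUCs around
0.6–0.76 against a 0.5 baseline are typical. Lower substitution rates
separate families sharply (AUC > 0.9 by rate 0.1).

Other limitations: cost is quadratic in sequence length per pair, so the
kernel is not suited to large database searches; scores carry no
significance estimate (no E-value analogue); gapped k-mers and weighted
sums over k are unsupported by design.
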