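# Methods

## The model

The data are a non-negative matrix of miRNA read counts, rows indexed by
miRNA (or, after condensation, by seed-sequence family) and columns by
sample library. The quantity analysed is the *relative read frequency*
rf<sub>ij</sub> = 100 · c<sub>ij</sub> / Σ<sub>i</sub> c<sub>ij</sub>,
the percent of a library's miRNA reads carried by family *i*. Read
frequencies are compositional: they are invariant to sequencing depth per
library, sum to 100 per column, and couple rows through closure (a family
that surges necessarily depresses all others in that library). Sequence
families are condensed by *summing* member frequencies — frequencies are
additive shares, so summation is the only rule that conserves the 100%
total; averaging would not.

A *bicluster* (transcription module) is a pair of signed score vectors
(r over families, c over samples), each supported on a subset and scaled
to unit max-norm, such that the pair is a fixed point of the ISA map

  c ← θ<sub>th_c</sub>(E<sub>r</sub>ᵀ r),  r ← θ<sub>th_r</sub>(E<sub>c</sub> c),

where θ<sub>t</sub> standardizes its argument to z-scores (population SD)
and zeroes entries with |z| ≤ t. Membership is soft and signed: |score| is
association strength, the sign the correlation direction, so a module may
contain mutually anti-correlated members and modules may overlap.
Samples/families outside every module simply score zero everywhere.

### Thresholding is two-sided

θ keeps entries by |z| > t and retains the signed z. A one-sided rule
could not produce the negative memberships that down-regulated modules
require (−1 meaning "maximally associated, oppositely directed"). The
inequality is strict; ties at the threshold have measure zero on real
data.

### Standardization is doubled, with prenormalization

ISA needs the matrix standardized in both directions. `row_std`
standardizes each row (each family's profile to mean 0, SD 1); `col_std`
standardizes each column *of the row-standardized matrix*, not of the raw
one. The raw frequencies span orders of magnitude between families, so
columns of the raw matrix are dominated by the static abundance profile;
column-standardizing them would make every row score measure abundance
rather than module membership (in experiments a high-abundance noise
family scored z ≈ 10 while true module rows stayed below 2). Removing the
family main effect first keeps both matrices informative; each retained
row of `row_std` and column of `col_std` still has mean 0, SD 1. Rows and
columns with zero variance are dropped from both matrices (iteratively,
since each removal can create new constants) and reported, never imputed.

### Convergence, canonical sign, deduplication

Iteration from a random sparse 0/1 seed stops when consecutive score
vectors on both sides correlate at Pearson ≥ 1 − ε (ε = 0.01) *and* have
identical supports; the support condition makes every reported module
verifiably stable under a further iteration (this is asserted for every
bicluster in the acceptance tests). Global sign flips map fixed points to
fixed points, so each bicluster is canonicalized to have positive column
score sum, and the duplicate criterion treats (r, c) and (−r, −c) as the
same module: two fixed points merge when both dense score correlations
exceed `cor_merge` = 0.9, or both fall below −0.9 with overlapping
supports (the overlap guard exists because disjoint modules in a small id
universe are trivially anti-correlated). Merged duplicates keep the
representative with the largest basin (number of converging seeds),
accumulating basin counts.

### Chance fixed points and the robustness filter

At a permissive column threshold (th_c = 1.0 retains |z| > 1, ≈ 30 % of
columns under noise) almost *every* sparse seed converges: a pair of
unrelated rows reinforces itself through the large soft column set it
selects. These chance fixed points are low-signal. Each module is scored
by its robustness

  rob(r, c) = √( max(0, rᵀE<sub>c</sub>c) · max(0, cᵀE<sub>r</sub>ᵀr) ) / (‖r‖‖c‖),

and the run is repeated with identical parameters on `n_permutations` = 3
copies of the data whose rows are independently shuffled. Modules are kept
only when their robustness exceeds 1.1 × the largest robustness any
permuted-data module achieves. The 1.1 margin exists because row
permutation destroys the compositional closure coupling between families,
which slightly strengthens chance modules on real relative-frequency data
relative to the null (measured: up to ~5 % above the null maximum, while
planted modules score ≈ 2× the null maximum — the margin sits in a wide
gap). A second, independent filter requires `min_basin` = 2: a module must
be reached from at least two independent seeds. Both filters are exposed
parameters and their settings are recorded in the run's parameter record.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_reads` | 5,000 | minimum total miRNA reads per library (inclusive: a library at exactly the threshold is kept) |
| `th_r`, `th_c` | 3.5, 1.0 | z-score thresholds for family and sample scores; higher = smaller, tighter modules |
| `n_seeds` | 300 | random sparse seeds per run; with sparsity 2 each row is expected in n_seeds·2/m seeds, and the reproducibility filter needs every true module hit at least twice |
| `sparsity` | 2 | ones per seed; larger seeds dilute single-module signal and lose modules |
| `eps` | 0.01 | convergence slack on the Pearson correlation of consecutive score vectors |
| `max_iter` | 100 | iteration cap per seed; non-converged seeds are dropped and counted |
| `cor_merge` | 0.9 | score-correlation threshold for collapsing duplicate fixed points |
| `min_basin` | 2 | minimum number of seeds that must reach a module |
| `n_permutations` | 3 | permuted-data reruns calibrating the robustness null |
| `robustness_margin` | 1.1 | safety factor on the null maximum (see above) |

A structural constraint worth knowing when choosing `th_r`: a coherent
module of k rows among m can push its rows' z-scores to at most about
√((m − k)/k), so at th_r = 3.5 and m = 200 only modules of roughly ten or
fewer families can clear the row threshold in full — consistent with
analyses at these settings reporting mostly few- or single-family
modules.

## The synthetic generator

`generate_counts` emulates a miRNA-seq cohort: family baselines are
log-normal (σ = 1.5, spanning the orders of magnitude real miRNA
abundances cover); library totals are log-uniform over a range that by
default spans the 5,000-read cut (2,000–500,000), so the depth filter is
exercised; counts are gamma-Poisson (negative binomial, dispersion 0.1,
i.e. ≈ 32 % biological CV) with an exactly-multinomial option for
conservation tests. Modules multiply their families' expected shares by
f (up) or 1/f (down) in their sample columns, with per-library
renormalization so totals stay at their designed values — which also
reproduces the closure cross-talk of real compositional data. Module rows
are drawn from the mid-upper abundance band (quantiles 0.5–0.95 of the
baseline distribution, disable-able): a module planted on families with
near-zero expected counts is undetectable at any realistic depth by any
method, the same way modules reported from real data necessarily involve
families that passed detection. `split_into_mirnas` expands families into
1–3 member miRNAs (Dirichlet-multinomial split) so the condensation step
can be tested against an exact inverse. `generate_cohort` draws
annotations with the default composition 46 % triple-negative; histology
68 % IDC, 9 % DCIS, 6 % normal, 5 % metaplastic, 3 % cell lines, 9 %
other; molecular subtype 42 % basal, 13 % luminal A, 12 % Her2, 11 %
normal, 3 % luminal B, 19 % unassigned. Receptor positivity among
non-triple-negative samples (ER 0.6, PR 0.5, Her2 0.3, redrawn if all
negative) is a plausible convention, not a fitted quantity; the three
characteristics are drawn independently, so the generator does not
reproduce real ER/subtype correlations.

What the generator does *not* emulate: isomiR structure, family-assignment
errors, batch effects, replicate merging, or correlated annotations.
Passing the recovery benchmark therefore shows the pipeline recovers clean
rectangular signed modules under realistic count noise and compositional
coupling — not that every module in a real cohort meets those
assumptions.

### Benchmark and problem sizes

The recovery benchmark plants three disjoint 8 × 12 up-regulated modules
at f = 4 in 200 × 150, library totals 10k–500k; the package recovers them
at relevance = recovery = 1.0 (median over seeds). Modules are 8 rows for
the z-ceiling reason above, and up-regulated because on the
relative-frequency scale a 1/f down-module shifts its families by only
(1 − 1/f) of their share versus (f − 1) for an up-module (measured
in-block z ≈ −1.8 vs +2.9 at f = 4): down-modules acquire diffuse sample
halos and are exercised by dedicated tests instead, which verify they are
detected with negative row memberships. Stability and fixed-point checks
run on the same scale (10 runs; 20 instances). These sizes keep the whole
suite fast while leaving each check's conclusion unchanged at larger m, n.

## Evaluation conventions

Module similarity is the Jaccard index on the union of row and column
supports (identifiers namespaced per side), so signed ISA output is
comparable with sign-free external biclusterings; a score-weighted cosine
similarity is available separately. Set-to-set comparison uses greedy
descending-Jaccard one-to-one assignment — transparent to audit and, at
these set sizes, indistinguishable from optimal assignment; relevance and
recovery are mean best-match Jaccards and do not depend on the
assignment. The stability protocol calls a configuration stable when all
runs return equally many modules and every matched pair reaches Jaccard
≥ 0.95 ("the same modules" up to score jitter and ordering). Association
tables use the two-sided Fisher exact test per (module, annotation level)
over samples with known status, odds ratios with a 0.5 Haldane correction
when a cell is empty (flagged), and Benjamini–Hochberg q-values across
all rows — labelled an extension in the output header, since the
underlying study design involves no formal test.

## Numerical notes

Population (1/n) denominators are used for every SD; ISA only needs
consistency and this keeps θ's oracle arithmetic exact. The seed-parallel
iteration is a vectorized re-expression of the per-seed loop (identical
to ~1e-15; the equivalence is tested). Bicluster files store scores to 12
significant digits and round-trip exactly. Degenerate cases: a zero-SD
score vector aborts that seed; an all-zero intermediate vector likewise;
zero converged seeds yield an empty result with a warning, not an error;
an all-below-cut library set, an unmapped miRNA at condensation, and a
zero-total library are hard errors naming the offending identifiers.

## Known limitations

* Down-regulated modules on the rf scale are intrinsically harder than
  up-regulated ones (see above); their sample supports include weakly
  scored halo columns at th_c = 1.0.
* The robustness null (independent row shuffles) under-represents
  compositional coupling; the 1.1 margin is a calibrated correction, not
  a theoretical one.
* Greedy assignment can in principle be suboptimal for large, heavily
  overlapping module sets.
* The GEO series-matrix reader expects integer count tables; series
  distributed as normalized expression require external preparation.
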