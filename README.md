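# mirbiclust

Biclustering of miRNA read-count profiles with the Iterative Signature
Algorithm (ISA), for studies that ask which *groups of miRNAs (or miRNA
sequence families) are co-deregulated in which subsets of samples* — e.g.
tumour cohorts where a module of oncogenic miRNAs is over-expressed only in
the triple-negative patients. Ordinary clustering groups miRNAs over *all*
samples at once; biclustering finds the local structure, allows modules to
overlap, and can legitimately report a single miRNA family tied to a
well-defined patient subgroup.

The package provides the full pipeline around the algorithm:

1. **Preprocessing** — drop libraries with fewer than 5,000 total miRNA
   reads, convert counts to relative-percent read frequencies
   (rf<sub>ij</sub> = 100 · c<sub>ij</sub> / Σ<sub>i</sub> c<sub>ij</sub>),
   condense miRNAs into seed-sequence families (`sf-` rows), and
   standardize.
2. **ISA** — from random sparse 0/1 seed vectors r₀ over the rows,
   alternate thresholded projections
   c = θ<sub>th_c</sub>(E<sub>r</sub>ᵀ r) and
   r = θ<sub>th_r</sub>(E<sub>c</sub> c),
   where θ<sub>t</sub> z-scores its argument and keeps entries with
   |z| > t, until consecutive score vectors agree (Pearson ≥ 1 − ε with
   fixed supports). Each fixed point is a bicluster with signed soft
   memberships in [−1, +1]; chance fixed points are removed by a
   permutation-calibrated robustness filter plus a ≥2-seed reproducibility
   requirement. Defaults th_r = 3.5, th_c = 1.0.
3. **Validation** — stability across random initializations, consensus
   matching against an external biclustering (e.g. SAMBA output
   re-expressed in the bicluster file dialect), and
   bicluster-versus-phenotype Fisher-exact association tables
   (ER/PR/Her2 status, TNBC, histology, molecular subtype).
4. **Synthetic data** — a planted-module generator (over-dispersed count
   libraries, long-tailed family abundances, signed rectangular modules)
   and a cohort-annotation generator, so every stage is testable without
   any external download.

## Worked example

```python
from mirbiclust import isa, preprocess, synthetic

design = synthetic.benchmark_design(seed=0)   # 200 families x 150 samples,
counts, truth = synthetic.generate_counts(design)  # three 8x12 modules, f=4
prep = preprocess.run_preprocessing(counts)   # filter -> rf -> standardize
found = isa.run_isa(prep.standardized, seed=0)
print(synthetic.recovery_score(found, truth))
```

prints (see `examples/01_recover_planted_modules.py`):

```
planted modules: 3, found: 3
  BC1: 8 families x 12 samples, reached from 18 seeds
  BC2: 8 families x 12 samples, reached from 19 seeds
  BC3: 8 families x 12 samples, reached from 16 seeds
relevance=1.000 recovery=1.000
```

Relevance is the mean best-match Jaccard (on the union of row and column
supports) of found modules into the planted truth; recovery the reverse.
1.000/1.000 means the three planted modules were re-discovered exactly,
with no spurious extras. The other scripts in `examples/` walk through the
preprocessing stages, the ten-run stability protocol, phenotype
association (the perfectly TNBC-separated module prints the two-sided
Fisher p = 2/C(10,5) ≈ 0.0079) and consensus matching.

## Command line

The same pipeline as a shell tool:

```sh
mirbiclust simulate  -o sim --seed 5 --benchmark
mirbiclust run       -o run --counts sim/counts.tsv \
                     --family-map sim/family_map.tsv --seed 5
mirbiclust evaluate  -o eval --counts sim/counts.tsv \
                     --family-map sim/family_map.tsv \
                     --metadata sim/metadata.tsv \
                     --external sim/truth_biclusters.txt --n-runs 10
mirbiclust heatmap   run/sample_membership.tsv heatmap.png
```

`run` writes the biclusters (a diff-able structured-text file that
round-trips exactly), both membership matrices as TSV, and a
samples-×-biclusters heatmap restricted to samples belonging to at least
one module (with a companion TSV of the exact plotted values). Every
command echoes its fully resolved configuration to `config.yaml` next to
its outputs; re-running from that file reproduces the outputs
byte-for-byte.

### Analysing a real cohort

For a real study — for instance a breast-cancer miRNA-seq cohort whose
expression table you have downloaded from GEO as a series-matrix file and
whose miRNA→family table comes from the study's supplementary material —
the documented route is:

```sh
python -c "from mirbiclust import io; io.write_count_matrix(
    io.read_geo_series_matrix('GSExxxx_series_matrix.txt'), 'counts.tsv')"
mirbiclust run -o real --counts counts.tsv --family-map families.tsv \
               --th-r 3.5 --th-c 1.0 --seed 0
```

Nothing in the package performs network access; the reader parses a local
file. Exact reproduction of any published module set additionally depends
on algorithm settings (seed count, deduplication rule) that publications
rarely state; all of them are exposed as options and recorded in the
output.

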