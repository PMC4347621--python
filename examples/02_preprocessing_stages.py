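"""The data-preparation stages, one by one, on a small simulated cohort:
depth filter, relative-percent read frequencies, sequence-family
condensation, and double standardization.

Run:  python examples/02_preprocessing_stages.py
"""

import numpy as np

from mirbiclust import preprocess, synthetic
from mirbiclust.synthetic import PlantedDesign

design = PlantedDesign(m=40, n=25, library_total_range=(2_000, 50_000), seed=1)
family_counts, _ = synthetic.generate_counts(design)
# expand families into member miRNAs (what a real count table looks like)
counts, family_map = synthetic.split_into_mirnas(
    family_counts, np.random.default_rng(1)
)
print(f"raw: {counts.shape[0]} miRNAs x {counts.shape[1]} libraries, "
      f"totals {counts.library_totals().min()}-{counts.library_totals().max()}")

kept = preprocess.filter_libraries(counts, min_reads=5000)
print(f"after 5,000-read filter: {kept.shape[1]} libraries "
      f"({counts.shape[1] - kept.shape[1]} dropped)")

freq = preprocess.to_read_frequencies(kept)
print(f"read frequencies: every column sums to "
      f"{freq.values.sum(axis=0).round(9).max()}%")

fam = preprocess.condense_families(freq, family_map)
print(f"condensed {freq.shape[0]} miRNAs into {fam.shape[0]} families "
      f"(column sums still {fam.values.sum(axis=0).round(9).max()}%)")

sp = preprocess.standardize(fam)
print(f"standardized: rows mean {sp.row_std.to_numpy().mean(axis=1).max():.1e}, "
      f"SD {sp.row_std.to_numpy().std(axis=1).mean():.6f}")
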