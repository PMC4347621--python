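"""Consensus matching against an externally produced biclustering (e.g.
SAMBA output re-expressed in the bicluster file dialect): pairwise support
Jaccard, greedy one-to-one assignment, relevance and recovery.

Run:  python examples/05_consensus_with_external.py
"""

import tempfile
from pathlib import Path

from mirbiclust import evaluate, io, isa, preprocess, synthetic

design = synthetic.benchmark_design(seed=0)
counts, truth = synthetic.generate_counts(design)
sp = preprocess.run_preprocessing(counts).standardized
ours = isa.run_isa(sp, seed=0)

# stand-in for an external result: the planted truth written to the
# bicluster file dialect and read back, exactly how SAMBA output would be
# ingested after re-expression in this format
with tempfile.TemporaryDirectory() as d:
    external_file = Path(d) / "external_biclusters.txt"
    io.write_biclusters(truth, external_file)
    external = io.read_biclusters(external_file)

match = evaluate.match_biclusters(ours, external)
print("pairwise support Jaccard (ours x external):")
print(match.jaccard.round(2).to_string())
print(f"relevance={match.relevance:.3f} recovery={match.recovery:.3f}")
# relevance: every one of our modules appears in the external set;
# recovery: every external module was also found by us.
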