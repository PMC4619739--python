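"""Coincidence ratios of ranked candidates against a reference gene list.

The synthetic fixture writes a reference list containing 60% of the true
candidates plus random decoys — a stand-in for a differential-expression hit
list.  Binning the ranked candidates shows the overlap concentrating at the
top of the level-2 ranking.
"""

import tempfile

from level2ppi import (
    SimConfig,
    classify_and_rank,
    coincidence_profile,
    emit_fixture_files,
    score_all,
    simulate,
)
from level2ppi.io import read_gene_list

truth = simulate(SimConfig(rng_seed=7))
seeds = truth.seed_genes.as_set()
records = classify_and_rank(score_all(truth.network, seeds), seeds)

with tempfile.TemporaryDirectory() as d:
    paths = emit_fixture_files(truth, d, rng_seed=7)
    reference = read_gene_list(paths["reference"])

profile = coincidence_profile(records, reference, bin_edges=[14, 76])
print("rank bin".ljust(12), "candidates", "in reference", "coincidence", sep="\t")
for b in profile.bins:
    hi = b.rank_hi or "end"
    ratio = f"{b.coincidence_ratio:.1%}" if b.coincidence_ratio is not None else "NA"
    print(f"{b.rank_lo}-{hi}".ljust(12), b.n_candidates, b.n_overlapping, ratio, sep="\t")

# Top-ranked candidates coincide with the reference list far more often than
# low-ranked ones: rank by indirect score carries the signal.
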