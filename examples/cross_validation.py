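"""Holdout cross-validation on a planted-module network.

Generates a synthetic network in which seed genes and 30 "true candidate"
genes share hub interactors (but never interact directly), then repeatedly
deletes 5 seeds, rescores, and compares the held-out genes' mean score with
the candidate background's.  A ratio above 1 means the network would have
re-discovered the deleted disease genes.
"""

from level2ppi import SimConfig, holdout_cv, simulate

truth = simulate(SimConfig(rng_seed=7))  # 500 background, 20 seeds, 15 hubs
res = holdout_cv(truth.network, truth.seed_genes.as_set(), k=5, n_reps=100, rng_seed=1)

print(f"replicates           : {res.n_replicates} (k={res.k_deleted} deleted each)")
print(f"mean ratio, level-1  : {res.mean_ratio_level1:.2f}")
print(f"mean ratio, level-2  : {res.mean_ratio_level2:.2f}")
print(f"paired t-test        : t={res.paired_t_stat:.1f}, p={res.paired_p:.2e}")

# The level-2 (common-interactor) ratio is far above both 1 and the level-1
# ratio: indirect interactions recover held-out disease genes much better
# than direct ones on this module structure.
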