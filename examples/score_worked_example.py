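"""Score the six-gene worked example and rank its candidates.

Seed gene A interacts directly with B, C and D.  Gene F never touches A but
shares all three of A's partners; gene E shares one.  The direct score counts
seed neighbors, the indirect score counts length-2 paths to seeds.
"""

from level2ppi import classify_and_rank, score_all, toy_network

net, seeds = toy_network()
scores = score_all(net, seeds)
records = classify_and_rank(scores, seeds)

print(f"{'gene':<6}{'direct':>8}{'indirect':>10}  membership")
for r in records:
    kind = "level-2 only" if r.level2_only else ("level-1" if r.level1_member else "-")
    print(f"{r.gene:<6}{r.direct_score:>8}{r.indirect_score:>10}  {kind}")

# F tops the ranking with indirect score 3: it shares three common
# interactors with the seed, despite having no direct seed interaction.
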