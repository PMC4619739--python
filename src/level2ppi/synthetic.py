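"""Synthetic PPI networks with a planted level-2 module.

The generator emulates the structure the scoring method exploits: a set of
disease (seed) genes and a set of "true candidate" genes that never interact
directly but share hub interactors, embedded in a random background.  Edge
probabilities by node-role pair:

* seed-seed: ``seed_edge_prob`` — seeds do interact among themselves in real
  disease networks (a majority of positives typically have at least one
  direct positive partner), and the holdout cross-validation's eligible pool
  is defined by such links;
* hub-seed and hub-true-candidate: ``attach_prob`` (the planted module);
* seed-true-candidate: never — true candidates are level-2-only by
  construction;
* every other pair: ``edge_prob`` (Erdős–Rényi background; background model
  deliberately has no degree heterogeneity beyond the planted hubs).

Gene symbols are generated as G000001, G000002, ... to avoid collisions with
real symbols.  Everything is reproducible from ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import GeneList, GeneSetCollection, write_gmt
from .network import build_network

_ROLE_BG, _ROLE_SEED, _ROLE_HUB, _ROLE_TC = 0, 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-module generator.

    ``n_background`` random genes plus ``n_seeds`` seeds, ``n_hubs`` hubs and
    ``n_true_candidates`` planted candidates.  Probabilities as documented in
    the module docstring.
    """

    n_background: int = 500
    edge_prob: float = 0.01
    n_seeds: int = 20
    n_hubs: int = 15
    n_true_candidates: int = 30
    attach_prob: float = 0.6
    seed_edge_prob: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_background", "n_seeds", "n_hubs", "n_true_candidates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("edge_prob", "attach_prob", "seed_edge_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_background + self.n_seeds + self.n_hubs + self.n_true_candidates < 1:
            raise ValueError("configuration generates no nodes")


@dataclass
class SimTruth:
    """Generated network plus ground-truth role lists (mutually disjoint)."""

    seed_genes: GeneList
    hub_genes: GeneList
    true_candidate_genes: GeneList
    network: nx.Graph
    config: SimConfig
    all_genes: list[str] = field(default_factory=list)


def _pair_prob(config: SimConfig) -> np.ndarray:
    """4x4 role-pair edge-probability lookup (symmetric)."""
    p = np.full((4, 4), config.edge_prob)
    p[_ROLE_SEED, _ROLE_SEED] = config.seed_edge_prob
    p[_ROLE_SEED, _ROLE_TC] = p[_ROLE_TC, _ROLE_SEED] = 0.0
    p[_ROLE_SEED, _ROLE_HUB] = p[_ROLE_HUB, _ROLE_SEED] = config.attach_prob
    p[_ROLE_TC, _ROLE_HUB] = p[_ROLE_HUB, _ROLE_TC] = config.attach_prob
    return p


def simulate(config: SimConfig) -> SimTruth:
    """Generate a planted-module network, reproducibly from ``config.rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    roles = np.concatenate(
        [
            np.full(config.n_background, _ROLE_BG, dtype=np.int8),
            np.full(config.n_seeds, _ROLE_SEED, dtype=np.int8),
            np.full(config.n_hubs, _ROLE_HUB, dtype=np.int8),
            np.full(config.n_true_candidates, _ROLE_TC, dtype=np.int8),
        ]
    )
    n = len(roles)
    names = [f"G{i + 1:06d}" for i in range(n)]
    prob = _pair_prob(config)

    edges: list[tuple[str, str]] = []
    for i in range(n - 1):
        p_row = prob[roles[i], roles[i + 1 :]]
        hits = np.nonzero(rng.random(n - i - 1) < p_row)[0]
        for j in hits:
            edges.append((names[i], names[i + 1 + int(j)]))

    net = build_network(edges)
    lo = config.n_background
    return SimTruth(
        seed_genes=GeneList("seeds", names[lo : lo + config.n_seeds]),
        hub_genes=GeneList(
            "hubs", names[lo + config.n_seeds : lo + config.n_seeds + config.n_hubs]
        ),
        true_candidate_genes=GeneList(
            "true_candidates", names[lo + config.n_seeds + config.n_hubs :]
        ),
        network=net,
        config=config,
        all_genes=names,
    )


#: Edges of the minimal worked example: seed A with direct partners B, C, D;
#: F shares all three of A's partners (indirect score 3), E shares one
#: (indirect score 1), and neither E nor F touches A directly.
TOY_EDGES: tuple[tuple[str, str], ...] = (
    ("A", "B"),
    ("A", "C"),
    ("A", "D"),
    ("E", "B"),
    ("F", "B"),
    ("F", "C"),
    ("F", "D"),
)


def toy_network() -> tuple[nx.Graph, set[str]]:
    """The six-gene worked-example network and its seed set ``{A}``."""
    return build_network(TOY_EDGES), {"A"}


def emit_fixture_files(
    truth: SimTruth,
    out_dir: str | Path,
    reference_fraction: float = 0.6,
    n_decoys: int = 50,
    n_random_sets: int = 9,
    random_set_size: int = 25,
    rng_seed: int = 0,
) -> dict[str, Path]:
    """Write the generated data as the exact file formats the readers accept.

    Produces a generic edge list, the same edges in the HPRD flat-file
    dialect, the seed list, a reference list containing ``reference_fraction``
    of the true candidates plus random decoy genes (a differential-expression
    stand-in), a GMT whose first set is the planted pathway (seeds plus true
    candidates) followed by random sets, and a JSON manifest recording the
    generating configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)
    paths: dict[str, Path] = {}

    edges = sorted(tuple(sorted(e)) for e in truth.network.edges)
    paths["edges"] = out / "edges.tsv"
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic PPI edge list (generic 2-column dialect)\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")

    paths["edges_hprd"] = out / "edges_hprd.txt"
    with open(paths["edges_hprd"], "w", encoding="utf-8") as fh:
        for i, (a, b) in enumerate(edges, start=1):
            # symbols in columns 1 and 4, filler ids elsewhere
            fh.write(
                f"{a}\t{i:05d}\tNP_{i:06d}\t{b}\t{i + 1:05d}\t"
                f"NP_{i + 1:06d}\tin vivo\t{10000000 + i}\n"
            )

    paths["seeds"] = out / "seeds.txt"
    with open(paths["seeds"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic positive (seed) genes\n")
        fh.writelines(g + "\n" for g in truth.seed_genes)

    tc = truth.true_candidate_genes.genes
    n_keep = int(round(reference_fraction * len(tc)))
    kept = list(rng.choice(tc, size=n_keep, replace=False)) if n_keep else []
    decoy_pool = [
        g
        for g in truth.all_genes
        if g not in truth.seed_genes.as_set()
        and g not in truth.true_candidate_genes.as_set()
    ]
    n_decoys = min(n_decoys, len(decoy_pool))
    decoys = list(rng.choice(decoy_pool, size=n_decoys, replace=False))
    reference = sorted(set(kept) | set(decoys))
    paths["reference"] = out / "reference.txt"
    with open(paths["reference"], "w", encoding="utf-8") as fh:
        fh.write("# synthetic reference gene list (e.g. DE-gene stand-in)\n")
        fh.writelines(g + "\n" for g in reference)

    sets: dict[str, tuple[str, set[str]]] = {
        "PLANTED_MODULE": (
            "seeds and true candidates of the planted module",
            truth.seed_genes.as_set() | truth.true_candidate_genes.as_set(),
        )
    }
    universe = np.array(truth.all_genes)
    for i in range(1, n_random_sets + 1):
        size = min(random_set_size, len(universe))
        members = set(rng.choice(universe, size=size, replace=False))
        sets[f"RANDOM_SET_{i:03d}"] = (f"random gene set {i}", members)
    paths["gmt"] = out / "genesets.gmt"
    write_gmt(GeneSetCollection(sets=sets), paths["gmt"])

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": asdict(truth.config),
                "reference_fraction": reference_fraction,
                "n_decoys": n_decoys,
                "n_random_sets": n_random_sets,
                "fixture_rng_seed": rng_seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
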