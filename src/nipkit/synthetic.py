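"""Synthetic proteomes, interaction networks and localizations.

The generator produces self-contained worlds with the statistical
structure the pipeline's assumptions rest on:

* **sequence families** — proteins derived from a few random ancestors by
  seeded point mutation, giving a spread of pairwise similarities with
  clear within/between-family contrast;
* **skewed degrees** — interaction edges sampled by preferential
  attachment, so a few hub proteins dominate, as in curated PPI networks;
* **similarity coupling** — the planted edge probability increases with
  sequence similarity, P(edge i,j) proportional to
  (d_i + 1) (d_j + 1) exp(coupling * s(i,j)), which is the signal the
  similarity-based negative strategy and the downstream classifier
  exploit;
* **partial observation** — the "observed" positive set is a seeded
  subsample of the planted true interactome, so random-pairing negatives
  can be contaminated by true-but-unobserved interactions while
  low-similarity negatives largely cannot.

Compartment labels emulate seven-way subcellular localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import InteractionSet, Protein, ProteinSet
from .similarity import SimilarityTable, pairwise_similarity

RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

COMPARTMENTS = (
    "cytoplasm",
    "nucleus",
    "mitochondrion",
    "endoplasmic_reticulum",
    "golgi_apparatus",
    "peroxisome",
    "vacuole",
)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world.

    ``length_range`` stays above 51 so every generated protein passes the
    default minimum-length filter and satisfies the lag-30 encoder
    precondition.  ``similarity_coupling`` > 0 plants the dependence of
    interaction probability on sequence similarity; 0 gives a pure
    preferential-attachment network.  ``observed_fraction`` is the share
    of planted true edges that are "observed" as the positive set.
    """

    n_proteins: int = 120
    length_range: tuple[int, int] = (60, 400)
    n_families: int = 6
    within_family_mutation_rate: float = 0.05
    n_positive_edges: int = 500
    similarity_coupling: float = 4.0
    n_compartments: int = 7
    observed_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_families, self.n_positive_edges,
               self.n_compartments) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.within_family_mutation_rate <= 1:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.length_range[0] < 51:
            raise ValueError("minimum sequence length must be >= 51")
        if not 0 < self.observed_fraction <= 1:
            raise ValueError("observed_fraction must be in (0, 1]")
        max_edges = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_positive_edges > max_edges:
            raise ValueError(
                f"n_positive_edges={self.n_positive_edges} exceeds the "
                f"{max_edges} possible pairs"
            )


def _mutate(rng: np.random.Generator, sequence: np.ndarray, rate: float
            ) -> np.ndarray:
    out = sequence.copy()
    hits = rng.random(len(out)) < rate
    out[hits] = rng.choice(RESIDUES, size=int(hits.sum()))
    return out


def generate_proteome(config: SyntheticConfig) -> ProteinSet:
    """Random ancestors, one per family; members by point mutation."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    ancestors = [
        rng.choice(RESIDUES, size=int(rng.integers(lo, hi + 1)))
        for _ in range(config.n_families)
    ]
    width = len(str(config.n_proteins - 1))
    proteins = ProteinSet()
    for i in range(config.n_proteins):
        family = i % config.n_families
        seq = _mutate(rng, ancestors[family],
                      config.within_family_mutation_rate)
        proteins.add(Protein(f"P{i:0{width}d}", "".join(seq)))
    return proteins


def generate_network(
    proteins: ProteinSet,
    config: SyntheticConfig,
    sim: SimilarityTable | None = None,
) -> InteractionSet:
    """Planted interactome: similarity-coupled preferential attachment.

    Edges are drawn sequentially; at each step the probability of the
    non-edge (i, j) is proportional to (d_i + 1)(d_j + 1) *
    exp(coupling * s(i, j)) with d the current degree.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = proteins.ids
    n = len(ids)
    if config.similarity_coupling != 0:
        if sim is None:
            sim = pairwise_similarity(proteins)
        order = [sim.ids.index(pid) for pid in ids]
        s = sim.symmetrized[np.ix_(order, order)]
        base = np.exp(config.similarity_coupling * s)
    else:
        base = np.ones((n, n))
    iu = np.triu_indices(n, k=1)
    weights = base[iu].astype(float)
    degrees = np.zeros(n)
    chosen = np.zeros(len(weights), dtype=bool)
    edges: list[tuple[str, str]] = []
    for _ in range(config.n_positive_edges):
        w = weights * (degrees[iu[0]] + 1) * (degrees[iu[1]] + 1)
        w[chosen] = 0.0
        total = w.sum()
        if total == 0:
            raise RuntimeError("no remaining candidate edges")
        t = rng.choice(len(w), p=w / total)
        chosen[t] = True
        i, j = int(iu[0][t]), int(iu[1][t])
        degrees[i] += 1
        degrees[j] += 1
        edges.append((ids[i], ids[j]))
    return InteractionSet(edges, label="positive")


def observed_positives(
    planted: InteractionSet, config: SyntheticConfig
) -> InteractionSet:
    """Seeded subsample of the planted interactome (the 'known' PPIs)."""
    pairs = sorted(planted.pairs)
    rng = np.random.default_rng(config.seed + 2)
    n_obs = max(1, int(round(config.observed_fraction * len(pairs))))
    idx = rng.choice(len(pairs), size=n_obs, replace=False)
    return InteractionSet([pairs[i] for i in sorted(idx)], label="positive")


def generate_localizations(
    proteins: ProteinSet, config: SyntheticConfig
) -> dict[str, str]:
    """Roughly balanced seeded assignment to compartments."""
    if config.n_compartments < 2:
        raise ValueError("need at least 2 compartments")
    names = [
        COMPARTMENTS[i] if i < len(COMPARTMENTS) else f"compartment_{i}"
        for i in range(config.n_compartments)
    ]
    rng = np.random.default_rng(config.seed + 3)
    ids = proteins.ids
    assignment = np.array(
        [names[i % len(names)] for i in range(len(ids))], dtype=object
    )
    rng.shuffle(assignment)
    return {pid: str(c) for pid, c in zip(ids, assignment)}


def generate_world(config: SyntheticConfig) -> dict:
    """Generate all fixtures at once.

    Returns a dict with the proteome, its similarity table, the planted
    and observed interactomes, and the localization table.
    """
    proteins = generate_proteome(config)
    sim = pairwise_similarity(proteins) if config.similarity_coupling != 0 else None
    planted = generate_network(proteins, config, sim=sim)
    observed = observed_positives(planted, config)
    localizations = generate_localizations(proteins, config)
    return {
        "proteins": proteins,
        "similarity": sim,
        "planted": planted,
        "observed": observed,
        "localizations": localizations,
    }
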