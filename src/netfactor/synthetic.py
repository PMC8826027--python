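"""Synthetic PPI networks with planted complexes, and expression/phenotype
data driven by latent complex activities.

The generator emulates the statistical structure the modelling pipeline
assumes: dense protein complexes planted inside a sparse background
interaction graph, gene expression produced as linear readouts of latent
per-complex activities, and phenotype classes that shift those activities.
It exists so the whole pipeline — induction, complex discovery, factor-graph
construction, training, evaluation, attribution — is testable without any
download.

All randomness flows from a single seed through a split-stream scheme
(``numpy.random.SeedSequence(seed).spawn(4)``: membership, topology, class
structure/latents, noise/labels), so each sub-generator is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .io import Clustering, ExpressionDataset

__all__ = ["SyntheticSpec", "generate_planted_network",
           "generate_expression_phenotype", "generate_dataset"]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic benchmark.

    Defaults: 300 genes carrying 12 planted complexes of 6–15 members each,
    within-complex edge probability 0.9 against a 0.01 background, a quarter
    of complexes sharing a gene with an earlier one, 400 samples in 3
    balanced classes whose means shift the latent complex activities with
    scale 2, gene-level Gaussian noise of SD 0.5.
    """

    n_genes: int = 300
    n_complexes: int = 12
    complex_size_range: tuple = (6, 15)
    p_in: float = 0.9
    p_out: float = 0.01
    overlap_fraction: float = 0.25
    activity_loading_scale: float = 1.0
    noise_sd: float = 0.5
    n_classes: int = 3
    n_samples: int = 400
    class_effect_scale: float = 2.0
    seed: int = 0

    def validate(self):
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ValueError("complex sizes must be >= 2 and ordered")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_samples < self.n_classes * 2:
            raise ValueError("need at least 2 samples per class")
        if self.noise_sd < 0 or self.class_effect_scale < 0:
            raise ValueError("scales must be non-negative")

    def streams(self):
        return np.random.SeedSequence(self.seed).spawn(4)


def _gene_names(n: int) -> list:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def generate_planted_network(spec: SyntheticSpec):
    """Background random graph with planted dense complexes.

    Genes are assigned to complexes first (a fraction of complexes reuse one
    already-assigned gene to create overlap); every within-complex pair is
    then connected with probability ``p_in`` and every other pair with
    ``p_out``. Returns the graph and the planted membership as the
    ground-truth clustering.
    """
    spec.validate()
    member_ss, edge_ss, _, _ = spec.streams()
    rng = np.random.default_rng(member_ss)
    genes = _gene_names(spec.n_genes)

    lo, hi = spec.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_complexes)
    n_overlapping = int(round(spec.overlap_fraction * max(spec.n_complexes - 1,
                                                          0)))
    overlapping = set(
        rng.choice(np.arange(1, spec.n_complexes), size=n_overlapping,
                   replace=False).tolist()
    ) if n_overlapping else set()
    fresh_needed = int(sizes.sum()) - len(overlapping)
    if fresh_needed > spec.n_genes:
        raise ValueError(
            f"complex sizes need {fresh_needed} distinct genes but only "
            f"{spec.n_genes} are available"
        )

    unassigned = list(genes)
    assigned = []
    clusters = []
    for i, size in enumerate(sizes):
        members = []
        if i in overlapping and assigned:
            members.append(assigned[int(rng.integers(len(assigned)))])
            size -= 1
        picks = rng.choice(len(unassigned), size=int(size), replace=False)
        chosen = [unassigned[j] for j in sorted(picks, reverse=True)]
        for j in sorted(picks, reverse=True):
            unassigned.pop(j)
        members.extend(chosen)
        assigned.extend(chosen)
        clusters.append((f"true_{i + 1}", frozenset(members)))

    within = set()
    for _, members in clusters:
        within.update(frozenset(p) for p in combinations(sorted(members), 2))

    rng_e = np.random.default_rng(edge_ss)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    all_pairs = list(combinations(genes, 2))
    draws = rng_e.random(len(all_pairs))
    for (a, b), r in zip(all_pairs, draws):
        p = spec.p_in if frozenset((a, b)) in within else spec.p_out
        if r < p:
            graph.add_edge(a, b)
    return graph, Clustering(clusters=clusters, algorithm="planted")


def generate_expression_phenotype(spec: SyntheticSpec,
                                  ground_truth: Clustering
                                  ) -> ExpressionDataset:
    """Expression driven by latent complex activities, labels from class-
    specific activity means.

    Per sample with class y, the latent activity of complex i is
    z_i ~ N(mu[y, i], 1) with class means drawn once at scale
    ``class_effect_scale``. A member gene reads x_g = Σ_i loading · z_i over
    its complexes plus N(0, noise_sd) noise; unassigned genes are pure
    noise. Labels are balanced across classes and shuffled.
    """
    spec.validate()
    _, _, latent_ss, noise_ss = spec.streams()
    rng = np.random.default_rng(latent_ss)
    rng_n = np.random.default_rng(noise_ss)
    genes = _gene_names(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    m, l = spec.n_samples, len(ground_truth)

    per_class = m // spec.n_classes
    labels = np.array(
        [f"class_{c}" for c in range(spec.n_classes) for _ in range(per_class)]
        + [f"class_{c}" for c in range(m - per_class * spec.n_classes)],
        dtype=object,
    )
    rng_n.shuffle(labels)
    class_idx = np.asarray([int(lab.split("_")[1]) for lab in labels])

    mu = rng.normal(0.0, spec.class_effect_scale, size=(spec.n_classes, l))
    z = mu[class_idx] + rng.normal(0.0, 1.0, size=(m, l))

    values = (rng_n.normal(0.0, spec.noise_sd, size=(m, spec.n_genes))
              if spec.noise_sd > 0 else np.zeros((m, spec.n_genes)))
    for i, (_, members) in enumerate(ground_truth):
        cols = [gene_pos[g] for g in sorted(members)]
        values[:, cols] += spec.activity_loading_scale * z[:, [i]]

    return ExpressionDataset(
        values=values,
        gene_names=genes,
        sample_ids=[f"s{j:04d}" for j in range(1, m + 1)],
        labels=labels,
        classes=[f"class_{c}" for c in range(spec.n_classes)],
    )


def generate_dataset(spec: SyntheticSpec):
    """Convenience: (network, ground-truth clustering, expression dataset)."""
    graph, truth = generate_planted_network(spec)
    dataset = generate_expression_phenotype(spec, truth)
    return graph, truth, dataset
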