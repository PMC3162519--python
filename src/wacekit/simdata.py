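"""Synthetic data with the structure the inference stages assume.

Two generators:

* :func:`simulate_study` emulates a two-group expression study in which
  copy-number events act in cis on the genes they cover: baseline
  expression is i.i.d. Gaussian noise, and every gene inside a planted
  amplified (deleted) segment has its case-group mean shifted up (down)
  by an effect size expressed in pooled-standard-deviation units, so
  detection power is platform-independent. Gene positions default to a
  uniform 100 kb grid, which keeps index-space and bp-space smoothing
  equivalent.

* :func:`simulate_dag_expression` builds a hub-structured DAG (root
  regulators each parenting a block of children, plus sparse extra
  edges among non-hubs) and draws linear-Gaussian expression from it,
  providing ground truth for structure learning and driver calling.

Both are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesnet import DirectedNetwork
from .io import ExpressionStudy
from .wace import GAIN, LOSS

__all__ = [
    "SimConfig",
    "PlantedSegment",
    "simulate_study",
    "simulate_dag_expression",
]


@dataclass
class PlantedSegment:
    """Ground-truth planted CNV segment (gene-index span is inclusive)."""

    chromosome: str
    start_gene: int  # index within the chromosome
    end_gene: int
    sign: str
    delta: float
    gene_ids: list = field(default_factory=list)
    start_bp: int = 0
    end_bp: int = 0


@dataclass
class SimConfig:
    """Study-level simulation settings.

    Defaults describe a desk-scale two-group microarray study: 5,000 genes
    on 20 equally sized chromosomes at uniform 100 kb spacing, 50 samples
    per outcome group, unit noise. ``segments`` entries are
    ``(chromosome, (start_gene, end_gene), sign, delta)`` with delta in
    pooled-sd units; ``covariate_effects`` entries are
    ``(name, coefficient)`` and add ``coefficient * value`` of a standard
    normal per-sample covariate to every gene.
    """

    n_genes: int = 5000
    n_samples_per_group: int = 50
    n_chromosomes: int = 20
    bp_spacing: int = 100_000
    segments: list = field(default_factory=list)
    noise_sd: float = 1.0
    covariate_effects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")

    def genes_per_chromosome(self) -> dict[str, int]:
        base = self.n_genes // self.n_chromosomes
        extra = self.n_genes % self.n_chromosomes
        return {
            f"chr{i + 1}": base + (1 if i < extra else 0)
            for i in range(self.n_chromosomes)
        }


def _validate_segments(config: SimConfig) -> None:
    sizes = config.genes_per_chromosome()
    by_chrom: dict[str, list] = {}
    for chrom, (a, b), sign, delta in config.segments:
        if sign not in (GAIN, LOSS):
            raise ValueError(f"segment sign must be 'gain' or 'loss', got {sign!r}")
        if delta <= 0:
            raise ValueError("segment effect size delta must be > 0")
        if chrom not in sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= a <= b < sizes[chrom]):
            raise ValueError(f"segment span ({a}, {b}) outside {chrom} (size {sizes[chrom]})")
        by_chrom.setdefault(chrom, []).append((a, b, sign))
    for chrom, segs in by_chrom.items():
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                a1, b1, s1 = segs[i]
                a2, b2, s2 = segs[j]
                if a1 <= b2 and a2 <= b1 and s1 != s2:
                    raise ValueError(
                        f"overlapping opposite-sign segments on {chrom}: "
                        f"({a1},{b1},{s1}) vs ({a2},{b2},{s2})"
                    )


def simulate_study(config: SimConfig) -> tuple[ExpressionStudy, list[PlantedSegment]]:
    """Generate a case/control study with planted cis-acting CNV segments.

    Baseline expression is N(0, noise_sd^2) i.i.d.; genes in a gain (loss)
    segment get +delta (-delta), in pooled-sd units, added to the case
    group. Returns the study (cases labelled 1) and the ground-truth
    segment list with gene IDs and bp extents filled in.
    """
    _validate_segments(config)
    rng = np.random.default_rng(config.seed)
    n_per = config.n_samples_per_group
    n_samples = 2 * n_per
    sizes = config.genes_per_chromosome()

    gene_ids, chroms, positions = [], [], []
    offsets: dict[str, int] = {}
    row = 0
    for chrom, size in sizes.items():
        offsets[chrom] = row
        for i in range(size):
            gene_ids.append(f"g_{chrom}_{i:04d}")
            chroms.append(chrom)
            positions.append((i + 1) * config.bp_spacing)
        row += size

    X = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    case_cols = np.arange(n_per)  # cases first, then controls

    truth: list[PlantedSegment] = []
    for chrom, (a, b), sign, delta in config.segments:
        lo = offsets[chrom] + a
        hi = offsets[chrom] + b + 1
        shift = delta * config.noise_sd * (1 if sign == GAIN else -1)
        X[lo:hi][:, case_cols] += shift
        truth.append(
            PlantedSegment(
                chromosome=chrom,
                start_gene=a,
                end_gene=b,
                sign=sign,
                delta=delta,
                gene_ids=gene_ids[lo:hi],
                start_bp=positions[lo],
                end_bp=positions[hi - 1],
            )
        )

    samples = [f"case_{i:03d}" for i in range(n_per)] + [f"ctrl_{i:03d}" for i in range(n_per)]
    covariates = {}
    for name, coef in config.covariate_effects:
        values = rng.standard_normal(n_samples)
        X += coef * values[None, :]
        covariates[name] = values

    study = ExpressionStudy(
        matrix=pd.DataFrame(X, index=gene_ids, columns=samples),
        annotation=pd.DataFrame(
            {"chrom": chroms, "position_bp": positions}, index=gene_ids
        ),
        phenotype=pd.Series([1] * n_per + [0] * n_per, index=samples),
        covariates=pd.DataFrame(covariates, index=samples),
        study_id=f"sim_seed{config.seed}",
    )
    return study, truth


def simulate_dag_expression(
    n_nodes: int,
    n_hubs: int,
    hub_out_degree: int,
    n_samples: int,
    seed: int = 0,
    extra_edge_prob: float = 0.02,
) -> tuple[pd.DataFrame, DirectedNetwork]:
    """Hub-structured DAG plus linear-Gaussian expression drawn from it.

    The first ``n_hubs`` nodes are root regulators, each parenting
    ``hub_out_degree`` distinct children; sparse extra edges are added
    among non-hub nodes (respecting topological order, so hubs stay
    roots). Child values follow sum(beta * parent) + unit noise with
    |beta| in [0.8, 1.2]. Returns (nodes x samples data, truth network).
    """
    if n_hubs * hub_out_degree >= n_nodes:
        raise ValueError("n_hubs * hub_out_degree must be < n_nodes")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    names = [f"n{i:03d}" for i in range(n_nodes)]
    edges: dict = {}
    child = n_hubs
    for h in range(n_hubs):
        for _ in range(hub_out_degree):
            edges[(h, child)] = 1.0
            child += 1
    for i in range(n_hubs, n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < extra_edge_prob:
                edges[(i, j)] = 1.0

    betas = {e: rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0]) for e in edges}
    X = np.zeros((n_nodes, n_samples))
    parents: dict[int, list] = {i: [] for i in range(n_nodes)}
    for (u, v) in edges:
        parents[v].append(u)
    for i in range(n_nodes):  # node index is a topological order
        X[i] = rng.standard_normal(n_samples)
        for p in parents[i]:
            X[i] += betas[(p, i)] * X[p]

    net = DirectedNetwork(
        nodes=names,
        edges={(names[u], names[v]): 1.0 for (u, v) in edges},
    )
    data = pd.DataFrame(X, index=names, columns=[f"s{j:03d}" for j in range(n_samples)])
    return data, net
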