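"""Synthetic expression and network fixtures with known ground truth.

The expression generator emulates a cross-sectional cortical aging cohort:
roughly 25-30 postmortem subjects with ages drawn uniformly on 25-95 years,
thousands of probesets on the log2 scale, and a minority of genes whose
expression shifts abruptly (a step of a few log2 units) at a planted
transition age. Step genes are the structure the dichotomized classifier is
built for; linear-trend genes give the regression baselines a regime where
they win; null genes carry only noise. The network generator grows a
preferential-attachment (scale-free-ish) graph and plants a high-degree
gene set for permutation-z tests.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ExpressionDataset, write_expression, write_metadata
from .network_topology import PPINetwork, write_network


@dataclass(frozen=True)
class StepGeneSpec:
    """A block of genes stepping by ``effect`` log2 units at age ``tau``.

    direction: 'up', 'down', or 'random' (each gene flips a fair coin).
    """

    count: int
    tau: float
    effect: float
    direction: str = "random"

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.direction not in ("up", "down", "random"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class TrendGeneSpec:
    """A block of genes drifting linearly with age (log2 units per year)."""

    count: int
    slope: float


@dataclass
class SyntheticSpec:
    """Study-condition parameters for one simulated cohort."""

    n_subjects: int = 29
    age_range: tuple[float, float] = (25.0, 95.0)
    step_genes: list[StepGeneSpec] = field(default_factory=list)
    trend_genes: list[TrendGeneSpec] = field(default_factory=list)
    null_genes: int = 2000
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    male_fraction: float = 0.6
    round_years: bool = False  # introduce age ties
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        for s in self.step_genes:
            if not lo <= s.tau <= hi:
                raise ValueError(f"tau {s.tau} outside age range {self.age_range}")

    @property
    def n_genes(self) -> int:
        return (
            sum(s.count for s in self.step_genes)
            + sum(t.count for t in self.trend_genes)
            + self.null_genes
        )


def simulate_expression(spec: SyntheticSpec) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Draw a cohort and expression matrix from the spec.

    Returns the dataset (with ages and sex attached) and a ground-truth
    table with one row per informative gene: gene_id, kind, tau, effect,
    direction, slope.
    """
    if spec.n_genes == 0:
        raise ValueError("spec describes zero genes")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, size=spec.n_subjects)
    if spec.round_years:
        ages = np.maximum(np.round(ages), 1.0)
    sex = np.where(
        rng.random(spec.n_subjects) < spec.male_fraction, "M", "F"
    ).astype(object)
    sample_ids = [f"s{j+1:03d}" for j in range(spec.n_subjects)]

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    truth_rows: list[dict] = []

    def baseline():
        return rng.normal(spec.baseline_mean, spec.baseline_sd)

    def noise():
        return rng.normal(0.0, spec.noise_sd, size=spec.n_subjects)

    gnum = 0
    for block_i, block in enumerate(spec.step_genes):
        for _ in range(block.count):
            gnum += 1
            gid = f"STEP{gnum:05d}"
            if block.direction == "random":
                sign = 1.0 if rng.random() < 0.5 else -1.0
            else:
                sign = 1.0 if block.direction == "up" else -1.0
            vals = baseline() + block.effect * sign * (ages > block.tau) + noise()
            gene_ids.append(gid)
            rows.append(vals)
            truth_rows.append(
                {
                    "gene_id": gid,
                    "kind": "step",
                    "tau": block.tau,
                    "effect": block.effect,
                    "direction": "up" if sign > 0 else "down",
                    "slope": 0.0,
                }
            )
    tnum = 0
    for block in spec.trend_genes:
        for _ in range(block.count):
            tnum += 1
            gid = f"TREND{tnum:05d}"
            vals = baseline() + block.slope * ages + noise()
            gene_ids.append(gid)
            rows.append(vals)
            truth_rows.append(
                {
                    "gene_id": gid,
                    "kind": "trend",
                    "tau": np.nan,
                    "effect": np.nan,
                    "direction": "up" if block.slope > 0 else "down",
                    "slope": block.slope,
                }
            )
    for i in range(spec.null_genes):
        gene_ids.append(f"NULL{i+1:05d}")
        rows.append(baseline() + noise())

    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.vstack(rows),
        ages=ages,
        sex=sex,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "kind", "tau", "effect", "direction", "slope"],
    )
    return dataset, truth


def simulate_network(
    n_nodes: int,
    attachment_m: int,
    planted_hub_set_size: int,
    seed: int = 0,
) -> tuple[PPINetwork, list[str]]:
    """Preferential-attachment graph with a planted central gene set.

    Each new node attaches to ``attachment_m`` existing nodes with
    probability proportional to degree, so the earliest nodes tend to
    become hubs. The planted set is the ``attachment_m`` earliest nodes
    padded with uniformly random other nodes up to the requested size.
    """
    if not (n_nodes > attachment_m >= 1):
        raise ValueError("need n_nodes > attachment_m >= 1")
    if not (1 <= planted_hub_set_size <= n_nodes):
        raise ValueError("planted set size must be in [1, n_nodes]")
    rng = np.random.default_rng(seed)
    g0 = nx.barabasi_albert_graph(
        n_nodes, attachment_m, seed=int(rng.integers(2**31 - 1))
    )
    width = len(str(n_nodes - 1))
    mapping = {i: f"P{i:0{width}d}" for i in g0.nodes}
    g = nx.relabel_nodes(g0, mapping)
    hubs = [mapping[i] for i in range(min(attachment_m, planted_hub_set_size))]
    rest = [mapping[i] for i in range(attachment_m, n_nodes)]
    pad = planted_hub_set_size - len(hubs)
    if pad > 0:
        hubs = hubs + list(rng.choice(rest, size=pad, replace=False))
    return PPINetwork(graph=g), hubs


def write_fixture(
    dataset: ExpressionDataset,
    truth: pd.DataFrame,
    out_dir,
    network: PPINetwork | None = None,
) -> dict[str, str]:
    """Write expr.tsv / meta.tsv / truth.tsv (and edges.tsv when a network
    is given) into ``out_dir``; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "expr": os.path.join(out_dir, "expr.tsv"),
        "meta": os.path.join(out_dir, "meta.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_expression(dataset, paths["expr"])
    meta = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "age": dataset.ages,
            "sex": dataset.sex if dataset.sex is not None else "unknown",
        }
    )
    write_metadata(meta, paths["meta"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if network is not None:
        paths["edges"] = os.path.join(out_dir, "edges.tsv")
        write_network(network, paths["edges"])
    return paths
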