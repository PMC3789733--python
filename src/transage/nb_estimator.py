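"""Greedy feature assignment and the naive-Bayes age estimator.

Each selected gene is a dichotomized classifier for a single age threshold:
it votes on whether a subject is older than its threshold delta via the
indicator ``b = 1[g > theta]``. The greedy step walks the thresholds from
youngest to oldest, repeatedly handing each threshold the unused gene with
the largest |log2 odds ratio|, until every threshold holds N genes (or genes
run out). The posterior over candidate ages (the training thresholds, with a
uniform prior) multiplies each classifier's Laplace-smoothed conditional
probability of its observed state; the predicted age is the argmax
threshold. All posterior arithmetic is done in log space.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data_io import ExpressionDataset
from .dichotomize_screen import ScreenResult

logger = logging.getLogger(__name__)


@dataclass
class GreedyAssignment:
    """Ordered gene lists per age threshold; no gene serves two thresholds."""

    deltas: np.ndarray
    genes_per_threshold: list[list[str]]
    rounds_completed: int
    exhausted: bool = False

    def as_dict(self) -> dict[float, list[str]]:
        return {
            float(d): list(g)
            for d, g in zip(self.deltas, self.genes_per_threshold)
        }

    @property
    def n_classifiers(self) -> int:
        return sum(len(g) for g in self.genes_per_threshold)


def greedy_assign(scores: ScreenResult, N: int) -> GreedyAssignment:
    """Assign up to N genes to each age threshold.

    Round-robin over threshold columns (youngest first): each column takes
    the unused gene maximizing |log2 OR| (ties: smaller p, then
    lexicographic gene id); a chosen gene is retired from every column.
    When genes run out, later rounds assign fewer, with a warning.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    G, T = scores.p.shape
    absl = np.abs(scores.log2_or)
    # per-column candidate order: by (-|log2 OR|, p, gene_id)
    ids = np.asarray(scores.gene_ids, dtype=object)
    col_orders = []
    for t in range(T):
        order = np.lexsort((ids, scores.p[:, t], -absl[:, t]))
        col_orders.append(order)
    pointers = [0] * T
    used = np.zeros(G, dtype=bool)
    columns: list[list[str]] = [[] for _ in range(T)]
    exhausted = False
    rounds = 0
    for _ in range(N):
        progressed = False
        for t in range(T):
            k = pointers[t]
            order = col_orders[t]
            while k < G and used[order[k]]:
                k += 1
            pointers[t] = k
            if k >= G:
                exhausted = True
                continue
            g = order[k]
            used[g] = True
            columns[t].append(str(ids[g]))
            progressed = True
        if not progressed:
            break
        rounds += 1
    if exhausted:
        warnings.warn(
            f"greedy_assign: ran out of genes before assigning N={N} to every "
            f"threshold ({int(used.sum())} genes over {T} thresholds)",
            stacklevel=2,
        )
    return GreedyAssignment(
        deltas=scores.deltas.copy(),
        genes_per_threshold=columns,
        rounds_completed=rounds,
        exhausted=exhausted,
    )


@dataclass(frozen=True)
class Classifier:
    """One dichotomized (gene, delta, theta) unit with smoothed conditionals
    for the high-expression state ``b = 1``."""

    gene_id: str
    delta: float
    theta: float
    p1_older: float
    p1_younger: float


@dataclass
class NBModel:
    """Fitted naive-Bayes age estimator: candidate thresholds (uniform
    prior) plus the per-threshold classifier lists."""

    deltas: np.ndarray
    classifiers: list[Classifier]
    N: int

    def __post_init__(self):
        for c in self.classifiers:
            if not (0.0 < c.p1_older < 1.0 and 0.0 < c.p1_younger < 1.0):
                raise ValueError(
                    f"conditional probabilities must lie in (0,1): {c}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [c.gene_id for c in self.classifiers]

    def to_json(self, path=None) -> str:
        payload = {
            "deltas": [float(d) for d in self.deltas],
            "N": self.N,
            "classifiers": [
                {
                    "gene_id": c.gene_id,
                    "delta": c.delta,
                    "theta": c.theta,
                    "p1_older": c.p1_older,
                    "p1_younger": c.p1_younger,
                }
                for c in self.classifiers
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NBModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            deltas=np.asarray(payload["deltas"], dtype=float),
            classifiers=[Classifier(**c) for c in payload["classifiers"]],
            N=int(payload["N"]),
        )


def smoothed_conditionals(c00: int, c01: int, c10: int, c11: int) -> tuple[float, float]:
    """Add-one smoothed P(b=1 | older) and P(b=1 | younger) from the
    training 2x2 table (rows low/high, columns young/old)."""
    p1_older = (c11 + 1.0) / (c01 + c11 + 2.0)
    p1_younger = (c10 + 1.0) / (c00 + c10 + 2.0)
    return p1_older, p1_younger


def fit_nb(dataset: ExpressionDataset, scores: ScreenResult, N: int) -> NBModel:
    """Greedy-assign genes to thresholds and freeze each classifier's theta
    and smoothed conditionals from its screening table."""
    assignment = greedy_assign(scores, N)
    if assignment.n_classifiers == 0:
        raise ValueError("empty greedy assignment; nothing to fit")
    gene_pos = {g: i for i, g in enumerate(scores.gene_ids)}
    classifiers: list[Classifier] = []
    for t, genes in enumerate(assignment.genes_per_threshold):
        for g in genes:
            gi = gene_pos[g]
            c00, c01, c10, c11 = (int(x) for x in scores.counts[gi, t])
            p1o, p1y = smoothed_conditionals(c00, c01, c10, c11)
            classifiers.append(
                Classifier(
                    gene_id=g,
                    delta=float(scores.deltas[t]),
                    theta=float(scores.theta[gi, t]),
                    p1_older=p1o,
                    p1_younger=p1y,
                )
            )
    return NBModel(deltas=scores.deltas.copy(), classifiers=classifiers, N=N)


@dataclass(frozen=True)
class AgeEstimate:
    sample_id: str
    posterior: np.ndarray
    predicted_age: float


def _log_conditionals(model: NBModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(K x I) log P(b=1 | class) matrices under each candidate threshold.

    A candidate age equal to a classifier's own delta counts as *younger*
    (the ``delta_k > delta_i`` comparison is strict).
    """
    deltas = np.asarray(model.deltas, dtype=float)
    cd = np.array([c.delta for c in model.classifiers])
    p1o = np.array([c.p1_older for c in model.classifiers])
    p1y = np.array([c.p1_younger for c in model.classifiers])
    older = deltas[:, None] > cd[None, :]  # K x I
    p1 = np.where(older, p1o[None, :], p1y[None, :])
    return np.log(p1), np.log1p(-p1), np.array([c.theta for c in model.classifiers]), older


def posterior_over_thresholds(model: NBModel, sample_expr, sample_id: str = "sample") -> AgeEstimate:
    """Posterior over candidate ages for one sample.

    ``sample_expr`` maps gene id -> log2 expression (dict or pandas Series)
    and must cover every model gene.
    """
    if isinstance(sample_expr, pd.Series):
        sample_expr = sample_expr.to_dict()
    values = []
    for c in model.classifiers:
        if c.gene_id not in sample_expr:
            raise KeyError(f"sample is missing model gene {c.gene_id!r}")
        values.append(float(sample_expr[c.gene_id]))
    log_p1, log_p0, thetas, _ = _log_conditionals(model)
    b = np.asarray(values) > thetas
    logpost = np.where(b[None, :], log_p1, log_p0).sum(axis=1)
    logpost = logpost - np.log(len(model.deltas))  # uniform prior
    logpost = logpost - logsumexp(logpost)
    post = np.exp(logpost)
    post = post / post.sum()
    pred = float(model.deltas[int(np.argmax(post))])  # argmax; ties -> smallest
    return AgeEstimate(sample_id=sample_id, posterior=post, predicted_age=pred)


def predict_ages(model: NBModel, dataset: ExpressionDataset) -> list[AgeEstimate]:
    """Vectorized posterior for every sample in the dataset."""
    gene_pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    missing = [g for g in model.gene_ids if g not in gene_pos]
    if missing:
        raise KeyError(f"dataset is missing model genes: {missing[:5]}")
    idx = np.array([gene_pos[c.gene_id] for c in model.classifiers], dtype=int)
    log_p1, log_p0, thetas, _ = _log_conditionals(model)
    B = dataset.values[idx, :] > thetas[:, None]  # I x S
    # K x S log posterior
    logpost = log_p1 @ B + log_p0 @ (~B)
    logpost -= np.log(len(model.deltas))
    logpost = logpost - logsumexp(logpost, axis=0, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=0, keepdims=True)
    best = np.argmax(post, axis=0)
    return [
        AgeEstimate(
            sample_id=sid,
            posterior=post[:, s].copy(),
            predicted_age=float(model.deltas[best[s]]),
        )
        for s, sid in enumerate(dataset.sample_ids)
    ]


def predictions_frame(model: NBModel, dataset: ExpressionDataset) -> pd.DataFrame:
    est = predict_ages(model, dataset)
    out = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in est],
            "predicted_age": [e.predicted_age for e in est],
        }
    )
    post = np.stack([e.posterior for e in est])
    for k, d in enumerate(model.deltas):
        out[f"p_{d:g}"] = post[:, k]
    return out


def select_N(dataset: ExpressionDataset, grid, k: int = 5, seed: int = 0) -> int:
    """Pick N from a grid by k-fold cross-validated error on the given data
    only (ties broken toward the smaller N)."""
    from .evaluation import kfold_cv  # deferred: evaluation imports this module

    grid = list(grid)
    if not grid:
        raise ValueError("empty N grid")
    best_n, best_err = None, np.inf
    for n in sorted(grid):
        err = kfold_cv(dataset, k=k, N=n, seed=seed).error
        logger.info("select_N: N=%d -> CV error %.3f", n, err)
        if err < best_err:
            best_n, best_err = n, err
    return int(best_n)
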