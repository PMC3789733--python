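"""Dichotomized feature screening.

Each gene is turned into a binary "older vs. younger" classifier: subject
ages are dichotomized at every midpoint between adjacent distinct ages (the
age thresholds delta), and gene expression is dichotomized at an expression
threshold theta chosen by exhaustive search over the gene's observed values.
Association between the two dichotomies is measured with the two-sided
Fisher exact test; effect direction and magnitude come from the log2 odds
ratio of the 2x2 table (Haldane-Anscombe +0.5 correction when any cell is
zero, so perfect separations remain rankable).

Conventions, applied uniformly:

* "low" means ``g <= theta``; "young" means ``age <= delta``.
* positive log2 odds ratio means high expression co-occurs with older
  subjects ("up with age").
* the two-sided p-value is the sum of hypergeometric probabilities of all
  tables with the observed margins whose probability does not exceed the
  observed table's (relative tolerance 1e-7); a zero margin gives p = 1.
* the best theta for a (gene, delta) pair minimizes p; ties prefer larger
  |log2 OR|, then smaller theta. A constant gene scores p = 1, flat.

``screen_matrix`` evaluates the full gene x threshold grid with vectorized
per-threshold lookup tables, which makes repeated in-fold screening cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_io import ExpressionDataset

#: relative tolerance when comparing hypergeometric point probabilities
REL_TOL = 1e-7


@dataclass(frozen=True)
class AgeThresholdSet:
    """Distinct sorted subject ages and the midpoints between neighbours."""

    ages_sorted: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self):
        if len(self.thresholds) != len(self.ages_sorted) - 1:
            raise ValueError("thresholds must be one fewer than distinct ages")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.thresholds)


def make_age_thresholds(ages) -> AgeThresholdSet:
    """Midpoints of adjacent *distinct* sorted ages. Tied subject ages
    collapse to a single grid point, so co-aged subjects always fall on the
    same side of every threshold."""
    distinct = np.unique(np.asarray(ages, dtype=float))
    if distinct.size < 3:
        raise ValueError(
            f"need >= 3 distinct ages to build a threshold grid, "
            f"got {distinct.size}"
        )
    mid = (distinct[:-1] + distinct[1:]) / 2.0
    return AgeThresholdSet(ages_sorted=distinct, thresholds=mid)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows low/high expression, columns young/old."""

    c00: int  # g <= theta, age <= delta
    c01: int  # g <= theta, age >  delta
    c10: int  # g >  theta, age <= delta
    c11: int  # g >  theta, age >  delta

    def __post_init__(self):
        for c in (self.c00, self.c01, self.c10, self.c11):
            if c < 0 or int(c) != c:
                raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.c00 + self.c01 + self.c10 + self.c11

    def as_array(self) -> np.ndarray:
        return np.array([[self.c00, self.c01], [self.c10, self.c11]], dtype=int)


def build_contingency(expr, ages, delta: float, theta: float) -> ContingencyTable:
    expr = np.asarray(expr, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if expr.shape != ages.shape:
        raise ValueError("expr and ages must have the same length")
    low = expr <= theta
    young = ages <= delta
    return ContingencyTable(
        c00=int(np.sum(low & young)),
        c01=int(np.sum(low & ~young)),
        c10=int(np.sum(~low & young)),
        c11=int(np.sum(~low & ~young)),
    )


def fisher_exact_p(table: ContingencyTable) -> float:
    """Two-sided conditional exact p-value for a 2x2 table.

    Sums hypergeometric point probabilities over all tables with the
    observed margins whose probability is <= the observed one (relative
    tolerance ``REL_TOL``). Any zero margin returns 1.0.
    """
    r1 = table.c00 + table.c01
    k1 = table.c00 + table.c10
    n = table.total
    if r1 == 0 or r1 == n or k1 == 0 or k1 == n:
        return 1.0
    lo = max(0, r1 + k1 - n)
    hi = min(r1, k1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, k1, r1)
    p_obs = pmf[table.c00 - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + REL_TOL)].sum())
    return min(p, 1.0)


def log2_odds_ratio(table: ContingencyTable) -> float:
    """log2 cross-product odds ratio, Haldane-Anscombe corrected (+0.5 to
    every cell) whenever any cell is zero. Positive values mean high
    expression is enriched in older subjects."""
    a, b, c, d = map(float, (table.c00, table.c01, table.c10, table.c11))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log2((a * d) / (b * c)))


def _direction(log2_or: float) -> str:
    if log2_or > 0:
        return "up"
    if log2_or < 0:
        return "down"
    return "flat"


@dataclass(frozen=True)
class GeneThresholdScore:
    """One (gene, age threshold) cell of the screen: the best expression
    threshold and its test statistics."""

    gene_id: str
    delta: float
    theta: float
    table: ContingencyTable
    p: float
    log2_or: float

    @property
    def direction(self) -> str:
        return _direction(self.log2_or)


def best_expression_threshold(
    expr, ages, delta: float, gene_id: str = "gene"
) -> GeneThresholdScore:
    """Exhaustive search of theta over the gene's observed values; returns
    the candidate minimizing the Fisher p (ties: larger |log2 OR|, then
    smaller theta). A constant gene is returned with p=1, log2_or=0."""
    expr = np.asarray(expr, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if expr.shape != ages.shape:
        raise ValueError("expr and ages must have the same length")
    candidates = np.unique(expr)
    if candidates.size == 1:
        n1 = int(np.sum(ages <= delta))
        tab = ContingencyTable(n1, expr.size - n1, 0, 0)
        return GeneThresholdScore(gene_id, delta, float(candidates[0]), tab, 1.0, 0.0)
    best = None
    for theta in candidates:
        tab = build_contingency(expr, ages, delta, float(theta))
        p = fisher_exact_p(tab)
        lor = log2_odds_ratio(tab)
        key = (p, -abs(lor), float(theta))
        if best is None or key < best[0]:
            best = (key, GeneThresholdScore(gene_id, delta, float(theta), tab, p, lor))
    return best[1]


@dataclass
class ScreenResult:
    """Dense gene x age-threshold grid of dichotomization scores.

    Array fields are indexed ``[gene, threshold]``; ``counts`` carries the
    winning 2x2 table as (c00, c01, c10, c11) along the last axis.
    """

    gene_ids: list[str]
    thresholds: AgeThresholdSet
    p: np.ndarray
    theta: np.ndarray
    log2_or: np.ndarray
    counts: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def deltas(self) -> np.ndarray:
        return self.thresholds.thresholds

    def score(self, gene: int | str, t_index: int) -> GeneThresholdScore:
        g = self.gene_ids.index(gene) if isinstance(gene, str) else gene
        tab = ContingencyTable(*(int(c) for c in self.counts[g, t_index]))
        return GeneThresholdScore(
            gene_id=self.gene_ids[g],
            delta=float(self.deltas[t_index]),
            theta=float(self.theta[g, t_index]),
            table=tab,
            p=float(self.p[g, t_index]),
            log2_or=float(self.log2_or[g, t_index]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (gene, delta)."""
        G, T = self.p.shape
        gi = np.repeat(np.arange(G), T)
        ti = np.tile(np.arange(T), G)
        lor = self.log2_or[gi, ti]
        return pd.DataFrame(
            {
                "gene_id": np.asarray(self.gene_ids, dtype=object)[gi],
                "delta": self.deltas[ti],
                "theta": self.theta[gi, ti],
                "c00": self.counts[gi, ti, 0],
                "c01": self.counts[gi, ti, 1],
                "c10": self.counts[gi, ti, 2],
                "c11": self.counts[gi, ti, 3],
                "p": self.p[gi, ti],
                "log2_or": lor,
                "direction": np.select(
                    [lor > 0, lor < 0], ["up", "down"], default="flat"
                ),
            }
        )


def _pvalue_lookup(n: int, n1: int) -> np.ndarray:
    """P[r, c] = two-sided Fisher p for the table with n samples, n1 young,
    row margin r low, and c00 = c. Rows with a zero margin are 1."""
    r = np.arange(n + 1)[:, None]
    c = np.arange(n + 1)[None, :]
    pmf = hypergeom.pmf(c, n, n1, r)  # 0 outside support
    # two-sided sum per row: entries with pmf <= pmf_obs * (1 + tol)
    mask = pmf[:, None, :] <= pmf[:, :, None] * (1.0 + REL_TOL)
    P = np.einsum("rob,rb->ro", mask, pmf)
    P = np.clip(P, 0.0, 1.0)
    if n1 == 0 or n1 == n:
        P[:] = 1.0
    P[0, :] = 1.0
    P[n, :] = 1.0
    return P


def screen_matrix(dataset: ExpressionDataset) -> ScreenResult:
    """Score every gene at every age threshold.

    Vectorized equivalent of calling :func:`best_expression_threshold` for
    each (gene, delta) cell; deterministic given the input.
    """
    if dataset.ages is None:
        raise ValueError("dataset has no ages; align metadata first")
    ages = dataset.ages
    X = dataset.values
    ths = make_age_thresholds(ages)
    deltas = ths.thresholds
    G, n = X.shape
    T = len(deltas)
    if G == 0:
        raise ValueError("dataset has no genes")

    orders = np.argsort(X, axis=1, kind="stable")
    V = np.take_along_axis(X, orders, axis=1)  # sorted values per gene
    lastocc = np.ones((G, n), dtype=bool)
    lastocc[:, :-1] = V[:, 1:] > V[:, :-1]  # last index of each distinct value
    const_gene = V[:, 0] == V[:, -1]
    r_idx = np.arange(1, n + 1)

    p = np.empty((G, T))
    theta = np.empty((G, T))
    lor_out = np.empty((G, T))
    counts = np.empty((G, T, 4), dtype=int)
    gi = np.arange(G)

    for t, delta in enumerate(deltas):
        young = ages <= delta
        n1 = int(young.sum())
        P = _pvalue_lookup(n, n1)
        yo = young[orders]  # young indicator in each gene's value order
        C00 = np.cumsum(yo, axis=1)  # row margin r = position + 1
        r = np.broadcast_to(r_idx, (G, n))
        pv = np.where(lastocc, P[r, C00], np.inf)
        C01 = r - C00
        C10 = n1 - C00
        C11 = (n - n1) - C01
        a, b, c, d = (C00.astype(float), C01.astype(float),
                      C10.astype(float), C11.astype(float))
        zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        h = 0.5 * zero
        lor = np.log2(((a + h) * (d + h)) / ((b + h) * (c + h)))
        # candidate selection: min p, then max |log2 OR|, then smallest theta
        pmin = pv.min(axis=1, keepdims=True)
        tie = pv == pmin
        absl = np.where(tie, np.abs(lor), -np.inf)
        tie2 = tie & (absl == absl.max(axis=1, keepdims=True))
        best = tie2.argmax(axis=1)  # first True = smallest theta
        p[:, t] = pv[gi, best]
        theta[:, t] = V[gi, best]
        lor_out[:, t] = lor[gi, best]
        counts[:, t, 0] = C00[gi, best]
        counts[:, t, 1] = C01[gi, best]
        counts[:, t, 2] = C10[gi, best]
        counts[:, t, 3] = C11[gi, best]
        if const_gene.any():
            n2 = n - n1
            p[const_gene, t] = 1.0
            lor_out[const_gene, t] = 0.0
            theta[const_gene, t] = V[const_gene, 0]
            counts[const_gene, t] = (n1, n2, 0, 0)

    return ScreenResult(
        gene_ids=list(dataset.gene_ids),
        thresholds=ths,
        p=p,
        theta=theta,
        log2_or=lor_out,
        counts=counts,
        provenance={"n_samples": n, "n_genes": G},
    )
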