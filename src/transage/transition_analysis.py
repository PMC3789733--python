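"""Transition age points, decade/age-group binning, and set overlaps.

Every gene's *transition age point* is the age threshold where its
dichotomized expression separates older from younger subjects most strongly
(minimum Fisher p over the threshold grid; ties prefer the larger |log2 OR|
and then the smaller threshold). Significant genes (default p < 0.005, with
Benjamini-Hochberg q-values computed over all genes) are binned into
decades and into young / middle / old / very-old groups, and gene-set
overlaps between datasets are tested with a one-sided hypergeometric
(enrichment) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .dichotomize_screen import ScreenResult

#: age-group cutpoints: [lower, upper) in years
AGE_GROUPS = (
    ("young", -np.inf, 40.0),
    ("middle", 40.0, 60.0),
    ("old", 60.0, 80.0),
    ("very_old", 80.0, np.inf),
)


def decade_label(transition_point: float) -> str:
    return f"{int(np.floor(transition_point / 10.0) * 10)}s"


def age_group(transition_point: float) -> str:
    for name, lo, hi in AGE_GROUPS:
        if lo <= transition_point < hi:
            return name
    raise ValueError(f"unplaceable transition point {transition_point}")


def assign_transition_points(scores: ScreenResult) -> pd.DataFrame:
    """One row per gene: transition_point (the argmin-p threshold), p,
    BH q-value over all genes, log2_or and direction at that threshold,
    decade and age_group labels."""
    p = scores.p
    absl = np.abs(scores.log2_or)
    G, T = p.shape
    # argmin p; ties -> larger |log2 OR|; final tie -> smaller delta (first)
    pmin = p.min(axis=1, keepdims=True)
    tie = p == pmin
    masked = np.where(tie, absl, -np.inf)
    tie2 = tie & (masked == masked.max(axis=1, keepdims=True))
    best = tie2.argmax(axis=1)
    gi = np.arange(G)
    tp = scores.deltas[best]
    p_best = p[gi, best]
    lor_best = scores.log2_or[gi, best]
    _, q, _, _ = multipletests(p_best, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene_id": scores.gene_ids,
            "transition_point": tp,
            "p": p_best,
            "q": q,
            "log2_or": lor_best,
            "direction": np.select(
                [lor_best > 0, lor_best < 0], ["up", "down"], default="flat"
            ),
            "decade": [decade_label(x) for x in tp],
            "age_group": [age_group(x) for x in tp],
        }
    )


def significant_transitions(
    transitions: pd.DataFrame, alpha: float = 0.005
) -> tuple[pd.DataFrame, float]:
    """Filter to p < alpha and report the largest BH q among the retained
    genes (NaN when nothing is retained). q-values are taken from (or, if
    absent, computed over) the full gene list."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    df = transitions.copy()
    if "q" not in df.columns:
        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["q"] = q
    kept = df[df["p"] < alpha].reset_index(drop=True)
    max_q = float(kept["q"].max()) if len(kept) else float("nan")
    return kept, max_q


def bin_decades(transitions: pd.DataFrame) -> pd.DataFrame:
    """Counts per (decade x direction); flat genes are excluded. The decade
    of a threshold is floor(delta/10)*10, boundaries belonging to their own
    decade."""
    df = transitions[transitions["direction"] != "flat"]
    counts = (
        df.groupby(["decade", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    order = sorted(counts.index, key=lambda s: int(s.rstrip("s")))
    counts = counts.reindex(order)
    for col in ("up", "down"):
        if col not in counts.columns:
            counts[col] = 0
    return counts[["up", "down"]]


def group_by_age(transitions: pd.DataFrame) -> dict[str, set[str]]:
    """Gene sets per age group (young <40, middle [40,60), old [60,80),
    very_old >=80)."""
    out: dict[str, set[str]] = {name: set() for name, _, _ in AGE_GROUPS}
    for gid, grp in zip(transitions["gene_id"], transitions["age_group"]):
        out[grp].add(gid)
    return out


@dataclass(frozen=True)
class OverlapTest:
    size_a: int
    size_b: int
    universe: int
    overlap: int
    p: float  # one-sided enrichment


def overlap_fisher(set_a, set_b, universe) -> OverlapTest:
    """One-sided hypergeometric enrichment test for the overlap of two gene
    sets within a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    overlap = len(a & b)
    U, na, nb = len(universe), len(a), len(b)
    # P(X >= overlap) with X ~ Hypergeom(U, na, nb)
    p = float(hypergeom.sf(overlap - 1, U, na, nb))
    return OverlapTest(size_a=na, size_b=nb, universe=U, overlap=overlap, p=min(p, 1.0))
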