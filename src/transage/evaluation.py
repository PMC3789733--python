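"""Cross-validated error, permutation significance, and linear baselines.

The headline error metric is the macro-averaged k-fold error: the mean over
folds of the fold's mean absolute difference between actual and predicted
age. By default feature selection (screening + greedy assignment) is redone
inside every training fold; the permissive variant that selects features on
the full dataset once is available as ``leaky_selection=True`` for
comparison, since out-of-fold selection inflates apparent accuracy.

Permutation significance shuffles ages across subjects and reruns the whole
cross-validation; the p-value is the proportion of permuted errors strictly
lower than the observed one (so p = 0 is reportable as < 1/n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV, LassoLarsCV
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .data_io import ExpressionDataset
from .dichotomize_screen import screen_matrix
from .nb_estimator import fit_nb, predict_ages

logger = logging.getLogger(__name__)


@dataclass
class CVResult:
    """k-fold cross-validation summary for one estimator."""

    fold_assignments: np.ndarray  # fold index per subject
    fold_errors: np.ndarray  # per-fold mean absolute error (years)
    error: float  # mean of fold_errors (macro average)
    sd_subjects: float  # SD of |actual - predicted| across subjects
    sd_folds: float  # SD of the per-fold mean errors
    predictions: pd.DataFrame  # sample_id, actual, predicted, fold
    N: int | None
    seed: int

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(
            self.predictions["actual"].to_numpy()
            - self.predictions["predicted"].to_numpy()
        )


def partition_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random partition into k folds; returns fold index per subject.

    Folds are disjoint, exhaustive, and as equal-sized as possible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} folds need at least {k} subjects, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = f
    return assignments


def age_spread_baseline(ages) -> float:
    """Error of the constant predictor: mean |age - median(age)|."""
    ages = np.asarray(ages, dtype=float)
    return float(np.mean(np.abs(ages - np.median(ages))))


def _summarize(predictions: pd.DataFrame, folds: np.ndarray, N, seed) -> CVResult:
    abs_err = np.abs(predictions["actual"] - predictions["predicted"]).to_numpy()
    fold_ids = np.unique(predictions["fold"])
    fold_errors = np.array(
        [abs_err[predictions["fold"] == f].mean() for f in fold_ids]
    )
    return CVResult(
        fold_assignments=folds,
        fold_errors=fold_errors,
        error=float(fold_errors.mean()),
        sd_subjects=float(abs_err.std(ddof=1)) if abs_err.size > 1 else 0.0,
        sd_folds=float(fold_errors.std(ddof=1)) if fold_errors.size > 1 else 0.0,
        predictions=predictions,
        N=N,
        seed=seed,
    )


def kfold_cv(
    dataset: ExpressionDataset,
    k: int = 5,
    N: int | list[int] = 20,
    seed: int = 0,
    leaky_selection: bool = False,
) -> CVResult:
    """k-fold cross-validated error of the naive-Bayes age estimator.

    ``N`` may be a single genes-per-threshold count or a grid; a grid is
    resolved per fold by nested cross-validation on the training part only.
    With ``leaky_selection`` the screen and greedy assignment are computed
    once on the full dataset (thresholds and conditionals are still refit
    per training fold); this reproduces the permissive protocol.
    """
    if dataset.ages is None:
        raise ValueError("dataset has no ages")
    n = dataset.n_samples
    folds = partition_folds(n, k, seed)
    grid = list(N) if isinstance(N, (list, tuple, np.ndarray)) else None

    leaky_scores = screen_matrix(dataset) if leaky_selection else None

    rows = []
    used_N: int | None = None
    for f in range(k):
        test_idx = np.where(folds == f)[0]
        train_idx = np.where(folds != f)[0]
        if test_idx.size < 1:
            raise ValueError(f"fold {f} has no test subjects; reduce k")
        train = dataset.subset_samples(train_idx)
        test = dataset.subset_samples(test_idx)
        if grid is not None:
            from .nb_estimator import select_N

            n_fold = select_N(train, grid, k=min(k, train.n_samples), seed=seed + 1)
        else:
            n_fold = int(N)
        used_N = n_fold
        if leaky_selection:
            scores = _restrict_scores(leaky_scores, train)
        else:
            scores = screen_matrix(train)
        model = fit_nb(train, scores, n_fold)
        for est, age in zip(predict_ages(model, test), test.ages):
            rows.append(
                {
                    "sample_id": est.sample_id,
                    "actual": float(age),
                    "predicted": est.predicted_age,
                    "fold": f,
                }
            )
    predictions = pd.DataFrame(rows)
    return _summarize(predictions, folds, used_N, seed)


def _restrict_scores(full_scores, train: ExpressionDataset):
    """Refit every winning (theta, delta) cell's contingency table and
    p/log-OR on the training subjects only, keeping the full-data theta
    (the leaky protocol: feature choice leaks, probabilities do not)."""
    from .dichotomize_screen import (
        ContingencyTable,
        ScreenResult,
        build_contingency,
        fisher_exact_p,
        log2_odds_ratio,
    )

    out_counts = np.empty_like(full_scores.counts)
    out_p = np.empty_like(full_scores.p)
    out_lor = np.empty_like(full_scores.log2_or)
    for gi in range(full_scores.p.shape[0]):
        for t, delta in enumerate(full_scores.deltas):
            tab = build_contingency(
                train.values[gi], train.ages, delta, full_scores.theta[gi, t]
            )
            out_counts[gi, t] = (tab.c00, tab.c01, tab.c10, tab.c11)
            out_p[gi, t] = fisher_exact_p(tab)
            out_lor[gi, t] = log2_odds_ratio(tab)
    return ScreenResult(
        gene_ids=list(full_scores.gene_ids),
        thresholds=full_scores.thresholds,
        p=out_p,
        theta=full_scores.theta.copy(),
        log2_or=out_lor,
        counts=out_counts,
        provenance=dict(full_scores.provenance, leaky=True),
    )


@dataclass
class PermutationResult:
    observed_error: float
    permuted_errors: np.ndarray
    p: float
    seed: int
    n_perm: int


def permutation_significance(
    dataset: ExpressionDataset,
    n_perm: int = 1000,
    k: int = 5,
    N: int = 20,
    seed: int = 0,
) -> PermutationResult:
    """Shuffle ages across subjects, rerun the full cross-validation per
    replicate, and report the proportion of permuted errors strictly lower
    than the observed error."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = kfold_cv(dataset, k=k, N=N, seed=seed).error
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_perm) % (2**31 - 1)
    permuted = np.empty(n_perm)
    for r in range(n_perm):
        rng = np.random.default_rng(child_seeds[2 * r])
        shuffled = dataset.ages[rng.permutation(dataset.n_samples)]
        perm_ds = ExpressionDataset(
            dataset.gene_ids,
            dataset.sample_ids,
            dataset.values,
            ages=shuffled,
            sex=dataset.sex,
        )
        permuted[r] = kfold_cv(
            perm_ds, k=k, N=N, seed=int(child_seeds[2 * r + 1])
        ).error
    p = float(np.mean(permuted < observed))
    return PermutationResult(
        observed_error=observed,
        permuted_errors=permuted,
        p=p,
        seed=seed,
        n_perm=n_perm,
    )


def linear_screen(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene OLS of expression on age with gender adjustment:

    ``Y = b0 + b1*age + b2*male + b3*(age if male else 0)``.

    With fewer than two subjects per sex the design is rank-deficient and
    the sex terms are dropped (flagged in the ``sex_adjusted`` column).
    Returns one row per gene: beta_age, beta_sex, beta_interaction, p_age.
    A zero-variance gene gets beta 0 and p 1 by convention.
    """
    if dataset.ages is None:
        raise ValueError("dataset has no ages")
    n = dataset.n_samples
    ages = dataset.ages
    sex = dataset.sex if dataset.sex is not None else np.array(["unknown"] * n, dtype=object)
    male = (sex == "M").astype(float)
    known = np.isin(sex, ["F", "M"])
    use_sex = known.all() and 2 <= male.sum() <= n - 2
    if use_sex:
        X = np.column_stack([np.ones(n), ages, male, ages * male])
    else:
        X = np.column_stack([np.ones(n), ages])
    d = X.shape[1]
    if n <= d:
        raise ValueError("too few subjects for the regression design")
    Y = dataset.values.T  # n x G
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - d
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_b1 = np.sqrt(sigma2 * xtx_inv[1, 1])
    constant = dataset.values.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se_b1 > 0, beta[1] / np.where(se_b1 > 0, se_b1, 1.0), 0.0)
    p_age = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p_age = np.where(constant | (se_b1 == 0), 1.0, p_age)
    out = pd.DataFrame(
        {
            "gene_id": dataset.gene_ids,
            "beta_age": np.where(constant, 0.0, beta[1]),
            "beta_sex": beta[2] if use_sex else np.nan,
            "beta_interaction": beta[3] if use_sex else np.nan,
            "p_age": p_age,
            "sex_adjusted": use_sex,
        }
    )
    if use_sex:
        out.loc[constant, ["beta_sex", "beta_interaction"]] = 0.0
    return out


def _forward_stepwise_predict(Xtr, ytr, Xte, max_steps: int, inner_k: int, seed: int):
    """Forward selection of predictors for age, step count tuned by nested
    CV; returns test predictions."""
    n, p = Xtr.shape
    max_steps = min(max_steps, p, max(1, n // 2))

    def fit_path(Xa, ya, steps):
        selected: list[int] = []
        resid = ya - ya.mean()
        models = []
        for _ in range(steps):
            corr = np.abs(resid @ Xa)
            corr[selected] = -np.inf
            j = int(np.argmax(corr))
            selected.append(j)
            D = np.column_stack([np.ones(len(ya)), Xa[:, selected]])
            coef, _, _, _ = np.linalg.lstsq(D, ya, rcond=None)
            resid = ya - D @ coef
            models.append((list(selected), coef))
        return models

    # nested CV to choose the number of steps
    kf = KFold(n_splits=min(inner_k, n), shuffle=True, random_state=seed)
    cv_err = np.zeros(max_steps)
    for tr, te in kf.split(Xtr):
        models = fit_path(Xtr[tr], ytr[tr], max_steps)
        for s, (sel, coef) in enumerate(models):
            D = np.column_stack([np.ones(len(te)), Xtr[te][:, sel]])
            cv_err[s] += np.abs(ytr[te] - D @ coef).mean()
    best_steps = int(np.argmin(cv_err)) + 1
    sel, coef = fit_path(Xtr, ytr, best_steps)[-1]
    D = np.column_stack([np.ones(Xte.shape[0]), Xte[:, sel]])
    return D @ coef


def penalized_age_baseline(
    dataset: ExpressionDataset,
    method: str = "lasso",
    k: int = 5,
    seed: int = 0,
    alphas=None,
    max_steps: int = 20,
) -> CVResult:
    """Cross-validated error of a penalized linear age regression baseline.

    ``lasso`` tunes the L1 penalty by nested k-fold CV on each training
    fold; ``stepwise`` is greedy forward selection with the step count tuned
    the same way (capped at half the training subjects).
    """
    if method not in ("lasso", "stepwise"):
        raise ValueError(f"unknown method {method!r}")
    if dataset.ages is None:
        raise ValueError("dataset has no ages")
    n = dataset.n_samples
    folds = partition_folds(n, k, seed)
    X_all = dataset.values.T  # samples x genes
    y_all = dataset.ages
    rows = []
    for f in range(k):
        te = np.where(folds == f)[0]
        tr = np.where(folds != f)[0]
        Xtr, ytr, Xte = X_all[tr], y_all[tr], X_all[te]
        if method == "lasso":
            inner = KFold(
                n_splits=min(5, len(tr)), shuffle=True, random_state=seed
            )
            if alphas is None:
                # LARS path: exact piecewise-linear solution path, tuned by
                # nested CV (the classic lasso/forward-stagewise machinery)
                est = LassoLarsCV(cv=inner)
            else:
                est = LassoCV(cv=inner, alphas=alphas, max_iter=20000)
            model = make_pipeline(StandardScaler(), est)
            model.fit(Xtr, ytr)
            pred = model.predict(Xte)
        else:
            scaler = StandardScaler().fit(Xtr)
            pred = _forward_stepwise_predict(
                scaler.transform(Xtr), ytr, scaler.transform(Xte),
                max_steps=max_steps, inner_k=5, seed=seed,
            )
        for i, s in enumerate(te):
            rows.append(
                {
                    "sample_id": dataset.sample_ids[s],
                    "actual": float(y_all[s]),
                    "predicted": float(pred[i]),
                    "fold": f,
                }
            )
    return _summarize(pd.DataFrame(rows), folds, None, seed)


def compare_methods(
    dataset: ExpressionDataset,
    methods=("nb", "lasso", "stepwise"),
    k: int = 5,
    N: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Run each estimator with identical fold assignments and tabulate
    (method, error, sd_subjects, sd_folds)."""
    rows = []
    for m in methods:
        if m == "nb":
            res = kfold_cv(dataset, k=k, N=N, seed=seed)
        else:
            res = penalized_age_baseline(dataset, method=m, k=k, seed=seed)
        rows.append(
            {
                "method": m,
                "error": res.error,
                "sd_subjects": res.sd_subjects,
                "sd_folds": res.sd_folds,
            }
        )
    return pd.DataFrame(rows)
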