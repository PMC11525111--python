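"""Added predictive value of a score via bootstrap train/test AUC.

The question: does adding a polygenic score to a reference set of
predictors (e.g. the traditional Framingham-style risk factors) improve
out-of-sample discrimination of CAD? The procedure:

1. bootstrap-resample the cohort (n draws with replacement);
2. split the resample 70/30 into train and test;
3. fit the reference and the augmented logistic model on the train part;
4. score the held-out 30% and compute both rank-based AUCs;
5. repeat for B replicates; the per-replicate difference
   ``delta_b = AUC_test_b - AUC_ref_b`` is paired because both models
   share each replicate's resample and split;
6. the empirical p-value is the proportion of ``delta_b`` below zero
   (exact zeros, if any, count half).

Headline AUCs are reported as the mean of the B per-replicate held-out
AUCs. A companion under-sampling helper balances cases and controls to
check that class imbalance does not drive the conclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "AddedValueReport",
    "auc",
    "train_test_auc",
    "bootstrap_delta_auc",
    "undersample_balance",
]


@dataclass
class AddedValueReport:
    """Bootstrap AUC distributions for a reference vs an augmented model."""

    auc_reference: float  # mean of per-replicate held-out AUCs, reference model
    auc_test: float  # same, augmented model
    delta_auc: np.ndarray  # per-replicate AUC_test - AUC_ref
    auc_ref_dist: np.ndarray
    auc_test_dist: np.ndarray
    p_value: float  # proportion of delta < 0 (zeros at half weight)
    B: int
    n_failed: int
    train_fraction: float
    seed: int | None
    balanced: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "auc_reference": self.auc_ref_dist,
            "auc_test": self.auc_test_dist,
            "delta_auc": self.delta_auc,
        })

    def summary(self) -> dict:
        return {
            "auc_reference": self.auc_reference,
            "auc_test": self.auc_test,
            "delta_auc_mean": float(np.mean(self.delta_auc)),
            "p_value": self.p_value,
            "B": self.B,
            "n_failed": self.n_failed,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "balanced": self.balanced,
        }


def auc(scores: np.ndarray | Sequence[float], labels: np.ndarray | Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve.

    Equals ``(#{case > control pairs} + 0.5 * #{tied pairs}) /
    (n_case * n_control)``; computed via midranks so ties are handled
    exactly without enumerating pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_case = int(np.sum(labels == 1))
    n_ctrl = int(np.sum(labels == 0))
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks
    u = ranks[labels == 1].sum() - n_case * (n_case + 1) / 2
    return float(u / (n_case * n_ctrl))


def _fit_predict(X_train, y_train, X_test) -> np.ndarray:
    X1 = np.column_stack([np.ones(len(X_train)), X_train])
    with warnings.catch_warnings():
        # rare quasi-separated resamples still yield usable predictions
        warnings.simplefilter("ignore")
        fit = sm.Logit(y_train, X1).fit(disp=0, maxiter=100)
    return expit(np.column_stack([np.ones(len(X_test)), X_test]) @ fit.params)


def _prepare(data: pd.DataFrame, ref_terms, test_terms, outcome):
    all_terms = list(dict.fromkeys([*ref_terms, *test_terms]))
    cc = data[[outcome, *all_terms]].dropna()
    y = cc[outcome].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class")
    X_ref = cc[list(ref_terms)].to_numpy(dtype=float)
    X_test = cc[list(test_terms)].to_numpy(dtype=float)
    return y, X_ref, X_test


def _split(n: int, train_fraction: float, rng: np.random.Generator,
           y: np.ndarray, stratify: bool) -> tuple[np.ndarray, np.ndarray]:
    if stratify:
        tr_parts, te_parts = [], []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            perm = rng.permutation(idx)
            cut = int(round(train_fraction * idx.size))
            tr_parts.append(perm[:cut])
            te_parts.append(perm[cut:])
        return np.concatenate(tr_parts), np.concatenate(te_parts)
    perm = rng.permutation(n)
    cut = int(round(train_fraction * n))
    return perm[:cut], perm[cut:]


def train_test_auc(
    data: pd.DataFrame,
    ref_terms: Sequence[str],
    test_terms: Sequence[str],
    train_fraction: float = 0.7,
    rng: np.random.Generator | int | None = None,
    outcome: str = "cad_case",
    stratify_split: bool = False,
) -> tuple[float, float]:
    """One random 70/30 split: fit both models on train, AUC on test.

    Both models share the same split, so with ``test_terms == ref_terms``
    the two AUCs are identical. A split leaving a single class in either
    part is redrawn once, then raises.
    """
    rng = np.random.default_rng(rng)
    y, X_ref, X_test = _prepare(data, ref_terms, test_terms, outcome)
    n = y.size
    for attempt in range(2):
        tr, te = _split(n, train_fraction, rng, y, stratify_split)
        if np.unique(y[tr]).size == 2 and np.unique(y[te]).size == 2:
            break
    else:
        raise ValueError("could not draw a split with both classes in train and test")
    p_ref = _fit_predict(X_ref[tr], y[tr], X_ref[te])
    p_tst = _fit_predict(X_test[tr], y[tr], X_test[te])
    return auc(p_ref, y[te]), auc(p_tst, y[te])


def bootstrap_delta_auc(
    data: pd.DataFrame,
    ref_terms: Sequence[str],
    test_terms: Sequence[str],
    B: int = 1000,
    train_fraction: float = 0.7,
    seed: int | None = None,
    outcome: str = "cad_case",
    stratify_split: bool = False,
    balanced: bool = False,
    max_failed_fraction: float = 0.05,
) -> AddedValueReport:
    """Bootstrap distribution of the paired held-out ΔAUC.

    Per replicate: resample n rows with replacement, split the resample
    70/30, fit reference and augmented models on the train part and
    evaluate both AUCs on the held-out part. Replicate-level RNG streams
    are spawned deterministically from ``seed``, so replicate b is
    reproducible independently of B. Replicates whose resample or split
    degenerates (single-class) are dropped and counted; more than
    ``max_failed_fraction`` failures aborts.
    """
    y, X_ref, X_test = _prepare(data, ref_terms, test_terms, outcome)
    n = y.size
    children = np.random.SeedSequence(seed if seed is not None else None).spawn(B)
    aucs_ref = np.full(B, np.nan)
    aucs_tst = np.full(B, np.nan)
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(children[b])
        ok = False
        for attempt in range(2):
            boot = rng.integers(0, n, n)
            yb = y[boot]
            tr, te = _split(n, train_fraction, rng, yb, stratify_split)
            if np.unique(yb[tr]).size == 2 and np.unique(yb[te]).size == 2:
                ok = True
                break
        if not ok:
            n_failed += 1
            continue
        try:
            p_ref = _fit_predict(X_ref[boot][tr], yb[tr], X_ref[boot][te])
            p_tst = _fit_predict(X_test[boot][tr], yb[tr], X_test[boot][te])
            aucs_ref[b] = auc(p_ref, yb[te])
            aucs_tst[b] = auc(p_tst, yb[te])
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
    if n_failed > max_failed_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed (degenerate resamples)"
        )
    ok_mask = ~np.isnan(aucs_ref)
    ref_dist, tst_dist = aucs_ref[ok_mask], aucs_tst[ok_mask]
    delta = tst_dist - ref_dist
    n_ok = delta.size
    p = float((np.sum(delta < 0) + 0.5 * np.sum(delta == 0)) / n_ok)
    return AddedValueReport(
        auc_reference=float(ref_dist.mean()),
        auc_test=float(tst_dist.mean()),
        delta_auc=delta,
        auc_ref_dist=ref_dist,
        auc_test_dist=tst_dist,
        p_value=p,
        B=B,
        n_failed=n_failed,
        train_fraction=train_fraction,
        seed=seed,
        balanced=balanced,
    )


def undersample_balance(
    data: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    outcome: str = "cad_case",
) -> pd.DataFrame:
    """Randomly under-sample the majority class to the minority count.

    Majority-class rows are drawn without replacement; minority rows are
    kept in full, so the output has equal class counts. Already balanced
    data comes back the same size (row order may differ).
    """
    rng = np.random.default_rng(rng)
    labels = data[outcome]
    if labels.isna().any():
        data = data.loc[labels.notna()]
        labels = data[outcome]
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to balance")
    minority = 1 if n1 < n0 else 0
    n_min = min(n0, n1)
    idx_min = np.flatnonzero((labels == minority).to_numpy())
    idx_maj = np.flatnonzero((labels != minority).to_numpy())
    keep_maj = rng.choice(idx_maj, size=n_min, replace=False)
    keep = np.sort(np.concatenate([idx_min, keep_maj]))
    return data.iloc[keep].reset_index(drop=True)
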