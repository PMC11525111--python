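"""Logistic association models for CAD: nested covariate sets, genotype
principal components, quantile-interval odds ratios, and stratified reruns.

Three nested model presets mirror common epidemiological practice for a
standardized genetic score:

* model 1 — score + age + sex + BMI;
* model 2 — score + the traditional (Framingham-style) risk factors:
  age, sex, smoking, HDL and total cholesterol, systolic blood pressure
  and hypertension treatment (clinical cohorts), or age, sex, BMI,
  smoking and hypertension treatment (autopsy cohorts where lipids and
  blood pressure are unavailable), plus leading genotype principal
  components;
* model 3 — model 2 plus a second polygenic score.

Fitting is maximum likelihood (Newton/IRLS via statsmodels); inference is
Wald: 95% CI = exp(beta +/- z_0.975 * SE), two-sided normal p-values.
Rows with any missing model term are excluded (complete-case), matching
how reduced analytic sample sizes are conventionally reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

from .cohort_io import DosageMatrix
from .scoring import QuantileBins, ScoreVector

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "PCMatrix",
    "SeparationError",
    "fit_logistic",
    "compute_pcs",
    "run_model",
    "quantile_association",
    "stratified_association",
]

_Z975 = stats.norm.ppf(0.975)

#: covariate sets behind the model presets, keyed by (preset, flavor)
_PRESET_TERMS: dict[tuple[str, str], list[str]] = {
    ("model1", "clinical"): ["score", "age", "sex_male", "bmi"],
    ("model1", "autopsy"): ["score", "age", "sex_male", "bmi"],
    ("model2", "clinical"): [
        "score", "age", "sex_male", "smoking", "hdl_chol",
        "total_chol", "sbp", "htn_med",
    ],
    ("model2", "autopsy"): ["score", "age", "sex_male", "bmi", "smoking", "htn_med"],
}


class SeparationError(RuntimeError):
    """Perfect separation: the MLE diverges and odds ratios are undefined."""


@dataclass(frozen=True)
class ModelSpec:
    """Selection of outcome, covariate preset and adjustment options."""

    preset: str = "model2"  # model1 | model2 | model3 | custom
    cohort_flavor: str = "clinical"  # clinical | autopsy
    pc_count: int = 5
    include_statin: bool = False
    custom_terms: tuple[str, ...] = ()
    outcome: str = "cad_case"
    force_pcs: bool = False  # let custom specs keep genotype-PC adjustment

    def terms(self) -> list[str]:
        """Ordered covariate names for the design (PCs appended separately)."""
        if self.preset == "custom":
            return list(self.custom_terms)
        base_preset = "model2" if self.preset == "model3" else self.preset
        try:
            terms = list(_PRESET_TERMS[(base_preset, self.cohort_flavor)])
        except KeyError:
            raise ValueError(f"unknown preset/flavor {self.preset}/{self.cohort_flavor}")
        if self.preset == "model3":
            terms.append("second_score")
        if self.include_statin:
            terms.append("statin")
        return terms

    @property
    def uses_pcs(self) -> bool:
        # model 1 is unadjusted for population structure by construction
        return (self.preset in ("model2", "model3") or self.force_pcs) and self.pc_count > 0


@dataclass
class AssociationResult:
    """Per-term odds ratios with Wald 95% CIs and two-sided p-values.

    ``terms`` is a DataFrame indexed by term name with columns
    estimate (log-odds), std_error, odds_ratio, ci_low, ci_high, p_value.
    """

    terms: pd.DataFrame
    n_used: int
    converged: bool
    log_likelihood: float
    warnings: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    def to_table(self) -> pd.DataFrame:
        """Publication-style layout: term, OR (95% CI), p."""
        t = self.terms
        return pd.DataFrame({
            "term": t.index,
            "OR": t["odds_ratio"].round(3),
            "CI95": [
                f"({lo:.3f}-{hi:.3f})" for lo, hi in zip(t["ci_low"], t["ci_high"])
            ],
            "P": t["p_value"],
        })


@dataclass
class PCMatrix:
    """Leading principal components of a genotype dosage matrix."""

    components: pd.DataFrame  # samples x k, columns PC1..PCk
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[1]


def fit_logistic(design: pd.DataFrame, outcome: str = "cad_case") -> AssociationResult:
    """Fit a logistic regression of ``outcome`` on the remaining columns.

    ``design`` holds the binary outcome column plus numeric covariates;
    rows with any missing value are dropped (complete-case). An intercept
    is added internally and not reported. Degenerate designs raise:
    single-class outcomes and rank-deficient covariate matrices are
    ``ValueError``, perfect separation is :class:`SeparationError`.
    """
    cc = design.dropna()
    n_used = len(cc)
    if n_used == 0:
        raise ValueError("no complete cases")
    y = cc[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class; odds ratios undefined")
    covars = cc.drop(columns=[outcome]).astype(float)
    X = sm.add_constant(covars.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear covariate)")
    warnings_list: list[str] = []
    try:
        with warnings.catch_warnings():
            # separation and non-convergence are re-reported explicitly below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)  # log(0) on perfect fits
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # PerfectSeparationError and numerical failures
        if "separation" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise
    params = fit.params
    bse = fit.bse
    if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 30:
        raise SeparationError("diverging coefficients indicate (quasi-)separation")
    converged = bool(fit.mle_retvals.get("converged", True))
    if not converged:
        warnings_list.append("optimizer did not report convergence")
    est, se = params[1:], bse[1:]  # drop intercept from the report
    terms = pd.DataFrame(
        {
            "estimate": est,
            "std_error": se,
            "odds_ratio": np.exp(est),
            "ci_low": np.exp(est - _Z975 * se),
            "ci_high": np.exp(est + _Z975 * se),
            "p_value": 2 * stats.norm.sf(np.abs(est / se)),
        },
        index=pd.Index(covars.columns, name="term"),
    )
    return AssociationResult(
        terms=terms,
        n_used=n_used,
        converged=converged,
        log_likelihood=float(fit.llf),
        warnings=warnings_list,
    )


def compute_pcs(matrix: DosageMatrix, k: int = 5) -> PCMatrix:
    """Leading principal components of the dosage matrix.

    Columns are centered by twice the estimated allele frequency and
    scaled by sqrt(2 f (1-f)) (the Patterson normalization for genotype
    data); monomorphic variants are dropped. Component scores are the
    leading left singular vectors scaled by their singular values, with
    the sign fixed so that each component's largest-magnitude variant
    loading is positive.
    """
    if k == 0:
        return PCMatrix(
            components=pd.DataFrame(index=matrix.dosages.index),
            explained_variance=np.empty(0),
        )
    d = matrix.dosages.to_numpy(dtype=float)
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_mean[np.newaxis, :], d)
    f = d.mean(axis=0) / 2.0
    poly = (f > 0) & (f < 1)
    d = d[:, poly]
    f = f[poly]
    if d.shape[1] < k:
        raise ValueError(f"need >= {k} polymorphic variants for {k} PCs, have {d.shape[1]}")
    if d.shape[0] < k + 1:
        raise ValueError(f"need >= {k + 1} samples for {k} PCs")
    z = (d - 2 * f) / np.sqrt(2 * f * (1 - f))
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum())
    if k > rank:
        raise ValueError(f"requested {k} PCs but matrix rank is {rank}")
    u, s, vt = u[:, :k], s[:k], vt[:k]
    signs = np.sign(vt[np.arange(k), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = u * s * signs
    return PCMatrix(
        components=pd.DataFrame(
            scores, index=matrix.dosages.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        explained_variance=s**2 / (d.shape[0] - 1),
    )


def _base_design(
    cohort: pd.DataFrame,
    score: ScoreVector | None,
    second_score: ScoreVector | None,
    pcs: PCMatrix | None,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Assemble the numeric design frame for a model spec.

    Sex enters as a male=1 indicator; the score enters standardized so
    its coefficient is per SD.
    """
    df = cohort.reset_index(drop=True)
    design = pd.DataFrame(index=df.index)
    design[spec.outcome] = pd.array(df[spec.outcome], dtype="Float64").to_numpy(dtype=float, na_value=np.nan)
    sex = df["sex"].map({"male": 1.0, "female": 0.0})
    available: dict[str, pd.Series] = {
        "age": df["age"], "sex_male": sex, "bmi": df["bmi"], "sbp": df["sbp"],
        "total_chol": df["total_chol"], "hdl_chol": df["hdl_chol"],
        "smoking": df["smoking"], "htn_med": df["htn_med"], "statin": df["statin"],
    }
    for name in spec.terms():
        if name == "score":
            if score is None or score.standardized is None:
                raise ValueError("a standardized score is required for the 'score' term")
            design["score"] = np.asarray(score.standardized, dtype=float)
        elif name == "second_score":
            if second_score is None or second_score.standardized is None:
                raise ValueError("model 3 requires a standardized second score")
            design["second_score"] = np.asarray(second_score.standardized, dtype=float)
        else:
            if name not in available:
                raise ValueError(f"unknown model term {name!r}")
            design[name] = pd.array(available[name], dtype="Float64").to_numpy(
                dtype=float, na_value=np.nan
            )
    if spec.uses_pcs:
        if pcs is None:
            raise ValueError(f"{spec.preset} requests {spec.pc_count} PCs but none supplied")
        for col in pcs.components.columns[: spec.pc_count]:
            design[col] = pcs.components[col].to_numpy(dtype=float)
    return design


def run_model(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    score: ScoreVector,
    second_score: ScoreVector | None = None,
    pcs: PCMatrix | None = None,
) -> AssociationResult:
    """Fit one preset logistic model on a cohort; the score OR is per SD."""
    design = _base_design(cohort, score, second_score, pcs, spec)
    return fit_logistic(design, outcome=spec.outcome)


def quantile_association(
    cohort: pd.DataFrame,
    bins: QuantileBins,
    spec: ModelSpec,
    second_score: ScoreVector | None = None,
    pcs: PCMatrix | None = None,
) -> AssociationResult:
    """Replace the continuous score with quantile-bin indicators.

    One indicator per non-reference bin; odds ratios are relative to the
    lowest interval (Q1).
    """
    design = _base_design(cohort, None, second_score, pcs, _drop_score(spec))
    labels = pd.Series(bins.bin_label, index=design.index)
    non_ref = [lb for lb in bins.labels if lb != bins.reference_bin]
    insert_at = 1  # after the outcome column, mirroring the score position
    for offset, lb in enumerate(non_ref):
        design.insert(insert_at + offset, f"bin_{lb}", (labels == lb).astype(float))
    cc_labels = labels[design.dropna().index]
    empty = [lb for lb in bins.labels if (cc_labels == lb).sum() == 0]
    if empty:
        raise ValueError(f"bin(s) {empty} empty after complete-case filtering")
    return fit_logistic(design, outcome=spec.outcome)


def _custom_spec(spec: ModelSpec, terms: tuple[str, ...]) -> ModelSpec:
    """Custom-term clone of ``spec`` preserving its PC adjustment."""
    return ModelSpec(
        preset="custom", cohort_flavor=spec.cohort_flavor, pc_count=spec.pc_count,
        include_statin=False, custom_terms=terms, outcome=spec.outcome,
        force_pcs=spec.uses_pcs,
    )


def _drop_score(spec: ModelSpec) -> ModelSpec:
    return _custom_spec(spec, tuple(t for t in spec.terms() if t != "score"))


LOW_POWER_N = 100  # strata smaller than this get a low-power warning


def stratified_association(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    score: ScoreVector,
    strata: str = "sex",
    second_score: ScoreVector | None = None,
    pcs: PCMatrix | None = None,
    age_cut: float = 40.0,
) -> dict[str, AssociationResult | str]:
    """Rerun a model within strata (by sex, or by age >= / < ``age_cut``).

    Returns a mapping stratum name -> result; strata that fail (empty,
    single outcome class, separation) map to an error string so the other
    strata are unaffected. Small strata are fitted but flagged with a
    low-power warning rather than dropped.
    """
    df = cohort.reset_index(drop=True)
    if strata == "sex":
        masks = {"male": df["sex"] == "male", "female": df["sex"] == "female"}
        sub_spec = _custom_spec(spec, tuple(t for t in spec.terms() if t != "sex_male"))
    elif strata == "age40":
        masks = {f"age_ge{age_cut:g}": df["age"] >= age_cut, f"age_lt{age_cut:g}": df["age"] < age_cut}
        sub_spec = spec
    else:
        raise ValueError("strata must be 'sex' or 'age40'")
    out: dict[str, AssociationResult | str] = {}
    std = np.asarray(score.standardized, dtype=float)
    second_std = None if second_score is None else np.asarray(second_score.standardized, dtype=float)
    for name, mask in masks.items():
        idx = np.flatnonzero(mask.fillna(False).to_numpy())
        if idx.size == 0:
            out[name] = "empty stratum"
            continue
        sub_score = ScoreVector(
            sample_ids=[df["sample_id"].iloc[i] for i in idx] if "sample_id" in df else [str(i) for i in idx],
            raw=np.asarray(score.raw)[idx],
            standardized=std[idx],
        )
        sub_second = None
        if second_std is not None:
            sub_second = ScoreVector(sample_ids=sub_score.sample_ids,
                                     raw=np.asarray(second_score.raw)[idx],
                                     standardized=second_std[idx])
        sub_pcs = None
        if pcs is not None:
            sub_pcs = PCMatrix(components=pcs.components.iloc[idx].reset_index(drop=True),
                               explained_variance=pcs.explained_variance)
        try:
            res = run_model(df.iloc[idx].reset_index(drop=True), sub_spec, sub_score,
                            sub_second, sub_pcs)
        except (ValueError, SeparationError) as exc:
            out[name] = str(exc)
            continue
        if res.n_used < LOW_POWER_N:
            res.warnings.append(f"low power: only {res.n_used} complete cases in stratum")
        out[name] = res
    return out
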