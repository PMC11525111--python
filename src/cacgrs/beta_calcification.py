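"""Beta regression of calcified-plaque area proportions.

Calcified plaque area in a coronary artery segment is a percentage of
the segment's wall area, i.e. a proportion in [0, 1] once divided by
100. It is modelled as ``y ~ Beta(mu * phi, (1 - mu) * phi)`` with
``logit(mu) = x' beta`` and a single constant precision ``phi`` —
the Ferrari–Cribari-Neto parameterization with a logit mean link.

Exact 0% and 100% observations occur in morphometry data but lie
outside the open-interval beta support, so proportions are first
squeezed with the Smithson–Verkuilen transform
``y' = (y * (n - 1) + 0.5) / n``.

Exponentiated mean-model coefficients are reported in an "OR" column for
table compatibility; they are odds ratios of the *expected proportion*
(``mu / (1 - mu)``), not case-control odds ratios — a distinction worth
keeping in mind when reading the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .association import ModelSpec, PCMatrix, _base_design
from .scoring import ScoreVector

__all__ = [
    "ProportionOutcome",
    "BetaRegResult",
    "squeeze_boundaries",
    "fit_betareg",
    "run_calcification_model",
]

_Z975 = stats.norm.ppf(0.975)

#: default adjustment set for the calcification models (autopsy cohorts)
CALC_TERMS = ("age", "sex_male", "bmi", "smoking", "htn_med")


@dataclass
class ProportionOutcome:
    """A proportion outcome with boundary values squeezed into (0, 1)."""

    y: np.ndarray
    y_adjusted: np.ndarray
    n_boundary: int


@dataclass
class BetaRegResult:
    """Beta-regression fit: mean-model terms plus the precision estimate."""

    terms: pd.DataFrame  # estimate, std_error, odds_ratio, ci_low, ci_high, p_value
    precision_phi: float
    log_likelihood: float
    n_used: int
    converged: bool
    boundary_adjusted: int = 0
    warnings: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def squeeze_boundaries(y: np.ndarray | Sequence[float], n: int | None = None) -> ProportionOutcome:
    """Smithson–Verkuilen squeeze: map [0, 1] data strictly inside (0, 1).

    ``y' = (y * (n - 1) + 0.5) / n`` with ``n`` the sample count
    (defaulting to ``len(y)``). Applied to every observation, it leaves
    0.5 fixed and pulls the boundaries to ``0.5 / n`` and ``1 - 0.5 / n``.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if n is None:
        n = y.size
    if n < 2:
        raise ValueError("need n >= 2 to squeeze boundaries")
    n_boundary = int(np.sum((y == 0) | (y == 1)))
    return ProportionOutcome(y=y, y_adjusted=(y * (n - 1) + 0.5) / n, n_boundary=n_boundary)


def fit_betareg(
    y: ProportionOutcome | np.ndarray,
    covariates: pd.DataFrame,
) -> BetaRegResult:
    """Maximum-likelihood beta regression with logit mean link, constant phi.

    Rows with missing covariates or outcome are dropped (complete-case).
    SEs come from the inverse observed information; 95% CIs are Wald on
    the coefficient scale and exponentiated. The precision is estimated
    on the log scale internally (guaranteeing ``phi > 0``) and reported
    on the natural scale.
    """
    if isinstance(y, ProportionOutcome):
        vals, n_boundary = y.y_adjusted, y.n_boundary
    else:
        vals, n_boundary = np.asarray(y, dtype=float), 0
    df = covariates.astype(float).copy()
    df.insert(0, "_y", vals)
    cc = df.dropna()
    n_used = len(cc)
    if n_used <= df.shape[1] + 1:
        raise ValueError(f"too few complete cases (n={n_used}) for {df.shape[1] - 1} terms")
    endog = cc["_y"].to_numpy()
    if np.any((endog <= 0) | (endog >= 1)):
        raise ValueError("outcome must lie strictly inside (0, 1); squeeze boundaries first")
    exog = np.column_stack([np.ones(n_used), cc.drop(columns="_y").to_numpy()])
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear covariate)")
    model = BetaModel(endog, exog)  # logit mean link, log precision link
    with warnings.catch_warnings():
        # convergence status is re-reported via the result's flag
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = model.fit(disp=0, maxiter=500)
    converged = bool(fit.mle_retvals.get("converged", True))
    warnings_list: list[str] = []
    if not converged:
        warnings_list.append("optimizer did not report convergence")
    phi = float(np.exp(fit.params[-1]))
    if not np.isfinite(phi) or phi < 1e-8 or phi > 1e8:
        warnings_list.append(f"degenerate precision estimate phi={phi:.3g}")
    est = fit.params[1:-1]  # mean-model coefficients, intercept and phi excluded
    se = fit.bse[1:-1]
    terms = pd.DataFrame(
        {
            "estimate": est,
            "std_error": se,
            "odds_ratio": np.exp(est),
            "ci_low": np.exp(est - _Z975 * se),
            "ci_high": np.exp(est + _Z975 * se),
            "p_value": 2 * stats.norm.sf(np.abs(est / se)),
        },
        index=pd.Index(list(covariates.columns), name="term"),
    )
    return BetaRegResult(
        terms=terms,
        precision_phi=phi,
        log_likelihood=float(fit.llf),
        n_used=n_used,
        converged=converged,
        boundary_adjusted=n_boundary,
        warnings=warnings_list,
    )


def run_calcification_model(
    cohort: pd.DataFrame,
    artery: str,
    score: ScoreVector,
    pcs: PCMatrix | None = None,
    pc_count: int = 5,
    min_samples: int = 30,
) -> BetaRegResult:
    """Beta regression of one artery's calcified-area % on the score.

    ``artery`` is "lad" or "rca"; the percentage is divided by 100 and
    squeezed before fitting. Adjustment: age, sex (male=1), BMI, smoking,
    hypertension treatment and the leading genotype PCs; complete-case.
    The score coefficient is per SD of the standardized score.
    """
    artery = artery.lower()
    if artery not in ("lad", "rca"):
        raise ValueError("artery must be 'lad' or 'rca'")
    col = f"calc_{artery}_pct"
    pct = pd.array(cohort[col], dtype="Float64").to_numpy(dtype=float, na_value=np.nan)
    if np.sum(~np.isnan(pct)) < min_samples:
        raise ValueError(
            f"only {int(np.sum(~np.isnan(pct)))} samples with {col}; need >= {min_samples}"
        )
    spec = ModelSpec(
        preset="custom", cohort_flavor="autopsy", pc_count=pc_count,
        custom_terms=("score",) + CALC_TERMS, force_pcs=pc_count > 0,
    )
    design = _base_design(cohort, score, None, pcs, spec)
    covars = design.drop(columns=["cad_case"])
    observed = ~np.isnan(pct)
    covars = covars.loc[observed].reset_index(drop=True)
    prop = squeeze_boundaries(pct[observed] / 100.0)
    return fit_betareg(prop, covars)
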