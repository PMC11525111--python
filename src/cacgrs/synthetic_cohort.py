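"""Synthetic case-control cohorts with the structure the pipeline assumes.

No public data accompany the three cohorts the analysis design targets
(a large clinical angiography cohort, a small clinical cohort, and an
autopsy cohort with morphometric calcification), so this module generates
cohorts with the same statistical skeleton and serves as the
parameter-recovery ground truth for every downstream stage:

* a small set of independent score SNPs (default 11) plus a larger
  stand-in panel for a genome-wide CAD score, all under Hardy-Weinberg
  equilibrium with no LD;
* a standardized genetic risk score with a configurable per-SD odds
  ratio on CAD (default 1.4) and a ~70/30 case/control imbalance,
  calibrated exactly by bisection on the logistic intercept;
* beta-distributed calcified-plaque area percentages linked to the score
  on the logit-mean scale;
* stenosis percentages generated as a noisy monotone function of
  calcification and case status, purely so that stenosis-threshold case
  definitions are exercised;
* questionnaire-style missingness of smoking/hypertension for the
  autopsy flavor (default 65.5% missing, i.e. 34.5% returned).

Every cohort is emitted with a :class:`TruthRecord` holding the full
generating state, and can be written to disk in the exact external
formats ``cohort_io`` reads (scoring TSV, dosage VCF or TSV, phenotype
CSV). The on-disk VCF randomizes ref/alt orientation per variant so the
read-and-harmonize path is genuinely exercised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_io import COHORT_COLUMNS, DosageMatrix, VariantWeight, write_phenotypes, write_score_file
from .scoring import ScoreVector, compute_grs, standardize

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimBundle",
    "PRESETS",
    "COHORT_CASE_CONTROL",
    "QUESTIONNAIRE_RETURNED",
    "QUESTIONNAIRE_TOTAL",
    "preset_config",
    "gen_weights",
    "gen_genotypes",
    "gen_covariates",
    "gen_outcomes",
    "simulate",
    "gen_cohort",
]

# Printed case/control counts of the three target cohorts; the generator's
# preset sizes and imbalance are anchored to these, and they double as the
# worked-example inputs for analytic-sample arithmetic.
COHORT_CASE_CONTROL: dict[str, tuple[int, int]] = {
    "luric": (1912, 830),
    "tvs": (98, 35),
    "tsds": (327, 295),
}
#: postal-questionnaire lifestyle data returned / total recruited (autopsy cohort)
QUESTIONNAIRE_RETURNED = 228
QUESTIONNAIRE_TOTAL = 660

_DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    # per-unit log-ORs on CAD, anchored to conventional effect directions
    "age": float(np.log(1.05)),        # per year
    "sex_male": float(np.log(2.7)),
    "smoking": float(np.log(1.83)),
    "htn_med": float(np.log(1.32)),
    "hdl_chol": float(np.log(0.98)),   # per mg/dL, protective
    "total_chol": 0.0,
    "sbp": 0.0,
    "bmi": 0.0,
}

# Covariate generating means, used to center effect contributions so the
# intercept calibration is stable and missing entries contribute average risk.
_COVARIATE_MEANS: dict[str, float] = {
    "age": 62.0, "sex_male": 0.72, "smoking": 0.6, "htn_med": 0.58,
    "hdl_chol": 38.0, "total_chol": 208.0, "sbp": 140.0, "bmi": 27.5,
}


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic cohort."""

    n_samples: int
    n_score_snps: int = 11
    n_meta_snps: int = 1000  # tractable stand-in for a 1.7M-variant score
    maf_range: tuple[float, float] = (0.05, 0.5)
    per_sd_or_cad: float = 1.4
    per_sd_or_meta: float = 2.1  # second-score effect when it enters the outcome
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    target_case_fraction: float = 0.70
    calc_link: tuple[float, float, float] = (-1.5, float(np.log(1.78)), 0.3)
    calc_phi: float = 5.0
    missing_rate_lifestyle: float = 0.0
    dosage_noise_sd: float = 0.0
    cohort_flavor: str = "clinical"  # clinical | autopsy
    # When True the second (meta) score also drives the outcome at
    # per_sd_or_meta; off by default so the primary score's marginal
    # per-SD OR equals per_sd_or_cad without non-collapsibility attenuation.
    meta_in_outcome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_case_fraction < 1):
            raise ValueError("target_case_fraction must be in (0, 1)")
        if self.per_sd_or_cad <= 0 or self.per_sd_or_meta <= 0:
            raise ValueError("odds ratios must be positive")
        if self.calc_phi <= 0:
            raise ValueError("calc_phi must be positive")
        if not (0 <= self.missing_rate_lifestyle <= 1):
            raise ValueError("missing_rate_lifestyle must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")


#: presets mirroring the three target cohorts' size, imbalance and flavor
PRESETS: dict[str, dict] = {
    "luric": dict(
        n_samples=sum(COHORT_CASE_CONTROL["luric"]),
        target_case_fraction=COHORT_CASE_CONTROL["luric"][0] / sum(COHORT_CASE_CONTROL["luric"]),
        cohort_flavor="clinical",
    ),
    "tvs": dict(
        n_samples=sum(COHORT_CASE_CONTROL["tvs"]),
        target_case_fraction=COHORT_CASE_CONTROL["tvs"][0] / sum(COHORT_CASE_CONTROL["tvs"]),
        cohort_flavor="clinical",
    ),
    "tsds": dict(
        n_samples=sum(COHORT_CASE_CONTROL["tsds"]),
        target_case_fraction=COHORT_CASE_CONTROL["tsds"][0] / sum(COHORT_CASE_CONTROL["tsds"]),
        cohort_flavor="autopsy",
        missing_rate_lifestyle=1 - QUESTIONNAIRE_RETURNED / QUESTIONNAIRE_TOTAL,
    ),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A :class:`SimConfig` for one of the cohort presets (luric/tvs/tsds)."""
    try:
        base = dict(PRESETS[name.lower()])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    base.update(overrides)
    return SimConfig(seed=seed, **base)


@dataclass
class TruthRecord:
    """Full generating state of one simulated cohort.

    Together with the seed this is sufficient to recompute every latent
    probability: it stores the calibrated intercept, the per-sample linear
    predictors and the true per-SD log-OR.
    """

    config: dict
    alpha: float
    per_sd_log_or: float
    allele_freqs: list[float]
    meta_allele_freqs: list[float]
    eta: list[float]
    case_prob: list[float]
    calc_mu_lad: list[float]
    calc_mu_rca: list[float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class SimBundle:
    """In-memory simulated cohort: inputs, aligned dosages, truth."""

    config: SimConfig
    weights: list[VariantWeight]
    meta_weights: list[VariantWeight]
    dosages: DosageMatrix
    meta_dosages: DosageMatrix
    cohort: pd.DataFrame
    score: ScoreVector
    meta_score: ScoreVector
    truth: TruthRecord


_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


def gen_weights(
    n_snps: int,
    maf_range: tuple[float, float],
    rng: np.random.Generator,
    *,
    tau: float = 1.0,
    id_prefix: str = "rs",
    allow_palindromic: bool = False,
) -> tuple[list[VariantWeight], np.ndarray]:
    """Draw a scoring file's worth of variants: alleles, frequencies, weights.

    Allele pairs are non-palindromic by default. Raw weights are
    ``Normal(0, tau^2)`` and then rescaled so the raw score has unit
    variance in expectation under HWE
    (``sum_i w_i^2 * 2 f_i (1 - f_i) = 1``); ``tau = 0`` yields all-zero
    weights, which downstream standardization rejects as degenerate.
    Returns the weight records and the effect-allele frequencies.
    """
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    freqs = rng.uniform(*maf_range, size=n_snps)
    raw_w = rng.normal(0.0, tau, size=n_snps) if tau > 0 else np.zeros(n_snps)
    var_raw = float(np.sum(raw_w**2 * 2 * freqs * (1 - freqs)))
    weights_arr = raw_w / np.sqrt(var_raw) if var_raw > 0 else raw_w
    pairs = _NON_PALINDROMIC_PAIRS if not allow_palindromic else (
        _NON_PALINDROMIC_PAIRS + [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
    )
    records = []
    positions = rng.integers(1, 250_000_000, size=n_snps)
    chroms = rng.integers(1, 23, size=n_snps)
    ids = rng.integers(10_000, 100_000_000, size=n_snps)
    for i in range(n_snps):
        ea, oa = pairs[rng.integers(len(pairs))]
        records.append(
            VariantWeight(
                variant_id=f"{id_prefix}{ids[i]}_{i}",
                chromosome=str(chroms[i]),
                position=int(positions[i]),
                effect_allele=ea,
                other_allele=oa,
                effect_weight=float(weights_arr[i]),
                imputation_r2=float(rng.uniform(0.31, 0.99)),
            )
        )
    return records, freqs


def gen_genotypes(
    freqs: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    *,
    variant_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
    alleles: dict[str, tuple[str, str]] | None = None,
    dosage_noise_sd: float = 0.0,
) -> DosageMatrix:
    """Hard genotypes under HWE, optionally blurred into imputation-like dosages.

    Dosages are ``Binomial(2, f)`` per sample-variant (independent SNPs,
    no LD); with ``dosage_noise_sd > 0`` Gaussian noise is added and the
    result clipped to [0, 2], mimicking imputed expected counts. The
    returned matrix counts effect alleles (already aligned).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    d = rng.binomial(2, freqs, size=(n_samples, freqs.size)).astype(float)
    if dosage_noise_sd > 0:
        d = np.clip(d + rng.normal(0.0, dosage_noise_sd, size=d.shape), 0.0, 2.0)
    if variant_ids is None:
        variant_ids = [f"var{i}" for i in range(freqs.size)]
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    frame = pd.DataFrame(d, index=pd.Index(sample_ids, name="sample_id"), columns=variant_ids)
    return DosageMatrix(dosages=frame, alleles=dict(alleles or {}), harmonized=True)


def _na_series(index, dtype: str) -> pd.Series:
    na = np.nan if dtype == "float64" else pd.NA
    return pd.Series(na, index=index, dtype=dtype)


def gen_covariates(
    n_samples: int,
    cohort_flavor: str,
    rng: np.random.Generator,
    missing_rate_lifestyle: float = 0.0,
) -> pd.DataFrame:
    """Clinical covariates with marginals typical of angiography cohorts.

    age ~ N(62, 10) clipped to [18, 95] years; 72% male; BMI ~ N(27.5, 4)
    kg/m2; SBP ~ N(140, 20) mmHg; total cholesterol ~ N(208, 40) and HDL
    ~ N(38, 12) mg/dL; smoking ~ Bern(0.6); hypertension treatment ~
    Bern(0.58); statin ~ Bern(0.48). The autopsy flavor omits blood
    pressure, lipids and statin entirely and masks smoking/hypertension
    at ``missing_rate_lifestyle`` (postal-questionnaire non-response).
    """
    n = n_samples
    table = pd.DataFrame({
        "sample_id": pd.array([f"S{i:05d}" for i in range(n)], dtype="string"),
        "age": np.clip(rng.normal(62, 10, n), 18, 95),
        "sex": pd.array(np.where(rng.random(n) < 0.72, "male", "female"), dtype="string"),
        "bmi": np.clip(rng.normal(27.5, 4, n), 14, 65),
        "smoking": pd.array(rng.binomial(1, 0.6, n), dtype="Int64"),
        "htn_med": pd.array(rng.binomial(1, 0.58, n), dtype="Int64"),
    })
    if cohort_flavor == "clinical":
        table["sbp"] = rng.normal(140, 20, n)
        table["total_chol"] = np.clip(rng.normal(208, 40, n), 60, 500)
        table["hdl_chol"] = np.clip(rng.normal(38, 12, n), 5, 120)
        table["statin"] = pd.array(rng.binomial(1, 0.48, n), dtype="Int64")
    elif cohort_flavor == "autopsy":
        for col in ("sbp", "total_chol", "hdl_chol", "statin"):
            table[col] = _na_series(table.index, COHORT_COLUMNS[col])
        if missing_rate_lifestyle > 0:
            mask = rng.random(n) < missing_rate_lifestyle
            table.loc[mask, ["smoking", "htn_med"]] = pd.NA
    else:
        raise ValueError("cohort_flavor must be 'clinical' or 'autopsy'")
    for col in ("cad_case", "stenosis_lad_pct", "stenosis_rca_pct", "calc_lad_pct", "calc_rca_pct"):
        table[col] = _na_series(table.index, COHORT_COLUMNS[col])
    return table[list(COHORT_COLUMNS)]


def _linear_predictor(
    cohort: pd.DataFrame,
    z: np.ndarray,
    z_meta: np.ndarray | None,
    config: SimConfig,
) -> np.ndarray:
    """Centered-covariate linear predictor, without the intercept.

    Missing covariate entries contribute zero (average risk), so the
    calibrated case fraction is insensitive to questionnaire missingness.
    """
    eta = np.log(config.per_sd_or_cad) * z
    if z_meta is not None and config.meta_in_outcome:
        eta = eta + np.log(config.per_sd_or_meta) * z_meta
    known = ("sex_male", "age", "bmi", "sbp", "total_chol", "hdl_chol", "smoking", "htn_med")
    for name, effect in config.covariate_effects.items():
        if effect == 0 or name not in known:
            continue
        if name == "sex_male":
            x = pd.array(cohort["sex"] == "male", dtype="Float64").to_numpy(
                dtype=float, na_value=np.nan
            )
        else:
            x = pd.array(cohort[name], dtype="Float64").to_numpy(dtype=float, na_value=np.nan)
        if np.all(np.isnan(x)):
            continue  # covariate absent in this flavor
        centered = np.nan_to_num(x - _COVARIATE_MEANS.get(name, np.nanmean(x)), nan=0.0)
        eta = eta + effect * centered
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection on alpha so that mean(expit(alpha + eta)) = target."""
    lo, hi = -30.0, 30.0
    f = lambda a: float(np.mean(expit(a + eta))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("target case fraction unreachable at any intercept")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if abs(f(mid)) < tol and (hi - lo) < 1e-10:
            break
    return 0.5 * (lo + hi)


def gen_outcomes(
    cohort: pd.DataFrame,
    score: ScoreVector,
    config: SimConfig,
    rng: np.random.Generator,
    meta_score: ScoreVector | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw CAD status, calcification percentages and stenosis.

    CAD: ``logit P(case) = alpha + log(OR_sd) * z + covariate effects``,
    with alpha calibrated by bisection so the population case fraction
    hits ``target_case_fraction`` to 1e-4. Calcification: independent
    LAD/RCA draws from ``Beta(mu * phi, (1 - mu) * phi)`` with
    ``logit(mu)`` linear in the standardized score and standardized age,
    scaled to percent. Stenosis: a noisy monotone transform of
    calcification plus a case offset, supplied only so stenosis-based
    case definitions are exercised — no biological fidelity is claimed.
    """
    if score.standardized is None:
        raise ValueError("score must be standardized before outcome generation")
    z = np.asarray(score.standardized, dtype=float)
    z_meta = None
    if meta_score is not None:
        if meta_score.standardized is None:
            raise ValueError("meta score must be standardized")
        z_meta = np.asarray(meta_score.standardized, dtype=float)
    eta = _linear_predictor(cohort, z, z_meta, config)
    alpha = _calibrate_intercept(eta, config.target_case_fraction)
    p = expit(alpha + eta)
    cad = rng.binomial(1, p)

    age = np.asarray(cohort["age"], dtype=float)
    z_age = (age - age.mean()) / age.std(ddof=1)
    icpt, b_score, b_age = config.calc_link
    mu_lad = expit(icpt + b_score * z + b_age * z_age)
    mu_rca = expit(icpt + b_score * z + b_age * z_age)
    phi = config.calc_phi
    calc_lad = 100 * rng.beta(mu_lad * phi, (1 - mu_lad) * phi)
    calc_rca = 100 * rng.beta(mu_rca * phi, (1 - mu_rca) * phi)

    sten_lad = np.clip(20 + 0.3 * calc_lad + 40 * cad + rng.normal(0, 10, cad.size), 0, 100)
    sten_rca = np.clip(20 + 0.3 * calc_rca + 40 * cad + rng.normal(0, 10, cad.size), 0, 100)

    out = cohort.copy()
    out["cad_case"] = pd.array(cad, dtype="Int64")
    out["calc_lad_pct"] = calc_lad
    out["calc_rca_pct"] = calc_rca
    out["stenosis_lad_pct"] = sten_lad
    out["stenosis_rca_pct"] = sten_rca
    truth = TruthRecord(
        config={**asdict(config), "covariate_effects": dict(config.covariate_effects)},
        alpha=alpha,
        per_sd_log_or=float(np.log(config.per_sd_or_cad)),
        allele_freqs=[],
        meta_allele_freqs=[],
        eta=(alpha + eta).tolist(),
        case_prob=p.tolist(),
        calc_mu_lad=mu_lad.tolist(),
        calc_mu_rca=mu_rca.tolist(),
    )
    return out, truth


def simulate(config: SimConfig) -> SimBundle:
    """End-to-end in-memory cohort: weights, dosages, covariates, outcomes.

    Deterministic in ``config.seed``: independent RNG streams are spawned
    for weights, genotypes, covariates and outcomes, so e.g. enlarging the
    meta panel does not reshuffle the covariates.
    """
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(6)
    rngs = [np.random.default_rng(s) for s in ss]

    weights, freqs = gen_weights(config.n_score_snps, config.maf_range, rngs[0])
    meta_weights, meta_freqs = gen_weights(
        config.n_meta_snps, config.maf_range, rngs[1], id_prefix="rsm"
    )
    sample_ids = [f"S{i:05d}" for i in range(config.n_samples)]
    dosages = gen_genotypes(
        freqs, config.n_samples, rngs[2],
        variant_ids=[w.variant_id for w in weights],
        sample_ids=sample_ids,
        alleles={w.variant_id: (w.other_allele, w.effect_allele) for w in weights},
        dosage_noise_sd=config.dosage_noise_sd,
    )
    meta_dosages = gen_genotypes(
        meta_freqs, config.n_samples, rngs[3],
        variant_ids=[w.variant_id for w in meta_weights],
        sample_ids=sample_ids,
        alleles={w.variant_id: (w.other_allele, w.effect_allele) for w in meta_weights},
        dosage_noise_sd=config.dosage_noise_sd,
    )
    score = standardize(compute_grs(weights, dosages))
    meta_score = standardize(compute_grs(meta_weights, meta_dosages))

    covariates = gen_covariates(
        config.n_samples, config.cohort_flavor, rngs[4],
        missing_rate_lifestyle=0.0,  # mask after outcome generation
    )
    cohort, truth = gen_outcomes(covariates, score, config, rngs[5], meta_score=meta_score)
    if config.cohort_flavor == "clinical":
        # morphometric calcification is an autopsy measurement
        cohort[["calc_lad_pct", "calc_rca_pct"]] = np.nan
    if config.cohort_flavor == "autopsy" and config.missing_rate_lifestyle > 0:
        mask = rngs[4].random(config.n_samples) < config.missing_rate_lifestyle
        cohort.loc[mask, ["smoking", "htn_med"]] = pd.NA
    cohort["sample_id"] = pd.array(sample_ids, dtype="string")
    truth.allele_freqs = freqs.tolist()
    truth.meta_allele_freqs = meta_freqs.tolist()
    return SimBundle(
        config=config,
        weights=weights,
        meta_weights=meta_weights,
        dosages=dosages,
        meta_dosages=meta_dosages,
        cohort=cohort,
        score=score,
        meta_score=meta_score,
        truth=truth,
    )


def _write_vcf(
    bundle: SimBundle, path: Path, rng: np.random.Generator
) -> None:
    """Plain-text VCF v4.2 with a DS FORMAT field for all simulated variants.

    Each variant's ref/alt orientation is randomized: with probability
    one half the effect allele is written as REF and the stored dosage as
    ``2 - d``, so reading the file back requires real harmonization.
    """
    all_weights = bundle.weights + bundle.meta_weights
    mats = [bundle.dosages, bundle.meta_dosages]
    samples = bundle.dosages.sample_ids
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in sorted({int(w.chromosome) for w in all_weights}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        rows = []
        for mat in mats:
            arr = mat.dosages.to_numpy(dtype=float)
            for j, vid in enumerate(mat.variant_ids):
                rows.append((vid, arr[:, j]))
        weight_by_id = {w.variant_id: w for w in all_weights}
        # VCFs are position-sorted in practice; sort by chrom, pos
        rows.sort(key=lambda r: (int(weight_by_id[r[0]].chromosome), weight_by_id[r[0]].position))
        for vid, dose in rows:
            w = weight_by_id[vid]
            flip = rng.random() < 0.5
            if flip:
                ref, alt = w.effect_allele, w.other_allele
                dose = 2.0 - dose
            else:
                ref, alt = w.other_allele, w.effect_allele
            ds = "\t".join(format(v, ".4g") for v in dose)
            fh.write(f"{w.chromosome}\t{w.position}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tDS\t{ds}\n")


def _write_dosage_tsv(bundle: SimBundle, path: Path, rng: np.random.Generator) -> None:
    """TSV dosage matrix with an ``#alleles`` header line, random orientation."""
    frames = []
    allele_tokens = []
    for mat, weights in ((bundle.dosages, bundle.weights), (bundle.meta_dosages, bundle.meta_weights)):
        frame = mat.dosages.copy()
        for w in weights:
            if rng.random() < 0.5:
                frame[w.variant_id] = 2.0 - frame[w.variant_id]
                allele_tokens.append(f"{w.variant_id}={w.effect_allele}/{w.other_allele}")
            else:
                allele_tokens.append(f"{w.variant_id}={w.other_allele}/{w.effect_allele}")
        frames.append(frame)
    merged = pd.concat(frames, axis=1)
    with path.open("w") as fh:
        fh.write("#alleles " + " ".join(allele_tokens) + "\n")
        merged.to_csv(fh, sep="\t", float_format="%.6g")


def gen_cohort(
    config: SimConfig,
    out_dir: str | Path,
    genotype_format: str = "vcf",
) -> SimBundle:
    """Simulate and write a complete cohort bundle in external formats.

    Emits ``weights.tsv`` and ``meta_weights.tsv`` (scoring-file dialect),
    ``genotypes.vcf`` or ``genotypes.tsv``, ``phenotypes.csv`` and
    ``truth.json`` under ``out_dir``. Byte-identical across runs with the
    same config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = simulate(config)
    write_score_file(bundle.weights, out_dir / "weights.tsv")
    write_score_file(bundle.meta_weights, out_dir / "meta_weights.tsv")
    orient_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6])
    if genotype_format == "vcf":
        _write_vcf(bundle, out_dir / "genotypes.vcf", orient_rng)
    elif genotype_format == "tsv":
        _write_dosage_tsv(bundle, out_dir / "genotypes.tsv", orient_rng)
    else:
        raise ValueError("genotype_format must be 'vcf' or 'tsv'")
    write_phenotypes(bundle.cohort, out_dir / "phenotypes.csv")
    bundle.truth.to_json(out_dir / "truth.json")
    return bundle
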