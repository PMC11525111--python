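"""End-to-end orchestration: ingest/simulate -> score -> associate ->
calcification -> added value, from a single config, with a provenance
manifest.

A run is described by a :class:`RunConfig` (buildable from YAML). Inputs
are either a named synthetic preset — in which case the generator writes
the external files and the pipeline *reads them back* through the same
parsers real data would use — or explicit paths to a weights TSV, a
genotype VCF/TSV and a phenotype CSV. Every stage writes its outputs
under the run directory and registers them, SHA-256 hashed, in
``manifest.json``; a stage failure is recorded and dependent stages are
skipped while completed outputs stay on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .added_value import bootstrap_delta_auc, undersample_balance
from .association import ModelSpec, compute_pcs, quantile_association, run_model, stratified_association
from .beta_calcification import run_calcification_model
from .cohort_io import harmonize_alleles, read_dosages, read_phenotypes, read_score_file
from .scoring import compute_grs, quantile_bins, standardize
from .synthetic_cohort import SimConfig, gen_cohort, preset_config

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

#: reference predictors for the added-value comparison (FRS covariates)
FRS_TERMS = ("age", "sex_male", "sbp", "total_chol", "hdl_chol", "smoking", "htn_med")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; every default is manifest-logged."""

    out_dir: str
    seed: int
    preset: str | None = None  # luric | tvs | tsds, or None with explicit paths
    weights_path: str | None = None
    meta_weights_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    genotype_format: str = "vcf"
    cohort_flavor: str = "clinical"
    models: tuple[int, ...] = (1, 2, 3)
    pc_count: int = 5
    n_bins: int = 4
    stratify: tuple[str, ...] = ()
    bootstraps: int = 1000
    train_fraction: float = 0.7
    balanced: bool = False
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("models", "stratify"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if cfg.preset is None:
            for p in (cfg.weights_path, cfg.genotypes_path, cfg.phenotypes_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path missing or nonexistent: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.data = {
            "tool": f"cacgrs {__version__}",
            "config": asdict(config),
            "stages": {},
            "outputs": {},
        }

    def record(self, stage: str, status: str, detail: str = "") -> None:
        self.data["stages"][stage] = {"status": status, "detail": detail}

    def add_output(self, path: Path) -> None:
        self.data["outputs"][str(path.relative_to(self.out_dir))] = _sha256(path)

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=1, default=str))
        return path


def _assoc_result_files(result, out_dir: Path, name: str, manifest: _Manifest) -> None:
    tsv = out_dir / f"{name}.tsv"
    result.to_table().to_csv(tsv, sep="\t", index=False)
    diag = out_dir / f"{name}.json"
    diag.write_text(json.dumps({
        "n_used": result.n_used,
        "converged": result.converged,
        "log_likelihood": result.log_likelihood,
        "warnings": result.warnings,
        "terms": result.terms.reset_index().to_dict(orient="records"),
    }, indent=1))
    manifest.add_output(tsv)
    manifest.add_output(diag)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, config)

    # --- input stage: simulate-or-load, always through the file readers ---
    try:
        if config.preset is not None:
            sim_cfg = preset_config(config.preset, seed=config.seed, **config.sim_overrides)
            input_dir = out_dir / "input"
            gen_cohort(sim_cfg, input_dir, genotype_format=config.genotype_format)
            flavor = sim_cfg.cohort_flavor
            weights_path = input_dir / "weights.tsv"
            meta_weights_path = input_dir / "meta_weights.tsv"
            genotypes_path = input_dir / f"genotypes.{config.genotype_format}"
            phenotypes_path = input_dir / "phenotypes.csv"
            for p in (weights_path, meta_weights_path, genotypes_path, phenotypes_path,
                      input_dir / "truth.json"):
                manifest.add_output(p)
        else:
            flavor = config.cohort_flavor
            weights_path = Path(config.weights_path)
            meta_weights_path = (
                Path(config.meta_weights_path) if config.meta_weights_path else None
            )
            genotypes_path = Path(config.genotypes_path)
            phenotypes_path = Path(config.phenotypes_path)

        weights = read_score_file(weights_path)
        cohort = read_phenotypes(phenotypes_path)
        matrix = read_dosages(genotypes_path, weights)
        matrix, weights, exclusions = harmonize_alleles(matrix, weights)
        meta_weights = meta_matrix = None
        if meta_weights_path is not None:
            meta_weights = read_score_file(meta_weights_path)
            meta_matrix = read_dosages(genotypes_path, meta_weights)
            meta_matrix, meta_weights, meta_excl = harmonize_alleles(meta_matrix, meta_weights)
            exclusions = exclusions + meta_excl
        excl_path = out_dir / "harmonization_exclusions.json"
        excl_path.write_text(json.dumps(exclusions, indent=1))
        manifest.add_output(excl_path)
        # align phenotype rows to the genotype sample order
        cohort = cohort.set_index("sample_id").loc[matrix.sample_ids].reset_index()
        cohort["sample_id"] = cohort["sample_id"].astype("string")
        manifest.record("input", "ok", f"{len(weights)} score variants, n={len(cohort)}")
    except Exception as exc:
        logger.exception("input stage failed")
        manifest.record("input", "failed", str(exc))
        for stage in ("score", "assoc", "calc", "added_value"):
            manifest.record(stage, "skipped", "input stage failed")
        manifest.write()
        return manifest.data

    # --- score stage ---
    try:
        score = standardize(compute_grs(weights, matrix))
        meta_score = None
        if meta_matrix is not None:
            meta_score = standardize(compute_grs(meta_weights, meta_matrix))
        bins = quantile_bins(score, n_bins=config.n_bins)
        score_path = out_dir / "scores.tsv"
        score.write_tsv(score_path, bins)
        manifest.add_output(score_path)
        manifest.record("score", "ok", f"{score.n_imputed_entries} imputed dosage entries")
    except Exception as exc:
        logger.exception("score stage failed")
        manifest.record("score", "failed", str(exc))
        for stage in ("assoc", "calc", "added_value"):
            manifest.record(stage, "skipped", "score stage failed")
        manifest.write()
        return manifest.data

    # --- association stage ---
    try:
        pc_source = meta_matrix if meta_matrix is not None else matrix
        pcs = compute_pcs(pc_source, k=config.pc_count) if config.pc_count > 0 else None
        assoc_dir = out_dir / "assoc"
        assoc_dir.mkdir(exist_ok=True)
        for m in config.models:
            if m == 3 and meta_score is None:
                manifest.record("assoc_model3", "skipped", "no second score supplied")
                continue
            spec = ModelSpec(preset=f"model{m}", cohort_flavor=flavor, pc_count=config.pc_count)
            res = run_model(cohort, spec, score, second_score=meta_score, pcs=pcs)
            _assoc_result_files(res, assoc_dir, f"model{m}", manifest)
        qspec = ModelSpec(preset="model2", cohort_flavor=flavor, pc_count=config.pc_count)
        qres = quantile_association(cohort, bins, qspec, pcs=pcs)
        _assoc_result_files(qres, assoc_dir, "quantiles_model2", manifest)
        for strata in config.stratify:
            sres = stratified_association(cohort, qspec, score, strata=strata, pcs=pcs)
            for sname, r in sres.items():
                if isinstance(r, str):
                    manifest.record(f"assoc_stratum_{sname}", "failed", r)
                else:
                    _assoc_result_files(r, assoc_dir, f"stratum_{sname}", manifest)
        manifest.record("assoc", "ok")
    except Exception as exc:
        logger.exception("association stage failed")
        manifest.record("assoc", "failed", str(exc))

    # --- calcification stage ---
    calc_available = cohort["calc_lad_pct"].notna().sum() >= 30 or \
        cohort["calc_rca_pct"].notna().sum() >= 30
    if not calc_available:
        manifest.record("calc", "skipped", "no calcified-plaque measurements in cohort")
    else:
        try:
            calc_dir = out_dir / "calc"
            calc_dir.mkdir(exist_ok=True)
            pcs_calc = pcs if config.pc_count > 0 else None
            for artery in ("lad", "rca"):
                res = run_calcification_model(cohort, artery, score, pcs=pcs_calc,
                                              pc_count=config.pc_count)
                tsv = calc_dir / f"{artery}.tsv"
                res.terms.reset_index().to_csv(tsv, sep="\t", index=False)
                diag = calc_dir / f"{artery}.json"
                diag.write_text(json.dumps({
                    "precision_phi": res.precision_phi,
                    "log_likelihood": res.log_likelihood,
                    "n_used": res.n_used,
                    "boundary_adjusted": res.boundary_adjusted,
                    "converged": res.converged,
                    "warnings": res.warnings,
                }, indent=1))
                manifest.add_output(tsv)
                manifest.add_output(diag)
            manifest.record("calc", "ok")
        except Exception as exc:
            logger.exception("calcification stage failed")
            manifest.record("calc", "failed", str(exc))

    # --- added-value stage ---
    try:
        design = _added_value_design(cohort, score, meta_score, flavor)
        data = undersample_balance(design, rng=config.seed) if config.balanced else design
        ref_terms = [t for t in FRS_TERMS if data[t].notna().any()]
        comparisons = {"grs": ref_terms + ["score"]}
        if meta_score is not None:
            comparisons["metagrs"] = ref_terms + ["second_score"]
            comparisons["both"] = ref_terms + ["score", "second_score"]
        av_dir = out_dir / "added_value"
        av_dir.mkdir(exist_ok=True)
        for name, test_terms in comparisons.items():
            report = bootstrap_delta_auc(
                data, ref_terms, test_terms, B=config.bootstraps,
                train_fraction=config.train_fraction, seed=config.seed,
                balanced=config.balanced,
            )
            tsv = av_dir / f"{name}_bootstrap_aucs.tsv"
            report.to_frame().to_csv(tsv, sep="\t", index=False)
            js = av_dir / f"{name}.json"
            js.write_text(json.dumps(report.summary(), indent=1))
            manifest.add_output(tsv)
            manifest.add_output(js)
        manifest.record("added_value", "ok")
    except Exception as exc:
        logger.exception("added-value stage failed")
        manifest.record("added_value", "failed", str(exc))

    manifest.write()
    return manifest.data


def _added_value_design(cohort, score, meta_score, flavor) -> pd.DataFrame:
    """Numeric frame with the outcome, FRS covariates and score columns."""
    design = pd.DataFrame(index=cohort.index)
    design["cad_case"] = pd.array(cohort["cad_case"], dtype="Float64").to_numpy(
        dtype=float, na_value=np.nan
    )
    design["sex_male"] = pd.array(cohort["sex"] == "male", dtype="Float64").to_numpy(
        dtype=float, na_value=np.nan
    )
    for col in ("age", "sbp", "total_chol", "hdl_chol", "smoking", "htn_med", "bmi"):
        design[col] = pd.array(cohort[col], dtype="Float64").to_numpy(
            dtype=float, na_value=np.nan
        )
    design["score"] = np.asarray(score.standardized, dtype=float)
    if meta_score is not None:
        design["second_score"] = np.asarray(meta_score.standardized, dtype=float)
    return design
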