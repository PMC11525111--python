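"""Generator correctness: HWE genotypes, calibrated outcomes, determinism."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from cacgrs.association import fit_logistic
from cacgrs.cohort_io import harmonize_alleles, read_dosages, read_score_file
from cacgrs.scoring import compute_grs, standardize
from cacgrs.synthetic_cohort import (
    COHORT_CASE_CONTROL,
    SimConfig,
    gen_cohort,
    gen_covariates,
    gen_genotypes,
    gen_outcomes,
    gen_weights,
    preset_config,
    simulate,
)


class TestGenWeights:
    def test_round_trips_through_score_file(self, tmp_path, rng):
        from cacgrs.cohort_io import write_score_file

        weights, _ = gen_weights(11, (0.05, 0.5), rng)
        assert len(weights) == 11
        assert not any(w.is_palindromic for w in weights)
        path = tmp_path / "w.tsv"
        write_score_file(weights, path)
        assert read_score_file(path) == weights

    def test_expected_unit_score_variance(self, rng):
        weights, freqs = gen_weights(11, (0.05, 0.5), rng)
        w = np.array([x.effect_weight for x in weights])
        assert np.sum(w**2 * 2 * freqs * (1 - freqs)) == pytest.approx(1.0)

    def test_tau_zero_makes_score_degenerate(self, rng):
        weights, freqs = gen_weights(5, (0.1, 0.5), rng, tau=0.0)
        matrix = gen_genotypes(freqs, 50, rng, variant_ids=[w.variant_id for w in weights])
        with pytest.raises(ValueError, match="degenerate"):
            standardize(compute_grs(weights, matrix))

    def test_same_seed_same_weights(self):
        w1, f1 = gen_weights(11, (0.05, 0.5), np.random.default_rng(7))
        w2, f2 = gen_weights(11, (0.05, 0.5), np.random.default_rng(7))
        assert w1 == w2 and np.array_equal(f1, f2)


class TestGenGenotypes:
    def test_mean_dosage_matches_frequency(self, rng):
        m = gen_genotypes(np.array([0.5]), 10_000, rng)
        assert m.dosages.to_numpy().mean() == pytest.approx(1.0, abs=0.02)

    def test_noiseless_dosages_are_hard_calls(self, rng):
        m = gen_genotypes(np.array([0.3, 0.4]), 200, rng)
        assert set(np.unique(m.dosages.to_numpy())) <= {0.0, 1.0, 2.0}

    def test_noise_blurs_but_stays_in_range(self, rng):
        m = gen_genotypes(np.array([0.3]), 500, rng, dosage_noise_sd=0.2)
        vals = m.dosages.to_numpy()
        assert np.all((vals >= 0) & (vals <= 2))
        assert not set(np.unique(vals)) <= {0.0, 1.0, 2.0}

    def test_hwe_genotype_proportions(self):
        """Chi-square against p^2/2pq/q^2 is non-significant in >= 95% of sims."""
        rng = np.random.default_rng(33)
        ok = 0
        for _ in range(100):
            f = rng.uniform(0.2, 0.5)
            d = gen_genotypes(np.array([f]), 2000, rng).dosages.to_numpy().ravel()
            obs = np.bincount(d.astype(int), minlength=3)
            exp = 2000 * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
            p = stats.chisquare(obs, exp).pvalue
            ok += p > 0.01
        assert ok >= 95


class TestGenCovariates:
    def test_clinical_flavor_is_complete(self, rng):
        t = gen_covariates(2000, "clinical", rng)
        for col in ("age", "sex", "bmi", "sbp", "total_chol", "hdl_chol", "smoking", "htn_med"):
            assert t[col].notna().all(), col

    def test_autopsy_missingness_near_design_rate(self, rng):
        t = gen_covariates(2000, "autopsy", rng, missing_rate_lifestyle=0.655)
        observed = t["smoking"].notna().mean()
        assert observed == pytest.approx(0.345, abs=0.03)
        assert t["sbp"].isna().all() and t["total_chol"].isna().all()

    def test_seeded_reproducibility(self):
        t1 = gen_covariates(100, "clinical", np.random.default_rng(5))
        t2 = gen_covariates(100, "clinical", np.random.default_rng(5))
        pd.testing.assert_frame_equal(t1, t2)


class TestGenOutcomes:
    def _score(self, rng, n):
        from cacgrs.scoring import ScoreVector

        raw = rng.normal(size=n)
        return standardize(ScoreVector([f"S{i}" for i in range(n)], raw))

    def test_null_model_hits_target_fraction_and_independence(self, rng):
        n = 20_000
        cfg = SimConfig(n_samples=n, per_sd_or_cad=1.0, covariate_effects={},
                        target_case_fraction=0.7)
        cov = gen_covariates(n, "clinical", rng)
        score = self._score(rng, n)
        out, truth = gen_outcomes(cov, score, cfg, rng)
        frac = out["cad_case"].mean()
        assert frac == pytest.approx(0.7, abs=3 * np.sqrt(0.21 / n) + 1e-4)
        r = np.corrcoef(score.standardized, out["cad_case"].to_numpy(dtype=float))[0, 1]
        assert abs(r) < 0.02

    def test_self_consistency_at_large_n(self, rng):
        """Refit of case status on the score alone recovers log(1.4) closely."""
        n = 100_000
        cfg = SimConfig(n_samples=n, per_sd_or_cad=1.4, covariate_effects={})
        cov = gen_covariates(n, "clinical", rng)
        score = self._score(rng, n)
        out, truth = gen_outcomes(cov, score, cfg, rng)
        res = fit_logistic(pd.DataFrame({
            "cad_case": out["cad_case"].to_numpy(dtype=float),
            "z": score.standardized,
        }))
        assert res.term("z")["estimate"] == pytest.approx(np.log(1.4), abs=0.03)

    def test_generative_inferential_consistency_with_covariates(self, rng):
        """The full generating model is recovered within 3 SEs at large n."""
        n = 100_000
        cfg = SimConfig(n_samples=n)
        cov = gen_covariates(n, "clinical", rng)
        score = self._score(rng, n)
        out, truth = gen_outcomes(cov, score, cfg, rng)
        design = pd.DataFrame({
            "cad_case": out["cad_case"].to_numpy(dtype=float),
            "z": score.standardized,
            "age": out["age"],
            "sex_male": (out["sex"] == "male").astype(float),
            "smoking": out["smoking"].to_numpy(dtype=float),
            "htn_med": out["htn_med"].to_numpy(dtype=float),
            "hdl_chol": out["hdl_chol"],
        })
        res = fit_logistic(design)
        for term, target in [
            ("z", np.log(1.4)), ("age", np.log(1.05)), ("sex_male", np.log(2.7)),
            ("smoking", np.log(1.83)), ("htn_med", np.log(1.32)), ("hdl_chol", np.log(0.98)),
        ]:
            t = res.term(term)
            assert abs(t["estimate"] - target) < 3 * t["std_error"], term

    def test_calcification_link_recovered(self, rng):
        from cacgrs.beta_calcification import fit_betareg, squeeze_boundaries

        n = 4000
        cfg = SimConfig(n_samples=n, cohort_flavor="autopsy")
        cov = gen_covariates(n, "autopsy", rng)
        score = self._score(rng, n)
        out, truth = gen_outcomes(cov, score, cfg, rng)
        prop = squeeze_boundaries(out["calc_lad_pct"].to_numpy() / 100)
        age = out["age"].to_numpy()
        res = fit_betareg(prop, pd.DataFrame({
            "z": score.standardized,
            "z_age": (age - age.mean()) / age.std(ddof=1),
        }))
        assert res.term("z")["estimate"] == pytest.approx(np.log(1.78), rel=0.1)
        assert res.precision_phi == pytest.approx(5.0, rel=0.15)

    def test_stenosis_tracks_case_status(self, rng):
        n = 3000
        cfg = SimConfig(n_samples=n)
        cov = gen_covariates(n, "clinical", rng)
        score = self._score(rng, n)
        out, _ = gen_outcomes(cov, score, cfg, rng)
        from cacgrs.cohort_io import define_cad_cases

        redefined = define_cad_cases(out)
        agree = (redefined["cad_case"] == out["cad_case"]).mean()
        assert agree > 0.8  # noisy but strongly concordant

    def test_unreachable_target_raises(self, rng):
        # one structurally risk-free sample caps the mean probability at 99/100
        cfg = SimConfig(n_samples=100, target_case_fraction=0.995, covariate_effects={})
        cov = gen_covariates(100, "clinical", rng)
        score = self._score(rng, 100)
        bad = score.standardized.copy()
        bad[0] = -np.inf
        from cacgrs.scoring import ScoreVector

        with pytest.raises(RuntimeError, match="unreachable"):
            gen_outcomes(cov, ScoreVector(score.sample_ids, score.raw, bad), cfg, rng)


class TestBundles:
    def test_preset_sizes_match_printed_counts(self):
        for name, (cases, controls) in COHORT_CASE_CONTROL.items():
            cfg = preset_config(name)
            assert cfg.n_samples == cases + controls
            assert cfg.target_case_fraction == pytest.approx(cases / (cases + controls))

    def test_gen_cohort_is_byte_deterministic(self, tmp_path):
        cfg = preset_config("tvs", seed=4, n_meta_snps=20)
        gen_cohort(cfg, tmp_path / "a")
        gen_cohort(cfg, tmp_path / "b")
        for fname in ("weights.tsv", "meta_weights.tsv", "genotypes.vcf",
                      "phenotypes.csv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / fname, tmp_path / "b" / fname, shallow=False), fname

    def test_bundle_files_reload_to_same_matrix(self, tmp_path):
        cfg = preset_config("tvs", seed=6, n_meta_snps=15)
        bundle = gen_cohort(cfg, tmp_path / "c", genotype_format="vcf")
        weights = read_score_file(tmp_path / "c" / "weights.tsv")
        matrix = read_dosages(tmp_path / "c" / "genotypes.vcf", weights)
        aligned, kept, excl = harmonize_alleles(matrix, weights)
        assert not excl
        np.testing.assert_allclose(
            aligned.dosages.to_numpy(), bundle.dosages.dosages.to_numpy()
        )

    def test_truth_record_reproduces_probabilities(self, tmp_path):
        cfg = preset_config("tvs", seed=8, n_meta_snps=15)
        bundle = gen_cohort(cfg, tmp_path / "d")
        truth = json.loads((tmp_path / "d" / "truth.json").read_text())
        np.testing.assert_allclose(
            expit(np.array(truth["eta"])), np.array(truth["case_prob"]), rtol=1e-12
        )
        assert truth["per_sd_log_or"] == pytest.approx(np.log(cfg.per_sd_or_cad))

    def test_autopsy_preset_runs_reduced_models(self, small_autopsy_bundle):
        b = small_autopsy_bundle
        assert b.cohort["sbp"].isna().all()
        assert b.cohort["smoking"].notna().mean() == pytest.approx(0.345, abs=0.06)
        assert b.cohort["calc_lad_pct"].notna().all()
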