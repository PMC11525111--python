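"""Readers, writers, allele harmonization and case definitions."""

import numpy as np
import pandas as pd
import pytest

from cacgrs.cohort_io import (
    DosageMatrix,
    FormatError,
    VariantWeight,
    define_cad_cases,
    filter_by_imputation_r2,
    harmonize_alleles,
    read_dosages,
    read_phenotypes,
    read_score_file,
    write_phenotypes,
    write_score_file,
)
from cacgrs.synthetic_cohort import gen_covariates, gen_weights

HEADER = "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"


def _weights_file(tmp_path, body, header=HEADER):
    p = tmp_path / "w.tsv"
    p.write_text("# a comment\n" + header + body)
    return p


class TestScoreFile:
    def test_eleven_row_file_parses_to_eleven_records(self, tmp_path):
        body = "".join(
            f"rs{i}\t{i % 22 + 1}\t{1000 + i}\tA\tG\t{0.01 * (i + 1)}\n" for i in range(11)
        )
        records = read_score_file(_weights_file(tmp_path, body))
        assert len(records) == 11
        assert [r.variant_id for r in records] == [f"rs{i}" for i in range(11)]
        assert records[3].effect_weight == pytest.approx(0.04)

    def test_empty_data_section_gives_empty_list(self, tmp_path):
        assert read_score_file(_weights_file(tmp_path, "")) == []

    def test_non_numeric_weight_names_line(self, tmp_path):
        body = "rs1\t1\t100\tA\tG\t0.1\nrs2\t2\t200\tC\tT\tNA\n"
        with pytest.raises(FormatError, match="line 4"):  # comment + header + 2 rows
            read_score_file(_weights_file(tmp_path, body))

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        header = "rsID\tchr_name\tchr_position\teffect_allele\teffect_weight\n"
        with pytest.raises(FormatError, match="other_allele"):
            read_score_file(_weights_file(tmp_path, "", header=header))

    def test_alleles_uppercased_and_validated(self, tmp_path):
        records = read_score_file(_weights_file(tmp_path, "rs1\t1\t100\ta\tg\t0.5\n"))
        assert records[0].effect_allele == "A" and records[0].other_allele == "G"
        with pytest.raises(ValueError, match="identical"):
            VariantWeight("rsx", "1", 1, "A", "A", 0.1)

    def test_write_read_round_trip_is_exact(self, tmp_path, rng):
        weights, _ = gen_weights(11, (0.05, 0.5), rng)
        path = tmp_path / "rt.tsv"
        write_score_file(weights, path)
        back = read_score_file(path)
        assert back == weights

    def test_imputation_r2_filter(self):
        ws = [
            VariantWeight("a", "1", 1, "A", "G", 0.1, imputation_r2=0.2),
            VariantWeight("b", "1", 2, "A", "G", 0.1, imputation_r2=0.9),
            VariantWeight("c", "1", 3, "A", "G", 0.1, imputation_r2=None),
        ]
        assert [w.variant_id for w in filter_by_imputation_r2(ws)] == ["b", "c"]


VCF_TEMPLATE = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID={fmt},Number=1,Type={typ},Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
{body}"""


class TestReadDosages:
    def test_gt_hard_calls_convert_to_counts(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_TEMPLATE.format(
            fmt="GT", typ="String",
            body="1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"))
        m = read_dosages(p, [VariantWeight("rs1", "1", 100, "G", "A", 0.3)])
        assert m.dosages["rs1"].tolist() == [0.0, 1.0, 2.0]

    def test_fractional_dosage_retained_unrounded(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_TEMPLATE.format(
            fmt="DS", typ="Float",
            body="1\t100\trs1\tA\tG\t.\tPASS\t.\tDS\t1.37\t0.0\t2.0\n"))
        m = read_dosages(p, [VariantWeight("rs1", "1", 100, "G", "A", 0.3)])
        assert m.dosages["rs1"].iloc[0] == pytest.approx(1.37)

    def test_absent_wanted_variant_is_reported(self, tmp_path, rng):
        weights, _ = gen_weights(11, (0.1, 0.5), rng)
        p = tmp_path / "a.vcf"
        body = "".join(
            f"{w.chromosome}\t{w.position}\t{w.variant_id}\t{w.other_allele}\t"
            f"{w.effect_allele}\t.\tPASS\t.\tDS\t1.0\t0.5\t2.0\n"
            for w in weights[:10]  # drop the 11th site
        )
        p.write_text(VCF_TEMPLATE.format(fmt="DS", typ="Float", body=body))
        m = read_dosages(p, weights)
        assert m.n_variants == 10
        assert m.missing_variants == [weights[10].variant_id]

    def test_no_wanted_variant_found_is_hard_error(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_TEMPLATE.format(
            fmt="DS", typ="Float",
            body="1\t100\trsX\tA\tG\t.\tPASS\t.\tDS\t1.0\t1.0\t1.0\n"))
        with pytest.raises(FormatError, match="none of the"):
            read_dosages(p, [VariantWeight("rs1", "2", 999, "G", "A", 0.3)])

    def test_match_by_position_when_id_differs(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_TEMPLATE.format(
            fmt="DS", typ="Float",
            body="1\t100\tchip_id_7\tA\tG\t.\tPASS\t.\tDS\t1.0\t0.0\t2.0\n"))
        m = read_dosages(p, [VariantWeight("rs1", "1", 100, "G", "A", 0.3)])
        assert m.n_variants == 1


def _matrix(dosage_rows, alleles):
    frame = pd.DataFrame(
        dosage_rows, index=[f"S{i}" for i in range(len(dosage_rows))],
        columns=list(alleles),
    )
    return DosageMatrix(dosages=frame, alleles=alleles)


class TestHarmonize:
    def test_ref_equals_effect_flips_dosage(self):
        w = [VariantWeight("v", "1", 1, "A", "G", 0.5)]
        m = _matrix([[0.5]], {"v": ("A", "G")})  # file ref=A=effect
        aligned, kept, excl = harmonize_alleles(m, w)
        assert aligned.dosages["v"].iloc[0] == pytest.approx(1.5)
        assert not excl

    def test_alt_equals_effect_is_identity(self):
        w = [VariantWeight("v", "1", 1, "G", "A", 0.5)]
        m = _matrix([[1.2]], {"v": ("A", "G")})
        aligned, _, _ = harmonize_alleles(m, w)
        assert aligned.dosages["v"].iloc[0] == pytest.approx(1.2)

    def test_palindromic_site_dropped_with_reason(self):
        w = [
            VariantWeight("pal", "1", 1, "A", "T", 0.5),
            VariantWeight("ok", "1", 2, "G", "A", 0.2),
        ]
        m = _matrix([[1.0, 1.0]], {"pal": ("T", "A"), "ok": ("A", "G")})
        aligned, kept, excl = harmonize_alleles(m, w)
        assert [k.variant_id for k in kept] == ["ok"]
        assert excl[0]["variant_id"] == "pal" and "palindromic" in excl[0]["reason"]

    def test_unresolvable_alleles_dropped(self):
        w = [VariantWeight("v", "1", 1, "G", "A", 0.5)]
        m = _matrix([[1.0]], {"v": ("C", "T")})
        aligned, kept, excl = harmonize_alleles(m, w)
        assert aligned.n_variants == 0 and "unresolvable" in excl[0]["reason"]

    def test_idempotence(self, rng):
        weights, freqs = gen_weights(8, (0.1, 0.5), rng)
        d = rng.binomial(2, freqs, size=(30, 8)).astype(float)
        alleles = {}
        for i, w in enumerate(weights):
            if rng.random() < 0.5:  # random orientation
                alleles[w.variant_id] = (w.effect_allele, w.other_allele)
                d[:, i] = 2 - d[:, i]
            else:
                alleles[w.variant_id] = (w.other_allele, w.effect_allele)
        m = DosageMatrix(
            dosages=pd.DataFrame(d, columns=[w.variant_id for w in weights]),
            alleles=alleles,
        )
        once, kept1, _ = harmonize_alleles(m, weights)
        twice, kept2, _ = harmonize_alleles(once, kept1)
        pd.testing.assert_frame_equal(once.dosages, twice.dosages)
        assert kept1 == kept2

    def test_flip_consistency(self, rng):
        """Recoding ref/alt in the source (d -> 2-d) changes nothing after harmonization."""
        weights, freqs = gen_weights(6, (0.1, 0.5), rng)
        d = rng.binomial(2, freqs, size=(20, 6)).astype(float)
        ids = [w.variant_id for w in weights]
        m1 = DosageMatrix(
            dosages=pd.DataFrame(d.copy(), columns=ids),
            alleles={w.variant_id: (w.other_allele, w.effect_allele) for w in weights},
        )
        m2 = DosageMatrix(
            dosages=pd.DataFrame(2 - d, columns=ids),
            alleles={w.variant_id: (w.effect_allele, w.other_allele) for w in weights},
        )
        a1, _, _ = harmonize_alleles(m1, weights)
        a2, _, _ = harmonize_alleles(m2, weights)
        pd.testing.assert_frame_equal(a1.dosages, a2.dosages)


class TestPhenotypes:
    def _csv(self, tmp_path, rows, header="sample_id,age,sex,smoking,calc_lad_pct"):
        p = tmp_path / "p.csv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_missing_token_becomes_na(self, tmp_path):
        p = self._csv(tmp_path, ["a,60,male,1,10", "b,61,female,NA,20", "c,62,male,0,30"])
        t = read_phenotypes(p)
        assert t["smoking"].isna().sum() == 1
        assert t["sex"].tolist() == ["male", "female", "male"]

    def test_out_of_range_percentage_names_sample(self, tmp_path):
        p = self._csv(tmp_path, ["a,60,male,1,130"])
        with pytest.raises(FormatError, match="'a'"):
            read_phenotypes(p)

    def test_duplicate_sample_id_is_hard_error(self, tmp_path):
        p = self._csv(tmp_path, ["a,60,male,1,10", "a,61,female,0,20"])
        with pytest.raises(FormatError, match="duplicate"):
            read_phenotypes(p)

    def test_column_mapping_and_sex_labels(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("id,yrs,gender\nx,55,M\ny,66,F\n")
        t = read_phenotypes(
            p, column_map={"id": "sample_id", "yrs": "age", "gender": "sex"},
            sex_labels={"M": "male", "F": "female"},
        )
        assert t["sex"].tolist() == ["male", "female"]
        assert t["age"].tolist() == [55.0, 66.0]

    def test_large_cohort_round_trips_bit_identically(self, tmp_path, rng):
        table = gen_covariates(2742, "clinical", rng)
        table.loc[5, "calc_lad_pct"] = 37.25
        path = tmp_path / "rt.csv"
        write_phenotypes(table, path)
        back = read_phenotypes(path)
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True), check_dtype=False)


class TestDefineCadCases:
    @pytest.mark.parametrize(
        "lad, rca, expected",
        [
            (61.5, 10.0, 1),   # high LAD stenosis dominates
            (49.9, 49.9, 0),   # just below threshold everywhere
            (50.0, np.nan, 1),  # inclusive boundary: "50% or more"
            (10.0, 72.0, 1),
            (np.nan, np.nan, None),  # unlabelable stays missing
        ],
    )
    def test_threshold_rule(self, lad, rca, expected):
        t = pd.DataFrame({
            "sample_id": ["s"], "stenosis_lad_pct": [lad], "stenosis_rca_pct": [rca],
        })
        out = define_cad_cases(t)
        got = out["cad_case"].iloc[0]
        if expected is None:
            assert pd.isna(got)
        else:
            assert got == expected

    def test_custom_threshold(self):
        t = pd.DataFrame({
            "sample_id": ["a", "b"],
            "stenosis_lad_pct": [60.0, 60.0],
            "stenosis_rca_pct": [np.nan, np.nan],
        })
        out = define_cad_cases(t, threshold_pct=70)
        assert out["cad_case"].tolist() == [0, 0]
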