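"""Input/output and allele harmonization for GRS cohorts.

This module reads the three external formats the pipeline consumes — a
PGS-Catalog-style variant-weights TSV, genotype dosages (VCF with a DS
FORMAT field, GT hard-call fallback, or a plain sample x variant TSV
matrix) and a phenotype/covariate table — and aligns genotype dosages to
the effect alleles of the scoring file so that downstream scoring is
well-defined.

Conventions
-----------
* Positions are 1-based, as in VCF.
* A dosage counts copies of a named allele and lives in [0, 2]; fractional
  values are imputed expected counts and are kept un-rounded.
* Variant matching is by ID first, with a chr:pos + allele-set fallback.
* Strand-ambiguous palindromic sites (A/T, C/G) are dropped during
  harmonization by default: an 11-SNP score cannot absorb silent strand
  errors, and no frequency-based strand inference is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantWeight",
    "DosageMatrix",
    "FormatError",
    "COHORT_COLUMNS",
    "read_score_file",
    "write_score_file",
    "read_dosages",
    "harmonize_alleles",
    "read_phenotypes",
    "write_phenotypes",
    "define_cad_cases",
]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class VariantWeight:
    """One scored SNP: alleles and per-allele log-scale effect size.

    ``effect_weight`` is the GWAS effect size attached to ``effect_allele``;
    ``imputation_r2`` optionally carries the upstream imputation-quality
    squared correlation (metadata only, no filtering by default).
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    effect_weight: float
    imputation_r2: float | None = None

    def __post_init__(self) -> None:
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea == oa:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical ({ea})")
        if ea not in _BASES or oa not in _BASES:
            raise ValueError(f"{self.variant_id}: alleles must be single bases, got {ea}/{oa}")
        if not np.isfinite(self.effect_weight):
            raise ValueError(f"{self.variant_id}: non-finite effect weight")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1 (1-based)")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G pairs."""
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass
class DosageMatrix:
    """Samples x variants matrix of allele dosages in [0, 2] (NaN = missing).

    ``alleles`` maps variant id -> (ref, alt) as recorded in the genotype
    source; before :func:`harmonize_alleles` the dosage counts the source
    file's ALT allele, afterwards the scoring file's effect allele.
    ``missing_variants`` lists wanted variants absent from the source.
    """

    dosages: pd.DataFrame
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    missing_variants: list[str] = field(default_factory=list)
    harmonized: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 2)
        if np.any(bad & ~np.isnan(vals)):
            raise ValueError("dosage entries must lie in [0, 2] or be missing")


# Canonical phenotype-table schema: column -> pandas dtype.
COHORT_COLUMNS: dict[str, str] = {
    "sample_id": "string",
    "cad_case": "Int64",
    "stenosis_lad_pct": "float64",
    "stenosis_rca_pct": "float64",
    "calc_lad_pct": "float64",
    "calc_rca_pct": "float64",
    "age": "float64",
    "sex": "string",  # "male" / "female"
    "bmi": "float64",
    "sbp": "float64",
    "total_chol": "float64",
    "hdl_chol": "float64",
    "smoking": "Int64",
    "htn_med": "Int64",
    "statin": "Int64",
}

_PCT_COLUMNS = ("stenosis_lad_pct", "stenosis_rca_pct", "calc_lad_pct", "calc_rca_pct")

_SCORE_FILE_COLUMNS = {
    "rsID": "variant_id",
    "chr_name": "chromosome",
    "chr_position": "position",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_weight": "effect_weight",
}


def read_score_file(path: str | Path) -> list[VariantWeight]:
    """Parse a PGS-Catalog-dialect scoring TSV into :class:`VariantWeight` records.

    Lines starting with ``#`` are comments. Mandatory columns: ``rsID``,
    ``chr_name``, ``chr_position``, ``effect_allele``, ``other_allele``,
    ``effect_weight``; optional ``imputation_r2``. Row order is preserved
    and alleles are upper-cased.
    """
    path = Path(path)
    header: list[str] | None = None
    records: list[VariantWeight] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = set(_SCORE_FILE_COLUMNS) - set(header)
                if missing:
                    raise FormatError(
                        f"{path}: missing mandatory column(s) {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                weight = float(row["effect_weight"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric effect_weight "
                    f"{row['effect_weight']!r} on line {lineno}"
                ) from exc
            try:
                pos = int(row["chr_position"])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer chr_position on line {lineno}"
                ) from exc
            r2: float | None = None
            if "imputation_r2" in row and row["imputation_r2"] not in ("", "NA"):
                try:
                    r2 = float(row["imputation_r2"])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric imputation_r2 on line {lineno}"
                    ) from exc
            records.append(
                VariantWeight(
                    variant_id=row["rsID"],
                    chromosome=str(row["chr_name"]),
                    position=pos,
                    effect_allele=row["effect_allele"],
                    other_allele=row["other_allele"],
                    effect_weight=weight,
                    imputation_r2=r2,
                )
            )
    if header is None:
        raise FormatError(f"{path}: no header line found")
    return records


def write_score_file(weights: Sequence[VariantWeight], path: str | Path) -> None:
    """Write weights in the same TSV dialect :func:`read_score_file` reads."""
    path = Path(path)
    cols = ["rsID", "chr_name", "chr_position", "effect_allele", "other_allele", "effect_weight"]
    has_r2 = any(w.imputation_r2 is not None for w in weights)
    if has_r2:
        cols.append("imputation_r2")
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for w in weights:
            row = [
                w.variant_id,
                w.chromosome,
                str(w.position),
                w.effect_allele,
                w.other_allele,
                repr(w.effect_weight),
            ]
            if has_r2:
                row.append("" if w.imputation_r2 is None else repr(w.imputation_r2))
            fh.write("\t".join(row) + "\n")


def filter_by_imputation_r2(
    weights: Sequence[VariantWeight], min_r2: float = 0.30
) -> list[VariantWeight]:
    """Drop variants whose imputation r-squared is known and <= ``min_r2``.

    Off by default in the pipeline (quality filtering is assumed to have
    happened upstream of the scoring file).
    """
    kept = [w for w in weights if w.imputation_r2 is None or w.imputation_r2 > min_r2]
    dropped = len(weights) - len(kept)
    if dropped:
        logger.info("imputation_r2 filter dropped %d variant(s) at r2 <= %s", dropped, min_r2)
    return kept


def _wanted_lookup(wanted: Sequence[VariantWeight]):
    by_id = {w.variant_id: w for w in wanted}
    by_locus = {
        (w.chromosome.removeprefix("chr"), w.position): w for w in wanted
    }
    return by_id, by_locus


def read_dosages(path: str | Path, wanted: Sequence[VariantWeight]) -> DosageMatrix:
    """Load dosages for ``wanted`` variants from a VCF or a TSV matrix.

    VCF: the DS FORMAT field is used when present, otherwise GT hard calls
    are converted to ALT-allele counts 0/1/2. Dosages count the ALT allele
    exactly as written in the file; effect-allele alignment is the job of
    :func:`harmonize_alleles`. TSV: first column = sample id, remaining
    columns = variant ids, with a ``#alleles`` comment line declaring
    ``variant=REF/ALT`` pairs.

    Wanted variants not present in the file are reported in
    ``missing_variants``; if *none* are found this is a hard error.
    """
    path = Path(path)
    if path.suffix in {".vcf"} or path.name.endswith((".vcf.gz", ".vcf.bgz")):
        matrix = _read_dosages_vcf(path, wanted)
    else:
        matrix = _read_dosages_tsv(path, wanted)
    if matrix.n_variants == 0:
        raise FormatError(f"{path}: none of the {len(wanted)} wanted variants were found")
    if matrix.missing_variants:
        logger.warning(
            "%s: %d wanted variant(s) absent: %s",
            path, len(matrix.missing_variants), ", ".join(matrix.missing_variants),
        )
    matrix.validate()
    return matrix


def _read_dosages_vcf(path: Path, wanted: Sequence[VariantWeight]) -> DosageMatrix:
    from cyvcf2 import VCF

    by_id, by_locus = _wanted_lookup(wanted)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for record in vcf:
        target = by_id.get(record.ID) if record.ID else None
        if target is None:
            target = by_locus.get((str(record.CHROM).removeprefix("chr"), record.POS))
        if target is None or target.variant_id in columns:
            continue
        if len(record.ALT) != 1:
            raise FormatError(
                f"{path}: multi-allelic record at {record.CHROM}:{record.POS} not supported"
            )
        dose = _record_dosage(record, path)
        columns[target.variant_id] = dose
        alleles[target.variant_id] = (record.REF.upper(), record.ALT[0].upper())
    found_order = [w.variant_id for w in wanted if w.variant_id in columns]
    missing = [w.variant_id for w in wanted if w.variant_id not in columns]
    frame = pd.DataFrame(
        {vid: columns[vid] for vid in found_order}, index=pd.Index(samples, name="sample_id")
    )
    return DosageMatrix(dosages=frame, alleles=alleles, missing_variants=missing)


def _record_dosage(record, path: Path) -> np.ndarray:
    try:
        ds = record.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        return np.asarray(ds, dtype=float).reshape(-1)
    # GT fallback: count ALT alleles; any missing allele call -> NaN
    gts = record.genotypes
    if gts is None:
        raise FormatError(f"{path}: record {record.CHROM}:{record.POS} has neither DS nor GT")
    calls = np.asarray([g[:-1] for g in gts], dtype=float)  # last entry is phasing flag
    dose = (calls > 0).sum(axis=1).astype(float)
    dose[(calls < 0).any(axis=1)] = np.nan
    return dose


def _read_dosages_tsv(path: Path, wanted: Sequence[VariantWeight]) -> DosageMatrix:
    alleles: dict[str, tuple[str, str]] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("#alleles"):
                for token in line.split()[1:]:
                    vid, pair = token.split("=")
                    ref, alt = pair.split("/")
                    alleles[vid] = (ref.upper(), alt.upper())
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    frame.index.name = "sample_id"
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric dosage entry: {exc}") from exc
    by_id, by_locus = _wanted_lookup(wanted)
    found = [w.variant_id for w in wanted if w.variant_id in frame.columns]
    missing = [w.variant_id for w in wanted if w.variant_id not in frame.columns]
    return DosageMatrix(
        dosages=frame[found],
        alleles={vid: alleles[vid] for vid in found if vid in alleles},
        missing_variants=missing,
    )


def harmonize_alleles(
    matrix: DosageMatrix,
    weights: Sequence[VariantWeight],
    *,
    drop_palindromic: bool = True,
) -> tuple[DosageMatrix, list[VariantWeight], list[dict]]:
    """Align dosage columns to the scoring file's effect alleles.

    For each variant with a (ref, alt) pair from its source file:

    * file alt == effect allele  -> dosage kept as-is;
    * file ref == effect allele and file alt == other allele -> dosage
      flipped to ``2 - d`` (the two alleles name the same site from
      opposite ends);
    * palindromic pair (A/T or C/G) -> dropped (strand ambiguity), unless
      ``drop_palindromic=False`` in which case same-pair sites are treated
      like any other;
    * allele pair not matching the weight's pair at all -> dropped as
      unresolvable.

    Returns the aligned matrix, the surviving weights in matrix column
    order, and a machine-readable exclusion report (one dict per dropped
    variant with an explanatory reason). Nothing here is fatal. Already
    harmonized matrices pass through unchanged (idempotence).
    """
    weight_by_id = {w.variant_id: w for w in weights}
    kept_cols: list[str] = []
    kept_weights: list[VariantWeight] = []
    exclusions: list[dict] = []
    new_data: dict[str, np.ndarray] = {}
    new_alleles: dict[str, tuple[str, str]] = {}

    for vid in matrix.variant_ids:
        w = weight_by_id.get(vid)
        if w is None:
            exclusions.append({"variant_id": vid, "reason": "no matching weight record"})
            continue
        if drop_palindromic and w.is_palindromic:
            exclusions.append({"variant_id": vid, "reason": "palindromic allele pair (strand-ambiguous)"})
            continue
        pair = matrix.alleles.get(vid)
        if pair is None:
            exclusions.append({"variant_id": vid, "reason": "source file records no ref/alt alleles"})
            continue
        ref, alt = pair
        col = matrix.dosages[vid].to_numpy(dtype=float)
        if matrix.harmonized or (alt == w.effect_allele and ref == w.other_allele):
            new_data[vid] = col
        elif ref == w.effect_allele and alt == w.other_allele:
            new_data[vid] = 2.0 - col
        else:
            exclusions.append({
                "variant_id": vid,
                "reason": f"unresolvable alleles: file {ref}/{alt} vs weight "
                          f"{w.effect_allele}/{w.other_allele}",
            })
            continue
        # after alignment the stored alt IS the effect allele
        new_alleles[vid] = (w.other_allele, w.effect_allele)
        kept_cols.append(vid)
        kept_weights.append(w)

    for exc in exclusions:
        logger.info("harmonization dropped %(variant_id)s: %(reason)s", exc)
    frame = pd.DataFrame(new_data, index=matrix.dosages.index, columns=kept_cols)
    aligned = DosageMatrix(
        dosages=frame,
        alleles=new_alleles,
        missing_variants=list(matrix.missing_variants),
        harmonized=True,
    )
    return aligned, kept_weights, exclusions


_MISSING_TOKENS = ["", "NA", "na", "NaN", "nan", "."]

_SEX_LABELS = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "0": "female",
}


def read_phenotypes(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    sex_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a phenotype/covariate CSV or TSV into the canonical schema.

    ``column_map`` maps file column names to canonical names (see
    ``COHORT_COLUMNS``); unmapped canonical columns are created as missing.
    ``sex_labels`` maps the file's sex encoding to "male"/"female"
    (defaults understand male/female, m/f and 1/0).
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, na_values=_MISSING_TOKENS, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    table = pd.DataFrame(index=raw.index)
    for col, dtype in COHORT_COLUMNS.items():
        if col in raw.columns:
            if col == "sex":
                labels = {str(k).lower(): v for k, v in (sex_labels or _SEX_LABELS).items()}
                series = raw[col].str.lower().map(labels)
                unknown = raw[col].notna() & series.isna()
                if unknown.any():
                    bad = raw.loc[unknown, col].iloc[0]
                    raise FormatError(f"{path}: unrecognized sex label {bad!r}")
                table[col] = series.astype("string")
            elif dtype == "string":
                table[col] = raw[col].astype("string")
            elif dtype == "Int64":
                table[col] = pd.to_numeric(raw[col]).round().astype("Int64")
            else:
                table[col] = pd.to_numeric(raw[col]).astype(dtype)
        else:
            na = np.nan if dtype == "float64" else pd.NA
            table[col] = pd.Series(na, index=raw.index, dtype=dtype)
    if table["sample_id"].isna().any():
        raise FormatError(f"{path}: missing sample_id values")
    dup = table["sample_id"].duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate sample_id {table.loc[dup, 'sample_id'].iloc[0]!r}")
    for col in _PCT_COLUMNS:
        vals = table[col]
        bad = vals.notna() & ((vals < 0) | (vals > 100))
        if bad.any():
            sid = table.loc[bad, "sample_id"].iloc[0]
            raise FormatError(
                f"{path}: {col} out of [0, 100] for sample {sid!r} "
                f"(value {float(vals[bad].iloc[0])})"
            )
    return table


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical phenotype table as CSV (full float precision)."""
    path = Path(path)
    out = table.copy()
    for col in out.columns:
        if out[col].dtype == "float64":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


def define_cad_cases(table: pd.DataFrame, threshold_pct: float = 50.0) -> pd.DataFrame:
    """Label CAD cases from stenosis percentages.

    A sample is a case when the maximum of its available stenosis
    percentages (LAD, RCA) is at or above ``threshold_pct`` — the
    threshold is inclusive ("50 % or more"). Samples with all stenosis
    values missing keep a missing ``cad_case``.
    """
    out = table.copy()
    sten = out[["stenosis_lad_pct", "stenosis_rca_pct"]]
    max_sten = sten.max(axis=1, skipna=True)
    any_obs = sten.notna().any(axis=1)
    cases = pd.Series(pd.NA, index=out.index, dtype="Int64")
    cases[any_obs] = (max_sten[any_obs] >= threshold_pct).astype("Int64")
    out["cad_case"] = cases
    return out
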