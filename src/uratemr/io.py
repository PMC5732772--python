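"""Tabular input/output: instrument weights, genotype dosages, phenotypes.

The analysis joins three inputs into a single per-subject cohort table:

* a weight file giving, for each instrument SNP, the effect allele and its
  per-allele effect on serum urate (µmol/L);
* a genotype table of effect-allele dosages in {0, 1, 2} (TSV, or extracted
  from a biallelic VCF);
* a phenotype/covariate table (age, sex, BMI, fasting blood glucose, blood
  urea nitrogen, serum urate, total bilirubin, urate-lowering-drug flag).

Weights are oriented at load so that every retained weight is positive and
the effect allele is the urate-increasing allele; genotype dosages are then
counts of that urate-increasing allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")

#: Covariate/phenotype columns expected in the phenotype table.
PHENO_COLUMNS = ("age", "sex", "bmi", "fbg", "bun", "su", "tbil", "urate_lowering_drug")


class WeightFileError(ValueError):
    """Raised for malformed or uninformative instrument weight files."""


class CohortValidationError(ValueError):
    """Raised when genotype/phenotype inputs violate the cohort contract."""


@dataclass(frozen=True)
class SnpWeight:
    """One instrument SNP with its per-allele serum-urate effect.

    Parameters
    ----------
    snp_id : str
        Variant identifier (rsID).
    effect_allele : str
        The urate-increasing allele after orientation; dosages count copies
        of this allele.
    weight : float
        Per-allele effect on serum urate in µmol/L; strictly positive after
        orientation.
    other_allele : str, optional
        The complementary allele at the site, needed to flip orientation of
        signed input weights and to match VCF REF/ALT pairs.
    flipped : bool
        True if the input listed the urate-*lowering* allele (negative
        weight) and the loader re-oriented it.
    """

    snp_id: str
    effect_allele: str
    weight: float
    other_allele: str | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        for name, allele in (("effect_allele", self.effect_allele),
                             ("other_allele", self.other_allele)):
            if allele is not None and allele not in _VALID_ALLELES:
                raise WeightFileError(
                    f"{self.snp_id}: {name} {allele!r} is not a single A/C/G/T base"
                )
        if self.weight == 0:
            raise WeightFileError(
                f"{self.snp_id}: zero weight — an uninformative instrument"
            )
        if self.weight < 0:
            raise WeightFileError(
                f"{self.snp_id}: weight must be oriented positive (got {self.weight})"
            )


# Per-allele serum-urate effects (µmol/L) for the four urate-transporter
# instrument SNPs, as estimated in the source genetic-association study of
# this Chinese cohort.  Effect/other alleles are taken from that study's
# reported coding and are user-overridable via any weights TSV; two of the
# published betas are negative and are re-oriented here to the
# urate-increasing allele.
DEFAULT_WEIGHTS: tuple[SnpWeight, ...] = (
    SnpWeight("rs1481012", "G", 27.555, other_allele="A"),
    SnpWeight("rs2231137", "G", 16.945, other_allele="A", flipped=True),
    SnpWeight("rs16890979", "C", 24.654, other_allele="T", flipped=True),
    SnpWeight("rs3799352", "C", 7.456, other_allele="T", flipped=True),
)


def read_weights(path) -> list[SnpWeight]:
    """Load an instrument weight TSV, orienting weights positive.

    The file must have header columns ``snp_id``, ``effect_allele``,
    ``weight`` and may have ``other_allele``.  A negative weight means the
    listed effect allele *lowers* urate: the loader flips the effect allele
    to ``other_allele`` and takes the absolute weight, so downstream scores
    are monotone in genetic urate burden.

    Raises
    ------
    WeightFileError
        On duplicate snp_id, zero weight, non-A/C/G/T alleles, or a negative
        weight with no ``other_allele`` to flip to.
    """
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "effect_allele", "weight"}
    if not required.issubset(tab.columns):
        raise WeightFileError(
            f"weight file needs columns {sorted(required)}, got {list(tab.columns)}"
        )
    if len(tab) == 0:
        raise WeightFileError("weight file has no rows")
    dups = tab["snp_id"][tab["snp_id"].duplicated()].tolist()
    if dups:
        raise WeightFileError(f"duplicate snp_id in weight file: {dups}")

    weights: list[SnpWeight] = []
    n_flipped = 0
    for row in tab.itertuples(index=False):
        raw = float(row.weight)
        other = getattr(row, "other_allele", None)
        other = None if other is None or pd.isna(other) else str(other)
        if raw == 0:
            raise WeightFileError(f"{row.snp_id}: zero weight — uninformative instrument")
        if raw < 0:
            if other is None:
                raise WeightFileError(
                    f"{row.snp_id}: negative weight needs an other_allele column "
                    "to re-orient to the urate-increasing allele"
                )
            weights.append(SnpWeight(str(row.snp_id), other, abs(raw),
                                     other_allele=str(row.effect_allele), flipped=True))
            n_flipped += 1
        else:
            weights.append(SnpWeight(str(row.snp_id), str(row.effect_allele), raw,
                                     other_allele=other))
    logger.info("loaded %d instrument SNPs (%d re-oriented) from %s",
                len(weights), n_flipped, path)
    return weights


def write_weights(weights, path) -> None:
    """Write SnpWeights to the TSV layout :func:`read_weights` accepts."""
    pd.DataFrame(
        {
            "snp_id": [w.snp_id for w in weights],
            "effect_allele": [w.effect_allele for w in weights],
            "weight": [w.weight for w in weights],
            "other_allele": [w.other_allele or "" for w in weights],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class JoinReport:
    """Accounting of the genotype/phenotype join and exclusion filters."""

    n_genotype: int = 0
    n_phenotype: int = 0
    n_joined: int = 0
    n_dropped_urate_lowering_drug: int = 0
    n_dropped_missing_phenotype: int = 0
    n_retained: int = 0
    warnings: list[str] = field(default_factory=list)


def _parse_sex(values: pd.Series) -> pd.Series:
    mapping = {"male": "male", "m": "male", "female": "female", "f": "female"}
    out = values.astype(str).str.strip().str.lower().map(mapping)
    bad = values[out.isna()]
    if len(bad):
        raise CohortValidationError(
            f"unrecognised sex value {bad.iloc[0]!r} for subject "
            f"{bad.index[0]!r} (expected male/female/M/F)"
        )
    return pd.Categorical(out, categories=["male", "female"])


def _parse_bool(values: pd.Series, column: str) -> pd.Series:
    mapping = {"0": False, "1": True, "true": True, "false": False}
    out = values.astype(str).str.strip().str.lower().map(mapping)
    bad = values[out.isna()]
    if len(bad):
        raise CohortValidationError(
            f"unrecognised boolean {bad.iloc[0]!r} in column {column} "
            f"for subject {bad.index[0]!r}"
        )
    return out.astype(bool)


def read_genotypes(path, weights) -> pd.DataFrame:
    """Read a genotype dosage TSV (subject_id + one 0/1/2/NA column per SNP)."""
    geno = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                       float_precision="round_trip")
    if "subject_id" not in geno.columns:
        raise CohortValidationError("genotype table lacks a subject_id column")
    geno = geno.set_index("subject_id")
    if geno.index.duplicated().any():
        dup = geno.index[geno.index.duplicated()][0]
        raise CohortValidationError(f"duplicate subject_id {dup!r} in genotype table")
    missing = [w.snp_id for w in weights if w.snp_id not in geno.columns]
    if missing:
        raise CohortValidationError(
            f"instrument SNP(s) absent from genotype columns: {missing}"
        )
    snp_ids = [w.snp_id for w in weights]
    geno = geno[snp_ids].apply(pd.to_numeric, errors="coerce").astype(float)
    validate_dosages(geno)
    return geno


def validate_dosages(geno: pd.DataFrame) -> None:
    """Dosages must lie in {0, 1, 2} or be missing."""
    values = geno.to_numpy(dtype=float)
    ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise CohortValidationError(
            f"dosage {values[i, j]!r} for subject {geno.index[i]!r} at "
            f"{geno.columns[j]} is outside {{0,1,2,NA}}"
        )


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the phenotype/covariate TSV."""
    pheno = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("subject_id",) + PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise CohortValidationError(f"phenotype table lacks column(s): {missing}")
    pheno = pheno.set_index("subject_id")
    if pheno.index.duplicated().any():
        dup = pheno.index[pheno.index.duplicated()][0]
        raise CohortValidationError(f"duplicate subject_id {dup!r} in phenotype table")
    out = pd.DataFrame(index=pheno.index)
    for col in ("age", "bmi", "fbg", "bun", "su", "tbil"):
        numeric = pd.to_numeric(pheno[col], errors="coerce")
        bad = numeric.isna() & pheno[col].notna() & (pheno[col].str.strip() != "")
        if bad.any():
            subj = pheno.index[bad][0]
            raise CohortValidationError(
                f"non-numeric value {pheno.loc[subj, col]!r} in column {col} "
                f"for subject {subj!r}"
            )
        out[col] = numeric
    out["sex"] = _parse_sex(pheno["sex"])
    out["urate_lowering_drug"] = _parse_bool(
        pheno["urate_lowering_drug"], "urate_lowering_drug"
    )
    # exposure/outcome must be positive to be usable; non-positive entries
    # become missing and are dropped (and counted) by the join
    for col in ("su", "tbil"):
        out.loc[out[col] <= 0, col] = np.nan
    return out


def read_cohort(genotype_path, phenotype_path, weights) -> tuple[pd.DataFrame, JoinReport]:
    """Join genotype and phenotype inputs into a cohort table.

    Subjects on urate-lowering drugs and subjects with a missing (or
    non-positive, hence unusable) exposure (serum urate) or outcome (total
    bilirubin) are dropped, with counts in the returned :class:`JoinReport`.  Subjects with missing genotype
    dosages are *retained* here; the risk-score layer applies its own
    missing-dosage policy.
    """
    geno = read_genotypes(genotype_path, weights)
    pheno = read_phenotypes(phenotype_path)
    report = JoinReport(n_genotype=len(geno), n_phenotype=len(pheno))

    cohort = pheno.join(geno, how="inner")
    report.n_joined = len(cohort)

    on_drug = cohort["urate_lowering_drug"]
    report.n_dropped_urate_lowering_drug = int(on_drug.sum())
    cohort = cohort[~on_drug]

    incomplete = cohort["su"].isna() | cohort["tbil"].isna()
    report.n_dropped_missing_phenotype = int(incomplete.sum())
    cohort = cohort[~incomplete]

    report.n_retained = len(cohort)
    snp_ids = [w.snp_id for w in weights]
    cohort = cohort[list(PHENO_COLUMNS[:-1]) + ["urate_lowering_drug"] + snp_ids]
    logger.info(
        "cohort join: %d genotype x %d phenotype -> %d joined, "
        "%d excluded on urate-lowering drugs, %d missing SU/TBIL, %d retained",
        report.n_genotype, report.n_phenotype, report.n_joined,
        report.n_dropped_urate_lowering_drug, report.n_dropped_missing_phenotype,
        report.n_retained,
    )
    return cohort.sort_index(), report


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to TSV; :func:`read_cohort_tsv` round-trips it."""
    out = cohort.copy()
    out["urate_lowering_drug"] = out["urate_lowering_drug"].astype(int)
    # %.17g survives the float round trip bit-for-bit
    out.to_csv(path, sep="\t", index=True, index_label="subject_id",
               float_format="%.17g")


def read_cohort_tsv(path, weights) -> pd.DataFrame:
    """Re-read a cohort table written by :func:`write_cohort`."""
    tab = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                      float_precision="round_trip").set_index("subject_id")
    tab["sex"] = pd.Categorical(tab["sex"], categories=["male", "female"])
    tab["urate_lowering_drug"] = tab["urate_lowering_drug"].astype(bool)
    snp_ids = [w.snp_id for w in weights]
    tab[snp_ids] = tab[snp_ids].astype(float)
    for col in ("age", "bmi", "fbg", "bun", "su", "tbil"):
        tab[col] = tab[col].astype(float)
    validate_dosages(tab[snp_ids])
    return tab


def read_vcf_dosages(vcf_path, weights) -> tuple[pd.DataFrame, JoinReport]:
    """Extract effect-allele dosages for the instrument SNPs from a VCF.

    Sites are matched to weights by rsID in the ID column and must be
    biallelic with a GT field.  The dosage counts copies of the (oriented)
    effect allele: if the effect allele is ALT the dosage is the ALT-allele
    count, if it is REF the dosage is ``2 - alt_count``; any other allele
    pair skips the site with a warning.  Missing genotypes (``./.``) become
    missing dosages.
    """
    from cyvcf2 import VCF

    wanted = {w.snp_id: w for w in weights}
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    report = JoinReport()

    for variant in vcf:
        snp_id = variant.ID
        if snp_id not in wanted or snp_id in columns:
            continue
        w = wanted[snp_id]
        if len(variant.ALT) != 1:
            report.warnings.append(f"{snp_id}: multiallelic site skipped")
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if w.effect_allele == alt:
            flip = False
        elif w.effect_allele == ref:
            flip = True
        else:
            report.warnings.append(
                f"{snp_id}: effect allele {w.effect_allele} matches neither "
                f"REF {ref} nor ALT {alt}; site skipped"
            )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        columns[snp_id] = 2.0 - dosage if flip else dosage
    for msg in report.warnings:
        logger.warning(msg)
    if not columns:
        raise CohortValidationError(
            f"none of the requested instrument SNPs found in {vcf_path}"
        )
    geno = pd.DataFrame(
        {sid: columns[sid] for sid in wanted if sid in columns},
        index=pd.Index(samples, name="subject_id"),
    )
    report.n_genotype = len(geno)
    return geno, report
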