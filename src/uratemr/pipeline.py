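"""Orchestration: exclusions, risk score, subgroups, OLS/2SLS/DWH tables.

Runs the full analysis on a cohort table: compute the composite instrument,
stratify by sex and by serum-urate level (hyperuricemia strictly above the
417 µmol/L threshold), and for every subgroup fit crude and
covariate-adjusted OLS and 2SLS models with a Durbin-Hausman comparison.
A per-SNP pass repeats the instrumental analysis with each single variant
as the instrument, carrying the weak-instrument flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dwh import dwh_contrast
from .grs import count_grs, weighted_grs
from .iv import DegenerateInstrumentError, first_stage, tsls_fit
from .regress import CollinearityError, confounder_check, ols_fit

logger = logging.getLogger(__name__)

#: Serum-urate threshold (µmol/L) above which a subject is hyperuricemic.
HYPERURICEMIA_THRESHOLD = 417.0

DEFAULT_ADJUST = ("age", "sex", "bmi", "bun", "fbg")
CONFOUNDERS = ("age", "sex", "bmi", "fbg", "bun")


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-wide settings; defaults mirror the study's analysis plan."""

    adjust: tuple[str, ...] = DEFAULT_ADJUST
    su_threshold: float = HYPERURICEMIA_THRESHOLD
    grs_mode: str = "weighted"
    missing_dosage: str = "drop"
    min_n: int = 30
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.grs_mode not in ("weighted", "count"):
            raise ValueError(f"unknown grs_mode {self.grs_mode!r}")
        unknown = set(self.adjust) - set(CONFOUNDERS)
        if unknown:
            raise ValueError(f"unknown adjustment covariate(s): {sorted(unknown)}")


@dataclass(frozen=True)
class SubgroupSpec:
    """A cohort stratum: optional sex and serum-urate-level restriction."""

    name: str
    sex: str | None = None              # "male" / "female" / None
    su_group: str | None = None         # "normal" / "hyper" / None

    def mask(self, cohort: pd.DataFrame, threshold: float) -> pd.Series:
        m = pd.Series(True, index=cohort.index)
        if self.sex is not None:
            m &= cohort["sex"] == self.sex
        if self.su_group == "hyper":
            m &= cohort["su"] > threshold      # strictly above: SU == threshold is normal
        elif self.su_group == "normal":
            m &= cohort["su"] <= threshold
        return m


def default_subgroups() -> list[SubgroupSpec]:
    """All/males/females, then the same trio within normal and high urate."""
    groups = [
        SubgroupSpec("all"),
        SubgroupSpec("males", sex="male"),
        SubgroupSpec("females", sex="female"),
    ]
    for level in ("normal", "hyper"):
        prefix = "normal_su" if level == "normal" else "hyperuricemia"
        groups.append(SubgroupSpec(prefix, su_group=level))
        groups.append(SubgroupSpec(f"{prefix}_males", sex="male", su_group=level))
        groups.append(SubgroupSpec(f"{prefix}_females", sex="female", su_group=level))
    return groups


def design_covariates(cohort: pd.DataFrame, adjust) -> tuple[np.ndarray, list[str]]:
    """Build the adjustment design block; sex coded male=1, female=0.

    Constant columns (e.g. sex inside a single-sex subgroup) are dropped,
    matching the convention that sex leaves the model in sex strata.
    """
    cols, names = [], []
    for name in adjust:
        if name == "sex":
            col = (cohort["sex"] == "male").to_numpy(dtype=float)
        else:
            col = cohort[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            continue
        cols.append(col)
        names.append(name)
    if not cols:
        return np.empty((len(cohort), 0)), []
    return np.column_stack(cols), names


_RESULT_COLUMNS = [
    "subgroup", "model", "estimator", "beta", "se", "stat", "p",
    "dwh_p", "dwh_method", "n", "f_stat", "r2", "weak_instrument", "status",
]


def _empty_row(subgroup: str, model: str, estimator: str, n: int,
               status: str) -> dict:
    return {
        "subgroup": subgroup, "model": model, "estimator": estimator,
        "beta": np.nan, "se": np.nan, "stat": np.nan, "p": np.nan,
        "dwh_p": np.nan, "dwh_method": "", "n": n, "f_stat": np.nan,
        "r2": np.nan, "weak_instrument": False, "status": status,
    }


def _analyse_stratum(sub: pd.DataFrame, score: pd.Series, subgroup: str,
                     config: AnalysisConfig) -> list[dict]:
    """Crude and adjusted OLS/2SLS/DWH rows for one stratum."""
    rows: list[dict] = []
    y = sub["tbil"].to_numpy()
    x = sub["su"].to_numpy()
    z = score.loc[sub.index].to_numpy()
    C_adj, adj_names = design_covariates(sub, config.adjust)

    for model in ("crude", "adjusted"):
        C = None if model == "crude" else C_adj
        names = None if model == "crude" else adj_names
        try:
            ols = ols_fit(y, x, covariates=C, term="su", covariate_names=names)
            fs = first_stage(x, z, C, on_perfect="raise")
            tsls = tsls_fit(y, x, z, covariates=C, covariate_names=names)
            d = dwh_contrast(ols, tsls, alpha=config.alpha,
                             fallback_data=(y, x, z, C))
        except (CollinearityError, DegenerateInstrumentError, ValueError) as exc:
            logger.warning("subgroup %s (%s): %s", subgroup, model, exc)
            for estimator in ("OLS", "TLS"):
                rows.append(_empty_row(subgroup, model, estimator, len(sub),
                                       "degenerate"))
            continue
        common = {
            "subgroup": subgroup, "model": model, "dwh_p": d.p,
            "dwh_method": d.method, "n": len(sub), "f_stat": fs.f_stat,
            "r2": fs.r2, "weak_instrument": fs.weak_instrument, "status": "ok",
        }
        rows.append({**common, "estimator": "OLS", "beta": ols.beta,
                     "se": ols.se, "stat": ols.stat, "p": ols.p})
        rows.append({**common, "estimator": "TLS", "beta": tsls.beta,
                     "se": tsls.se, "stat": tsls.stat, "p": tsls.p})
    return rows


def _instrument_scores(cohort: pd.DataFrame, weights, config: AnalysisConfig) -> pd.Series:
    fn = weighted_grs if config.grs_mode == "weighted" else count_grs
    return fn(cohort, weights, missing=config.missing_dosage)


def run_analysis(cohort: pd.DataFrame, weights,
                 config: AnalysisConfig | None = None,
                 subgroups: list[SubgroupSpec] | None = None) -> pd.DataFrame:
    """Full subgroup analysis table (one row per subgroup x model x estimator).

    Subjects with a missing risk score (incomplete genotypes under the
    complete-case policy) are excluded from every stratum.  Strata smaller
    than ``config.min_n`` are emitted with status ``insufficient_n`` rather
    than silently dropped.
    """
    config = config or AnalysisConfig()
    subgroups = subgroups if subgroups is not None else default_subgroups()
    score = _instrument_scores(cohort, weights, config)
    usable = cohort[score.notna()]
    if len(usable) < len(cohort):
        logger.info("dropped %d subjects with incomplete genotypes",
                    len(cohort) - len(usable))
    score = score.loc[usable.index]

    rows: list[dict] = []
    for sg in subgroups:
        sub = usable[sg.mask(usable, config.su_threshold)]
        if len(sub) < config.min_n:
            for model in ("crude", "adjusted"):
                for estimator in ("OLS", "TLS"):
                    rows.append(_empty_row(sg.name, model, estimator,
                                           len(sub), "insufficient_n"))
            continue
        rows.extend(_analyse_stratum(sub, score, sg.name, config))
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def per_snp_analysis(cohort: pd.DataFrame, weights,
                     config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Single-variant instrumental analysis (all/males/females per SNP).

    Each SNP's dosage column serves alone as the instrument; the
    weak-instrument flag (first-stage F < 10) is carried per row, and a
    monomorphic SNP yields rows marked ``degenerate`` with no estimate.
    """
    config = config or AnalysisConfig()
    if not weights:
        raise ValueError("need at least one instrument SNP")
    rows: list[dict] = []
    strata = [SubgroupSpec("all"), SubgroupSpec("males", sex="male"),
              SubgroupSpec("females", sex="female")]
    for w in weights:
        dosage = cohort[w.snp_id]
        usable = cohort[dosage.notna()]
        for sg in strata:
            sub = usable[sg.mask(usable, config.su_threshold)]
            base = {"snp_id": w.snp_id, "subgroup": sg.name, "n": len(sub)}
            if len(sub) < config.min_n:
                rows.append({**base, "status": "insufficient_n"})
                continue
            z = sub[w.snp_id].to_numpy(dtype=float)
            if np.ptp(z) == 0:
                rows.append({**base, "status": "degenerate"})
                continue
            y = sub["tbil"].to_numpy()
            x = sub["su"].to_numpy()
            C, names = design_covariates(sub, config.adjust)
            try:
                fs = first_stage(x, z, C)
                ols = ols_fit(y, x, covariates=C, term="su", covariate_names=names)
                tsls = tsls_fit(y, x, z, covariates=C, covariate_names=names)
                d = dwh_contrast(ols, tsls, alpha=config.alpha,
                                 fallback_data=(y, x, z, C))
            except (CollinearityError, DegenerateInstrumentError, ValueError):
                rows.append({**base, "status": "degenerate"})
                continue
            rows.append({
                **base, "f_stat": fs.f_stat, "r2": fs.r2,
                "weak_instrument": fs.weak_instrument,
                "beta": tsls.beta, "se": tsls.se, "p": tsls.p,
                "dwh_p": d.p, "dwh_method": d.method, "status": "ok",
            })
    columns = ["snp_id", "subgroup", "n", "f_stat", "r2", "weak_instrument",
               "beta", "se", "p", "dwh_p", "dwh_method", "status"]
    return pd.DataFrame(rows).reindex(columns=columns)


def instrument_diagnostics(cohort: pd.DataFrame, weights,
                           config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Instrument validity table: first-stage strength and confounder checks.

    First block: univariate first-stage F, R² and p per sex stratum (the
    instrument-relevance assumption).  Second block: crude and adjusted
    association of the score with each measured confounder (the
    instrument-independence assumption); each confounder is adjusted for
    the remaining covariates.
    """
    config = config or AnalysisConfig()
    score = _instrument_scores(cohort, weights, config)
    usable = cohort[score.notna()]
    score = score.loc[usable.index]
    rows: list[dict] = []
    strata = [SubgroupSpec("all"), SubgroupSpec("males", sex="male"),
              SubgroupSpec("females", sex="female")]
    for sg in strata:
        sub = usable[sg.mask(usable, config.su_threshold)]
        if len(sub) < config.min_n:
            continue
        fs = first_stage(sub["su"], score.loc[sub.index])
        rows.append({"block": "first_stage", "subgroup": sg.name,
                     "confounder": "", "model": "crude", "beta": np.nan,
                     "se": np.nan, "f_stat": fs.f_stat, "r2": fs.r2,
                     "p": fs.p, "n": fs.n})
        for conf in CONFOUNDERS:
            target = ((sub["sex"] == "male").to_numpy(dtype=float)
                      if conf == "sex" else sub[conf].to_numpy(dtype=float))
            others = tuple(c for c in config.adjust if c != conf)
            if sg.sex is not None:
                others = tuple(c for c in others if c != "sex")
            if conf == "sex" and sg.sex is not None:
                continue
            C, names = design_covariates(sub, others)
            try:
                checks = confounder_check(score.loc[sub.index], target,
                                          adjust=C, confounder_name=conf,
                                          adjust_names=names)
            except CollinearityError:
                continue
            for model, res in checks.items():
                rows.append({"block": "confounder", "subgroup": sg.name,
                             "confounder": conf, "model": model,
                             "beta": res.beta, "se": res.se,
                             "f_stat": np.nan, "r2": np.nan,
                             "p": res.p, "n": res.n})
    return pd.DataFrame(rows)


def write_table(table: pd.DataFrame, path) -> None:
    """Deterministic TSV serialisation (stable float formatting)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
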