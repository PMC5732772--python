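"""Genetic risk scores: the composite instrument for the urate analysis.

The weighted score for subject *i* is ``sum_j dosage_ij * weight_j`` where
the dosage counts urate-increasing alleles and the weight is that allele's
per-allele serum-urate effect (µmol/L), so the score is on the µmol/L scale
and monotone in genetic urate burden.  The unweighted variant simply counts
risk alleles (0 to 2 * n_snps) and is kept for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SnpWeight


class GeneticRiskScore(TransformerMixin, BaseEstimator):
    """Transformer mapping SNP dosage columns to a per-subject risk score.

    Parameters
    ----------
    weights : sequence of SnpWeight
        Oriented instrument weights; defines both the SNP set and, in
        weighted mode, the multipliers.
    mode : {"weighted", "count"}
        "weighted" (default, the analysis instrument) multiplies each
        dosage by its per-allele urate effect; "count" sums raw dosages.
    missing : {"drop", "mean"}
        "drop" (complete-case, default) yields NaN scores for subjects with
        any missing dosage, which downstream analyses exclude; "mean"
        imputes each SNP's mean dosage first.

    Attributes
    ----------
    snp_ids_ : list of str
        Dosage columns used, in weight order.
    weights_ : ndarray
        Effective per-SNP multipliers (all ones in count mode).
    max_score_ : float
        Attainable maximum, ``2 * sum(weights_)``.
    """

    def __init__(self, weights=None, mode: str = "weighted", missing: str = "drop"):
        self.weights = weights
        self.mode = mode
        self.missing = missing

    def fit(self, X: pd.DataFrame, y=None):
        if not self.weights:
            raise ValueError("GeneticRiskScore needs a non-empty weight list")
        if self.mode not in ("weighted", "count"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.missing not in ("drop", "mean"):
            raise ValueError(f"unknown missing policy {self.missing!r}")
        for w in self.weights:
            if not isinstance(w, SnpWeight):
                raise TypeError("weights must be SnpWeight instances")
        absent = [w.snp_id for w in self.weights if w.snp_id not in X.columns]
        if absent:
            raise ValueError(f"dosage column(s) missing from input: {absent}")
        self.snp_ids_ = [w.snp_id for w in self.weights]
        if self.mode == "weighted":
            self.weights_ = np.array([w.weight for w in self.weights], dtype=float)
        else:
            self.weights_ = np.ones(len(self.weights))
        self.max_score_ = float(2.0 * self.weights_.sum())
        self.n_features_in_ = len(self.snp_ids_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "snp_ids_"):
            raise AttributeError("GeneticRiskScore is not fitted")
        dosages = X[self.snp_ids_].to_numpy(dtype=float)
        bad = ~(np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage {dosages[i, j]} at column {self.snp_ids_[j]} "
                "is outside {0,1,2,NA}"
            )
        if self.missing == "mean":
            col_means = np.nanmean(dosages, axis=0)
            idx = np.where(np.isnan(dosages))
            dosages[idx] = np.take(col_means, idx[1])
        scores = dosages @ self.weights_
        name = "grs" if self.mode == "weighted" else "grs_count"
        return pd.Series(scores, index=X.index, name=name)


def weighted_grs(cohort: pd.DataFrame, weights, missing: str = "drop") -> pd.Series:
    """Weighted genetic risk score, µmol/L scale (see :class:`GeneticRiskScore`)."""
    return GeneticRiskScore(weights, mode="weighted", missing=missing).fit_transform(cohort)


def count_grs(cohort: pd.DataFrame, weights, missing: str = "drop") -> pd.Series:
    """Unweighted risk-allele count, integer 0 to 2 * n_snps."""
    return GeneticRiskScore(weights, mode="count", missing=missing).fit_transform(cohort)


def write_grs(scores: pd.Series, path) -> None:
    """Emit a per-subject `subject_id<TAB>score` file."""
    scores.rename("score").to_csv(path, sep="\t", index_label="subject_id",
                                  float_format="%.10g")
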