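"""Weighted polygenic risk score construction, validation and sensitivity sweeps.

The score for individual j is sum_i w_i g_ij over the score variants, where
g_ij is the dosage of the effect allele and w_i an externally estimated
log-odds weight. Scores are reported per 1 standard deviation; association
with case status uses logistic regression adjusted for four ancestry
components. A pruning-and-thresholding sweep rebuilds weight tables from
summary statistics at increasingly permissive p-value thresholds.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import statcore
from .meta import LdProvider, ld_clump

__all__ = [
    "ScoreVector",
    "AssociationSummary",
    "load_weight_table",
    "packaged_weight_table",
    "compute_prs",
    "standardize_prs",
    "prs_association",
    "subgroup_prs_analysis",
    "pt_sweep",
]

WEIGHT_COLUMNS = ("SNP", "A1", "WEIGHT", "SOURCE")


@dataclass
class ScoreVector:
    """Per-individual raw and standardized polygenic scores."""

    raw: np.ndarray
    z: np.ndarray
    reference_mean: float
    reference_sd: float


@dataclass
class AssociationSummary:
    """Logistic association of a score (or group indicator) with case status."""

    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p: float
    beta: float
    se: float
    n_cases: int
    n_controls: int
    converged: bool


def load_weight_table(path) -> pd.DataFrame:
    """Load a tab-separated PRS weight table (SNP, A1, WEIGHT, SOURCE)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WEIGHT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if df["SNP"].duplicated().any():
        raise ValueError("duplicate variant ids in weight table")
    return df


def packaged_weight_table() -> pd.DataFrame:
    """The packaged 39-variant score table.

    The variants mirror the canonical score's structure (39 genome-wide
    significant loci, APOE excluded); the weights shipped here are SYNTHETIC
    placeholders of realistic magnitude, for simulation and testing -- they
    are not estimates from any study.
    """
    ref = importlib.resources.files("adgwas.data") / "prs_weights_39_synthetic.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_weight_table(path)


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame,
                allele_alignment: dict[str, str] | None = None) -> np.ndarray:
    """Raw weighted scores: score_j = sum_i w_i * g_ij.

    ``dosages`` columns are variant IDs storing effect-allele counts in [0, 2];
    when ``allele_alignment`` maps a variant to an allele different from the
    weight table's A1, the stored orientation is flipped as 2 - dosage.
    Missing dosages are mean-imputed as twice the in-sample effect-allele
    frequency.
    """
    missing_ids = [v for v in weights["SNP"] if v not in dosages.columns]
    if missing_ids:
        raise KeyError(f"weight variants absent from dosage matrix: {missing_ids}")

    n = dosages.shape[0]
    score = np.zeros(n)
    for snp, a1, w in zip(weights["SNP"], weights["A1"], weights["WEIGHT"]):
        d = dosages[snp].to_numpy(dtype=float)
        if allele_alignment is not None:
            stored = allele_alignment.get(snp, a1)
            if stored != a1:
                d = 2.0 - d
        nan = np.isnan(d)
        if nan.any():
            if nan.all():
                raise ValueError(f"{snp}: no observed dosages to impute from")
            eaf = d[~nan].mean() / 2.0
            d = np.where(nan, 2.0 * eaf, d)
        score += w * d
    return score


def standardize_prs(raw, reference_subset=None) -> ScoreVector:
    """Standardize raw scores to a reference mean/SD (n-1 denominator).

    ``reference_subset`` is an index/boolean mask selecting the individuals
    that define the scale (default: everyone, the all-analyzed-individuals
    convention; a controls-only reference is a caller choice).
    """
    raw = np.asarray(raw, dtype=float)
    ref = raw if reference_subset is None else raw[np.asarray(reference_subset)]
    if ref.size < 2:
        raise ValueError("reference subset must have at least 2 individuals")
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0:
        raise ValueError("reference subset has zero score variance")
    return ScoreVector(raw, (raw - mean) / sd, mean, sd)


def _logistic_summary(predictor, status, covariates) -> AssociationSummary:
    status = np.asarray(status, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    design = np.column_stack([np.ones(status.size), predictor, cov])
    fit = statcore.logistic_fit(design, status)
    beta, se = float(fit.coefficients[1]), float(fit.standard_errors[1])
    or_, lo, hi = statcore.wald_or_ci(beta, se)
    p = float(fit.p_values()[1])
    return AssociationSummary(or_, lo, hi, p, beta, se,
                              int(status.sum()), int((1 - status).sum()),
                              fit.converged)


def prs_association(scores: ScoreVector, status, covariates) -> AssociationSummary:
    """Odds ratio per 1-SD PRS from logistic regression with ancestry covariates."""
    return _logistic_summary(scores.z, status, covariates)


def subgroup_prs_analysis(scores: ScoreVector, status, covariates,
                          subgroups: dict[str, np.ndarray],
                          shared_controls: bool = True) -> dict[str, AssociationSummary | None]:
    """Per-subgroup PRS association.

    ``subgroups`` maps labels to boolean masks over individuals. With
    ``shared_controls`` (the default) each subgroup's cases are compared
    against the full control set, mirroring designs where every case subset
    uses one common control panel. Subgroups lacking either class are
    reported as None (skipped with a diagnostic entry).
    """
    status = np.asarray(status, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    out: dict[str, AssociationSummary | None] = {}
    for label, mask in subgroups.items():
        mask = np.asarray(mask, dtype=bool)
        keep = (mask & (status == 1))
        keep = keep | ((status == 0) if shared_controls else (mask & (status == 0)))
        s = status[keep]
        if not (np.any(s == 1) and np.any(s == 0)):
            out[label] = None
            continue
        out[label] = _logistic_summary(scores.z[keep], s, covariates[keep])
    return out


def pt_sweep(sumstats: pd.DataFrame, ld: LdProvider, thresholds,
             clump_r2: float = 0.001, clump_window: int = 1_000_000) -> dict[float, pd.DataFrame]:
    """Pruning-and-thresholding sweep.

    ``sumstats`` needs SNP, CHR, BP, A1, BETA, P. Variants are clumped once at
    the strict settings; for each p-value threshold, the clump sentinels below
    the threshold form a weight table with weights equal to their betas.
    Tables are nested across increasing (looser) thresholds by construction.
    """
    clumps = ld_clump(sumstats, ld, r2_threshold=clump_r2, window_bp=clump_window)
    sent = pd.DataFrame({"SNP": [c.sentinel for c in clumps],
                         "P": [c.sentinel_p for c in clumps]})
    ref = sumstats.set_index(sumstats["SNP"].astype(str))
    out: dict[float, pd.DataFrame] = {}
    for thr in sorted(thresholds):
        keep = sent[sent["P"] < thr]["SNP"]
        rows = ref.loc[keep]
        out[thr] = pd.DataFrame({
            "SNP": rows["SNP"].astype(str).to_numpy(),
            "A1": rows["A1"].to_numpy(),
            "WEIGHT": rows["BETA"].to_numpy(dtype=float),
            "SOURCE": f"pt<{thr:g}",
        }).reset_index(drop=True)
    return out
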