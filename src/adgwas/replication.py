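"""Recipes that re-derive the study's headline quantities at run time.

Each function runs the full pipeline path on freshly generated inputs: the
printed discovery/follow-up interval estimates pooled by fixed-effects IVW,
and synthetic-cohort recovery of the per-SD polygenic odds ratio, the
extreme-percentile risk contrast, the onset-age gaps between combined
APOE/PRS strata, and the pathologically-confirmed case-series effect.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import statcore
from .meta import ivw_meta, se_from_ci
from .prs import prs_association, standardize_prs
from .stratify import aao_compare, anchored_percentiles, assign_combined_groups
from .synthdata import GeneratorConfig, simulate_cohort, table1_variant_panel

__all__ = [
    "followup_overall_odds_ratios",
    "per_sd_replicates",
    "pathology_series_replicates",
    "aao_gap_recovery",
]

PCS = ["PC1", "PC2", "PC3", "PC4"]


def followup_overall_odds_ratios() -> pd.DataFrame:
    """Combined odds ratio per follow-up locus from the packaged printed
    discovery and follow-up estimates (se reconstructed from the 95% CIs,
    fixed-effects IVW pooling, exponentiated)."""
    import importlib.resources

    ref = importlib.resources.files("adgwas.data") / "followup_loci.tsv"
    with importlib.resources.as_file(ref) as path:
        loci = pd.read_csv(path, sep="\t")
    rows = []
    for row in loci.itertuples(index=False):
        disc = (math.log(row.OR_DISC), se_from_ci(row.OR_DISC, row.L_DISC, row.U_DISC))
        fu = (math.log(row.OR_FU), se_from_ci(row.OR_FU, row.L_FU, row.U_FU))
        rec = ivw_meta([disc, fu], row.SNP, ["discovery", "followup"])
        rows.append({"SNP": row.SNP, "GENE": row.GENE, "GROUP": row.GROUP,
                     "OR_OVERALL": rec.odds_ratio(),
                     "BETA": rec.beta_combined, "SE": rec.se_combined,
                     "P": rec.p})
    return pd.DataFrame(rows)


def _extreme_bin_or(z, status, age, pcs, k: int = 50) -> float:
    """Logistic OR of the top vs bottom anchored percentile bin."""
    _, bins = anchored_percentiles(z, status, age, k=k)
    keep = (bins == 1) | (bins == k)
    top = (bins[keep] == k).astype(float)
    design = np.column_stack([np.ones(int(keep.sum())), top, pcs[keep]])
    fit = statcore.logistic_fit(design, status[keep].astype(float))
    return float(math.exp(fit.coefficients[1]))


def per_sd_replicates(seeds, n_cases: int = 6331, n_controls: int = 6055,
                      per_sd_or: float = 1.27,
                      extreme_bins: bool = False) -> dict:
    """Replicate-mean recovery of the per-SD polygenic odds ratio.

    Each replicate simulates a cohort under the effect-isolated generator,
    standardizes the polygenic score over all individuals and fits a logistic
    model with the four ancestry components. With ``extreme_bins`` the top-
    versus-bottom 2-percentile contrast (boundaries anchored on controls aged
    55 or younger) is also estimated per replicate.
    """
    ors, extremes = [], []
    for seed in seeds:
        cfg = GeneratorConfig.prs_validation(int(seed), n_cases=n_cases,
                                             n_controls=n_controls,
                                             per_sd_or=per_sd_or)
        ph = simulate_cohort(cfg).pheno
        status = ph.STATUS.to_numpy()
        pcs = ph[PCS].to_numpy()
        sv = standardize_prs(ph.POLY_SCORE.to_numpy())
        ors.append(prs_association(sv, status, pcs).odds_ratio)
        if extreme_bins:
            extremes.append(_extreme_bin_or(sv.z, status,
                                            ph.AGE.to_numpy(), pcs))
    out = {"mean_or": float(np.mean(ors)), "ors": ors,
           "n": n_cases + n_controls, "n_replicates": len(ors)}
    if extreme_bins:
        out["mean_extreme_or"] = float(np.mean(extremes))
        out["extreme_ors"] = extremes
    return out


def pathology_series_replicates(seeds, n_cases: int = 332,
                                n_controls: int = 1386,
                                per_sd_or: float = 1.38) -> dict:
    """Per-SD recovery at the pathologically-confirmed case-series scale."""
    return per_sd_replicates(seeds, n_cases=n_cases, n_controls=n_controls,
                             per_sd_or=per_sd_or)


def aao_gap_recovery(seeds, n_cases: int = 90_000,
                     n_controls: int = 20_000) -> dict:
    """Median onset-age gaps between extreme combined strata.

    Per replicate: simulate under the onset-age recovery configuration, call
    and pool APOE genotypes from the epsilon-variant dosages, assign combined
    (group, PRS bin) strata with young-control-anchored boundaries, and
    compare case onset medians with the rank-sum machinery. Returns the
    replicate-mean absolute gaps between (e2e2/e2e3, lowest bin) and
    (e4e4, highest bin), and within e4e4 between its extreme bins.
    """
    from .stratify import call_apoe_frame

    gaps_extreme, gaps_e4e4, min_n = [], [], np.inf
    for seed in seeds:
        cfg = GeneratorConfig.aao_recovery(int(seed), n_cases=n_cases,
                                           n_controls=n_controls)
        ph = simulate_cohort(cfg).pheno
        group = call_apoe_frame(ph)
        combined = assign_combined_groups(
            ph.POLY_SCORE.to_numpy(), ph.STATUS.to_numpy(),
            ph.AGE.to_numpy(), group)
        cases = ph.STATUS.to_numpy() == 1
        lab = combined.COMBINED.to_numpy()
        aao = ph.AAO.to_numpy()

        def stratum(label):
            return aao[cases & (lab == label)]

        low, high = stratum("e2e2/e2e3:1"), stratum("e4e4:3")
        e4_low = stratum("e4e4:1")
        min_n = min(min_n, low.size, high.size, e4_low.size)
        _, d_extreme = aao_compare(low, high)
        _, d_within = aao_compare(e4_low, high)
        gaps_extreme.append(abs(d_extreme))
        gaps_e4e4.append(abs(d_within))
    return {"gap_extreme_groups": float(np.mean(gaps_extreme)),
            "gap_within_e4e4": float(np.mean(gaps_e4e4)),
            "min_stratum_cases": int(min_n),
            "n_replicates": len(gaps_extreme)}
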