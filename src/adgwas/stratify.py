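"""PRS percentile stratification within APOE genotype groups.

Implements survival-bias-corrected percentile boundaries (computed on young
controls only, then applied to everyone), APOE genotype calling from the two
epsilon-defining variants and pooling into four risk groups, logistic
contrasts of combined (APOE group x PRS bin) strata against a reference
group, median age-at-onset comparisons by Wilcoxon rank-sum, and a case-only
Cox proportional-hazards model of onset age with a PRS x APOE interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import statcore
from .statcore import FitResult, RankTestResult

__all__ = [
    "ApoeGenotype",
    "BoundarySet",
    "APOE_POOLING",
    "POOLED_GROUPS",
    "CANONICAL_APOE_BINS",
    "call_apoe",
    "call_apoe_frame",
    "anchored_percentiles",
    "assign_combined_groups",
    "combined_group_contrasts",
    "aao_compare",
    "cox_prs_apoe",
    "survival_curves",
]

APOE_POOLING = {
    "e2e2": "e2e2/e2e3",
    "e2e3": "e2e2/e2e3",
    "e3e3": "e3e3",
    "e2e4": "e2e4/e3e4",
    "e3e4": "e2e4/e3e4",
    "e4e4": "e4e4",
}

#: Pooled groups ordered from lowest to highest APOE-attributable risk.
POOLED_GROUPS = ("e2e2/e2e3", "e3e3", "e2e4/e3e4", "e4e4")

#: Canonical PRS bin counts per pooled group (sizes roughly proportional to n).
CANONICAL_APOE_BINS = {"e2e2/e2e3": 7, "e3e3": 25, "e2e4/e3e4": 15, "e4e4": 3}


@dataclass(frozen=True)
class ApoeGenotype:
    label: str          # e2e2 .. e4e4
    pooled_group: str   # one of POOLED_GROUPS


@dataclass
class BoundarySet:
    """PRS cut-points (z-score units) and the anchoring rule that produced them."""

    cuts: np.ndarray
    anchor_n: int
    anchor_rule: str
    degenerate: bool = False


def call_apoe(rs429358_dosage: float, rs7412_dosage: float) -> ApoeGenotype:
    """Call the APOE genotype from the two epsilon-defining variant dosages.

    rs429358 dosage counts the epsilon-4-tagging C allele; rs7412 dosage
    counts the epsilon-2-tagging T allele; remaining alleles are epsilon 3.
    The rs429358=1 / rs7412=1 double heterozygote is resolved as e2e4 under
    the convention that the rare epsilon-1 haplotype is absent. Dosages more
    than 0.1 from an integer are not hard-callable.
    """
    e4 = round(float(rs429358_dosage))
    e2 = round(float(rs7412_dosage))
    if abs(rs429358_dosage - e4) > 0.1 or abs(rs7412_dosage - e2) > 0.1:
        raise ValueError("dosage not hard-callable (further than 0.1 from an integer)")
    if not (0 <= e4 <= 2 and 0 <= e2 <= 2):
        raise ValueError("dosages must lie in [0, 2]")
    if e4 + e2 > 2:
        raise ValueError(f"inconsistent genotype: {e4} e4 alleles + {e2} e2 alleles")
    e3 = 2 - e4 - e2
    alleles = sorted(["e2"] * e2 + ["e3"] * e3 + ["e4"] * e4)
    label = "".join(alleles)
    return ApoeGenotype(label, APOE_POOLING[label])


def call_apoe_frame(pheno: pd.DataFrame,
                    rs429358_col: str = "APOE_RS429358_DS",
                    rs7412_col: str = "APOE_RS7412_DS") -> pd.Series:
    """Vectorized pooled-group call over a phenotype table."""
    return pd.Series(
        [call_apoe(a, b).pooled_group
         for a, b in zip(pheno[rs429358_col], pheno[rs7412_col])],
        index=pheno.index, name="APOE_GROUP")


def _assign_bins(values: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """1-based bin assignment; intervals are right-closed, extremes clamp."""
    return np.searchsorted(cuts, values, side="left") + 1


def anchored_percentiles(scores, status, age, k: int = 50,
                         anchor_max_age: float = 55.0) -> tuple[BoundarySet, np.ndarray]:
    """Percentile bins with boundaries anchored on young controls.

    Boundaries are the k-quantile cut-points of the scores of controls aged
    ``anchor_max_age`` or younger -- individuals young enough that selective
    survival and onset have not yet distorted the score distribution. Every
    individual (anchor or not) is then assigned by those same boundaries;
    scores beyond the extreme cut-points clamp into bins 1 and k.
    """
    z = np.asarray(scores, dtype=float)
    status = np.asarray(status)
    age = np.asarray(age, dtype=float)
    anchor = (status == 0) & (age <= anchor_max_age)
    n_anchor = int(anchor.sum())
    if n_anchor < k:
        raise ValueError(f"anchor subset ({n_anchor}) smaller than k ({k})")
    qb = statcore.quantile_boundaries(z[anchor], k)
    bounds = BoundarySet(qb.cuts, n_anchor,
                         f"controls with age <= {anchor_max_age:g}", qb.degenerate)
    return bounds, _assign_bins(z, qb.cuts)


def assign_combined_groups(scores, status, age, apoe_group,
                           bins_per_group: dict[str, int] | None = None,
                           anchor_max_age: float = 55.0) -> pd.DataFrame:
    """Combined (APOE pooled group, within-group PRS bin) stratum per individual.

    Within each pooled APOE group, members are split into the configured
    number of PRS strata. Boundaries are anchored on the group's young
    controls when that anchor is at least as large as the bin count;
    otherwise (tiny strata) they fall back to all group members, and the
    rule used is recorded.
    """
    bins_per_group = dict(bins_per_group or CANONICAL_APOE_BINS)
    z = np.asarray(scores, dtype=float)
    status = np.asarray(status)
    age = np.asarray(age, dtype=float)
    groups = pd.Series(apoe_group).reset_index(drop=True)

    bin_idx = np.zeros(z.size, dtype=int)
    rules = {}
    for g, k in bins_per_group.items():
        in_g = (groups == g).to_numpy()
        if not in_g.any():
            continue
        anchor = in_g & (status == 0) & (age <= anchor_max_age)
        if int(anchor.sum()) >= max(k, 2):
            qb = statcore.quantile_boundaries(z[anchor], k)
            rules[g] = f"young controls (n={int(anchor.sum())})"
        else:
            qb = statcore.quantile_boundaries(z[in_g], k)
            rules[g] = f"all group members (n={int(in_g.sum())})"
        bin_idx[in_g] = _assign_bins(z[in_g], qb.cuts)

    df = pd.DataFrame({
        "APOE_GROUP": groups.to_numpy(),
        "PRS_BIN": bin_idx,
    })
    df["COMBINED"] = df["APOE_GROUP"] + ":" + df["PRS_BIN"].astype(str)
    df.attrs["anchor_rules"] = rules
    df.attrs["bins_per_group"] = bins_per_group
    return df


def combined_group_contrasts(groups, status, covariates,
                             reference: str) -> pd.DataFrame:
    """Logistic odds ratio of every stratum against a reference stratum.

    Each contrast fits an indicator for stratum membership plus the ancestry
    covariates on the rows belonging to the stratum or the reference. Strata
    in which either class is absent are returned flagged without an estimate.
    Works for the 50-bin PRS-only design and the APOE-combined design alike
    (``groups`` is any per-individual label vector).
    """
    labels = pd.Series(groups).reset_index(drop=True)
    status = np.asarray(status, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if reference not in set(labels):
        raise ValueError(f"reference group {reference!r} is empty")
    ref_mask = (labels == reference).to_numpy()
    if not (np.any(status[ref_mask] == 1) and np.any(status[ref_mask] == 0)):
        raise ValueError("reference group must contain both cases and controls")

    rows = []
    for g in sorted(set(labels)):
        mask = (labels == g).to_numpy()
        n_cases = int(status[mask].sum())
        n_controls = int((1 - status[mask]).sum())
        row = {"group": g, "reference_group": reference,
               "n_cases": n_cases, "n_controls": n_controls,
               "OR": np.nan, "CI_L": np.nan, "CI_U": np.nan, "P": np.nan,
               "flag": ""}
        if g == reference:
            row["OR"], row["flag"] = 1.0, "reference"
        elif n_cases == 0 or n_controls == 0:
            row["flag"] = "single_class"
        else:
            keep = mask | ref_mask
            design = np.column_stack([np.ones(int(keep.sum())),
                                      mask[keep].astype(float), cov[keep]])
            fit = statcore.logistic_fit(design, status[keep])
            beta, se = float(fit.coefficients[1]), float(fit.standard_errors[1])
            or_, lo, hi = statcore.wald_or_ci(beta, se)
            row.update(OR=or_, CI_L=lo, CI_U=hi, P=float(fit.p_values()[1]))
            if not fit.converged:
                row["flag"] = "non_converged"
        rows.append(row)
    return pd.DataFrame(rows)


def aao_compare(aao_group_a, aao_group_b,
                mode: str = "auto") -> tuple[RankTestResult, float]:
    """Median onset ages of two case groups, their difference (a - b) and a
    two-sided Wilcoxon rank-sum p-value."""
    a = np.asarray(aao_group_a, dtype=float)
    b = np.asarray(aao_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = statcore.wilcoxon_rank_sum(a, b, mode=mode)
    return res, float(res.medians[0] - res.medians[1])


def cox_prs_apoe(aao, prs_z, apoe_group, covariates,
                 reference_group: str = "e2e2/e2e3") -> FitResult:
    """Case-only Cox model of onset age on PRS, APOE group and their interaction.

    All individuals are cases (event = 1). Terms: centered PRS main effect,
    indicators for each non-reference pooled APOE group, PRS x group
    interactions, and the ancestry covariates. Because the PRS is centered,
    APOE main effects are at-mean-PRS effects. With a single APOE group
    present the model reduces to PRS + covariates.
    """
    t = np.asarray(aao, dtype=float)
    z = np.asarray(prs_z, dtype=float)
    z = z - z.mean()
    groups = pd.Series(apoe_group).reset_index(drop=True)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]

    present = [g for g in POOLED_GROUPS if (groups == g).any()]
    others = [g for g in present if g != reference_group]
    cols = [z]
    names = ["prs"]
    for g in others:
        ind = (groups == g).to_numpy(dtype=float)
        cols.append(ind)
        names.append(f"apoe[{g}]")
    for g in others:
        ind = (groups == g).to_numpy(dtype=float)
        cols.append(ind * z)
        names.append(f"prs:apoe[{g}]")
    for j in range(cov.shape[1]):
        cols.append(cov[:, j])
        names.append(f"pc{j + 1}")
    x = np.column_stack(cols)
    return statcore.cox_ph_fit(t, np.ones(t.size), x, names=names)


def survival_curves(aao, groups, fit: FitResult | None = None,
                    design: np.ndarray | None = None) -> pd.DataFrame:
    """Onset-by-age curves per group: 1 - S(age), the probability a case has
    developed disease by each age.

    Always returns nonparametric Kaplan-Meier curves (all-events data makes
    these the empirical onset CDF per group). When a Cox ``fit`` and its
    ``design`` matrix are supplied, Breslow baseline-based model curves at
    each group's mean covariates are added alongside, labelled ``method``.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(aao, dtype=float)
    labels = pd.Series(groups).reset_index(drop=True)
    frames = []
    for g in sorted(set(labels)):
        mask = (labels == g).to_numpy()
        km = KaplanMeierFitter()
        km.fit(t[mask], event_observed=np.ones(int(mask.sum())))
        sf = km.survival_function_
        frames.append(pd.DataFrame({
            "group": g, "age": sf.index.to_numpy(dtype=float),
            "onset_probability": 1.0 - sf.iloc[:, 0].to_numpy(),
            "method": "kaplan_meier"}))

    if fit is not None and design is not None:
        x = np.asarray(design, dtype=float)
        eta = x @ fit.coefficients
        order = np.argsort(t, kind="stable")
        ts, etas = t[order], eta[order]
        uniq, first = np.unique(ts, return_index=True)
        # Breslow cumulative baseline hazard on the event grid
        r = np.exp(etas)
        denom = np.cumsum(r[::-1])[::-1]  # sum over risk set {i: t_i >= t}
        d = np.diff(np.append(first, ts.size))
        h0 = d / denom[first]
        H0 = np.cumsum(h0)
        for g in sorted(set(labels)):
            mask = (labels == g).to_numpy()
            eta_g = float(eta[mask].mean())
            frames.append(pd.DataFrame({
                "group": g, "age": uniq,
                "onset_probability": 1.0 - np.exp(-H0 * np.exp(eta_g - 0)),
                "method": "cox_breslow"}))
    return pd.concat(frames, ignore_index=True)
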