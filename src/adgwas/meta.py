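"""Fixed-effects inverse-variance-weighted meta-analysis and LD-aware post-processing.

Covers: pooling per-study log-OR estimates with weights 1/se^2, reconstructing
standard errors from printed confidence intervals, the genomic inflation
factor lambda, pairwise LD (r^2 and D') from dosage vectors, greedy LD
clumping of association results, and selection of suggestive variants for
follow-up around sentinel loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaRecord",
    "ClumpSet",
    "LdEstimate",
    "LdProvider",
    "se_from_ci",
    "ivw_meta",
    "meta_analyze",
    "genomic_lambda",
    "compute_ld",
    "ld_clump",
    "select_followup",
]

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class MetaRecord:
    """Combined evidence across studies for one variant."""

    variant_id: str
    beta_combined: float
    se_combined: float
    z: float
    p: float
    per_study: list[tuple[str, float, float, float]]  # (study, beta, se, weight)
    n_studies: int
    cochran_q: float = float("nan")
    q_p: float = float("nan")

    def odds_ratio(self) -> float:
        return math.exp(self.beta_combined)


@dataclass
class ClumpSet:
    """A sentinel variant and the correlated neighbours it absorbs."""

    sentinel: str
    members: list[str]
    sentinel_p: float


@dataclass
class LdEstimate:
    r2: float
    d_prime: float


def se_from_ci(or_point: float, lower: float, upper: float,
               level: float = 0.95) -> float:
    """Standard error of ln(OR) reconstructed from a printed confidence interval.

    Assumes the interval is symmetric on the log scale:
    se = (ln upper - ln lower) / (2 z).
    """
    if min(or_point, lower, upper) <= 0:
        raise ValueError("odds ratio and bounds must be positive")
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    if not lower <= or_point <= upper:
        raise ValueError("point estimate outside its interval")
    if lower == upper:
        raise ValueError("zero-width interval carries no uncertainty")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (math.log(upper) - math.log(lower)) / (2.0 * z)


def ivw_meta(inputs, variant_id: str = "", study_names=None) -> MetaRecord:
    """Fixed-effects inverse-variance-weighted pooling of (beta, se) pairs.

    weight_i = se_i^-2; beta = sum(w b)/sum(w); se = sum(w)^-1/2; two-sided
    normal p. Deterministic and order-independent.
    """
    inputs = list(inputs)
    if not inputs:
        raise ValueError("at least one study is required")
    names = list(study_names) if study_names is not None else [
        f"study{i + 1}" for i in range(len(inputs))]
    per_study = []
    sw = swb = 0.0
    for name, (beta, se) in zip(names, inputs):
        if se <= 0:
            raise ValueError("standard errors must be positive")
        w = se ** -2
        per_study.append((name, float(beta), float(se), w))
        sw += w
        swb += w * beta
    beta_c = swb / sw
    se_c = sw ** -0.5
    z = beta_c / se_c
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = sum(w * (b - beta_c) ** 2 for _, b, _, w in per_study)
    q_p = float(stats.chi2.sf(q, len(inputs) - 1)) if len(inputs) > 1 else float("nan")
    return MetaRecord(variant_id, float(beta_c), float(se_c), float(z), p,
                      per_study, len(inputs), float(q), q_p)


def meta_analyze(study_frames: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """IVW meta-analysis of several harmonized summary-statistic tables.

    Each frame needs columns SNP, CHR, BP, BETA, SE; variants are joined on
    SNP and pooled across whichever studies report them. Returns a tidy table
    with the combined estimate, z, p, Cochran's Q (reported, not filtered on)
    and the number of contributing studies.
    """
    merged: dict[str, dict] = {}
    for study, df in study_frames.items():
        for row in df.itertuples(index=False):
            ent = merged.setdefault(row.SNP, {"CHR": row.CHR, "BP": row.BP, "studies": []})
            ent["studies"].append((study, float(row.BETA), float(row.SE)))
    rows = []
    for snp, ent in merged.items():
        rec = ivw_meta([(b, s) for _, b, s in ent["studies"]], snp,
                       [nm for nm, _, _ in ent["studies"]])
        rows.append({"SNP": snp, "CHR": ent["CHR"], "BP": ent["BP"],
                     "BETA": rec.beta_combined, "SE": rec.se_combined,
                     "Z": rec.z, "P": rec.p, "Q": rec.cochran_q,
                     "Q_P": rec.q_p, "N_STUDIES": rec.n_studies})
    out = pd.DataFrame(rows)
    return out.sort_values(["CHR", "BP"], kind="stable").reset_index(drop=True)


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median association chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def _em_haplotype_d(ga: np.ndarray, gb: np.ndarray,
                    n_iter: int = 100, tol: float = 1e-10) -> float:
    """D' between two loci from hard-called genotypes via EM haplotype phasing."""
    pa = ga.mean() / 2.0
    pb = gb.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")
    # haplotype frequencies hAB, hAb, haB, hab
    h = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    dh = (ga == 1) & (gb == 1)  # double heterozygotes: ambiguous phase
    n_dh = int(dh.sum())
    n = ga.size
    # unambiguous haplotype counts: each person contributes two haplotypes
    base = np.zeros(4)
    gau, gbu = ga[~dh], gb[~dh]
    for a, b, w in ((2, 2, (0, 0)), (2, 1, (0, 1)), (2, 0, (1, 1)),
                    (1, 2, (0, 2)), (1, 0, (1, 3)),
                    (0, 2, (2, 2)), (0, 1, (2, 3)), (0, 0, (3, 3))):
        m = int(((gau == a) & (gbu == b)).sum())
        base[w[0]] += m
        base[w[1]] += m
    for _ in range(n_iter):
        # E step: split double-het pairs between cis (AB/ab) and trans (Ab/aB)
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        tot = cis + trans
        f_cis = 0.5 if tot == 0 else cis / tot
        counts = base.copy()
        counts[0] += n_dh * f_cis
        counts[3] += n_dh * f_cis
        counts[1] += n_dh * (1 - f_cis)
        counts[2] += n_dh * (1 - f_cis)
        new_h = counts / (2.0 * n)
        if np.max(np.abs(new_h - h)) < tol:
            h = new_h
            break
        h = new_h
    d = h[0] - (h[0] + h[1]) * (h[0] + h[2])
    pa_, pb_ = h[0] + h[1], h[0] + h[2]
    if d >= 0:
        dmax = min(pa_ * (1 - pb_), (1 - pa_) * pb_)
    else:
        dmax = min(pa_ * pb_, (1 - pa_) * (1 - pb_))
    if dmax == 0:
        return 0.0
    return float(min(1.0, abs(d) / dmax))


def compute_ld(dosages_a, dosages_b) -> LdEstimate:
    """Pairwise LD between two variants from dosage vectors.

    r^2 is the squared Pearson correlation of the dosages; D' comes from EM
    haplotype-frequency estimation on hard-called genotypes, normalized by its
    frequency bound.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least two non-missing pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    ga, gb = np.round(a), np.round(b)
    d_prime = _em_haplotype_d(ga, gb)
    return LdEstimate(float(r ** 2), d_prime)


class LdProvider:
    """Pairwise r^2 lookups from a square matrix or long-format table.

    Long format columns: id_a, id_b, r2 (symmetrized). Missing pairs resolve
    to the configured default (0.0, logged through ``misses``) or raise.
    """

    def __init__(self, r2: dict[tuple[str, str], float],
                 missing: str = "zero"):
        if missing not in ("zero", "error"):
            raise ValueError("missing must be 'zero' or 'error'")
        self._r2 = r2
        self.missing = missing
        self.misses: list[tuple[str, str]] = []

    @classmethod
    def from_long(cls, df: pd.DataFrame, missing: str = "zero") -> "LdProvider":
        table = {}
        for row in df.itertuples(index=False):
            a, b, v = str(row[0]), str(row[1]), float(row[2])
            table[(a, b)] = v
            table[(b, a)] = v
        return cls(table, missing)

    @classmethod
    def from_square(cls, df: pd.DataFrame, missing: str = "zero") -> "LdProvider":
        ids = [str(c) for c in df.columns]
        table = {}
        m = df.to_numpy(dtype=float)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                table[(a, b)] = m[i, j]
        return cls(table, missing)

    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame) -> "LdProvider":
        corr = dosages.corr().to_numpy() ** 2
        ids = [str(c) for c in dosages.columns]
        table = {}
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                v = corr[i, j]
                table[(a, b)] = 0.0 if np.isnan(v) else float(v)
        return cls(table)

    def r2(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 1.0
        try:
            return self._r2[(id_a, id_b)]
        except KeyError:
            if self.missing == "error":
                raise KeyError(f"no LD value for pair ({id_a}, {id_b})")
            self.misses.append((id_a, id_b))
            return 0.0


def ld_clump(records: pd.DataFrame, ld: LdProvider,
             r2_threshold: float = 0.001, window_bp: int = 250_000,
             forced_sentinels=()) -> list[ClumpSet]:
    """Greedy LD clumping of association results.

    ``records`` needs columns SNP, CHR, BP, P. Repeatedly the smallest-p
    unassigned variant becomes a sentinel and absorbs unassigned variants on
    the same chromosome within ``window_bp`` (inclusive) with r^2 >=
    ``r2_threshold``. Ties at equal p break toward the smaller genomic
    coordinate. ``forced_sentinels`` are promoted first regardless of p
    (e.g. the two APOE-defining variants inside that region); clumps are
    returned ordered by sentinel position.
    """
    df = records[["SNP", "CHR", "BP", "P"]].copy()
    df["SNP"] = df["SNP"].astype(str)
    df = df.sort_values(["P", "CHR", "BP"], kind="stable").reset_index(drop=True)
    unassigned = dict(zip(df["SNP"], zip(df["CHR"], df["BP"].astype(int), df["P"])))

    order = [s for s in forced_sentinels if s in unassigned]
    order += [s for s in df["SNP"] if s not in set(order)]

    clumps: list[ClumpSet] = []
    for sent in order:
        if sent not in unassigned:
            continue
        chrom, pos, p = unassigned.pop(sent)
        members = []
        for vid in list(unassigned):
            c2, pos2, _ = unassigned[vid]
            if c2 != chrom or abs(pos2 - pos) > window_bp:
                continue
            if ld.r2(sent, vid) >= r2_threshold:
                members.append(vid)
                del unassigned[vid]
        clumps.append(ClumpSet(sent, members, float(p)))
    pos_of = dict(zip(records["SNP"].astype(str),
                      zip(records["CHR"], records["BP"].astype(int))))
    clumps.sort(key=lambda c: pos_of[c.sentinel])
    return clumps


def select_followup(records: pd.DataFrame, sentinels, p_threshold: float = 1e-5,
                    window_bp: int = 200_000, excluded_regions=()) -> list[str]:
    """Variants with suggestive association near sentinel loci.

    Selects every variant with p < ``p_threshold`` lying within ``window_bp``
    of any sentinel on the same chromosome, excluding those inside
    ``excluded_regions`` (list of (chrom, start, end) intervals, inclusive) --
    regions already established in earlier studies are not re-followed.
    """
    sent_pos = []
    by_id = dict(zip(records["SNP"].astype(str),
                     zip(records["CHR"], records["BP"].astype(int))))
    for s in sentinels:
        if s not in by_id:
            raise KeyError(f"sentinel {s} not found in records")
        sent_pos.append(by_id[s])

    out = []
    for row in records.itertuples(index=False):
        if not row.P < p_threshold:
            continue
        chrom, pos = row.CHR, int(row.BP)
        if any(chrom == c and a <= pos <= b for c, a, b in excluded_regions):
            continue
        if any(chrom == sc and abs(pos - sp) <= window_bp for sc, sp in sent_pos):
            out.append(str(row.SNP))
    return out
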