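"""Read, write, harmonize, quality-filter and proxy-rescale GWAS summary statistics.

File format: tab-separated text with header columns CHR, BP, SNP, A1, A2,
FRQ_A1, BETA (or OR, or OR with OR_L/OR_U confidence bounds), SE, P, N, INFO.
A1 is the effect allele; coordinates are 1-based GRCh37. gzip is handled
transparently. Variant-level QC of cohort dosage matrices implements the
standard array-QC rules: call rate, minor allele frequency, Hardy-Weinberg
equilibrium in controls, differential missingness between cases and controls,
and imputation quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import statcore
from .meta import se_from_ci

__all__ = [
    "SummaryStatRecord",
    "StudyDescriptor",
    "QcThresholds",
    "QcReport",
    "ReadResult",
    "HarmonizeResult",
    "read_sumstats",
    "write_sumstats",
    "harmonize_alleles",
    "rescale_proxy_effects",
    "variant_qc",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_COLUMNS = ("CHR", "BP", "SNP", "A1", "A2")


@dataclass
class SummaryStatRecord:
    """One variant's association evidence in one study (case-control log-OR scale)."""

    chrom: str
    pos: int
    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    p: float
    n_effective: float | None = None
    imputation_r2: float | None = None
    rescaled: bool = False

    def z(self) -> float:
        return self.beta / self.se


@dataclass
class StudyDescriptor:
    """A contributing GWAS: direct case-control or by-proxy design."""

    name: str
    design: str  # "case_control" | "proxy"
    n_cases: int = 0
    n_controls: int = 0
    proxy_rescale_factor: float = 2.0

    def __post_init__(self):
        if self.design not in ("case_control", "proxy"):
            raise ValueError(f"unknown study design: {self.design!r}")
        if self.proxy_rescale_factor <= 0:
            raise ValueError("proxy_rescale_factor must be positive")


@dataclass
class QcThresholds:
    """Variant-QC cut-offs (defaults mirror standard array-QC practice)."""

    call_rate: float = 0.95
    maf: float = 0.01
    hwe_p: float = 1e-4
    diff_missing_p: float = 1e-6
    imputation_r2: float = 0.30


@dataclass
class QcReport:
    n_input: int
    n_pass: int
    passed: list[str]
    failures: dict[str, list[str]] = field(default_factory=dict)

    def failed_variants(self) -> set[str]:
        return {v for ids in self.failures.values() for v in ids}


@dataclass
class ReadResult:
    records: list[SummaryStatRecord]
    malformed: list[tuple[int, str]]


@dataclass
class HarmonizeResult:
    records: list[SummaryStatRecord]
    dropped: list[tuple[str, str]]


def _norm_allele(a) -> str:
    a = str(a).strip().upper()
    if not a or not all(c in "ACGT" for c in a):
        raise ValueError(f"invalid allele {a!r}")
    return a


def read_sumstats(path, dialect: dict[str, str] | None = None) -> ReadResult:
    """Parse a delimited summary-statistics table into records.

    ``dialect`` maps canonical column names (CHR, BP, SNP, A1, A2, FRQ_A1,
    BETA, OR, OR_L, OR_U, SE, P, N, INFO) to the file's own header names.
    OR columns are converted to beta = ln(OR); a missing SE is imputed from
    [OR_L, OR_U] when present; a missing P is filled from the Wald z.
    Malformed rows are collected with reasons, never silently dropped.
    """
    df = pd.read_csv(path, sep="\t")
    if dialect:
        rename = {v: k for k, v in dialect.items() if v in df.columns}
        df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col}")
    if "BETA" not in df.columns and "OR" not in df.columns:
        raise ValueError("missing required column: BETA or OR")
    if "SE" not in df.columns and not {"OR_L", "OR_U"}.issubset(df.columns):
        raise ValueError("missing required column: SE (or OR_L/OR_U bounds)")

    records: list[SummaryStatRecord] = []
    malformed: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValueError, KeyError) as exc:
            malformed.append((int(i), str(exc)))
    return ReadResult(records, malformed)


def _get(row, col):
    if col in row.index:
        v = row[col]
        if pd.notna(v):
            return v
    return None


def _row_to_record(row) -> SummaryStatRecord:
    a1 = _norm_allele(row["A1"])
    a2 = _norm_allele(row["A2"])
    if a1 == a2:
        raise ValueError("effect and other allele are identical")

    beta = _get(row, "BETA")
    if beta is None:
        or_ = float(row["OR"])
        if or_ <= 0:
            raise ValueError(f"non-positive odds ratio: {or_}")
        beta = math.log(or_)
    beta = float(beta)

    se = _get(row, "SE")
    if se is None:
        lo, hi = _get(row, "OR_L"), _get(row, "OR_U")
        if lo is None or hi is None:
            raise ValueError("no SE and no CI bounds to impute it from")
        se = se_from_ci(math.exp(beta), float(lo), float(hi))
    se = float(se)
    if se <= 0:
        raise ValueError(f"non-positive standard error: {se}")

    p = _get(row, "P")
    if p is None:
        p = float(2.0 * stats.norm.sf(abs(beta / se)))
    p = float(p)
    if not 0 < p <= 1:
        raise ValueError(f"p-value outside (0, 1]: {p}")

    eaf = _get(row, "FRQ_A1")
    if eaf is not None:
        eaf = float(eaf)
        if not 0 <= eaf <= 1:
            raise ValueError(f"allele frequency outside [0, 1]: {eaf}")
    n = _get(row, "N")
    info = _get(row, "INFO")
    return SummaryStatRecord(
        chrom=str(row["CHR"]), pos=int(row["BP"]), variant_id=str(row["SNP"]),
        effect_allele=a1, other_allele=a2, eaf=eaf, beta=beta, se=se, p=p,
        n_effective=float(n) if n is not None else None,
        imputation_r2=float(info) if info is not None else None,
    )


def write_sumstats(records, path) -> None:
    """Write records to the canonical tab-separated layout (round-trips with read)."""
    rows = [{
        "CHR": r.chrom, "BP": r.pos, "SNP": r.variant_id,
        "A1": r.effect_allele, "A2": r.other_allele, "FRQ_A1": r.eaf,
        "BETA": r.beta, "SE": r.se, "P": r.p, "N": r.n_effective,
        "INFO": r.imputation_r2,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return (len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2)


def _complement(a: str) -> str:
    return "".join(_COMPLEMENT[c] for c in a)


def harmonize_alleles(records, reference,
                      ambiguous_eaf_window=(0.4, 0.6)) -> HarmonizeResult:
    """Align effect alleles to a reference panel keyed by chrom:pos.

    Flipped variants get beta negated and eaf complemented; strand flips are
    resolved by base complement; palindromic (A/T, C/G) variants whose effect
    allele frequency lies inside ``ambiguous_eaf_window`` are dropped as
    strand-unresolvable. Irreconcilable allele pairs are dropped with a reason.
    """
    ref_by_pos = {(r.chrom, r.pos): r for r in reference}
    lo, hi = ambiguous_eaf_window
    out: list[SummaryStatRecord] = []
    dropped: list[tuple[str, str]] = []
    for rec in records:
        ref = ref_by_pos.get((rec.chrom, rec.pos))
        if ref is None:
            dropped.append((rec.variant_id, "not_in_reference"))
            continue
        if _is_palindromic(rec.effect_allele, rec.other_allele):
            if rec.eaf is not None and lo <= rec.eaf <= hi:
                dropped.append((rec.variant_id, "ambiguous_palindrome"))
                continue
        pair = (rec.effect_allele, rec.other_allele)
        target = (ref.effect_allele, ref.other_allele)
        if pair == target:
            out.append(rec)
        elif pair == target[::-1]:
            out.append(replace(rec, effect_allele=ref.effect_allele,
                               other_allele=ref.other_allele,
                               beta=-rec.beta,
                               eaf=None if rec.eaf is None else 1.0 - rec.eaf))
        else:
            try:
                comp = (_complement(pair[0]), _complement(pair[1]))
            except KeyError:
                comp = None
            if comp == target:
                out.append(replace(rec, effect_allele=ref.effect_allele,
                                   other_allele=ref.other_allele))
            elif comp == target[::-1]:
                out.append(replace(rec, effect_allele=ref.effect_allele,
                                   other_allele=ref.other_allele,
                                   beta=-rec.beta,
                                   eaf=None if rec.eaf is None else 1.0 - rec.eaf))
            else:
                dropped.append((rec.variant_id, "irreconcilable_alleles"))
    return HarmonizeResult(out, dropped)


def rescale_proxy_effects(records, descriptor: StudyDescriptor) -> list[SummaryStatRecord]:
    """Rescale by-proxy effect estimates to the direct case-control scale.

    beta and se are both multiplied by the descriptor's rescale factor (default
    2: one parent transmits half the genome), so z and p are unchanged. A
    second application is rejected via the per-record ``rescaled`` flag.
    """
    if descriptor.design != "proxy":
        raise ValueError("rescaling applies only to proxy-design studies")
    f = descriptor.proxy_rescale_factor
    out = []
    for rec in records:
        if rec.rescaled:
            raise ValueError(f"{rec.variant_id}: proxy effects already rescaled")
        out.append(replace(rec, beta=rec.beta * f, se=rec.se * f, rescaled=True))
    return out


def _hard_call(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to genotypes; intermediate dosages become missing (NaN)."""
    g = np.round(dosage)
    uncertain = np.abs(dosage - g) > 0.1
    g = np.where(uncertain, np.nan, g)
    return g


def variant_qc(dosages: pd.DataFrame, status,
               thresholds: QcThresholds | None = None,
               imputation_r2: dict[str, float] | None = None) -> QcReport:
    """Apply the variant-level QC rules to a dosage matrix.

    ``dosages`` has individuals as rows and variant IDs as columns, values in
    [0, 2] with NaN for missing. Rules (applied independently, so a variant
    can fail several): call rate, MAF, Hardy-Weinberg equilibrium in controls
    (on hard-called genotypes), differential missingness between cases and
    controls (two-sided Fisher exact test), and imputation quality when an
    INFO map is given.
    """
    thr = thresholds or QcThresholds()
    status = np.asarray(status)
    controls = status == 0
    cases = status == 1
    failures: dict[str, list[str]] = {
        "call_rate": [], "maf": [], "hwe": [], "diff_missing": [], "imputation": []}
    passed: list[str] = []

    for vid in dosages.columns:
        d = dosages[vid].to_numpy(dtype=float)
        missing = np.isnan(d)
        ok = True
        call_rate = 1.0 - missing.mean()
        if call_rate < thr.call_rate:
            failures["call_rate"].append(vid)
            ok = False

        obs = d[~missing]
        if obs.size:
            freq = obs.mean() / 2.0
            maf = min(freq, 1.0 - freq)
        else:
            maf = 0.0
        if maf <= thr.maf:
            failures["maf"].append(vid)
            ok = False

        g = _hard_call(d[controls & ~missing])
        g = g[~np.isnan(g)]
        if g.size:
            counts = [int((g == k).sum()) for k in (0, 1, 2)]
            # orient so the hom classes are (common, rare); test is symmetric
            p_hwe = statcore.hwe_exact_test(counts[0], counts[1], counts[2])
            if p_hwe < thr.hwe_p:
                failures["hwe"].append(vid)
                ok = False

        m_case, m_ctl = int(missing[cases].sum()), int(missing[controls].sum())
        n_case, n_ctl = int(cases.sum()), int(controls.sum())
        if n_case and n_ctl:
            table = [[m_case, n_case - m_case], [m_ctl, n_ctl - m_ctl]]
            p_dm = stats.fisher_exact(table, alternative="two-sided")[1]
            if p_dm < thr.diff_missing_p:
                failures["diff_missing"].append(vid)
                ok = False

        if imputation_r2 is not None and vid in imputation_r2:
            if imputation_r2[vid] < thr.imputation_r2:
                failures["imputation"].append(vid)
                ok = False

        if ok:
            passed.append(vid)

    failures = {k: v for k, v in failures.items() if v}
    return QcReport(n_input=dosages.shape[1], n_pass=len(passed),
                    passed=passed, failures=failures)
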