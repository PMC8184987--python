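"""Synthetic GWAS summary statistics and case-control cohorts.

The generator emulates the data structure the analysis pipeline consumes: a
large clinic-based case-control cohort with imputed dosages at the score
variants, APOE genotypes, ages, onset ages for cases, ancestry components
and neuropathology flags; and per-study summary statistics (direct
case-control and by-proxy designs) with true effects at configurable loci.

Disease status follows a logistic liability,

    logit P(case) = alpha + sum_i ln(OR_i) (g_i - 2 maf_i)
                  + ln(OR_APOE[group]) + ln(OR_perSD) * z,

where z is a standard-normal polygenic score independent of the simulated
variants, and alpha is solved so the expected case count matches the
configured cohort size. Case onset ages are drawn from truncated normals
whose medians interpolate, within each APOE group, between configured
extreme-PRS-bin medians. All output is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import prs as prs_mod
from .sumstats import StudyDescriptor, SummaryStatRecord

__all__ = [
    "VariantSpec",
    "LdBlock",
    "GeneratorConfig",
    "SimulatedCohort",
    "table1_variant_panel",
    "null_variant_panel",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_sumstats",
]


@dataclass(frozen=True)
class VariantSpec:
    """One simulated variant: identity, frequency and true disease effect.

    ``maf`` is the effect-allele frequency (it may exceed 0.5 when the effect
    allele is the major one); ``true_or`` is the odds ratio per effect-allele
    copy on the case-control scale.
    """

    variant_id: str
    chrom: str
    pos: int
    maf: float
    true_or: float = 1.0
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self):
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"{self.variant_id}: maf must lie in (0, 1)")
        if self.true_or <= 0:
            raise ValueError(f"{self.variant_id}: odds ratio must be positive")


@dataclass(frozen=True)
class LdBlock:
    """A block of correlated variants: each member has allele-level correlation
    sqrt(r2) with the block's first (tag) variant."""

    size: int
    r2: float
    maf: float = 0.3
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing_bp: int = 10_000

    def __post_init__(self):
        if self.size < 2 or not 0.0 <= self.r2 <= 1.0 or not 0 < self.maf < 1:
            raise ValueError("invalid LD block specification")


# Pooled-group default parameters. APOE odds ratios vs e3e3 are
# order-of-magnitude literature-style placeholders (editable configuration);
# the AAO medians for the extreme PRS bins are the study-condition defaults.
DEFAULT_APOE_FREQS = {
    "e2e2": 0.0050, "e2e3": 0.0756, "e3e3": 0.6146,
    "e2e4": 0.0200, "e3e4": 0.2540, "e4e4": 0.0308,
}
DEFAULT_APOE_ORS = {
    "e2e2/e2e3": 0.6, "e3e3": 1.0, "e2e4/e3e4": 3.0, "e4e4": 12.0,
}
DEFAULT_AAO_MEDIANS = {
    "e2e2/e2e3": (82.0, 83.0),
    "e3e3": (82.0, 81.0),
    "e2e4/e3e4": (81.0, 77.0),
    "e4e4": (78.5, 73.0),
}
DEFAULT_APOE_BINS = {"e2e2/e2e3": 7, "e3e3": 25, "e2e4/e3e4": 15, "e4e4": 3}

_POOL = {"e2e2": "e2e2/e2e3", "e2e3": "e2e2/e2e3", "e3e3": "e3e3",
         "e2e4": "e2e4/e3e4", "e3e4": "e2e4/e3e4", "e4e4": "e4e4"}
_E4_DOSE = {"e2e2": 0, "e2e3": 0, "e3e3": 0, "e2e4": 1, "e3e4": 1, "e4e4": 2}
_E2_DOSE = {"e2e2": 2, "e2e3": 1, "e3e3": 0, "e2e4": 1, "e3e4": 0, "e4e4": 0}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort and summary statistics.

    Defaults emulate the discovery cohort: 6331 cases, 6055 controls of whom
    3546 are aged 55 or younger, APOE pooled-group sizes ~998/7611/3399/382,
    a per-SD polygenic odds ratio of 1.27, and extreme-bin onset-age medians
    per APOE group as configured in DEFAULT_AAO_MEDIANS.
    """

    seed: int
    n_cases: int = 6331
    n_controls: int = 6055
    n_young_controls: int = 3546
    variant_spec: list[VariantSpec] = field(default_factory=list)
    apoe_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_APOE_FREQS))
    apoe_ors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_APOE_ORS))
    prs_per_sd_or: float = 1.27
    aao_medians: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AAO_MEDIANS))
    aao_sd: float = 8.0
    aao_range: tuple[float, float] = (40.0, 105.0)
    apoe_bins: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_APOE_BINS))
    pathology_rates: tuple[float, float] = (0.84, 0.488)
    female_fraction: float = 0.6
    control_age_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (40.0, 55.0), (56.0, 90.0))
    ld_blocks: list[LdBlock] = field(default_factory=list)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        total = sum(self.apoe_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"APOE genotype probabilities sum to {total}, not 1")
        if any(v <= 0 for v in self.apoe_ors.values()) or self.prs_per_sd_or <= 0:
            raise ValueError("all odds ratios must be positive")
        if not 0 <= self.n_young_controls <= self.n_controls:
            raise ValueError("n_young_controls must not exceed n_controls")
        any_rate, multi_rate = self.pathology_rates
        if not (0 <= multi_rate <= any_rate <= 1):
            raise ValueError("pathology rates must satisfy 0 <= multiple <= any <= 1")

    @classmethod
    def default(cls, seed: int, **overrides) -> "GeneratorConfig":
        """The canonical study-scale configuration: the Table-1-like locus
        panel plus the packaged 39-variant score panel (weights as true
        log-odds effects)."""
        spec = table1_variant_panel() + score_variant_panel()
        return cls(seed=seed, variant_spec=spec, **overrides)

    @classmethod
    def prs_validation(cls, seed: int, n_cases: int = 6331,
                       n_controls: int = 6055, n_young_controls: int | None = None,
                       per_sd_or: float = 1.27) -> "GeneratorConfig":
        """Effect-isolated configuration for per-SD recovery studies.

        The polygenic term is the only liability component (no variant panel,
        all APOE odds ratios 1) so the marginal logistic coefficient equals
        the generative per-SD log-odds exactly -- with other liability terms
        present the marginal estimate is attenuated (non-collapsibility) and
        would not recover the generative value.
        """
        if n_young_controls is None:
            n_young_controls = (3546 if n_controls == 6055
                                else round(n_controls * 3546 / 6055))
        return cls(seed=seed, n_cases=n_cases, n_controls=n_controls,
                   n_young_controls=n_young_controls, variant_spec=[],
                   apoe_ors={g: 1.0 for g in DEFAULT_APOE_ORS},
                   prs_per_sd_or=per_sd_or)

    @classmethod
    def aao_recovery(cls, seed: int, n_cases: int = 90_000,
                     n_controls: int = 20_000) -> "GeneratorConfig":
        """Configuration for onset-age stratification recovery.

        APOE genotype frequencies are enriched toward the extreme groups so
        each extreme (group, bin) stratum holds thousands of cases, and the
        polygenic score drives only the onset-age strata (not case status),
        so the anchoring controls are representative of the population score
        distribution and bin boundaries are recovered without selection shift.
        """
        return cls(seed=seed, n_cases=n_cases, n_controls=n_controls,
                   n_young_controls=n_controls // 2, variant_spec=[],
                   apoe_freqs={"e2e2": 0.01, "e2e3": 0.44, "e3e3": 0.05,
                               "e2e4": 0.02, "e3e4": 0.08, "e4e4": 0.40},
                   apoe_ors={g: 1.0 for g in DEFAULT_APOE_ORS},
                   prs_per_sd_or=1.0)


@dataclass
class SimulatedCohort:
    pheno: pd.DataFrame
    dosages: pd.DataFrame
    config: GeneratorConfig
    alpha: float


def table1_variant_panel() -> list[VariantSpec]:
    """Variant panel from the packaged follow-up locus table: printed
    frequencies with the replicating loci's overall odds ratios as truth."""
    import importlib.resources

    ref = importlib.resources.files("adgwas.data") / "followup_loci.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    overall = {  # printed overall odds ratios of the replicating loci
        "rs876461": 1.07, "rs34674752": 1.13, "rs34173062": 1.14,
        "rs3935877": 0.92, "rs72835061": 1.09, "rs2154481": 0.95,
        "rs4351014": 0.94, "rs4985556": 1.08, "rs12444183": 0.95,
    }
    out = []
    for row in df.itertuples(index=False):
        if row.SNP not in overall:
            continue
        out.append(VariantSpec(row.SNP, str(row.CHR), int(row.BP),
                               maf=float(row.FRQ_A1),
                               true_or=overall[row.SNP],
                               effect_allele=row.A1, other_allele=row.A2))
    return out


def score_variant_panel() -> list[VariantSpec]:
    """The packaged synthetic 39-variant score panel, with each weight acting
    as the variant's true log-odds effect."""
    df = prs_mod.packaged_weight_table()
    return [VariantSpec(r.SNP, str(r.CHR), int(r.BP), maf=float(r.MAF),
                        true_or=math.exp(float(r.WEIGHT)),
                        effect_allele=r.A1, other_allele=r.A2)
            for r in df.itertuples(index=False)]


def null_variant_panel(m: int, maf: float = 0.3, chrom: str = "1",
                       spacing_bp: int = 1_000_000) -> list[VariantSpec]:
    """m independent null variants (true OR 1) for calibration checks."""
    return [VariantSpec(f"null{i:06d}", chrom, (i + 1) * spacing_bp, maf=maf)
            for i in range(m)]


def _block_variants(block: LdBlock, idx: int) -> list[VariantSpec]:
    return [VariantSpec(f"block{idx}_{j}", block.chrom,
                        block.start_pos + j * block.spacing_bp, maf=block.maf)
            for j in range(block.size)]


def simulate_genotypes(config: GeneratorConfig, n: int,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Dosage matrix (n individuals x variants) under Hardy-Weinberg sampling.

    Independent variants draw allele counts Binomial(2, maf). Within an LD
    block, each member haplotype copies the tag haplotype's allele with
    probability r = sqrt(r2) and redraws Bernoulli(maf) otherwise, which
    yields allele-level correlation exactly r with the tag while preserving
    the marginal frequency.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cols: dict[str, np.ndarray] = {}
    for v in config.variant_spec:
        cols[v.variant_id] = rng.binomial(2, v.maf, size=n).astype(float)
    for bi, block in enumerate(config.ld_blocks):
        r = math.sqrt(block.r2)
        tag_h = rng.random((n, 2)) < block.maf  # two haplotypes per person
        members = _block_variants(block, bi)
        cols[members[0].variant_id] = tag_h.sum(axis=1).astype(float)
        for member in members[1:]:
            copy = rng.random((n, 2)) < r
            fresh = rng.random((n, 2)) < block.maf
            h = np.where(copy, tag_h, fresh)
            cols[member.variant_id] = h.sum(axis=1).astype(float)
    return pd.DataFrame(cols)


def _interp_median(medians: tuple[float, float], bin_idx: np.ndarray,
                   k: int) -> np.ndarray:
    """Linear interpolation of the stratum median in the bin index."""
    low, high = medians
    if k == 1:
        return np.full(bin_idx.shape, (low + high) / 2.0)
    frac = (bin_idx - 1) / (k - 1)
    return low + frac * (high - low)


def _truncnorm_draw(rng, loc, scale, lo, hi):
    a = (lo - loc) / scale
    b = (hi - loc) / scale
    u = rng.random(np.shape(loc))
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def simulate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Simulate a full cohort table and its dosage matrix.

    See the module docstring for the liability model. Control examination
    ages are a two-part mixture placing the configured fraction at or below
    55; case onset ages are stratum-median truncated normals with the
    stratum defined by the APOE pooled group and the population-quantile PRS
    bin of the polygenic score.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    target = config.n_cases / n

    dosages = simulate_genotypes(config, n, rng)

    labels = np.array(list(config.apoe_freqs))
    probs = np.array([config.apoe_freqs[g] for g in labels], dtype=float)
    probs = probs / probs.sum()
    apoe = rng.choice(labels, size=n, p=probs)
    pooled = np.array([_POOL[g] for g in apoe])

    poly_z = rng.standard_normal(n)
    pcs = rng.standard_normal((n, 4))
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female

    eta = np.zeros(n)
    for v in config.variant_spec:
        if v.true_or != 1.0:
            g = dosages[v.variant_id].to_numpy()
            eta += math.log(v.true_or) * (g - 2.0 * v.maf)
    apoe_lor = np.array([math.log(config.apoe_ors[g]) for g in pooled])
    eta += apoe_lor + math.log(config.prs_per_sd_or) * poly_z

    if not 0.0 < target < 1.0:
        raise ValueError("cannot solve intercept: case fraction must lie in (0, 1)")

    def expected_rate(alpha):
        return float(np.mean(special.expit(alpha + eta))) - target

    try:
        alpha = optimize.brentq(expected_rate, -40.0, 40.0, xtol=1e-10)
    except ValueError as exc:
        raise ValueError("cannot solve intercept for the requested case count") from exc
    status = (rng.random(n) < special.expit(alpha + eta)).astype(int)

    # ages: controls are a young/old mixture; case age is the onset age
    age = np.full(n, np.nan)
    ctl = status == 0
    n_ctl = int(ctl.sum())
    frac_young = (config.n_young_controls / config.n_controls
                  if config.n_controls else 0.0)
    young = rng.random(n_ctl) < frac_young
    (y_lo, y_hi), (o_lo, o_hi) = config.control_age_ranges
    ages_ctl = np.where(young,
                        rng.uniform(y_lo, y_hi, n_ctl),
                        rng.uniform(o_lo, o_hi, n_ctl))
    age[ctl] = ages_ctl

    aao = np.full(n, np.nan)
    cases = status == 1
    u = stats.norm.cdf(poly_z)  # population quantile of the polygenic score
    lo, hi = config.aao_range
    for group, k in config.apoe_bins.items():
        m = cases & (pooled == group)
        if not m.any():
            continue
        bin_idx = np.minimum(k, np.floor(u[m] * k).astype(int) + 1)
        med = _interp_median(config.aao_medians[group], bin_idx, k)
        aao[m] = _truncnorm_draw(rng, med, config.aao_sd, lo, hi)
    age[cases] = aao[cases]

    any_rate, multi_rate = config.pathology_rates
    path_any = np.where(cases, rng.random(n) < any_rate, False)
    cond = multi_rate / any_rate if any_rate > 0 else 0.0
    path_multi = path_any & (rng.random(n) < cond)

    pheno = pd.DataFrame({
        "IID": [f"id{i:06d}" for i in range(n)],
        "STATUS": status,
        "SEX": sex,
        "AGE": age,
        "AAO": aao,
        "PC1": pcs[:, 0], "PC2": pcs[:, 1], "PC3": pcs[:, 2], "PC4": pcs[:, 3],
        "APOE": apoe,
        "APOE_GROUP": pooled,
        "APOE_RS429358_DS": np.array([_E4_DOSE[g] for g in apoe], dtype=float),
        "APOE_RS7412_DS": np.array([_E2_DOSE[g] for g in apoe], dtype=float),
        "POLY_SCORE": poly_z,
        "PATH_ANY": path_any.astype(int),
        "PATH_MULTI": path_multi.astype(int),
    })
    dosages.index = pheno["IID"]
    return SimulatedCohort(pheno, dosages, config, float(alpha))


def simulate_sumstats(config: GeneratorConfig, study: StudyDescriptor,
                      rng: np.random.Generator | None = None) -> list[SummaryStatRecord]:
    """Per-study summary statistics with sampling noise.

    The estimate for each variant is beta_hat ~ Normal(ln OR_true, se) with
    se = (2 maf (1-maf) n_eff)^(-1/2), n_eff = 4 / (1/n_cases + 1/n_controls).
    Proxy-design studies report beta_hat/2 and se/2 (the attenuated
    parental-history scale), so that rescaling by 2 restores the case-control
    scale with z unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if study.n_cases <= 0 or study.n_controls <= 0:
        raise ValueError("study sample sizes must be positive")
    n_eff = 4.0 / (1.0 / study.n_cases + 1.0 / study.n_controls)
    half = 0.5 if study.design == "proxy" else 1.0
    out = []
    for v in config.variant_spec:
        se = (2.0 * v.maf * (1.0 - v.maf) * n_eff) ** -0.5
        beta_hat = rng.normal(math.log(v.true_or), se)
        z = beta_hat / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(SummaryStatRecord(
            chrom=v.chrom, pos=v.pos, variant_id=v.variant_id,
            effect_allele=v.effect_allele, other_allele=v.other_allele,
            eaf=v.maf, beta=beta_hat * half, se=se * half, p=max(p, 5e-324),
            n_effective=n_eff))
    return out
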