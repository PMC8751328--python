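"""Synthetic case-cohort data with the structure the analysis assumes.

The generator emulates a prospective cohort with a randomly sampled
subcohort and long follow-up: genotypes under Hardy-Weinberg equilibrium
with block LD (latent-Gaussian threshold model), sex-specific exposure
distributions, exponential event times under exact proportional hazards,
administrative censoring, multinomial tumor subsites among cases, and
completely-at-random genotyping missingness with a sub-95%-call-rate
sample stratum.

Defaults mirror the study design this package targets, scaled to desk
size: a cohort of 20,000 aged 55-69 at baseline, a random subcohort of
3,000, 20.3 years of follow-up, and a 24-SNP panel in 10 pathway genes
grouped into per-gene LD blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ACTIVITY_LEVELS,
    ALCOHOL_LEVELS,
    ENERGY_RESTRICTION_LEVELS,
    MISSING,
    SMOKING_LEVELS,
    SUBSITES,
    GenotypeMatrix,
    validate_cohort,
)


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    gene: str
    maf: float
    block_id: int

    def __post_init__(self):
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")


@dataclass(frozen=True)
class ContinuousExposure:
    name: str
    mean: dict  # per sex
    sd: dict
    log_hr_per_unit: float = 0.0


@dataclass(frozen=True)
class CategoricalExposure:
    name: str
    levels: tuple
    probs: dict        # per sex, tuple of level probabilities
    log_hrs: tuple = ()  # per level, reference first (0.0)

    def __post_init__(self):
        for sex, p in self.probs.items():
            if len(p) != len(self.levels) or abs(sum(p) - 1) > 1e-9:
                raise ValueError(f"{self.name}: probs for {sex} must sum to 1")
        if self.log_hrs and len(self.log_hrs) != len(self.levels):
            raise ValueError(f"{self.name}: log_hrs length mismatch")


def default_snp_panel() -> list[SnpSpec]:
    """24 common SNPs in 10 mTOR-PI3K-Akt pathway genes, one LD block per gene."""
    panel = [
        ("rs2295080", "MTOR", 0.28), ("rs1057079", "MTOR", 0.30),
        ("rs2516739", "TSC2", 0.35), ("rs1800720", "TSC2", 0.22),
        ("rs2074969", "TSC2", 0.41), ("rs9928737", "TSC2", 0.16),
        ("rs12918803", "TSC2", 0.12), ("rs6723872", "PDK1", 0.19),
        ("rs6605631", "EIF4EBP1", 0.44), ("rs12787021", "RPS6KB2", 0.33),
        ("rs3006939", "AKT3", 0.26), ("rs14403", "AKT3", 0.38),
        ("rs7523198", "AKT3", 0.21), ("rs7523742", "AKT3", 0.29),
        ("rs1352162", "AKT3", 0.34), ("rs946824", "AKT3", 0.27),
        ("rs874269", "AKT2", 0.24), ("rs16974157", "AKT2", 0.09),
        ("rs7250897", "AKT2", 0.31), ("rs7503807", "RPTOR", 0.40),
        ("rs2043112", "RICTOR", 0.45), ("rs1051424", "RPS6KB1", 0.23),
        ("rs2871865", "IGF1R", 0.15), ("rs891088", "INSR", 0.25),
    ]
    genes = {}
    out = []
    for snp, gene, maf in panel:
        block = genes.setdefault(gene, len(genes))
        out.append(SnpSpec(snp, gene, maf, block))
    return out


def default_exposures() -> list:
    """Sex-specific exposure/confounder families at cohort-typical values."""
    return [
        ContinuousExposure("bmi", {"male": 25.0, "female": 25.1},
                           {"male": 2.6, "female": 3.6}),
        ContinuousExposure("height_cm", {"male": 176.6, "female": 165.8},
                           {"male": 6.6, "female": 6.2}),
        ContinuousExposure("bmi_age20", {"male": 21.7, "female": 21.4},
                           {"male": 2.2, "female": 2.5}),
        ContinuousExposure("trouser_skirt_size", {"male": 52.0, "female": 42.0},
                           {"male": 2.5, "female": 3.0}),
        CategoricalExposure("activity", ACTIVITY_LEVELS,
                            {"male": (0.18, 0.31, 0.51),
                             "female": (0.26, 0.32, 0.42)}),
        CategoricalExposure("energy_restriction", ENERGY_RESTRICTION_LEVELS,
                            {"male": (0.24, 0.15, 0.61),
                             "female": (0.28, 0.16, 0.56)}),
        CategoricalExposure("family_history", (0, 1),
                            {"male": (0.945, 0.055), "female": (0.945, 0.055)}),
        CategoricalExposure("smoking", SMOKING_LEVELS,
                            {"male": (0.12, 0.52, 0.36),
                             "female": (0.59, 0.20, 0.21)}),
        CategoricalExposure("alcohol", ALCOHOL_LEVELS,
                            {"male": (0.14, 0.71, 0.15),
                             "female": (0.32, 0.645, 0.035)}),
        ContinuousExposure("meat_gd", {"male": 104.7, "female": 92.5},
                           {"male": 43.4, "female": 41.8}),
        ContinuousExposure("processed_meat_gd", {"male": 16.6, "female": 10.7},
                           {"male": 17.5, "female": 12.4}),
        ContinuousExposure("energy_kcald", {"male": 2140.0, "female": 1658.0},
                           {"male": 505.0, "female": 411.0}),
    ]


#: case subsite mix: proximal/distal colon, rectosigmoid, rectum
DEFAULT_SUBSITE_PROBS = (0.360, 0.317, 0.095, 0.228)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; identical config + seed is byte-reproducible."""

    n_cohort: int = 20_000
    subcohort_size: int = 3_000
    sex_fraction_male: float = 0.5
    snp_spec: tuple = tuple(default_snp_panel())
    block_rho: float = 0.3
    true_log_hr_per_allele: tuple = ()  # per SNP; empty -> all zero
    exposure_spec: tuple = tuple(default_exposures())
    baseline_hazard: float = 0.0019     # per year; ~3.8% cumulative over 20.3 y
    admin_censor_time: float = 20.3
    subsite_probs: tuple = DEFAULT_SUBSITE_PROBS
    missing_rate_snp: float = 0.01
    sample_dropout_rate: float = 0.02
    dropout_missing_rate: float = 0.10  # per-SNP missing prob in dropout samples
    age_range: tuple = (55.0, 69.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_cohort < 1:
            raise ValueError("n_cohort must be positive")
        if not (1 <= self.subcohort_size <= self.n_cohort):
            raise ValueError("subcohort_size must be in [1, n_cohort]")
        if not (0 <= self.sex_fraction_male <= 1):
            raise ValueError("sex_fraction_male must be in [0, 1]")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must be in [0, 1)")
        for r in (self.missing_rate_snp, self.sample_dropout_rate,
                  self.dropout_missing_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be non-negative")
        if self.true_log_hr_per_allele and (
            len(self.true_log_hr_per_allele) != len(self.snp_spec)
        ):
            raise ValueError("true_log_hr_per_allele must match snp_spec length")
        if abs(sum(self.subsite_probs) - 1) > 1e-9 or len(self.subsite_probs) != 4:
            raise ValueError("subsite_probs must be 4 probabilities summing to 1")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


_ALLELES = ("A", "C", "G", "T")


def simulate_genotypes(
    n: int, snp_spec, block_rho: float, seed_or_rng
) -> GenotypeMatrix:
    """HWE genotypes with exchangeable within-block LD.

    Each LD block draws two latent multivariate-Gaussian haplotype vectors
    with exchangeable correlation ``block_rho`` (one-factor construction);
    each coordinate is thresholded at the Phi^-1(maf) quantile to give a
    minor-allele indicator, and the two haplotypes are summed to a 0/1/2
    genotype.  Across blocks the latent draws are independent, so r^2
    decays to 0; within a block r^2 increases monotonically with
    ``block_rho``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    snp_spec = list(snp_spec)
    m = len(snp_spec)
    geno = np.empty((n, m), dtype=np.int8)
    blocks: dict[int, list[int]] = {}
    for j, s in enumerate(snp_spec):
        if not (0 < s.maf <= 0.5):
            raise ValueError(f"maf outside (0, 0.5] for {s.snp_id}")
        blocks.setdefault(s.block_id, []).append(j)
    sq_rho = np.sqrt(block_rho)
    sq_res = np.sqrt(1 - block_rho)
    for cols in blocks.values():
        thresh = stats.norm.ppf([snp_spec[j].maf for j in cols])
        g = np.zeros((n, len(cols)), dtype=np.int8)
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            latent = sq_rho * shared + sq_res * rng.standard_normal((n, len(cols)))
            g += (latent < thresh).astype(np.int8)
        geno[:, cols] = g
    alleles = [rng.choice(4, size=2, replace=False) for _ in range(m)]
    meta = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snp_spec],
            "gene": [s.gene for s in snp_spec],
            "major_allele": [_ALLELES[a[0]] for a in alleles],
            "minor_allele": [_ALLELES[a[1]] for a in alleles],
        }
    )
    ids = np.array([f"P{i:07d}" for i in range(n)])
    return GenotypeMatrix(geno, ids, meta)


def _draw_exposures(rng, sexes: np.ndarray, exposure_spec) -> pd.DataFrame:
    n = len(sexes)
    cols = {}
    lp = np.zeros(n)
    for spec in exposure_spec:
        if isinstance(spec, ContinuousExposure):
            x = np.empty(n)
            for sex in ("male", "female"):
                mask = sexes == sex
                x[mask] = rng.normal(spec.mean[sex], spec.sd[sex], mask.sum())
            cols[spec.name] = x
            lp += spec.log_hr_per_unit * x
        else:
            idx = np.empty(n, dtype=int)
            for sex in ("male", "female"):
                mask = sexes == sex
                idx[mask] = rng.choice(
                    len(spec.levels), size=mask.sum(), p=spec.probs[sex]
                )
            cols[spec.name] = np.asarray(spec.levels, dtype=object)[idx]
            if spec.log_hrs:
                lp += np.asarray(spec.log_hrs)[idx]
    df = pd.DataFrame(cols)
    df.attrs["linear_predictor"] = lp
    return df


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Full cohort + genotypes under exact proportional hazards.

    Event times are exponential with rate
    ``baseline_hazard * exp(sum_j beta_j g_j + exposure terms)``,
    administratively censored at ``admin_censor_time``; subsites are
    multinomial among cases.  ``subcohort`` is all-zero here — use
    :func:`draw_case_cohort` to sample the subcohort and restrict to
    analysis rows.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cohort
    geno = simulate_genotypes(n, config.snp_spec, config.block_rho, rng)
    sexes = np.where(
        rng.random(n) < config.sex_fraction_male, "male", "female"
    ).astype(object)
    age = rng.uniform(*config.age_range, size=n)
    expo = _draw_exposures(rng, sexes, config.exposure_spec)
    lp = expo.attrs["linear_predictor"].copy()
    if config.true_log_hr_per_allele:
        betas = np.asarray(config.true_log_hr_per_allele, dtype=float)
        lp += geno.values.astype(float) @ betas
    rate = config.baseline_hazard * np.exp(lp)
    with np.errstate(divide="ignore"):
        raw_t = np.where(rate > 0, rng.exponential(1.0, n) / np.maximum(rate, 1e-300),
                         np.inf)
    event = (raw_t <= config.admin_censor_time).astype(int)
    time = np.minimum(raw_t, config.admin_censor_time)
    # strictly positive follow-up even in the rate -> inf corner
    time = np.maximum(time, 1e-9)
    subsite = np.full(n, "none", dtype=object)
    n_cases = int(event.sum())
    if n_cases:
        subsite[event == 1] = rng.choice(
            SUBSITES, size=n_cases, p=config.subsite_probs
        )
    df = pd.DataFrame(
        {
            "id": geno.sample_ids,
            "sex": sexes,
            "age_years": age,
            "time_years": time,
            "event": event,
            "subsite": subsite,
            "subcohort": 0,
        }
    )
    df = pd.concat([df, expo], axis=1)
    return df, geno


def draw_case_cohort(
    cohort: pd.DataFrame, subcohort_size: int, seed_or_rng
) -> pd.DataFrame:
    """Random subcohort (independent of everything) union all cases.

    Mirrors the case-cohort design: the subcohort is a simple random
    sample of the full cohort drawn "at baseline", cases outside it are
    appended, and ``subcohort`` flags membership.
    """
    if subcohort_size > len(cohort):
        raise ValueError("subcohort_size exceeds cohort size")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    picked = rng.choice(len(cohort), size=subcohort_size, replace=False)
    flags = np.zeros(len(cohort), dtype=int)
    flags[picked] = 1
    out = cohort.copy()
    out["subcohort"] = flags
    keep = (out["subcohort"] == 1) | (out["event"].astype(int) == 1)
    return out.loc[keep].reset_index(drop=True)


def inject_missingness(
    geno: GenotypeMatrix,
    missing_rate_snp,
    sample_dropout_rate: float,
    seed_or_rng,
    dropout_missing_rate: float = 0.10,
) -> GenotypeMatrix:
    """MCAR missingness: a per-SNP base rate plus a low-call-rate sample stratum.

    ``missing_rate_snp`` may be a scalar or a per-SNP vector.  A fraction
    ``sample_dropout_rate`` of samples additionally gets every genotype
    set missing with probability ``dropout_missing_rate``, producing
    samples below a 95% call-rate threshold.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    rates = np.broadcast_to(
        np.asarray(missing_rate_snp, dtype=float), (geno.n_snps,)
    )
    if ((rates < 0) | (rates > 1)).any() or not (0 <= sample_dropout_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    values = geno.values.copy()
    mask = rng.random(values.shape) < rates[None, :]
    dropouts = rng.random(geno.n_samples) < sample_dropout_rate
    if dropouts.any():
        extra = rng.random((int(dropouts.sum()), geno.n_snps)) < dropout_missing_rate
        mask[dropouts] |= extra
    values[mask] = MISSING
    return GenotypeMatrix(values, geno.sample_ids, geno.snp_meta)


def simulate_case_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """One-call convenience: cohort -> case-cohort rows -> QC-style missingness.

    Returns the analysis table (validated) and the genotype matrix
    restricted to the analysis rows.
    """
    rng = np.random.default_rng(config.seed + 1)
    cohort, geno = simulate_cohort(config)
    rows = draw_case_cohort(cohort, config.subcohort_size, rng)
    sub_geno = geno.subset(rows["id"].to_numpy())
    sub_geno = inject_missingness(
        sub_geno,
        config.missing_rate_snp,
        config.sample_dropout_rate,
        rng,
        config.dropout_missing_rate,
    )
    return validate_cohort(rows), sub_geno
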