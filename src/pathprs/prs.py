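"""Sex-specific split-half cross-weighted polygenic risk scores.

The construction, stage by stage:

1. split the analysis rows into random halves A and B (stratified by
   sex x case status so both halves support sex-specific Cox fits);
2. in each half and sex, fit an age-adjusted Cox model per SNP
   (genotype 0/1/2 continuous) giving beta, SE and weight = beta/SE;
3. keep only SNPs whose betas have the same sign in both halves; when
   the estimated weight is negative the coding is reversed (g -> 2-g:
   the major allele is the risk allele) and the absolute weight is used;
4. among kept SNPs, prune pairs in high LD (r^2 > 0.6) keeping one
   member of each pair at random;
5. score each half with the *other* half's weights (cross-weighting, so
   the score is never evaluated on the data that chose its weights):
   score = sum over SNPs of n_risk_alleles * |beta/SE|;
6. divide by the proportion of successfully genotyped score SNPs to
   adjust for missing genotypes;
7. standardize with sex-specific subcohort means/SDs per half, then
   merge the halves back into one dataset.

A deliberately-wrong same-half weighting mode exists as a negative
control for the overfitting the cross-weighting prevents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cox as coxmod
from .datatypes import MISSING, SEXES, GenotypeMatrix, PrsModel, SnpWeight, analysis_rows
from .qc import LD_R2_THRESHOLD, ld_matrix


def split_halves(df: pd.DataFrame, seed_or_rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random halves of ~equal size, stratified by sex x case status.

    Within every stratum the two halves differ by at most one row.  A
    stratum with fewer than 2 rows goes wholly to half A (with a warning
    attribute rather than a hard failure).
    """
    if len(df) == 0:
        raise ValueError("empty dataset")
    df = df.reset_index(drop=True)
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    half = np.zeros(len(df), dtype=int)
    strata = df.groupby(["sex", "event"], sort=True, observed=True).indices
    tiny = []
    for key in sorted(strata):
        idx = np.asarray(strata[key])
        if len(idx) < 2:
            tiny.append(key)
            continue
        perm = rng.permutation(idx)
        half[perm[: len(perm) // 2]] = 1  # half B gets the floor
    a = df.loc[half == 0].reset_index(drop=True)
    b = df.loc[half == 1].reset_index(drop=True)
    a.attrs["tiny_strata"] = tiny
    return a, b


def per_snp_cox_weights(
    half: pd.DataFrame,
    geno: GenotypeMatrix,
    sex: str,
    snp_id: str,
    half_label: str,
    policy: coxmod.RiskSetPolicy | None = None,
) -> SnpWeight | None:
    """Age-adjusted sex-specific Cox weight for one SNP in one half.

    Returns ``None`` when the SNP is monomorphic in the stratum or the
    fit does not converge (the SNP is then excluded from the score).
    """
    rows = half.loc[half["sex"] == sex, ["id", "age_years", "time_years", "event", "subcohort"]]
    g = pd.Series(
        geno.column(snp_id), index=geno.sample_ids, name="genotype"
    ).reindex(rows["id"])
    rows = rows.assign(genotype=g.to_numpy(dtype=float))
    rows.loc[rows["genotype"] == MISSING, "genotype"] = np.nan
    rows = rows.dropna(subset=["genotype"])
    if len(rows) == 0 or rows["event"].sum() < 1:
        return None
    try:
        fit = coxmod.fit_cox(rows, ["genotype", "age_years"], policy=policy)
    except (ValueError, coxmod.ConvergenceError):
        return None
    if not fit.converged:
        return None
    beta = float(fit.params[0])
    se = float(fit.se[0])
    if not np.isfinite(beta) or not np.isfinite(se) or se == 0:
        return None
    return SnpWeight(snp_id=snp_id, sex=sex, half=half_label, beta=beta, se=se)


def select_consistent_snps(
    weights_a: dict[str, SnpWeight],
    weights_b: dict[str, SnpWeight],
    ld: pd.DataFrame,
    seed_or_rng,
    r2_threshold: float = LD_R2_THRESHOLD,
) -> tuple[list[str], dict[str, str]]:
    """Direction-consistency and LD pruning.

    A SNP is kept iff its beta has the same strict sign in both halves
    (an exactly-zero beta counts as inconsistent).  Among kept SNPs,
    pairs with r^2 above the threshold (strictly greater: r^2 <= 0.6 is
    "low LD" and both members stay) are resolved by removing one member
    chosen at random, processing pairs in descending r^2 order.

    Returns (kept snp ids in input order, {snp: reason} for drops).
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    dropped: dict[str, str] = {}
    kept = []
    for snp in weights_a:
        wa, wb = weights_a.get(snp), weights_b.get(snp)
        if wa is None or wb is None:
            dropped[snp] = "fit_failed_in_one_half"
            continue
        if wa.beta == 0 or wb.beta == 0 or np.sign(wa.beta) != np.sign(wb.beta):
            dropped[snp] = "direction_inconsistent"
            continue
        kept.append(snp)
    pairs = [
        (float(ld.loc[x, y]), x, y)
        for i, x in enumerate(kept)
        for y in kept[i + 1:]
        if float(ld.loc[x, y]) > r2_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(kept)
    for r2, x, y in pairs:
        if x in alive and y in alive:
            loser = (x, y)[rng.integers(2)]
            alive.discard(loser)
            dropped[loser] = f"ld_pruned_r2={r2:.4f}"
    return [s for s in kept if s in alive], dropped


def raw_score(
    genotype_row: np.ndarray | dict,
    weights: dict[str, SnpWeight],
    snp_order: list[str] | None = None,
) -> tuple[float, int]:
    """Weighted risk-allele count: sum of n_risk * |beta/SE|.

    ``n_risk`` is the genotype when unflipped and ``2 - genotype`` when
    the weight was negative (major allele risk-conferring).  Missing
    genotypes contribute nothing here; returns ``(score, n_genotyped)``
    so the missingness rescaling can follow.
    """
    if not weights:
        raise ValueError("empty weight set")
    if isinstance(genotype_row, dict):
        get = genotype_row.get
    else:
        order = snp_order or list(weights)
        lookup = dict(zip(order, np.asarray(genotype_row)))
        get = lookup.get
    score = 0.0
    n_geno = 0
    for snp, w in weights.items():
        g = get(snp, MISSING)
        if g is None or g == MISSING or (isinstance(g, float) and np.isnan(g)):
            continue
        n_risk = 2 - g if w.flipped else g
        score += n_risk * w.abs_weight
        n_geno += 1
    return score, n_geno


def rescale_for_missingness(raw: float, n_genotyped: int, n_score_snps: int) -> float:
    """Divide by the proportion of successfully genotyped score SNPs.

    ``raw / [(n genotyped alleles) / (2 * n score SNPs)]``; with zero
    genotyped SNPs the score is undefined (NaN) and the individual is
    dropped from score analyses.
    """
    if n_score_snps < 1:
        raise ValueError("score must contain at least one SNP")
    if n_genotyped == 0:
        return float("nan")
    return raw / (n_genotyped / n_score_snps)


def standardize(
    scores: pd.Series, subcohort_flags: pd.Series
) -> tuple[pd.Series, float, float]:
    """(x - mean) / SD with constants from the subcohort distribution.

    All individuals are transformed; the constants come only from
    subcohort members with a defined score.
    """
    sub = scores[(subcohort_flags.to_numpy() == 1) & scores.notna().to_numpy()]
    if len(sub) < 2:
        raise ValueError("need >= 2 subcohort members with scores to standardize")
    mean = float(sub.mean())
    sd = float(sub.std(ddof=1))
    if sd == 0:
        raise ValueError("zero subcohort score SD; cannot standardize")
    return (scores - mean) / sd, mean, sd


def _score_half(
    half: pd.DataFrame,
    geno: GenotypeMatrix,
    sex: str,
    weights: dict[str, SnpWeight],
    included: list[str],
) -> pd.DataFrame:
    """Raw + rescaled + standardized scores for one (half, sex) cell."""
    rows = half.loc[half["sex"] == sex]
    sub = geno.subset(rows["id"].to_numpy())
    use = {s: weights[s] for s in included}
    vals = np.array(
        [raw_score(dict(zip(sub.snp_ids, r)), use) for r in sub.values],
        dtype=float,
    )
    raw = pd.Series(vals[:, 0], index=rows.index)
    n_geno = vals[:, 1].astype(int)
    rescaled = pd.Series(
        [rescale_for_missingness(r, n, len(included)) for r, n in zip(raw, n_geno)],
        index=rows.index,
    )
    std, mean, sd = standardize(rescaled, rows["subcohort"])
    out = rows.copy()
    out["prs_raw"] = raw
    out["prs_rescaled"] = rescaled
    out["prs_std"] = std
    out.attrs["standardization"] = (mean, sd)
    return out


def build_prs(
    dataset: pd.DataFrame,
    geno: GenotypeMatrix,
    seed: int,
    r2_threshold: float = LD_R2_THRESHOLD,
    cross_weighting: bool = True,
    policy: coxmod.RiskSetPolicy | None = None,
    ld: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, PrsModel]:
    """Full score construction; returns (scored dataset, fitted model).

    ``cross_weighting=False`` is the overfitting negative control: each
    half is scored with its own weights.  The LD matrix is computed on
    all analysis individuals unless supplied.
    """
    dataset = analysis_rows(dataset)
    rng = np.random.default_rng(seed)
    half_a, half_b = split_halves(dataset, rng)
    if ld is None:
        ld = ld_matrix(geno)
    sexes = [s for s in SEXES if (dataset["sex"] == s).any()]
    weights: dict = {sex: {"A": {}, "B": {}} for sex in sexes}
    for half_label, half in (("A", half_a), ("B", half_b)):
        for sex in sexes:
            for snp in geno.snp_ids:
                w = per_snp_cox_weights(half, geno, sex, snp, half_label, policy)
                if w is not None:
                    weights[sex][half_label][snp] = w
    included: dict = {}
    dropped: dict = {}
    scored_parts = []
    standardization: dict = {}
    for sex in sexes:
        inc, drops = select_consistent_snps(
            weights[sex]["A"], weights[sex]["B"], ld, rng, r2_threshold
        )
        # record fit failures visible only from half B
        for snp in weights[sex]["B"]:
            if snp not in weights[sex]["A"] and snp not in drops:
                drops[snp] = "fit_failed_in_one_half"
        if not inc:
            raise ValueError(
                f"no SNPs survived selection for sex={sex!r}; "
                f"drop reasons: {drops}"
            )
        included[sex] = inc
        dropped[sex] = drops
        standardization[sex] = {}
        for half_label, half, other in (("A", half_a, "B"), ("B", half_b, "A")):
            src = other if cross_weighting else half_label
            part = _score_half(half, geno, sex, weights[sex][src], inc)
            standardization[sex][half_label] = part.attrs["standardization"]
            part = part.assign(prs_half=half_label)
            scored_parts.append(part)
    scored = pd.concat(scored_parts, ignore_index=True)
    model = PrsModel(
        included_snps=included,
        weights={
            sex: {h: {s: weights[sex][h][s] for s in included[sex]
                      if s in weights[sex][h]}
                  for h in ("A", "B")}
            for sex in sexes
        },
        standardization=standardization,
        dropped=dropped,
        seed=seed,
        r2_threshold=r2_threshold,
        cross_weighting=cross_weighting,
    )
    return scored, model
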