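"""Genotype quality control: call rates, allele frequencies, HWE, LD r^2.

Conventions follow the surrounding pipeline: genotype columns count minor
alleles (0/1/2, -1 missing); a sample passes QC at a call rate of 95% or
higher; Hardy-Weinberg equilibrium is checked with the exact conditional
test and used as a flag only (flagged SNPs are not excluded); pairwise LD
is the squared allelic correlation r^2 from EM-estimated haplotype
frequencies, with "low LD" defined as r^2 <= 0.6.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

SAMPLE_CALL_RATE_THRESHOLD = 0.95
HWE_ALPHA = 0.05
LD_R2_THRESHOLD = 0.6


# ---------------------------------------------------------------- call rates

def sample_call_rates(geno: GenotypeMatrix) -> pd.Series:
    """Fraction of non-missing genotypes per sample."""
    ok = (geno.values != MISSING).mean(axis=1)
    return pd.Series(ok, index=geno.sample_ids, name="call_rate")


def filter_samples(
    geno: GenotypeMatrix, threshold: float = SAMPLE_CALL_RATE_THRESHOLD
) -> tuple[GenotypeMatrix, pd.Series]:
    """Drop samples below the call-rate threshold; returns (kept, excluded ids)."""
    rates = sample_call_rates(geno)
    keep = rates >= threshold
    kept = GenotypeMatrix(
        geno.values[keep.to_numpy()], geno.sample_ids[keep.to_numpy()], geno.snp_meta
    )
    return kept, rates[~keep]


def snp_call_rates(geno: GenotypeMatrix) -> pd.Series:
    ok = (geno.values != MISSING).mean(axis=0)
    return pd.Series(ok, index=geno.snp_ids, name="call_rate")


# ---------------------------------------------------------- allele frequency

def genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    col = np.asarray(column)
    col = col[col != MISSING]
    return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


def allele_frequency(column: np.ndarray) -> tuple[float, bool]:
    """Minor-allele frequency and whether the orientation had to be swapped.

    ``swapped`` is True when the coded "minor" allele is actually the
    major one (frequency > 0.5); ties at exactly 0.5 keep the input
    labels.
    """
    n0, n1, n2 = genotype_counts(column)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all genotypes missing")
    f = (n1 + 2 * n2) / (2 * n)
    if f > 0.5:
        return 1 - f, True
    return f, False


# ---------------------------------------------------------------- HWE exact

def hwe_exact_test(column: np.ndarray) -> float:
    """Exact conditional HWE test (two-sided, by probability ordering).

    Conditions on the minor-allele count and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    Monomorphic columns return p = 1.0 by convention.
    """
    n0, n1, n2 = genotype_counts(column)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all genotypes missing")
    n_minor = n1 + 2 * n2
    if n_minor > n:  # orient so the rare allele is counted
        n_minor = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    hets = hets[(n_minor - hets) // 2 + hets <= n]
    from scipy.special import gammaln

    n_hom_min = (n_minor - hets) // 2
    n_hom_maj = n - hets - n_hom_min
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_hom_min + 1)
        - gammaln(n_hom_maj + 1)
        + hets * np.log(2)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n1][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ------------------------------------------------------------------- LD r^2

def _em_haplotype_freqs(table: np.ndarray, tol=1e-13, max_iter=50_000):
    """EM over the double-heterozygote phase ambiguity.

    ``table[i, j]`` counts individuals with i minor alleles at SNP 1 and
    j at SNP 2.  Returns haplotype frequencies (pAB, pAb, paB, pab) with
    "A"/"B" the minor alleles, and the attained log-likelihood.  Single
    deterministic start at linkage equilibrium.
    """
    n = table.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    # known haplotype counts (double het table[1,1] is ambiguous)
    i_idx, j_idx = np.meshgrid([0, 1, 2], [0, 1, 2], indexing="ij")
    pA = (i_idx * table).sum() / (2 * n)  # minor at SNP1
    pB = (j_idx * table).sum() / (2 * n)
    # haplotype contributions per genotype cell (phase-known part)
    cAB = (
        2 * table[2, 2] + table[2, 1] + table[1, 2]
    )
    cAb = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    caB = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    cab = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    dh = table[1, 1]
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    p = np.maximum(p, 1e-12)
    p /= p.sum()
    # EM converges linearly, so the stop is on parameter movement (the
    # log-likelihood flattens well before the haplotype frequencies settle)
    for _ in range(max_iter):
        denom = p[0] * p[3] + p[1] * p[2]
        frac = 0.5 if denom == 0 else p[0] * p[3] / denom
        counts = np.array(
            [cAB + dh * frac, cAb + dh * (1 - frac),
             caB + dh * (1 - frac), cab + dh * frac],
            dtype=float,
        )
        p_new = counts / (2 * n)
        moved = np.max(np.abs(p_new - p))
        p = p_new
        if moved < tol:
            break
    return p, _hap_loglik(table, p)


def _hap_loglik(table: np.ndarray, p: np.ndarray) -> float:
    pAB, pAb, paB, pab = np.maximum(p, 1e-300)
    # genotype-cell probabilities under random mating
    cell = np.empty((3, 3))
    cell[2, 2] = pAB**2
    cell[2, 1] = 2 * pAB * pAb
    cell[2, 0] = pAb**2
    cell[1, 2] = 2 * pAB * paB
    cell[1, 1] = 2 * (pAB * pab + pAb * paB)
    cell[1, 0] = 2 * pAb * pab
    cell[0, 2] = paB**2
    cell[0, 1] = 2 * paB * pab
    cell[0, 0] = pab**2
    with np.errstate(divide="ignore"):
        lc = np.log(np.maximum(cell, 1e-300))
    return float((table * lc).sum())


def ld_r2(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Pairwise LD r^2 = D^2 / (pA pa pB pb) from EM haplotype frequencies.

    Computed on pairwise-complete individuals.  Monomorphic input is
    undefined; callers treat it as 0 for pruning (see :func:`ld_matrix`).
    """
    ci = np.asarray(col_i)
    cj = np.asarray(col_j)
    ok = (ci != MISSING) & (cj != MISSING)
    ci, cj = ci[ok], cj[ok]
    if len(ci) < 2:
        raise ValueError("fewer than 2 pairwise-complete individuals")
    if ci.std() == 0 or cj.std() == 0:
        raise ValueError("monomorphic column; r^2 undefined")
    table = np.zeros((3, 3))
    np.add.at(table, (ci, cj), 1.0)
    p, _ = _em_haplotype_freqs(table)
    pA = p[0] + p[1]
    pB = p[0] + p[2]
    D = p[0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise ValueError("degenerate allele frequencies after EM")
    return float(min(1.0, D * D / denom))


def ld_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric SNP x SNP r^2 matrix; undefined pairs (monomorphic SNPs)
    are set to 0 and recorded in ``df.attrs['undefined_pairs']``."""
    ids = geno.snp_ids
    m = len(ids)
    out = np.eye(m)
    undefined = []
    for a in range(m):
        for b in range(a + 1, m):
            try:
                r2 = ld_r2(geno.values[:, a], geno.values[:, b])
            except ValueError:
                r2 = 0.0
                undefined.append((ids[a], ids[b]))
            out[a, b] = out[b, a] = r2
    df = pd.DataFrame(out, index=ids, columns=ids)
    df.attrs["undefined_pairs"] = undefined
    return df


# ------------------------------------------------------------------- report

def qc_report(
    geno: GenotypeMatrix,
    sample_threshold: float = SAMPLE_CALL_RATE_THRESHOLD,
    hwe_alpha: float = HWE_ALPHA,
) -> dict:
    """Per-sample and per-SNP QC summary (flags only; nothing is removed)."""
    samples = sample_call_rates(geno)
    snp_rows = []
    for j, snp in enumerate(geno.snp_ids):
        col = geno.values[:, j]
        try:
            maf, swapped = allele_frequency(col)
            hwe_p = hwe_exact_test(col)
        except ValueError:
            maf, swapped, hwe_p = np.nan, False, np.nan
        snp_rows.append(
            {
                "snp_id": snp,
                "call_rate": float((col != MISSING).mean()),
                "maf": maf,
                "orientation_swapped": swapped,
                "hwe_p": hwe_p,
                "hwe_flag": bool(hwe_p < hwe_alpha) if np.isfinite(hwe_p) else True,
            }
        )
    return {
        "samples": pd.DataFrame(
            {"call_rate": samples, "excluded": samples < sample_threshold}
        ),
        "snps": pd.DataFrame(snp_rows).set_index("snp_id"),
        "thresholds": {
            "sample_call_rate": sample_threshold,
            "hwe_alpha": hwe_alpha,
        },
    }
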