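"""Association tables: PRS-outcome, single-SNP, and stratified-exposure analyses.

Endpoints are cause-specific: colorectal cancer overall and its subsites
(colon = proximal + distal; rectosigmoid cases count as events only for
the overall endpoint).  For a narrower endpoint, cases of other subsites
are censored at their diagnosis time.  All hazard ratios come from the
case-cohort Cox machinery with cluster-robust confidence intervals.
Reported person-time is the subcohort person-time at risk (the
case-cohort estimate of cohort person-time) within the stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import ConvergenceError, RiskSetPolicy, fit_cox, wald_joint_test
from .datatypes import MISSING, SEXES, GenotypeMatrix

ENDPOINTS: dict[str, tuple[str, ...]] = {
    "CRC": ("proximal_colon", "distal_colon", "rectosigmoid", "rectum"),
    "colon": ("proximal_colon", "distal_colon"),
    "proximal_colon": ("proximal_colon",),
    "distal_colon": ("distal_colon",),
    "rectum": ("rectum",),
}

#: Table-3 style confounder sets: base adjustment plus exposure-specific extras
BASE_CONFOUNDERS = [
    ("age_years", "continuous", None),
    ("family_history", "categorical", 0),
    ("smoking", "categorical", "never"),
    ("alcohol", "categorical", "0"),
    ("meat_gd", "continuous", None),
    ("processed_meat_gd", "continuous", None),
    ("energy_kcald", "continuous", None),
]

EXPOSURE_EXTRA_CONFOUNDERS = {
    "bmi": [("activity", "categorical", "<=30")],
    "trouser_skirt_size": [("bmi", "continuous", None),
                           ("activity", "categorical", "<=30")],
    "bmi_age20": [("bmi", "continuous", None),
                  ("activity", "categorical", "<=30")],
    "activity": [("bmi", "continuous", None)],
    "height_cm": [("bmi", "continuous", None),
                  ("activity", "categorical", "<=30")],
    "energy_restriction": [("bmi", "continuous", None),
                           ("activity", "categorical", "<=30")],
}


@dataclass(frozen=True)
class Covariate:
    """Declarative covariate: continuous as-is, categorical dummy-coded."""

    name: str
    kind: str = "continuous"
    reference: object | None = None


def endpoint_outcome(df: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Cause-specific event recoding for one endpoint.

    Cases of subsites outside the endpoint become censored observations
    at their event time; their follow-up time is unchanged.
    """
    if endpoint not in ENDPOINTS:
        raise KeyError(f"unknown endpoint {endpoint!r}")
    included = ENDPOINTS[endpoint]
    out = df.copy()
    is_case = out["event"].astype(int) == 1
    out["event"] = (is_case & out["subsite"].isin(included)).astype(int)
    # non-subcohort cases of other subsites enter the Prentice risk set only
    # at a failure they no longer have: they contribute nothing and are dropped
    keep = (out["subcohort"].astype(int) == 1) | (out["event"] == 1)
    return out.loc[keep]


def build_design(df: pd.DataFrame, covariates: list[Covariate]) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix: continuous columns pass through, categoricals become
    indicator columns ``name=level`` for every non-reference level."""
    cols = {}
    names = []
    for cov in covariates:
        if cov.kind == "continuous":
            cols[cov.name] = pd.to_numeric(df[cov.name])
            names.append(cov.name)
        elif cov.kind == "categorical":
            levels = [l for l in pd.unique(df[cov.name].dropna())]
            ref = cov.reference
            if ref is None:
                ref = sorted(map(str, levels))[0]
            for level in levels:
                if str(level) == str(ref):
                    continue
                name = f"{cov.name}={level}"
                cols[name] = (df[cov.name].astype(str) == str(level)).astype(float)
                names.append(name)
        else:
            raise ValueError(f"unknown covariate kind {cov.kind!r}")
    X = pd.DataFrame(cols, index=df.index)
    return X, names


def sex_tertiles(
    scores: pd.Series, subcohort_flags: pd.Series, sexes: pd.Series
) -> pd.Series:
    """Tertile category (1/2/3) cut at sex-specific subcohort quantiles.

    Cuts are the subcohort 1/3 and 2/3 quantiles within each sex; every
    individual (cases included) is assigned by those cuts, boundary
    values falling to the lower tertile (upper-inclusive intervals).
    """
    out = pd.Series(np.zeros(len(scores), dtype=int), index=scores.index)
    for sex in pd.unique(sexes):
        m = (sexes == sex).to_numpy()
        sub = scores[m & (subcohort_flags.to_numpy() == 1)].dropna()
        if sub.nunique() < 3:
            raise ValueError(f"degenerate subcohort score distribution for {sex!r}")
        q1, q2 = np.quantile(sub, [1 / 3, 2 / 3])
        x = scores[m]
        out[m] = 1 + (x > q1).astype(int) + (x > q2).astype(int)
    out = out.where(scores.notna())  # undefined scores stay unassigned (NaN)
    return out.rename("prs_tertile")


def _stratum_pt_cases(rows: pd.DataFrame) -> tuple[float, int]:
    pt = float(rows.loc[rows["subcohort"] == 1, "time_years"].sum())
    return pt, int(rows["event"].sum())


def prs_association_table(
    scored: pd.DataFrame,
    endpoints: list[str] | None = None,
    policy: RiskSetPolicy | None = None,
) -> pd.DataFrame:
    """Per sex x endpoint: tertile contrasts and continuous per-SD HRs,
    age-adjusted, with robust CIs (Table-2 layout)."""
    endpoints = endpoints or list(ENDPOINTS)
    df = scored.dropna(subset=["prs_std"]).copy()
    if "prs_tertile" not in df.columns:
        df["prs_tertile"] = sex_tertiles(df["prs_std"], df["subcohort"], df["sex"])
    rows = []
    for sex in [s for s in SEXES if (df["sex"] == s).any()]:
        d_sex = df[df["sex"] == sex]
        for ep in endpoints:
            d = endpoint_outcome(d_sex, ep)
            if d["event"].sum() == 0:
                rows.append(dict(endpoint=ep, sex=sex, contrast="all",
                                 flagged="no_events"))
                continue
            # tertile model
            d["t2"] = (d["prs_tertile"] == 2).astype(float)
            d["t3"] = (d["prs_tertile"] == 3).astype(float)
            fit_t = fit_cox(d, ["t2", "t3", "age_years"], policy=policy)
            ci = fit_t.conf_int()
            p = fit_t.p_values()
            for j, (name, tert) in enumerate((("T2 vs T1", 2), ("T3 vs T1", 3))):
                pt, nc = _stratum_pt_cases(d[d["prs_tertile"] == tert])
                pt1, nc1 = _stratum_pt_cases(d[d["prs_tertile"] == 1])
                rows.append(dict(
                    endpoint=ep, sex=sex, contrast=name,
                    person_time=pt, person_time_ref=pt1,
                    n_cases=nc, n_cases_ref=nc1,
                    hr=float(fit_t.hr[j]), ci_low=float(ci[j, 0]),
                    ci_high=float(ci[j, 1]), p=float(p[j]), flagged="",
                ))
            fit_c = fit_cox(d, ["prs_std", "age_years"], policy=policy)
            cic = fit_c.conf_int()
            pt, nc = _stratum_pt_cases(d)
            rows.append(dict(
                endpoint=ep, sex=sex, contrast="continuous",
                person_time=pt, person_time_ref=np.nan,
                n_cases=nc, n_cases_ref=np.nan,
                hr=float(fit_c.hr[0]), ci_low=float(cic[0, 0]),
                ci_high=float(cic[0, 1]), p=float(fit_c.p_values()[0]), flagged="",
            ))
    return pd.DataFrame(rows)


def single_snp_associations(
    dataset: pd.DataFrame,
    geno: GenotypeMatrix,
    mode: str = "additive",
    endpoint: str = "CRC",
    policy: RiskSetPolicy | None = None,
) -> pd.DataFrame:
    """Age-adjusted per-SNP Cox models by sex.

    ``additive`` models the 0/1/2 count continuously; ``codominant``
    fits two indicators (het vs major-hom, minor-hom vs major-hom).
    Monomorphic SNPs and empty codominant classes are flagged, not fit.
    """
    if mode not in ("additive", "codominant"):
        raise ValueError(f"unknown inheritance mode {mode!r}")
    d0 = endpoint_outcome(dataset, endpoint)
    gene_of = dict(zip(geno.snp_ids, geno.snp_meta["gene"]))
    rows = []
    for sex in [s for s in SEXES if (dataset["sex"] == s).any()]:
        d_sex = d0[d0["sex"] == sex]
        for snp in geno.snp_ids:
            g = pd.Series(geno.column(snp), index=geno.sample_ids).reindex(
                d_sex["id"]
            ).to_numpy(dtype=float)
            d = d_sex.assign(genotype=np.where(g == MISSING, np.nan, g)).dropna(
                subset=["genotype"]
            )
            base = dict(snp=snp, gene=gene_of[snp], sex=sex, mode=mode)
            if d.empty or d["genotype"].std() == 0:
                rows.append({**base, "contrast": "all", "flagged": "monomorphic"})
                continue
            try:
                if mode == "additive":
                    fit = fit_cox(d, ["genotype", "age_years"], policy=policy)
                    ci = fit.conf_int()
                    rows.append({**base, "contrast": "per_allele",
                                 "beta": float(fit.params[0]),
                                 "hr": float(fit.hr[0]),
                                 "ci_low": float(ci[0, 0]),
                                 "ci_high": float(ci[0, 1]),
                                 "p": float(fit.p_values()[0]), "flagged": ""})
                else:
                    d = d.assign(het=(d["genotype"] == 1).astype(float),
                                 hom=(d["genotype"] == 2).astype(float))
                    missing_class = [c for c, col in (("het", "het"), ("hom", "hom"))
                                     if d[col].sum() == 0]
                    use = [c for c in ("het", "hom") if c not in missing_class]
                    fit = fit_cox(d, use + ["age_years"], policy=policy)
                    ci = fit.conf_int()
                    for j, c in enumerate(use):
                        rows.append({**base,
                                     "contrast": {"het": "het_vs_major",
                                                  "hom": "hom_vs_major"}[c],
                                     "beta": float(fit.params[j]),
                                     "hr": float(fit.hr[j]),
                                     "ci_low": float(ci[j, 0]),
                                     "ci_high": float(ci[j, 1]),
                                     "p": float(fit.p_values()[j]), "flagged": ""})
                    for c in missing_class:
                        rows.append({**base, "contrast": f"{c}_vs_major",
                                     "flagged": "empty_genotype_class"})
            except (ValueError, ConvergenceError) as exc:
                rows.append({**base, "contrast": "all", "flagged": str(exc)})
    return pd.DataFrame(rows)


def gene_based_fdr(
    pvals: pd.DataFrame,
    q: float = 0.20,
    raw_alpha: float = 0.05,
    pool: str = "gene",
) -> pd.DataFrame:
    """Gene-based Benjamini-Hochberg decisions with the dual p<0.05 rule.

    Within each pooling unit (default: all of a gene's SNP x sex tests),
    p-values are ranked ascending and compared with the BH step-up
    critical values ``q * rank / m``; a test is significant iff the BH
    step-up procedure rejects it AND its raw p is below ``raw_alpha``.

    ``pvals`` needs columns ``snp``, ``gene``, ``sex``, ``p``.
    """
    if ((pvals["p"] < 0) | (pvals["p"] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pvals.copy()
    out["bh_critical"] = np.nan
    out["bh_reject"] = False
    group_cols = {"gene": ["gene"], "gene_sex": ["gene", "sex"]}[pool]
    for _, idx in out.groupby(group_cols, sort=False).groups.items():
        p = out.loc[idx, "p"].to_numpy(dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        crit = q * (np.arange(1, m + 1)) / m
        passed = p[order] <= crit
        k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
        reject = np.zeros(m, dtype=bool)
        reject[order[:k]] = True  # step-up closure: all ranks <= k rejected
        out.loc[idx, "bh_critical"] = crit[np.argsort(order, kind="stable")]
        out.loc[idx, "bh_reject"] = reject
    out["significant"] = out["bh_reject"] & (out["p"] < raw_alpha)
    return out


def stratified_exposure_table(
    scored: pd.DataFrame,
    exposure: str,
    endpoint: str = "CRC",
    confounders: list[tuple] | None = None,
    policy: RiskSetPolicy | None = None,
    exposure_kind: str | None = None,
) -> pd.DataFrame:
    """Exposure-outcome HRs within PRS tertiles plus an interaction p.

    Per sex and per tertile stratum, fits the exposure (categorical:
    dummies vs its first/reference level; continuous: per-unit) with the
    endpoint- and exposure-specific confounder set.  The interaction p
    comes from a joint robust Wald test on all exposure x tertile
    product terms in one pooled model (tertile-coded PRS, matching the
    stratified presentation).  Rows with missing exposure/confounders
    are excluded complete-case; counts are recorded in ``attrs``.
    """
    if confounders is None:
        confounders = BASE_CONFOUNDERS + EXPOSURE_EXTRA_CONFOUNDERS.get(exposure, [])
    confounders = [c for c in confounders if c[0] != exposure]
    cov_objs = [Covariate(*c) for c in confounders]
    if exposure_kind is None:
        exposure_kind = (
            "categorical" if scored[exposure].dtype == object else "continuous"
        )
    df = scored.dropna(subset=["prs_std"]).copy()
    if "prs_tertile" not in df.columns:
        df["prs_tertile"] = sex_tertiles(df["prs_std"], df["subcohort"], df["sex"])
    df = endpoint_outcome(df, endpoint)
    needed = [exposure] + [c[0] for c in confounders]
    n_before = len(df)
    df = df.dropna(subset=needed)
    rows = []
    interaction = {}
    for sex in [s for s in SEXES if (df["sex"] == s).any()]:
        d_sex = df[df["sex"] == sex]
        if d_sex[exposure].astype(str).nunique() < 2:
            raise ValueError(f"exposure '{exposure}' is constant for sex={sex!r}")
        Xe, e_names = build_design(
            d_sex, [Covariate(exposure, exposure_kind)]
        )
        Xc, c_names = build_design(d_sex, cov_objs)
        d_full = pd.concat([d_sex.reset_index(drop=True),
                            Xe.reset_index(drop=True),
                            Xc.reset_index(drop=True)], axis=1)
        # continuous covariates pass through under their own name; keep one copy
        d_full = d_full.loc[:, ~d_full.columns.duplicated()]
        # per-stratum fits
        for tert in (1, 2, 3):
            d_t = d_full[d_full["prs_tertile"] == tert]
            pt_ref, nc_ref = np.nan, np.nan
            if exposure_kind == "categorical":
                ref_level = sorted(d_sex[exposure].astype(str).unique())[0]
                ref_rows = d_t[d_t[exposure].astype(str) == str(ref_level)]
                pt_ref, nc_ref = _stratum_pt_cases(ref_rows)
            usable = [n for n in e_names if d_t[n].std() > 0]
            flagged_terms = [n for n in e_names if n not in usable]
            try:
                fit = fit_cox(d_t, usable + c_names, policy=policy)
                ci = fit.conf_int()
                p = fit.p_values()
                for j, name in enumerate(usable):
                    cell = d_t[d_t[name] == 1] if exposure_kind == "categorical" else d_t
                    pt, nc = _stratum_pt_cases(cell)
                    rows.append(dict(endpoint=endpoint, sex=sex, tertile=tert,
                                     contrast=name, person_time=pt, n_cases=nc,
                                     person_time_ref=pt_ref, n_cases_ref=nc_ref,
                                     hr=float(fit.hr[j]), ci_low=float(ci[j, 0]),
                                     ci_high=float(ci[j, 1]), p=float(p[j]),
                                     flagged=""))
            except (ValueError, ConvergenceError) as exc:
                rows.append(dict(endpoint=endpoint, sex=sex, tertile=tert,
                                 contrast="all", flagged=str(exc)))
                flagged_terms = e_names
            for name in flagged_terms:
                rows.append(dict(endpoint=endpoint, sex=sex, tertile=tert,
                                 contrast=name, flagged="empty_cell"))
        # pooled interaction model
        d_full = d_full.assign(
            t2=(d_full["prs_tertile"] == 2).astype(float),
            t3=(d_full["prs_tertile"] == 3).astype(float),
        )
        prod_names = []
        for name in e_names:
            for t in ("t2", "t3"):
                pn = f"{name}:{t}"
                d_full[pn] = d_full[name] * d_full[t]
                prod_names.append(pn)
        usable_prod = [n for n in prod_names if d_full[n].std() > 0]
        reduced_df = len(prod_names) - len(usable_prod)
        try:
            fit = fit_cox(
                d_full,
                [n for n in e_names if d_full[n].std() > 0] + ["t2", "t3"]
                + usable_prod + c_names,
                policy=policy,
            )
            chi2, dfree, p_int = wald_joint_test(fit, usable_prod)
            interaction[sex] = dict(chi2=chi2, df=dfree, p=p_int,
                                    df_reduced_by=reduced_df)
        except (ValueError, ConvergenceError) as exc:
            interaction[sex] = dict(chi2=np.nan, df=0, p=np.nan, error=str(exc))
    table = pd.DataFrame(rows)
    table.attrs["interaction"] = interaction
    table.attrs["n_excluded_missing"] = n_before - len(df)
    table["interaction_p"] = table["sex"].map(
        {s: v.get("p", np.nan) for s, v in interaction.items()}
    )
    return table
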