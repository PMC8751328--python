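"""Core containers shared across the pipeline.

The cohort table is a plain :class:`pandas.DataFrame` (one participant per
row) validated by :func:`validate_cohort`; genotypes live in
:class:`GenotypeMatrix`, a thin wrapper over an ``int8`` count matrix with
``-1`` marking missing calls.  Genotype coding follows the usual
epidemiological convention: 0 = homozygote for the major allele,
1 = heterozygote, 2 = homozygote for the minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SEXES = ("male", "female")
SUBSITES = ("proximal_colon", "distal_colon", "rectosigmoid", "rectum")
NO_EVENT_SUBSITE = "none"

ACTIVITY_LEVELS = ("<=30", ">30-60", ">60")
ENERGY_RESTRICTION_LEVELS = ("non_western", "western_rural", "western_city")
SMOKING_LEVELS = ("never", "ex", "current")
ALCOHOL_LEVELS = ("0", "0.1-29", ">=30")

#: canonical phenotype column dictionary (name -> allowed levels or None for numeric)
PHENOTYPE_COLUMNS: dict[str, tuple | None] = {
    "id": None,
    "sex": SEXES,
    "age_years": None,
    "time_years": None,
    "event": (0, 1),
    "subsite": SUBSITES + (NO_EVENT_SUBSITE,),
    "subcohort": (0, 1),
    "bmi": None,
    "trouser_skirt_size": None,
    "bmi_age20": None,
    "activity": ACTIVITY_LEVELS,
    "height_cm": None,
    "energy_restriction": ENERGY_RESTRICTION_LEVELS,
    "family_history": (0, 1),
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "meat_gd": None,
    "processed_meat_gd": None,
    "energy_kcald": None,
}


class GenotypeMatrix:
    """Individuals x SNPs genotype counts with per-SNP metadata.

    Parameters
    ----------
    values
        ``(n_samples, n_snps)`` integer array with entries in ``{0, 1, 2}``
        or :data:`MISSING` (``-1``).
    sample_ids
        Participant identifiers, unique, aligned with the rows.
    snp_meta
        One row per SNP (aligned with columns) with columns
        ``snp_id``, ``gene``, ``major_allele``, ``minor_allele``.
    """

    def __init__(self, values: np.ndarray, sample_ids, snp_meta: pd.DataFrame):
        values = np.asarray(values, dtype=np.int8)
        if values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        bad = ~np.isin(values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype value {values[i, j]} at row {i}, column {j}"
            )
        sample_ids = np.asarray(sample_ids)
        if len(sample_ids) != values.shape[0]:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(np.unique(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        snp_meta = snp_meta.reset_index(drop=True)
        required = {"snp_id", "gene", "major_allele", "minor_allele"}
        if not required.issubset(snp_meta.columns):
            raise ValueError(f"snp_meta must have columns {sorted(required)}")
        if len(snp_meta) != values.shape[1]:
            raise ValueError("snp_meta rows do not match genotype columns")
        if snp_meta["snp_id"].duplicated().any():
            raise ValueError("duplicate snp ids")
        self.values = values
        self.sample_ids = sample_ids
        self.snp_meta = snp_meta
        self._row_index = pd.Index(sample_ids)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["snp_id"])

    def column(self, snp_id: str) -> np.ndarray:
        """Genotype column for one SNP (missing coded -1)."""
        j = self.snp_meta.index[self.snp_meta["snp_id"] == snp_id]
        if len(j) == 0:
            raise KeyError(snp_id)
        return self.values[:, j[0]]

    def subset(self, ids) -> "GenotypeMatrix":
        """Rows restricted (and reordered) to ``ids``."""
        locs = self._row_index.get_indexer(np.asarray(ids))
        if (locs < 0).any():
            missing = np.asarray(ids)[locs < 0][:3]
            raise KeyError(f"sample ids not in genotype matrix: {list(missing)}")
        return GenotypeMatrix(self.values[locs], np.asarray(ids), self.snp_meta)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(), self.sample_ids.copy(), self.snp_meta.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with NA for missing calls (used by the TSV writer)."""
        df = pd.DataFrame(
            self.values.astype(float), index=self.sample_ids, columns=self.snp_ids
        )
        return df.mask(df < 0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_snps} SNPs)"


@dataclass
class SnpWeight:
    """Per-SNP, per-sex, per-half weight from the age-adjusted Cox fit.

    ``weight`` is beta/SE; scoring uses ``abs(weight)`` with the coding
    reversed (g -> 2-g) when ``flipped`` (original beta negative, i.e. the
    major allele is the risk allele).
    """

    snp_id: str
    sex: str
    half: str
    beta: float
    se: float
    flipped: bool = field(init=False)

    def __post_init__(self):
        self.flipped = self.beta < 0

    @property
    def weight(self) -> float:
        return self.beta / self.se

    @property
    def abs_weight(self) -> float:
        return abs(self.weight)


@dataclass
class PrsModel:
    """Fitted polygenic-score definition: everything needed to re-score.

    Attributes
    ----------
    included_snps
        Per sex, the SNP set shared by both halves (identical by
        construction; only weights differ between halves).
    weights
        ``weights[sex][half][snp_id]`` -> :class:`SnpWeight`.
    standardization
        ``standardization[sex][half]`` -> (subcohort mean, subcohort SD)
        of the rescaled score among that half's subcohort members.
    dropped
        Per sex: SNPs removed with reasons (sign-inconsistent, LD-pruned,
        fit failure).
    seed
        Seed governing the split and LD-pruning randomness.
    """

    included_snps: dict
    weights: dict
    standardization: dict
    dropped: dict
    seed: int
    r2_threshold: float = 0.6
    cross_weighting: bool = True

    def summary(self) -> dict:
        """JSON-serializable provenance report."""
        out = {
            "seed": self.seed,
            "r2_threshold": self.r2_threshold,
            "cross_weighting": self.cross_weighting,
            "sexes": {},
        }
        for sex, snps in self.included_snps.items():
            out["sexes"][sex] = {
                "included_snps": list(snps),
                "dropped": self.dropped.get(sex, {}),
                "weights": {
                    half: {
                        s: {"beta": w.beta, "se": w.se, "weight": w.weight,
                            "flipped": bool(w.flipped)}
                        for s, w in ws.items()
                    }
                    for half, ws in self.weights[sex].items()
                },
                "standardization": {
                    half: {"mean": m, "sd": s}
                    for half, (m, s) in self.standardization[sex].items()
                },
            }
        return out


def validate_cohort(df: pd.DataFrame, require_all_columns: bool = False) -> pd.DataFrame:
    """Validate a cohort/phenotype table against the column dictionary.

    Checks id uniqueness, positive follow-up time, the event<->subsite
    consistency rule, and categorical levels.  Returns the (unmodified)
    frame for chaining.
    """
    needed = ["id", "sex", "age_years", "time_years", "event", "subsite", "subcohort"]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"cohort table missing required column '{col}'")
    if require_all_columns:
        for col in PHENOTYPE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"cohort table missing column '{col}'")
    if df["id"].duplicated().any():
        raise ValueError("duplicate participant ids")
    if (df["time_years"] <= 0).any():
        bad = df.loc[df["time_years"] <= 0, "id"].iloc[0]
        raise ValueError(f"non-positive follow-up time for participant {bad!r}")
    ev = df["event"].astype(int)
    has_site = df["subsite"].isin(SUBSITES)
    if ((ev == 1) & ~has_site).any():
        bad = df.loc[(ev == 1) & ~has_site, "id"].iloc[0]
        raise ValueError(f"event without tumor subsite for participant {bad!r}")
    if ((ev == 0) & has_site).any():
        bad = df.loc[(ev == 0) & has_site, "id"].iloc[0]
        raise ValueError(f"subsite recorded for non-case participant {bad!r}")
    for col, levels in PHENOTYPE_COLUMNS.items():
        if levels is None or col not in df.columns or col in ("event", "subcohort"):
            continue
        vals = df[col].dropna()
        bad = ~vals.astype(str).isin([str(v) for v in levels])
        if bad.any():
            raise ValueError(
                f"unknown level {vals[bad].iloc[0]!r} in column '{col}' "
                f"(allowed: {list(levels)})"
            )
    return df


def analysis_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Restrict to case-cohort analysis rows: subcohort members and cases.

    Raises if any row is neither (such rows carry no person-time in the
    case-cohort likelihood and indicate an upstream bookkeeping error).
    """
    keep = (df["subcohort"].astype(int) == 1) | (df["event"].astype(int) == 1)
    if not keep.all():
        n = int((~keep).sum())
        raise ValueError(
            f"{n} rows are neither subcohort members nor cases; "
            "case-cohort analysis input must contain only subcohort + cases"
        )
    return df
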