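"""File formats and the reproducible pipeline runner.

Interchange is plain text: genotypes as TSV (rows = participants,
columns = SNPs, NA = missing, with a small ``##meta`` header block for
alleles/genes), phenotypes as CSV following the column dictionary in
:mod:`pathprs.datatypes`, run configuration as YAML.  Every output table
carries a provenance header (# key: value lines) with the seed, the
threshold set, and a content hash of the inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import MISSING, GenotypeMatrix, validate_cohort

log = logging.getLogger("pathprs")

DEFAULT_THRESHOLDS = {
    "sample_call_rate": 0.95,
    "ld_r2": 0.6,
    "fdr_q": 0.20,
    "raw_significance": 0.05,
}


def content_hash(*paths_or_bytes) -> str:
    h = hashlib.sha256()
    for item in paths_or_bytes:
        if isinstance(item, (str, Path)) and Path(item).exists():
            h.update(Path(item).read_bytes())
        else:
            h.update(str(item).encode())
    return h.hexdigest()[:16]


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for _, row in geno.snp_meta.iterrows():
            fh.write(
                f"##meta\t{row.snp_id}\t{row.gene}\t{row.major_allele}\t{row.minor_allele}\n"
            )
        fh.write("id\t" + "\t".join(geno.snp_ids) + "\n")
        for sid, vals in zip(geno.sample_ids, geno.values):
            cells = ["NA" if v == MISSING else str(int(v)) for v in vals]
            fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    """Parse the genotype TSV; malformed cells raise with coordinates."""
    path = Path(path)
    meta_rows = []
    header = None
    data = []
    ids = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##meta"):
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{lineno}: malformed ##meta line")
                meta_rows.append(parts[1:])
                continue
            if header is None:
                header = line.split("\t")
                if header[0] != "id":
                    raise ValueError(f"{path}:{lineno}: first column must be 'id'")
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            ids.append(cells[0])
            row = np.empty(len(cells) - 1, dtype=np.int8)
            for j, c in enumerate(cells[1:], start=1):
                if c == "NA":
                    row[j - 1] = MISSING
                elif c in ("0", "1", "2"):
                    row[j - 1] = int(c)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid genotype {c!r} in row {len(ids)}, "
                        f"column {header[j]!r}"
                    )
            data.append(row)
    if header is None or not data:
        raise ValueError(f"{path}: no genotype data")
    snp_ids = header[1:]
    if meta_rows:
        meta = pd.DataFrame(
            meta_rows, columns=["snp_id", "gene", "major_allele", "minor_allele"]
        )
        meta = meta.set_index("snp_id").loc[snp_ids].reset_index()
    else:
        meta = pd.DataFrame(
            {"snp_id": snp_ids, "gene": "unknown",
             "major_allele": "A", "minor_allele": "B"}
        )
    return GenotypeMatrix(np.vstack(data), np.array(ids), meta)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return validate_cohort(df)


def provenance_header(seed, inputs_hash, thresholds=None, extra=None) -> str:
    lines = [
        "# pathprs output",
        f"# seed: {seed}",
        f"# inputs_hash: {inputs_hash}",
    ]
    for k, v in (thresholds or DEFAULT_THRESHOLDS).items():
        lines.append(f"# threshold {k}: {v}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, seed, inputs_hash, thresholds=None, extra=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, inputs_hash, thresholds, extra))
        df.to_csv(fh, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config: dict, out_dir) -> dict:
    """simulate (optional) -> QC -> PRS -> association tables.

    ``config`` keys: ``seed`` (required), ``geno``/``pheno`` paths (or
    ``simulate: {...}`` overrides for the generator), ``thresholds``
    overrides, ``endpoints``, ``exposures``.  Returns a manifest of the
    written artifacts; any stage failure raises with the stage name.
    """
    from . import associations, prs, qc, simulate

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    log.info("run_pipeline seed=%s out=%s", seed, out_dir)
    manifest = {"seed": seed, "outputs": []}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    if "geno" in config and "pheno" in config:
        geno = _stage("read_genotypes", lambda: read_genotypes(config["geno"]))
        pheno = _stage("read_phenotypes", lambda: read_phenotypes(config["pheno"]))
        ih = content_hash(config["geno"], config["pheno"])
    else:
        sim_kw = dict(config.get("simulate", {}))
        sim_cfg = simulate.SimulationConfig(seed=seed, **sim_kw)
        pheno, geno = _stage("simulate", lambda: simulate.simulate_case_cohort(sim_cfg))
        ih = content_hash(json.dumps(sim_kw, sort_keys=True), seed)
        write_genotypes(geno, out_dir / "genotypes.tsv")
        write_phenotypes(pheno, out_dir / "phenotypes.csv")
        manifest["outputs"] += ["genotypes.tsv", "phenotypes.csv"]

    # QC
    report = _stage("qc", lambda: qc.qc_report(geno, thresholds["sample_call_rate"]))
    excluded = report["samples"][report["samples"]["excluded"]]
    log.info("QC: %d samples below call-rate threshold", len(excluded))
    kept_geno, _ = qc.filter_samples(geno, thresholds["sample_call_rate"])
    kept_ids = set(kept_geno.sample_ids)
    pheno_kept = pheno[pheno["id"].astype(str).isin(map(str, kept_ids))].reset_index(
        drop=True
    )
    kept_geno = kept_geno.subset(pheno_kept["id"].to_numpy())
    write_table(report["snps"].reset_index(), out_dir / "qc_snps.csv", seed, ih, thresholds)
    write_table(
        report["samples"].reset_index(names="id"),
        out_dir / "qc_samples.csv", seed, ih, thresholds,
        extra={"n_excluded_samples": len(excluded)},
    )
    manifest["outputs"] += ["qc_snps.csv", "qc_samples.csv"]

    # PRS
    scored, model = _stage(
        "build_prs",
        lambda: prs.build_prs(pheno_kept, kept_geno, seed,
                              r2_threshold=thresholds["ld_r2"]),
    )
    write_table(
        scored[["id", "sex", "prs_half", "prs_raw", "prs_rescaled", "prs_std"]],
        out_dir / "scores.csv", seed, ih, thresholds,
    )
    (out_dir / "prs_model.json").write_text(json.dumps(model.summary(), indent=2))
    manifest["outputs"] += ["scores.csv", "prs_model.json"]

    # associations
    scored = scored.copy()
    scored["prs_tertile"] = associations.sex_tertiles(
        scored["prs_std"], scored["subcohort"], scored["sex"]
    )
    table2 = _stage(
        "associate",
        lambda: associations.prs_association_table(
            scored, config.get("endpoints")
        ),
    )
    write_table(table2, out_dir / "prs_associations.csv", seed, ih, thresholds)
    snp_tabs = []
    for mode in ("additive", "codominant"):
        snp_tabs.append(
            _stage("snp_assoc",
                   lambda m=mode: associations.single_snp_associations(
                       pheno_kept, kept_geno, m))
        )
    snp_tab = pd.concat(snp_tabs, ignore_index=True)
    add = snp_tab[(snp_tab["mode"] == "additive") & (snp_tab["flagged"] == "")]
    if len(add):
        fdr = associations.gene_based_fdr(
            add[["snp", "gene", "sex", "p"]],
            q=thresholds["fdr_q"], raw_alpha=thresholds["raw_significance"],
        )
        snp_tab = snp_tab.merge(
            fdr[["snp", "sex", "bh_critical", "bh_reject", "significant"]],
            on=["snp", "sex"], how="left",
        )
    write_table(snp_tab, out_dir / "snp_associations.csv", seed, ih, thresholds)
    manifest["outputs"] += ["prs_associations.csv", "snp_associations.csv"]

    for exposure in config.get("exposures", []):
        tab = _stage(
            "stratify",
            lambda e=exposure: associations.stratified_exposure_table(scored, e),
        )
        name = f"stratified_{exposure}.csv"
        write_table(tab, out_dir / name, seed, ih, thresholds,
                    extra={"interaction": json.dumps(tab.attrs["interaction"])})
        manifest["outputs"].append(name)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
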