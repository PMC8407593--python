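"""File readers and writers: genotypes, phenotypes, masks, summary stats.

Formats are plain text throughout: TSV genotype matrices (rows individuals,
columns SNPs, first column IID), the PLINK ``.raw`` dialect, two-column
phenotype tables, long-format annotation masks, tab-separated summary
statistics and dense LD matrices.  Missing genotype entries are mean-imputed
per column with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationMask
from .summary import SummaryData

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "write_phenotype",
    "read_snp_map",
    "write_snp_map",
    "read_mask",
    "write_mask",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "write_fit_tables",
]

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _impute_missing(df: pd.DataFrame) -> np.ndarray:
    X = df.to_numpy(dtype=np.float64)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        means = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = means[idx[1]]
        logger.info("imputed %d missing genotype entries to column means", n_missing)
    bad = (X < 0) | (X > 2)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"dosage outside {{0,1,2}} at row {r}, column {c}")
    return X


def read_genotypes(path, dialect: str = "tsv"):
    """Read a dosage matrix; returns (X, sample_ids, snp_ids).

    dialect="tsv": tab-separated, header of SNP ids, first column IID.
    dialect="plink_raw": whitespace-separated PLINK .raw with the standard
    six metadata columns and SNP columns named ``<snp>_<counted allele>``.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA", "nan", ""], float_precision="round_trip")
        sample_ids = df.iloc[:, 0].astype(str).to_numpy()
        body = df.iloc[:, 1:]
        snp_ids = np.array(body.columns, dtype=object)
        counted = None
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA", "-9", ""])
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f"PLINK .raw header missing columns: {missing_meta}")
        sample_ids = df["IID"].astype(str).to_numpy()
        body = df.drop(columns=_PLINK_META)
        snp_ids, counted = [], []
        for col in body.columns:
            name, _, allele = col.rpartition("_")
            if not name:
                raise ValueError(f"PLINK .raw column {col!r} lacks a counted-allele suffix")
            snp_ids.append(name)
            counted.append(allele)
        snp_ids = np.array(snp_ids, dtype=object)
        counted = np.array(counted, dtype=object)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        X = _impute_missing(body.apply(pd.to_numeric))
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric or invalid dosage: {exc}") from exc
    return X, sample_ids, snp_ids


def write_genotypes(path, X, sample_ids, snp_ids, dialect: str = "tsv", counted_allele: str = "A"):
    X = np.asarray(X)
    if dialect == "tsv":
        df = pd.DataFrame(X, columns=list(snp_ids))
        df.insert(0, "IID", list(sample_ids))
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "plink_raw":
        cols = {m: 0 for m in _PLINK_META}
        df = pd.DataFrame(cols, index=range(len(sample_ids)))
        df["FID"] = df["IID"] = list(sample_ids)
        df["PAT"] = df["MAT"] = 0
        df["SEX"] = 0
        df["PHENOTYPE"] = -9
        for j, s in enumerate(snp_ids):
            df[f"{s}_{counted_allele}"] = X[:, j]
        df.to_csv(path, sep=" ", index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_phenotype(path):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df.iloc[:, 0].astype(str).to_numpy(), df.iloc[:, 1].to_numpy(dtype=np.float64)


def write_phenotype(path, sample_ids, y):
    pd.DataFrame({"IID": list(sample_ids), "phenotype": np.asarray(y)}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_snp_map(path):
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    return df[["snp_id", "chromosome", "position"]]


def write_snp_map(path, snp_map: pd.DataFrame):
    snp_map.to_csv(path, sep="\t", index=False)


def write_mask(path, mask: AnnotationMask):
    mask.to_long_frame().to_csv(path, sep="\t", index=False)


def read_mask(path, snp_ids) -> AnnotationMask:
    return AnnotationMask.from_long_frame(pd.read_csv(path, sep="\t"), snp_ids)


def write_summary_stats(path, snp_map: pd.DataFrame, theta_hat, se, n: int):
    df = snp_map[["snp_id", "chromosome", "position"]].copy()
    df.rename(columns={"chromosome": "chrom", "position": "pos"}, inplace=True)
    df["beta"] = np.asarray(theta_hat)
    df["se"] = np.asarray(se)
    df["n"] = n
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path):
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"snp_id", "chrom", "pos", "beta", "se", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary statistics file missing columns: {sorted(missing)}")
    return df


def write_ld_matrix(path, R, snp_ids):
    pd.DataFrame(np.asarray(R), index=list(snp_ids), columns=list(snp_ids)).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_ld_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=np.float64), np.array(df.columns, dtype=object)


def load_summary_data(stats_path, ld_path) -> tuple[SummaryData, pd.DataFrame]:
    df = read_summary_stats(stats_path)
    R, ld_ids = read_ld_matrix(ld_path)
    if not np.array_equal(ld_ids, df["snp_id"].to_numpy(dtype=object)):
        raise ValueError("LD matrix SNP ids do not match the summary statistics")
    data = SummaryData(
        theta_hat=df["beta"].to_numpy(np.float64),
        se=df["se"].to_numpy(np.float64),
        ld=R,
        n_effective=int(df["n"].iloc[0]),
    )
    return data, df


def write_fit_tables(outdir, result, snp_map: pd.DataFrame, mask: AnnotationMask):
    """Write snp_pips.tsv, set_pips.tsv, pve.tsv and elbo_trace.tsv.

    Column layouts: SNP table (chromosome, snp_id, position, pip,
    posterior_mean); set table adds boundaries, member count and the top
    member SNP with its PIP.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snp_tab = pd.DataFrame(
        {
            "chromosome": snp_map["chromosome"],
            "snp_id": snp_map["snp_id"],
            "position": snp_map["position"],
            "pip": result.pip_snp,
            "posterior_mean": result.m_theta,
        }
    )
    snp_tab.to_csv(outdir / "snp_pips.tsv", sep="\t", index=False)

    top_snp, top_pip, counts = [], [], []
    ids = mask.snp_ids
    for g in range(mask.n_sets):
        mem = mask.members(g)
        counts.append(len(mem))
        best = mem[np.argmax(result.pip_snp[mem])]
        top_snp.append(ids[best])
        top_pip.append(result.pip_snp[best])
    set_tab = pd.DataFrame(
        {
            "set_name": mask.set_names,
            "set_kind": mask.set_kind,
            "n_snps": counts,
            "pip": result.pip_set,
            "posterior_mean": result.m_w,
            "top_snp": top_snp,
            "top_snp_pip": top_pip,
        }
    )
    if mask.set_bounds is not None:
        set_tab = set_tab.merge(mask.set_bounds, on="set_name", how="left")
    set_tab.to_csv(outdir / "set_pips.tsv", sep="\t", index=False)

    pd.DataFrame(
        {"scale": ["snp", "snp_set"], "pve": [result.pve_snp, result.pve_set]}
    ).to_csv(outdir / "pve.tsv", sep="\t", index=False)

    rows = []
    for layer, traces, elbos, weights in (
        ("inner", result.elbo_trace_inner, result.grid_elbos_inner, result.grid_weights_inner),
        ("outer", result.elbo_trace_outer, result.grid_elbos_outer, result.grid_weights_outer),
    ):
        for i, trace in enumerate(traces):
            for sweep, e in enumerate(trace):
                rows.append((layer, i, sweep, e, elbos[i], weights[i]))
    pd.DataFrame(
        rows, columns=["layer", "grid_index", "sweep", "elbo", "final_elbo", "weight"]
    ).to_csv(outdir / "elbo_trace.tsv", sep="\t", index=False)
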