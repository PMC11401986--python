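"""Batch QC: informative-SNP filtering, call rates, heterozygosity, PCA.

Two deliberately different denominators are used:

* :func:`callrate` reports each genotype class as a proportion of ALL
  records in the group, no-calls included — so AA + AB + BB + NC = 1.
* :func:`heterozygosity` reports the AB fraction among CALLED genotypes
  only (AA + AB + BB), since a no-call says nothing about zygosity.

For haploid cells (sperm) any AB call is necessarily an amplification
artifact, so the heterozygosity of a haploid batch directly estimates its
allele drop-in burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import IntegrityError, ParameterError
from .types import GENOTYPES

DOSAGE = {"AA": 0.0, "AB": 1.0, "BB": 2.0}


def filter_informative(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only genotype-informative SNP records.

    Drops rows with chromosome token "0" (no genomic placement), rows whose
    SNP name contains the substring "cnv" (case-sensitive; copy-number
    probes), and rows flagged intensity-only in the manifest.  Idempotent;
    an empty result is permitted.
    """
    for col in ("Chr", "Name"):
        if col not in table.columns:
            raise ParameterError(f"table missing required column {col!r}")
    keep = (table["Chr"].astype(str) != "0") & ~table["Name"].astype(str).str.contains("cnv", regex=False)
    if "intensity_only" in table.columns:
        keep &= ~table["intensity_only"].astype(bool)
    return table.loc[keep].reset_index(drop=True)


def _check_keys(table: pd.DataFrame, group_by: list[str]) -> None:
    unknown = [k for k in group_by if k not in table.columns]
    if unknown:
        raise ParameterError(f"unknown grouping keys {unknown}")
    if "gtype" not in table.columns:
        raise ParameterError("table missing 'gtype' column")


def callrate(table: pd.DataFrame, group_by: list[str] | None = None) -> pd.DataFrame:
    """Proportion of each genotype class per group, no-calls included.

    Returns a long-format frame with the grouping keys plus ``gtype`` and
    ``proportion``; every group carries all four classes (absent ones as
    0.0) and its proportions sum to 1.
    """
    group_by = list(group_by or [])
    _check_keys(table, group_by)
    if group_by:
        counts = (table.groupby(group_by + ["gtype"], sort=True, dropna=False)
                  .size().rename("n").reset_index())
        totals = table.groupby(group_by, sort=True, dropna=False).size().rename("total")
        # complete the gtype classes so absent genotypes appear as zero
        keys = counts[group_by].drop_duplicates()
        full = keys.merge(pd.DataFrame({"gtype": list(GENOTYPES)}), how="cross")
        counts = full.merge(counts, on=group_by + ["gtype"], how="left").fillna({"n": 0})
        counts = counts.merge(totals, left_on=group_by, right_index=True)
    else:
        n = table.groupby("gtype").size()
        counts = pd.DataFrame({
            "gtype": list(GENOTYPES),
            "n": [n.get(g, 0) for g in GENOTYPES],
            "total": len(table),
        })
    counts["proportion"] = counts["n"] / counts["total"]
    order = ["AA", "AB", "BB", "NC"]
    counts["gtype"] = pd.Categorical(counts["gtype"], categories=order, ordered=True)
    counts = counts.sort_values(group_by + ["gtype"]).reset_index(drop=True)
    counts["gtype"] = counts["gtype"].astype(str)
    return counts[group_by + ["gtype", "proportion"]]


def heterozygosity(table: pd.DataFrame, group_by: list[str] | None = None) -> pd.DataFrame:
    """AB fraction among called genotypes per group (NC excluded).

    Groups with zero called genotypes report NaN, never 0.
    """
    group_by = list(group_by or [])
    _check_keys(table, group_by)
    called = table["gtype"].isin(["AA", "AB", "BB"])
    is_ab = (table["gtype"] == "AB") & called
    work = pd.DataFrame({"called": called, "ab": is_ab})
    if group_by:
        for k in group_by:
            work[k] = table[k].values
        agg = work.groupby(group_by, sort=True).sum().reset_index()
    else:
        agg = pd.DataFrame([work.sum()])
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["ab_fraction"] = np.where(
            agg["called"] > 0, agg["ab"] / agg["called"], np.nan
        )
    return agg[group_by + ["ab_fraction"]]


@dataclass
class PCAResult:
    """Per-sample principal-component coordinates over genotype dosages."""

    coordinates: pd.DataFrame          # index sample_id, columns PC1..PCk
    explained_variance_ratio: np.ndarray
    n_snps_used: int
    chromosome: str | None = None      # set when computed per chromosome


def genotype_pca(table: pd.DataFrame, k: int = 2,
                 by_chrom: bool = False) -> PCAResult | list[PCAResult]:
    """PCA of samples over complete-case genotype dosages.

    Uses only SNPs called (non-NC) in every sample; genotypes are encoded
    as B-allele dosage (AA=0, AB=1, BB=2) and columns are centred but not
    scaled.  With ``by_chrom`` the decomposition is repeated independently
    per chromosome token.
    """
    if by_chrom:
        results = []
        for chrom, sub in table.groupby("Chr", sort=True):
            res = genotype_pca(sub, k=k, by_chrom=False)
            res.chromosome = str(chrom)
            results.append(res)
        return results
    wide = table.pivot(index="sample_id", columns="Name", values="gtype")
    if wide.shape[0] < 2:
        raise ParameterError("PCA requires at least 2 samples")
    complete = wide.columns[(wide != "NC").all(axis=0) & wide.notna().all(axis=0)]
    if len(complete) == 0:
        raise IntegrityError("no SNP is called in every sample; cannot run PCA")
    if len(complete) < k:
        raise ParameterError(
            f"only {len(complete)} complete-case SNPs for k={k} components"
        )
    dosage = wide[complete].map(DOSAGE.get).astype(float)
    centred = dosage - dosage.mean(axis=0)
    k_eff = min(k, min(centred.shape) - 0)
    pca = PCA(n_components=k_eff, svd_solver="full")
    coords = pca.fit_transform(centred.values)
    frame = pd.DataFrame(
        coords, index=dosage.index,
        columns=[f"PC{i + 1}" for i in range(k_eff)],
    )
    return PCAResult(frame, pca.explained_variance_ratio_, len(complete))
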