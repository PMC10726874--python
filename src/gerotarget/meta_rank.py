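"""Per-cancer meta-analysis and cross-cancer target prioritization.

Each cancer contributes several case-control differential-expression tables
(one per dataset).  Per gene, log-fold-changes are combined across datasets
(inverse-variance weighting by default; a literal standard-deviation-product
mode is kept as an alternative), two-sided p-values are combined by
Stouffer's signed-z method weighted by the square root of dataset sample
size, and Benjamini-Hochberg FDR is applied across genes within the cancer.

Ranked per-cancer target lists (top 100 per novelty setting, produced by an
external prioritization engine and consumed here as input) are pooled into
common-target lists: genes sorted by descending occurrence across cancers,
then ascending average rank, then gene id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "stouffer_combine",
    "combine_logfc",
    "bh_fdr",
    "meta_analyze_cancer",
    "prioritize_common_targets",
]


class MetaRankError(ValueError):
    pass


_P_EPS = 1e-300


def stouffer_combine(
    p_values: Sequence[float],
    effect_signs: Sequence[int],
    weights: Sequence[float] | None = None,
) -> tuple:
    """Combine two-sided p-values with Stouffer's signed-z method.

    ``z_i = Phi^-1(1 - p_i/2) * sign_i``;  ``Z = sum(w_i z_i) / sqrt(sum w_i^2)``;
    the combined two-sided p is ``2 (1 - Phi(|Z|))``.  Boundary p-values are
    clipped to machine bounds with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    signs = np.asarray(effect_signs, dtype=float)
    if not np.all(np.isin(signs, (-1.0, 1.0))):
        raise MetaRankError("effect signs must be -1 or +1")
    if p.shape != signs.shape:
        raise MetaRankError("p-values and signs must have equal length")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise MetaRankError("weights must be positive")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("p-values at 0 or 1 clipped to machine bounds", stacklevel=2)
        p = np.clip(p, _P_EPS, 1 - 1e-16)
    z = stats.norm.isf(p / 2.0) * signs
    Z = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p_comb = float(2 * stats.norm.sf(abs(Z)))
    return Z, p_comb


def combine_logfc(
    logfcs: Sequence[float], sds: Sequence[float], method: str = "ivw"
) -> float:
    """Combine per-dataset logFCs.

    ``ivw`` (default): inverse-variance weighted mean, sum(lfc/sd^2)/sum(1/sd^2).
    ``sd_product``: sd-weighted mean, sum(lfc*sd)/sum(sd).
    """
    lfc = np.asarray(logfcs, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if lfc.shape != sd.shape:
        raise MetaRankError("logfcs and sds must have equal length")
    if np.any(sd <= 0):
        raise MetaRankError("standard deviations must be positive")
    if method == "ivw":
        w = 1.0 / sd**2
    elif method == "sd_product":
        w = sd
    else:
        raise MetaRankError(f"unknown method {method!r}")
    return float(np.sum(w * lfc) / np.sum(w))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise MetaRankError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_analyze_cancer(
    per_dataset_de_tables: Mapping[str, pd.DataFrame],
    cancer: str,
    *,
    logfc_method: str = "ivw",
) -> pd.DataFrame:
    """Pool one cancer's dataset-level DE tables into a single meta-table.

    Each input table needs columns ``gene_id, logfc, p_value, se, n``.  Genes
    are combined over the datasets that measured them; Stouffer weights are
    the square root of dataset sample size; FDR is computed across genes
    within the cancer.
    """
    if not per_dataset_de_tables:
        raise MetaRankError("at least one dataset table required")
    pieces = []
    for ds_id, tab in per_dataset_de_tables.items():
        t = tab[["gene_id", "logfc", "p_value", "se", "n"]].copy()
        t["dataset_id"] = ds_id
        pieces.append(t)
    long = pd.concat(pieces, ignore_index=True)

    rows = []
    for gene, grp in long.groupby("gene_id", sort=True):
        sds = grp["se"].to_numpy()
        # guard exact-zero standard errors (constant genes)
        sds = np.where(sds > 0, sds, np.nanmax([sds.max(), 1e-8]))
        clfc = combine_logfc(grp["logfc"].to_numpy(), sds, method=logfc_method)
        signs = np.where(grp["logfc"].to_numpy() >= 0, 1, -1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, p = stouffer_combine(
                grp["p_value"].to_numpy(), signs, np.sqrt(grp["n"].to_numpy())
            )
        rows.append(
            {
                "gene_id": gene,
                "cancer": cancer,
                "combined_logfc": clfc,
                "stouffer_z": z,
                "combined_p": p,
                "n_datasets": len(grp),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["combined_p"].to_numpy())
    return out


def prioritize_common_targets(
    per_cancer_top_lists: pd.DataFrame, top_n: int = 100
) -> pd.DataFrame:
    """Pool per-cancer ranked lists into common-target lists per novelty
    setting.

    Input: long frame with columns ``cancer, gene_id, rank, setting``; each
    (cancer, setting) list must have unique genes.  Output: per setting, the
    top ``top_n`` genes sorted by descending occurrence, ascending average
    rank, then gene id.
    """
    required = {"cancer", "gene_id", "rank", "setting"}
    if not required <= set(per_cancer_top_lists.columns):
        raise MetaRankError(f"rank lists need columns {sorted(required)}")
    out = []
    for setting, sub in per_cancer_top_lists.groupby("setting", sort=True):
        for (cancer, _), lst in sub.groupby(["cancer", "setting"], sort=False):
            if lst["gene_id"].duplicated().any():
                dup = lst.loc[lst["gene_id"].duplicated(), "gene_id"].iloc[0]
                raise MetaRankError(
                    f"duplicate gene {dup!r} in list for cancer {cancer!r}"
                )
        agg = (
            sub.groupby("gene_id")
            .agg(occurrence=("cancer", "nunique"), avg_rank=("rank", "mean"))
            .reset_index()
        )
        agg = agg.sort_values(
            ["occurrence", "avg_rank", "gene_id"], ascending=[False, True, True]
        ).head(top_n)
        agg["novelty_setting"] = setting
        out.append(agg)
    return pd.concat(out, ignore_index=True)[
        ["gene_id", "occurrence", "avg_rank", "novelty_setting"]
    ]
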