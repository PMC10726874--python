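"""Age-association calling on healthy-tissue expression.

A gene is called age-associated in a tissue when it passes two tests at
p < 0.05 simultaneously:

1. a two-sided partial Pearson correlation between age and expression,
   controlling for sex::

       r_ae.s = (r_ae - r_as * r_es) / sqrt((1 - r_as^2) (1 - r_es^2))

   with p from the t distribution on n - 2 degrees of freedom; and

2. an old-vs-young differential-expression fit ``Y = b0 + b1*old + b2*sex``
   where ``old = 1[age >= 60]`` and samples with 50 <= age < 60 are
   excluded, with an empirical-Bayes moderated t-statistic (per-gene
   residual variances shrunk toward a pooled prior, raising the effective
   degrees of freedom).

The call direction is the sign of the old-vs-young coefficient (the logFC).
A chi-square contingency test compares age-association rates between tumor
suppressor genes and other genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .preprocess import ExpressionStudy

__all__ = [
    "PartialCorrelationResult",
    "ContingencyTestResult",
    "partial_pearson",
    "partial_pearson_table",
    "de_old_young",
    "de_case_control",
    "call_age_associated",
    "age_association_table",
    "tsg_enrichment_test",
]


class AgeAssocError(ValueError):
    pass


@dataclass
class PartialCorrelationResult:
    gene_id: str
    r_ae: float
    r_as: float
    r_es: float
    r_partial: float
    n: int
    t_stat: float
    df: int
    p_value: float


@dataclass
class ContingencyTestResult:
    table: np.ndarray
    chi2: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# partial Pearson correlation
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def partial_pearson(
    age: Sequence[float], expr: Sequence[float], sex: Sequence[float], gene_id: str = ""
) -> PartialCorrelationResult:
    """Partial correlation of age and expression controlling for sex."""
    age = np.asarray(age, dtype=float)
    expr = np.asarray(expr, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = age.size
    if n < 4:
        raise AgeAssocError("partial correlation needs n >= 4")
    if np.ptp(age) == 0 or np.ptp(expr) == 0:
        raise AgeAssocError("age and expression must be non-constant")
    r_ae = _pearson(age, expr)
    if np.ptp(sex) == 0:
        # no sex variation: nothing to control for, fall back to plain Pearson
        r_as = r_es = 0.0
    else:
        r_as = _pearson(age, sex)
        r_es = _pearson(expr, sex)
    if abs(r_as) >= 1.0 or abs(r_es) >= 1.0:
        raise AgeAssocError("sex is collinear with age or expression")
    r_partial = (r_ae - r_as * r_es) / np.sqrt((1 - r_as**2) * (1 - r_es**2))
    r_partial = float(np.clip(r_partial, -1.0, 1.0))
    df = n - 2
    if abs(r_partial) >= 1.0:
        t = np.inf * np.sign(r_partial)
        p = 0.0
    else:
        t = r_partial * np.sqrt(df / (1 - r_partial**2))
        p = 2 * stats.t.sf(abs(t), df)
    return PartialCorrelationResult(gene_id, r_ae, r_as, r_es, r_partial, n, float(t), df, float(p))


def partial_pearson_table(study: ExpressionStudy) -> pd.DataFrame:
    """Vectorized partial correlation for every gene of a study.

    Returns columns ``gene_id, r_partial, p_corr, n``.
    """
    age = study.samples["age"].to_numpy(dtype=float)
    sex = study.samples["sex"].to_numpy(dtype=float)
    X = study.matrix.to_numpy(dtype=float)
    n = age.size

    def _z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    az = _z(age)
    sz = _z(sex)
    sds = X.std(axis=1)
    ok = sds > 0
    Xz = np.zeros_like(X)
    Xz[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sds[ok, None]
    r_ae = Xz @ az / n
    r_es = Xz @ sz / n
    r_as = float(az @ sz / n)
    denom = np.sqrt((1 - r_as**2) * np.clip(1 - r_es**2, 1e-300, None))
    r_p = np.clip((r_ae - r_as * r_es) / denom, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r_p * np.sqrt(df / np.clip(1 - r_p**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df)
    p[~ok] = 1.0
    return pd.DataFrame(
        {"gene_id": study.gene_ids, "r_partial": r_p, "p_corr": p, "n": n}
    )


# ---------------------------------------------------------------------------
# moderated-t differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: int) -> tuple:
    """Moment-match a scaled F prior to the observed residual variances.

    Returns (prior_df, prior_var).  prior_df may be ``inf`` when the
    variances show no excess dispersion beyond the chi-square expectation.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return float(d0), float(s0_2)


def _moderated_fit(
    Y: np.ndarray,
    X: np.ndarray,
    coef_index: int,
    prior_df: float | None,
) -> dict:
    """Least-squares fit of every gene on design X with EB-shrunk variances.

    ``Y`` is genes x samples.  Returns per-gene arrays for the coefficient of
    interest, its moderated t / p, residual sd, and the shrink parameters.
    """
    n, k = X.shape
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise AgeAssocError("design leaves no residual degrees of freedom")
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = (xtx_inv @ X.T @ Y.T).T  # genes x k
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    c = xtx_inv[coef_index, coef_index]

    # snap floating-point noise to exact zero (constant genes)
    scale = np.abs(Y).max(axis=1) + 1.0
    s2 = np.where(s2 < (1e-9 * scale) ** 2, 0.0, s2)
    beta[:, coef_index] = np.where(
        np.abs(beta[:, coef_index]) < 1e-9 * scale, 0.0, beta[:, coef_index]
    )

    if prior_df is None:
        if np.all(s2 == 0):
            warnings.warn(
                "all residual variances are zero; falling back to ordinary t",
                stacklevel=2,
            )
            d0, s0_2 = 0.0, 0.0
        else:
            d0, s0_2 = _fit_f_dist(s2, df_resid)
    else:
        d0, s0_2 = float(prior_df), float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 > 0:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    else:  # ordinary t
        s2_post = s2
        df_total = float(df_resid)

    b = beta[:, coef_index]
    se = np.sqrt(np.clip(s2_post * c, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, 0.0)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)
    return {
        "beta": beta,
        "logfc": b,
        "se": se,
        "residual_sd": np.sqrt(s2),
        "t": t,
        "p": p,
        "df_resid": df_resid,
        "prior_df": d0,
        "prior_var": s0_2,
        "moderated_df": df_total,
    }


def de_old_young(
    study: ExpressionStudy,
    old_min: float = 60,
    young_max: float = 50,
    *,
    prior_df: float | None = None,
    continuous_age: bool = False,
) -> pd.DataFrame:
    """Old-vs-young differential expression with sex as covariate.

    Samples with ``young_max <= age < old_min`` are excluded.  By default the
    age term is a binary old indicator so the coefficient reads as an
    old-vs-young logFC; ``continuous_age=True`` switches to age in years.
    ``prior_df=0`` disables shrinkage (ordinary OLS t), ``None`` estimates it
    from the data.

    Returns a frame with ``gene_id, logfc, beta_sex, residual_sd, t,
    moderated_df, p_value, n, se``.
    """
    age = study.samples["age"].to_numpy(dtype=float)
    sex = study.samples["sex"].to_numpy(dtype=float)
    keep = (age >= old_min) | (age < young_max)
    if not ((age[keep] >= old_min).any() and (age[keep] < young_max).any()):
        raise AgeAssocError("both old and young strata must be non-empty")
    Y = study.matrix.to_numpy(dtype=float)[:, keep]
    term = age[keep] if continuous_age else (age[keep] >= old_min).astype(float)
    X = np.column_stack([np.ones(keep.sum()), term, sex[keep]])
    fit = _moderated_fit(Y, X, coef_index=1, prior_df=prior_df)
    return pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "logfc": fit["logfc"],
            "beta_sex": fit["beta"][:, 2],
            "residual_sd": fit["residual_sd"],
            "t": fit["t"],
            "moderated_df": fit["moderated_df"],
            "p_value": fit["p"],
            "n": int(keep.sum()),
            "se": fit["se"],
        }
    )


def de_case_control(
    study: ExpressionStudy, *, prior_df: float | None = None
) -> pd.DataFrame:
    """Case-vs-control differential expression (moderated t), for cancer
    datasets.  Same output schema as :func:`de_old_young`."""
    cond = study.samples["condition"].to_numpy()
    is_case = (cond == "case").astype(float)
    if is_case.sum() == 0 or is_case.sum() == len(cond):
        raise AgeAssocError("both case and control arms must be non-empty")
    Y = study.matrix.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(cond)), is_case])
    fit = _moderated_fit(Y, X, coef_index=1, prior_df=prior_df)
    return pd.DataFrame(
        {
            "gene_id": study.gene_ids,
            "logfc": fit["logfc"],
            "residual_sd": fit["residual_sd"],
            "t": fit["t"],
            "moderated_df": fit["moderated_df"],
            "p_value": fit["p"],
            "n": len(cond),
            "se": fit["se"],
        }
    )


# ---------------------------------------------------------------------------
# the dual-criterion call
# ---------------------------------------------------------------------------

def call_age_associated(
    pc_results: pd.DataFrame,
    de_results: pd.DataFrame,
    alpha: float = 0.05,
    tissue: str = "",
) -> pd.DataFrame:
    """Dual-criterion call: age-associated iff both p-values < ``alpha``;
    direction is the sign of the old-vs-young logFC."""
    pc_genes = set(pc_results["gene_id"])
    de_genes = set(de_results["gene_id"])
    if pc_genes != de_genes:
        diff = sorted(pc_genes ^ de_genes)
        raise AgeAssocError(f"gene sets differ between the two analyses: {diff[:10]}")
    merged = pc_results.merge(
        de_results[["gene_id", "logfc", "p_value"]].rename(columns={"p_value": "p_de"}),
        on="gene_id",
    )
    merged["tissue"] = tissue
    merged["is_age_associated"] = (merged["p_corr"] < alpha) & (merged["p_de"] < alpha)
    merged["direction"] = np.where(merged["logfc"] >= 0, "up", "down")
    return merged[
        ["gene_id", "tissue", "r_partial", "p_corr", "logfc", "p_de",
         "is_age_associated", "direction"]
    ]


def age_association_table(
    study: ExpressionStudy, alpha: float = 0.05, tissue: str | None = None
) -> pd.DataFrame:
    """Full per-tissue age-association table (partial correlation + DE +
    call), one row per gene."""
    if tissue is None:
        tissue = str(study.samples["tissue"].iloc[0])
    pc = partial_pearson_table(study)
    de = de_old_young(study)
    return call_age_associated(pc, de, alpha=alpha, tissue=tissue)


def tsg_enrichment_test(
    calls_across_tissues: pd.DataFrame, tsg_ids: Iterable[str]
) -> ContingencyTestResult:
    """Pearson chi-square (no continuity correction) for whether tumor
    suppressor genes are age-associated (in >= 1 tissue) more often than
    other genes.

    ``calls_across_tissues`` holds the concatenated per-tissue call tables.
    """
    tsg = set(tsg_ids)
    per_gene = calls_across_tissues.groupby("gene_id")["is_age_associated"].any()
    is_tsg = per_gene.index.isin(tsg)
    if is_tsg.all() or not is_tsg.any():
        raise AgeAssocError("both TSG and non-TSG groups must be non-empty")
    table = np.array(
        [
            [int((per_gene[is_tsg]).sum()), int((~per_gene[is_tsg]).sum())],
            [int((per_gene[~is_tsg]).sum()), int((~per_gene[~is_tsg]).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise AgeAssocError("contingency table has an empty margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ContingencyTestResult(table, float(chi2), int(df), float(p))
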