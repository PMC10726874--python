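"""Hallmark annotation, age-association filtering, therapeutic direction,
and the four-group lifespan-evidence classification.

Common cancer targets flow through four steps:

1. **Hallmark mapping** — a gene is linked to an aging hallmark when any of
   its GO term names contains (case-insensitive substring) any keyword of
   that hallmark; there are exactly 12 hallmark categories.
2. **Age-association filter** — keep targets age-associated in more than
   10% of healthy tissues (with 47 tissues, at least 5) AND carrying at
   least one hallmark.
3. **Therapeutic direction** — antagonism when the gene is significantly
   (FDR < 0.05) upregulated in a majority of cancers, agonism when
   downregulated; a curated override table wins when present (e.g. a target
   whose higher expression is protective despite upregulation).
4. **Group classification** — Group 1: lifespan-extension evidence with the
   anti-aging and anti-cancer directions concordant; Group 2: extension
   evidence, directions opposed; Group 3: shortening evidence only;
   Group 4: no evidence or no effect.  Dual-purpose proposals are Group-1
   genes minus tumor suppressor genes (antagonizing a TSG could promote
   tumorigenesis), ordered by the number of tissues dysregulated in aging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HALLMARKS_OF_AGING",
    "TherapeuticDirection",
    "map_hallmarks",
    "filter_age_associated_targets",
    "propose_direction",
    "classify_groups",
    "propose_dual_purpose",
    "min_tissue_count",
]


class TargetAnnotError(ValueError):
    pass


#: the 12 canonical aging hallmark categories
HALLMARKS_OF_AGING = (
    "genomic instability",
    "telomere attrition",
    "epigenetic alterations",
    "loss of proteostasis",
    "compromised autophagy",
    "deregulated nutrient sensing",
    "mitochondrial dysfunction",
    "cellular senescence",
    "stem cell exhaustion",
    "altered intercellular communication",
    "chronic inflammation",
    "dysbiosis",
)

LIFESPAN_EFFECTS = frozenset({"extends", "shortens", "no_effect", "none"})


@dataclass
class TherapeuticDirection:
    gene_id: str
    cancer_direction: str  # antagonism | agonism | unknown
    basis: str  # expression | override | unknown
    n_cancers_up: int
    n_cancers_down: int


def map_hallmarks(
    go_annotation: Mapping[str, Iterable[str]],
    keyword_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Assign aging hallmarks to genes by keyword matching on GO term names.

    ``go_annotation`` maps gene id -> iterable of GO term names;
    ``keyword_map`` maps each of the 12 hallmarks -> keyword list.  A gene
    gets hallmark H iff any of its term names contains any keyword of H
    (case-insensitive substring).
    """
    if len(keyword_map) != 12:
        raise TargetAnnotError(
            f"keyword map must have exactly the 12 hallmark keys, got {len(keyword_map)}"
        )
    lowered = {
        h: [k.lower() for k in kws] for h, kws in keyword_map.items()
    }
    rows = []
    for gene, terms in go_annotation.items():
        names = [t.lower() for t in terms]
        hits = sorted(
            h
            for h, kws in lowered.items()
            if any(kw in name for kw in kws for name in names)
        )
        rows.append(
            {"gene_id": gene, "hallmarks": tuple(hits), "n_hallmarks": len(hits)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "hallmarks", "n_hallmarks"])


def min_tissue_count(tissue_count: int, min_frac: float = 0.1) -> int:
    """Smallest tissue count strictly greater than ``min_frac * tissue_count``
    (with 47 tissues and 10%, that is 5)."""
    return int(np.floor(min_frac * tissue_count)) + 1


def filter_age_associated_targets(
    common_targets: Iterable[str],
    per_tissue_calls: pd.DataFrame,
    hallmark_annotations: pd.DataFrame,
    tissue_count: int,
    min_frac: float = 0.1,
) -> pd.DataFrame:
    """Keep targets age-associated in more than ``min_frac`` of the tissues
    and carrying at least one aging hallmark.

    ``per_tissue_calls`` is the concatenated call table (gene_id, tissue,
    is_age_associated, direction).  Returns the retained targets with their
    tissue tallies and hallmark counts.
    """
    if tissue_count <= 0:
        raise TargetAnnotError("tissue_count must be positive")
    targets = list(dict.fromkeys(common_targets))
    assoc = per_tissue_calls[per_tissue_calls["is_age_associated"]]
    n_tissues = assoc.groupby("gene_id")["tissue"].nunique()
    n_up = (
        assoc[assoc["direction"] == "up"].groupby("gene_id")["tissue"].nunique()
    )
    hm = hallmark_annotations.set_index("gene_id")
    rows = []
    for gene in targets:
        nt = int(n_tissues.get(gene, 0))
        nh = int(hm["n_hallmarks"].get(gene, 0))
        if nt > min_frac * tissue_count and nh >= 1:
            nu = int(n_up.get(gene, 0))
            rows.append(
                {
                    "gene_id": gene,
                    "n_tissues_age_associated": nt,
                    "n_tissues_up": nu,
                    "n_tissues_down": nt - nu,
                    "n_hallmarks": nh,
                    "hallmarks": hm["hallmarks"].get(gene, ()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_tissues_age_associated",
            "n_tissues_up",
            "n_tissues_down",
            "n_hallmarks",
            "hallmarks",
        ],
    )


def propose_direction(
    meta_results_for_gene: pd.DataFrame,
    overrides: Mapping[str, str] | None = None,
    fdr_cut: float = 0.05,
) -> TherapeuticDirection:
    """Anti-cancer direction from the majority significant expression sign.

    ``meta_results_for_gene`` holds one row per cancer (columns ``gene_id,
    combined_logfc, fdr``).  Upregulation in a majority of significant
    cancers proposes antagonism, downregulation agonism.  An override entry
    (gene -> direction) wins regardless.  With no significant cancer and no
    override (or an exact tie) the direction is unknown and flagged.
    """
    if len(meta_results_for_gene) == 0:
        raise TargetAnnotError("at least one cancer meta-result required")
    gene = str(meta_results_for_gene["gene_id"].iloc[0])
    sig = meta_results_for_gene[meta_results_for_gene["fdr"] < fdr_cut]
    n_up = int((sig["combined_logfc"] > 0).sum())
    n_down = int((sig["combined_logfc"] < 0).sum())
    if overrides and gene in overrides:
        return TherapeuticDirection(gene, overrides[gene], "override", n_up, n_down)
    if n_up > n_down:
        return TherapeuticDirection(gene, "antagonism", "expression", n_up, n_down)
    if n_down > n_up:
        return TherapeuticDirection(gene, "agonism", "expression", n_up, n_down)
    return TherapeuticDirection(gene, "unknown", "unknown", n_up, n_down)


def _resolve_ledger(ledger: pd.DataFrame) -> pd.DataFrame:
    """Collapse a (possibly multi-row) evidence ledger to one row per gene.

    Contradictory evidence (both extends and shortens) resolves to
    ``extends`` with a warning; the anti-aging direction is taken from the
    extends rows when present.
    """
    bad = set(ledger["lifespan_effect"]) - LIFESPAN_EFFECTS
    if bad:
        raise TargetAnnotError(f"unknown lifespan_effect labels {sorted(bad)}")
    rows = []
    for gene, grp in ledger.groupby("gene_id", sort=True):
        effects = set(grp["lifespan_effect"])
        if "extends" in effects:
            if "shortens" in effects:
                warnings.warn(
                    f"gene {gene!r} has both extends and shortens evidence; "
                    "resolving to extends",
                    stacklevel=3,
                )
            effect = "extends"
            dirs = grp.loc[grp["lifespan_effect"] == "extends", "aging_direction"]
        elif "shortens" in effects:
            effect = "shortens"
            dirs = grp.loc[grp["lifespan_effect"] == "shortens", "aging_direction"]
        elif "no_effect" in effects:
            effect, dirs = "no_effect", grp["aging_direction"]
        else:
            effect, dirs = "none", grp["aging_direction"]
        known = [d for d in dirs if d in ("agonism", "antagonism")]
        aging_dir = known[0] if known else "unknown"
        rows.append(
            {"gene_id": gene, "lifespan_effect": effect, "aging_direction": aging_dir}
        )
    return pd.DataFrame(rows)


def classify_groups(
    filtered_targets: Iterable[str],
    ledger: pd.DataFrame,
    cancer_directions: Mapping[str, str],
    tsg_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Four-group lifespan-evidence classification.

    Group 1: extension evidence, anti-aging direction equals the proposed
    anti-cancer direction; Group 2: extension evidence, directions differ
    (or unknown); Group 3: shortening evidence only; Group 4: no evidence or
    no effect.  ``is_dual_purpose`` marks Group-1 genes that are not TSGs.
    Every target must appear in the ledger (effect ``none`` is allowed).
    """
    targets = list(dict.fromkeys(filtered_targets))
    resolved = _resolve_ledger(ledger).set_index("gene_id")
    missing = [g for g in targets if g not in resolved.index]
    if missing:
        raise TargetAnnotError(f"targets missing from ledger: {missing[:10]}")
    tsg = set(tsg_ids)
    rows = []
    for gene in targets:
        effect = resolved.loc[gene, "lifespan_effect"]
        aging_dir = resolved.loc[gene, "aging_direction"]
        cancer_dir = cancer_directions.get(gene, "unknown")
        if effect == "extends":
            group = 1 if (aging_dir == cancer_dir and aging_dir != "unknown") else 2
        elif effect == "shortens":
            group = 3
        else:  # none / no_effect
            group = 4
        is_tsg = gene in tsg
        rows.append(
            {
                "gene_id": gene,
                "group": group,
                "is_tsg": is_tsg,
                "is_dual_purpose": bool(group == 1 and not is_tsg),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "group", "is_tsg", "is_dual_purpose"])


def propose_dual_purpose(
    group1_genes: Iterable[str],
    tsg_ids: Iterable[str],
    n_tissues_dysregulated: Mapping[str, int] | None = None,
) -> list:
    """Group-1 genes minus TSGs, ordered by the number of aging-dysregulated
    tissues (descending) then alphabetically."""
    tsg = set(tsg_ids)
    kept = [g for g in dict.fromkeys(group1_genes) if g not in tsg]
    if not kept and list(group1_genes):
        warnings.warn("all Group-1 genes are TSGs; dual-purpose list is empty",
                      stacklevel=2)
    key = (lambda g: (-(n_tissues_dysregulated.get(g, 0)), g)) if n_tissues_dysregulated else (lambda g: g)
    return sorted(kept, key=key)
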