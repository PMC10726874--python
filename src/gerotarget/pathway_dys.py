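"""Pathway activation scoring, multi-dataset consensus, and process rollup.

A two-level hierarchy maps every pathway to exactly one parent cellular
process (27 processes by default, mirroring the top level of a Reactome-like
hierarchy).  Per comparison (one case-control dataset, or one tissue's
old-vs-young contrast) each pathway receives a signed activation score
computed from the member genes' differential expression; scores past ±0.01
mark the pathway activated/inhibited.  Per cancer, a pathway is called
dysregulated only when at least half of that cancer's datasets agree in
direction AND the arithmetic mean of the agreeing scores itself passes the
threshold.  Calls roll up to per-process activated/inhibited percentages and
to a four-category aging x cancer cross-classification.

The scorer is a transparent surrogate for topology-aware network
decomposition scoring: genes sharing a coexpression-module label are first
collapsed to their mean log-fold-change and mean significance weight, then a
weighted mean of signed logFCs is scaled into the ±0.01 threshold regime.
All constants (scale, relaxed significance weight, threshold) are explicit
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pathway",
    "PathwayCollection",
    "PathwayScore",
    "ConsensusCall",
    "pathway_activation_score",
    "consensus_direction",
    "process_summary",
    "cross_classify",
]

DEFAULT_THRESHOLD = 0.01
DEFAULT_SCALE = 0.1
DEFAULT_S_RELAX = 0.1


class PathwayError(ValueError):
    pass


@dataclass
class Pathway:
    """A gene set with optional per-gene topology weights and coexpression
    module labels, plus its single parent process."""

    pathway_id: str
    name: str
    genes: tuple
    process: str
    weights: Mapping[str, float] | None = None
    modules: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise PathwayError(f"pathway {self.pathway_id} has no genes")
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise PathwayError(f"pathway {self.pathway_id} has non-positive weights")


@dataclass
class PathwayCollection:
    pathways: dict

    def __post_init__(self) -> None:
        for pid, pw in self.pathways.items():
            if pw.pathway_id != pid:
                raise PathwayError(f"key {pid} does not match pathway id {pw.pathway_id}")

    def __getitem__(self, pid: str) -> Pathway:
        return self.pathways[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways

    def __len__(self) -> int:
        return len(self.pathways)

    @property
    def processes(self) -> list:
        return sorted({p.process for p in self.pathways.values()})

    def pathways_in_process(self, process: str) -> list:
        return [pid for pid, p in self.pathways.items() if p.process == process]

    def gene_universe(self) -> set:
        out: set = set()
        for p in self.pathways.values():
            out.update(p.genes)
        return out

    # -- plain-text serialization ------------------------------------------
    def to_gmt(self, path) -> None:
        """One pathway per line: id, description/name, member genes."""
        with open(path, "w") as fh:
            for pid, p in self.pathways.items():
                fh.write("\t".join([pid, p.name, *p.genes]) + "\n")

    def write_hierarchy(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pathway_id\tprocess_name\n")
            for pid, p in self.pathways.items():
                fh.write(f"{pid}\t{p.process}\n")

    @classmethod
    def from_gmt(cls, gmt_path, hierarchy_path) -> "PathwayCollection":
        hierarchy = pd.read_csv(hierarchy_path, sep="\t").set_index("pathway_id")[
            "process_name"
        ]
        pathways = {}
        with open(gmt_path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                pid, name, genes = parts[0], parts[1], tuple(parts[2:])
                pathways[pid] = Pathway(pid, name, genes, process=str(hierarchy[pid]))
        return cls(pathways)


@dataclass
class PathwayScore:
    pathway_id: str
    comparison_id: str
    score: float
    status: str  # activated | inhibited | none | undefined
    n_genes_used: int = 0


@dataclass
class ConsensusCall:
    pathway_id: str
    comparison: str  # cancer or tissue label
    n_datasets: int
    n_up: int
    n_down: int
    mean_score: float
    final_status: str  # activated | inhibited | none


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def pathway_activation_score(
    de_results: pd.DataFrame,
    pathway: Pathway,
    comparison_id: str = "",
    *,
    scale: float = DEFAULT_SCALE,
    s_relax: float = DEFAULT_S_RELAX,
    alpha: float = 0.05,
    threshold: float = DEFAULT_THRESHOLD,
) -> PathwayScore:
    """Signed activation score for one pathway in one comparison.

    ``de_results`` needs columns ``gene_id``, ``logfc``, ``p_value``.  Member
    genes absent from the table are ignored; if none are measured the score
    is undefined.  Significant genes (p < ``alpha``) carry full weight,
    others the relaxed weight ``s_relax``; genes sharing a coexpression
    module are collapsed to their means before averaging.
    """
    table = de_results.set_index("gene_id") if "gene_id" in de_results.columns else de_results
    present = [g for g in pathway.genes if g in table.index]
    if not present:
        return PathwayScore(pathway.pathway_id, comparison_id, float("nan"), "undefined", 0)

    logfc = table.loc[present, "logfc"].to_numpy(dtype=float)
    pvals = table.loc[present, "p_value"].to_numpy(dtype=float)
    sig = np.where(pvals < alpha, 1.0, s_relax)
    topo = np.array(
        [pathway.weights.get(g, 1.0) if pathway.weights else 1.0 for g in present]
    )

    # collapse coexpression modules to their mean logFC / mean weights
    labels = [
        pathway.modules.get(g) if pathway.modules else None for g in present
    ]
    groups: dict = {}
    for i, lab in enumerate(labels):
        key = lab if lab is not None else ("__solo__", i)
        groups.setdefault(key, []).append(i)
    g_logfc, g_sig, g_topo = [], [], []
    for idx in groups.values():
        g_logfc.append(logfc[idx].mean())
        g_sig.append(sig[idx].mean())
        g_topo.append(topo[idx].mean())
    g_logfc, g_sig, g_topo = map(np.asarray, (g_logfc, g_sig, g_topo))

    score = scale * float(np.sum(g_topo * g_sig * g_logfc) / np.sum(g_topo))
    if score > threshold:
        status = "activated"
    elif score < -threshold:
        status = "inhibited"
    else:
        status = "none"
    return PathwayScore(pathway.pathway_id, comparison_id, score, status, len(present))


def consensus_direction(
    scores: Sequence[float],
    *,
    pathway_id: str = "",
    comparison: str = "",
    threshold: float = DEFAULT_THRESHOLD,
    min_frac: float = 0.5,
) -> ConsensusCall:
    """Consensus call for one pathway across all datasets of one cancer.

    Counts datasets past ±``threshold``; a direction wins when it covers at
    least ``min_frac`` of ALL datasets and strictly beats the opposite
    direction (an exact tie is not unidirectional and yields ``none``).  The
    mean is taken over the majority-direction scores only and must itself
    pass the threshold.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise PathwayError("consensus_direction needs at least one dataset score")
    n = arr.size
    n_up = int(np.sum(arr > threshold))
    n_down = int(np.sum(arr < -threshold))

    final, mean_score = "none", float("nan")
    if n_up / n >= min_frac and n_up > n_down:
        mean_score = float(arr[arr > threshold].mean())
        if mean_score > threshold:
            final = "activated"
    elif n_down / n >= min_frac and n_down > n_up:
        mean_score = float(arr[arr < -threshold].mean())
        if mean_score < -threshold:
            final = "inhibited"
    return ConsensusCall(pathway_id, comparison, n, n_up, n_down, mean_score, final)


# ---------------------------------------------------------------------------
# rollup
# ---------------------------------------------------------------------------

def process_summary(
    consensus_calls: Iterable[ConsensusCall], collection: PathwayCollection
) -> pd.DataFrame:
    """Per process: percent of its pathways activated / inhibited.

    The denominator is the total pathway count of the process; processes with
    no dysregulated pathways report 0.
    """
    calls = list(consensus_calls)
    for c in calls:
        if c.pathway_id not in collection:
            raise PathwayError(f"unknown pathway id {c.pathway_id!r}")
    status = {c.pathway_id: c.final_status for c in calls}
    rows = []
    for process in collection.processes:
        pids = collection.pathways_in_process(process)
        total = len(pids)
        n_act = sum(status.get(pid) == "activated" for pid in pids)
        n_inh = sum(status.get(pid) == "inhibited" for pid in pids)
        rows.append(
            {
                "process_name": process,
                "percent_up": 100.0 * n_act / total if total else 0.0,
                "percent_down": 100.0 * n_inh / total if total else 0.0,
                "n_pathways_total": total,
            }
        )
    return pd.DataFrame(rows)


_CATEGORIES = {
    ("activated", "activated"): "up_up",
    ("inhibited", "inhibited"): "down_down",
    ("activated", "inhibited"): "cancer_up_aging_down",
    ("inhibited", "activated"): "cancer_down_aging_up",
}


def cross_classify(
    aging_calls: Iterable[ConsensusCall],
    cancer_calls: Iterable[ConsensusCall],
    collection: PathwayCollection,
) -> pd.DataFrame:
    """Four-category aging x cancer cross-classification per process.

    For every pathway dysregulated in BOTH comparisons, assign one of:
    up in both, down in both, up in cancer / down in aging, down in cancer /
    up in aging.  Percentages are reported against two denominators: all
    pathways of the process (``pct_*``) and the overlapped dysregulated
    pathways of the process (``pct_*_of_overlap``).
    """
    aging = {c.pathway_id: c.final_status for c in aging_calls if c.final_status != "none"}
    cancer = {c.pathway_id: c.final_status for c in cancer_calls if c.final_status != "none"}
    overlap = {
        pid: _CATEGORIES[(cancer[pid], aging[pid])]
        for pid in set(aging) & set(cancer)
    }
    rows = []
    for process in collection.processes:
        pids = collection.pathways_in_process(process)
        total = len(pids)
        in_overlap = [pid for pid in pids if pid in overlap]
        n_overlap = len(in_overlap)
        row = {
            "process_name": process,
            "n_pathways_total": total,
            "n_overlap": n_overlap,
        }
        for cat in _CATEGORIES.values():
            k = sum(overlap[pid] == cat for pid in in_overlap)
            row[f"pct_{cat}"] = 100.0 * k / total if total else 0.0
            row[f"pct_{cat}_of_overlap"] = 100.0 * k / n_overlap if n_overlap else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
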