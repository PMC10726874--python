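"""End-to-end orchestration of the dual-purpose target discovery pipeline.

``run_pipeline`` executes the stages in method order — synthetic generation,
normalization/filtering, per-tissue age-association calling, pathway
dysregulation scoring with per-cancer consensus and process rollup,
per-cancer meta-analysis and common-target prioritization, hallmark
annotation and four-group classification, GO-overlap candidate prediction,
and lifespan-assay analysis — from a single configuration, writing TSV
outputs per stage plus a machine-readable JSON report that records the
configuration and seed needed to reproduce it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    age_assoc,
    enrich_predict,
    lifespan,
    meta_rank,
    pathway_dys,
    preprocess,
    synthio,
    target_annot,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("gerotarget")

STAGES = (
    "simulate",
    "preprocess",
    "age_assoc",
    "pathways",
    "meta",
    "classify",
    "enrich",
    "lifespan",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Synthetic study conditions plus the analysis thresholds."""

    synth: synthio.SyntheticConfig = field(default_factory=synthio.SyntheticConfig)
    alpha: float = 0.05  # per-test significance for the dual criterion
    ipanda_threshold: float = 0.01  # pathway activation threshold
    consensus_frac: float = 0.5  # min fraction of agreeing datasets
    tissue_frac: float = 0.1  # min fraction of tissues for target filter
    fdr_cut: float = 0.05
    top_n: int = 100
    max_zero_fraction: float = 0.25
    pathway_scale: float = 0.1
    pathway_s_relax: float = 0.1

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, synth=replace(self.synth, seed=seed))


def load_config(path) -> PipelineConfig:
    """Read a plain-text YAML key/value config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    synth_keys = set(synthio.SyntheticConfig.__dataclass_fields__)
    pipe_keys = set(PipelineConfig.__dataclass_fields__) - {"synth"}
    unknown = set(raw) - synth_keys - pipe_keys
    if unknown:
        raise synthio.ConfigError(f"unknown config keys: {sorted(unknown)}")
    synth = synthio.SyntheticConfig(**{k: v for k, v in raw.items() if k in synth_keys})
    return PipelineConfig(
        synth=synth, **{k: v for k, v in raw.items() if k in pipe_keys}
    )


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(
    config: PipelineConfig,
    outdir,
    upto: str = "lifespan",
) -> dict:
    """Run the pipeline through stage ``upto`` (inclusive) and return the
    report dictionary (also written to ``report.json``)."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGES}")
    last = STAGES.index(upto)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.synth
    report: dict = {
        "config": {**asdict(cfg), **{k: v for k, v in asdict(config).items() if k != "synth"}},
        "seed": cfg.seed,
        "outputs": {},
    }

    # ---- simulate ---------------------------------------------------------
    truth = synthio.planted_truth(cfg)
    truth.to_json(outdir / "planted_truth.json")
    collection = synthio.generate_pathway_collection(cfg, truth)
    annotations = synthio.generate_annotations(cfg, truth)
    tissues = [synthio.generate_tissue_study(cfg, t, truth) for t in range(cfg.n_tissues)]
    cancer_sets = {
        synthio._cancer_label(c): [
            synthio.generate_cancer_dataset(cfg, c, d, truth)
            for d in range(cfg.datasets_per_cancer)
        ]
        for c in range(cfg.n_cancers)
    }
    records = synthio.generate_lifespan_assay(cfg, truth)
    collection.to_gmt(outdir / "pathways.gmt")
    collection.write_hierarchy(outdir / "pathway_hierarchy.tsv")
    _write(annotations.rank_lists, outdir / "target_rank_lists.tsv")
    _write(annotations.ledger, outdir / "evidence_ledger.tsv")
    lifespan.write_lifespan_tsv(records, outdir / "lifespan_records.tsv")
    log.info(
        "simulate: %d tissues x %d samples, %d cancers x %d datasets, %d pathways",
        cfg.n_tissues, cfg.samples_per_tissue, cfg.n_cancers,
        cfg.datasets_per_cancer, len(collection),
    )
    report["outputs"]["truth"] = str(outdir / "planted_truth.json")
    if last == 0:
        return _finish(report, outdir)

    # ---- preprocess -------------------------------------------------------
    def _norm(study):
        study = preprocess.filter_zero_coverage(study, config.max_zero_fraction)
        return preprocess.quantile_normalize(study)

    tissues = [_norm(s) for s in tissues]
    cancer_sets = {c: [_norm(s) for s in sets] for c, sets in cancer_sets.items()}
    log.info("preprocess: %d genes retained", tissues[0].matrix.shape[0])
    if last == 1:
        return _finish(report, outdir)

    # ---- age association --------------------------------------------------
    tissue_calls, tissue_de = [], {}
    for study in tissues:
        tissue = str(study.samples["tissue"].iloc[0])
        pc = age_assoc.partial_pearson_table(study)
        de = age_assoc.de_old_young(study)
        tissue_de[tissue] = de
        tissue_calls.append(age_assoc.call_age_associated(pc, de, config.alpha, tissue))
    calls = pd.concat(tissue_calls, ignore_index=True)
    _write(calls, outdir / "age_association_calls.tsv")
    n_assoc = calls.groupby("tissue")["is_age_associated"].sum()
    log.info("age_assoc: per-tissue associated gene counts %s", n_assoc.to_dict())
    report["n_age_associated_per_tissue"] = {k: int(v) for k, v in n_assoc.items()}
    try:
        tsg_res = age_assoc.tsg_enrichment_test(calls, annotations.tsg_ids)
        report["tsg_chi2"] = tsg_res.chi2
        report["tsg_p"] = tsg_res.p_value
    except age_assoc.AgeAssocError as exc:  # degenerate small configs
        log.warning("tsg test skipped: %s", exc)
    if last == 2:
        return _finish(report, outdir)

    # ---- pathway dysregulation -------------------------------------------
    def _scores(de_table, comparison):
        return [
            pathway_dys.pathway_activation_score(
                de_table, pw, comparison,
                scale=config.pathway_scale, s_relax=config.pathway_s_relax,
                alpha=config.alpha, threshold=config.ipanda_threshold,
            )
            for pw in collection.pathways.values()
        ]

    aging_consensus = {}
    for tissue, de in tissue_de.items():
        per = _scores(de, tissue)
        aging_consensus[tissue] = [
            pathway_dys.consensus_direction(
                [s.score], pathway_id=s.pathway_id, comparison=tissue,
                threshold=config.ipanda_threshold, min_frac=config.consensus_frac,
            )
            for s in per
            if np.isfinite(s.score)
        ]
    cancer_consensus, cancer_de = {}, {}
    for cancer, sets in cancer_sets.items():
        de_tables = {
            str(s.samples["dataset_id"].iloc[0]): age_assoc.de_case_control(s)
            for s in sets
        }
        cancer_de[cancer] = de_tables
        per_dataset = {ds: _scores(de, ds) for ds, de in de_tables.items()}
        cancer_consensus[cancer] = [
            pathway_dys.consensus_direction(
                [per_dataset[ds][i].score for ds in per_dataset
                 if np.isfinite(per_dataset[ds][i].score)],
                pathway_id=pid, comparison=cancer,
                threshold=config.ipanda_threshold, min_frac=config.consensus_frac,
            )
            for i, pid in enumerate(collection.pathways)
        ]
    summaries = []
    for comparison, calls_ in {**aging_consensus, **cancer_consensus}.items():
        s = pathway_dys.process_summary(calls_, collection)
        s.insert(0, "comparison", comparison)
        summaries.append(s)
    _write(pd.concat(summaries, ignore_index=True), outdir / "process_summaries.tsv")
    cross = []
    pairs = list(zip(sorted(aging_consensus), sorted(cancer_consensus)))
    for tissue, cancer in pairs:
        cc = pathway_dys.cross_classify(
            aging_consensus[tissue], cancer_consensus[cancer], collection
        )
        cc.insert(0, "pair", f"{tissue}|{cancer}")
        cross.append(cc)
    if cross:
        _write(pd.concat(cross, ignore_index=True), outdir / "cross_classification.tsv")
    log.info("pathways: %d aging and %d cancer comparisons",
             len(aging_consensus), len(cancer_consensus))
    if last == 3:
        return _finish(report, outdir)

    # ---- meta-analysis and common targets --------------------------------
    meta_tables = {
        cancer: meta_rank.meta_analyze_cancer(tables, cancer)
        for cancer, tables in cancer_de.items()
    }
    meta_all = pd.concat(meta_tables.values(), ignore_index=True)
    _write(meta_all, outdir / "meta_analysis.tsv")
    common = meta_rank.prioritize_common_targets(annotations.rank_lists, config.top_n)
    _write(common, outdir / "common_targets.tsv")
    log.info("meta: %d common-target rows across settings", len(common))
    report["n_common_target_rows"] = int(len(common))
    if last == 4:
        return _finish(report, outdir)

    # ---- hallmarks, filter, directions, groups ----------------------------
    target_genes = list(dict.fromkeys(common["gene_id"]))
    hallmarks = target_annot.map_hallmarks(
        {g: annotations.go_annotation.get(g, ()) for g in target_genes},
        annotations.hallmark_keywords,
    )
    filtered = target_annot.filter_age_associated_targets(
        target_genes, calls, hallmarks, cfg.n_tissues, config.tissue_frac
    )
    directions = {}
    for gene in filtered["gene_id"]:
        rows = meta_all[meta_all["gene_id"] == gene]
        if len(rows):
            directions[gene] = target_annot.propose_direction(
                rows, fdr_cut=config.fdr_cut
            ).cancer_direction
    groups = target_annot.classify_groups(
        filtered["gene_id"], annotations.ledger, directions, annotations.tsg_ids
    )
    merged = filtered.merge(groups, on="gene_id")
    _write(merged.assign(hallmarks=merged["hallmarks"].map(lambda h: ";".join(h))),
           outdir / "target_wheel.tsv")
    n_tissue_map = dict(
        zip(filtered["gene_id"], filtered["n_tissues_age_associated"])
    )
    dual = target_annot.propose_dual_purpose(
        groups.loc[groups["group"] == 1, "gene_id"], annotations.tsg_ids, n_tissue_map
    )
    group_sizes = groups["group"].value_counts().to_dict()
    report["group_sizes"] = {int(k): int(v) for k, v in sorted(group_sizes.items())}
    report["n_filtered_targets"] = int(len(filtered))
    report["dual_purpose_targets"] = list(dual)
    log.info("classify: %d filtered targets, groups %s, %d dual-purpose",
             len(filtered), report["group_sizes"], len(dual))
    if last == 5:
        return _finish(report, outdir)

    # ---- enrichment-based candidate prediction ----------------------------
    universe = [g for g, terms in annotations.go_annotation.items() if terms]
    by_group = {
        k: set(groups.loc[groups["group"].isin(v), "gene_id"]) & set(universe)
        for k, v in {"extenders": (1, 2), "g3": (3,), "g4": (4,)}.items()
    }
    enriched = {}
    for name, query in by_group.items():
        if query:
            tab = enrich_predict.enrich_gene_set(
                query, annotations.go_term_sets, universe, config.fdr_cut
            )
            enriched[name] = set(tab.loc[tab["enriched"], "term_id"])
            _write(tab, outdir / f"enrichment_{name}.tsv")
        else:
            enriched[name] = set()
    overlap = enrich_predict.overlap_terms(
        enriched["extenders"], enriched["g3"], enriched["g4"]
    )
    candidates = enrich_predict.candidate_genes(
        overlap, sorted(by_group["g4"]), annotations.go_term_sets
    )
    if len(candidates):
        _write(
            candidates.assign(
                supporting_terms=candidates["supporting_terms"].map(lambda t: ";".join(t))
            ),
            outdir / "candidates.tsv",
        )
    report["n_overlap_terms"] = len(overlap)
    report["candidate_genes"] = list(candidates["gene_id"]) if len(candidates) else []
    log.info("enrich: %d overlap terms, %d candidates", len(overlap), len(candidates))
    if last == 6:
        return _finish(report, outdir)

    # ---- lifespan ---------------------------------------------------------
    summary = lifespan.summarize_assay(
        records, n_bootstrap=200, rng=np.random.default_rng([cfg.seed, 30])
    )
    report["lifespan"] = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in summary.items()
    }
    log.info("lifespan: median change %.1f%%, logrank p %.3g",
             summary["median_change_percent"], summary["logrank_p"])
    return _finish(report, outdir)


def _finish(report: dict, outdir: Path) -> dict:
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    report["outputs"]["report"] = str(path)
    return report
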