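"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here at a reduced but
structurally faithful scale: healthy-tissue expression studies with linear
age and additive sex effects on a configurable fraction of genes,
case-control cancer datasets with planted differential expression shared
across a cancer's datasets, a two-level pathway hierarchy (27 parent
processes by default) with planted directional pathway effects, annotation
tables (GO terms, hallmark keywords, a tumor-suppressor list, ranked target
lists, a lifespan-evidence ledger), and Gompertz-distributed worm lifespan
assays with a configurable median shift.

The planted truth (which genes carry age slopes, which genes are
differentially expressed per cancer and with what sign, which pathways are
pushed in which direction, the true lifespan medians) is emitted alongside
the data and is never consumed by the analysis modules.  Identical
configuration and seed give byte-identical outputs.

Planted pathway directions are realised through gene membership: a planted
pathway draws most of its members from a shared "core" pool of genes that
are simultaneously age-associated (slope sign = the pathway's aging
direction) and differentially expressed in every cancer (logFC sign = the
pathway's cancer direction), so pathway-level signal emerges from the same
per-gene effects the expression generators plant.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pathway_dys import Pathway, PathwayCollection
from .preprocess import ExpressionStudy

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "AnnotationBundle",
    "ConfigError",
    "planted_truth",
    "generate_tissue_study",
    "generate_cancer_dataset",
    "generate_pathway_collection",
    "generate_annotations",
    "generate_lifespan_assay",
]


class ConfigError(ValueError):
    pass


# the 27 top-level cellular processes of a Reactome-like hierarchy
PROCESS_NAMES_27 = (
    "Cell Cycle",
    "DNA Repair",
    "DNA Replication",
    "Metabolism of RNA",
    "Protein localization",
    "Programmed Cell Death",
    "Signal Transduction",
    "Gene expression (Transcription)",
    "Chromatin organization",
    "Cellular responses to external stimuli",
    "Immune System",
    "Metabolism",
    "Metabolism of proteins",
    "Developmental Biology",
    "Extracellular matrix organization",
    "Transport of small molecules",
    "Vesicle-mediated transport",
    "Cell-Cell communication",
    "Muscle contraction",
    "Neuronal System",
    "Organelle biogenesis and maintenance",
    "Sensory Perception",
    "Reproduction",
    "Hemostasis",
    "Circadian Clock",
    "Autophagy",
    "Disease",
)

#: keyword lists linking GO term names to the 12 aging hallmarks
HALLMARK_KEYWORDS = {
    "genomic instability": ["dna repair", "dna damage", "replication fork"],
    "telomere attrition": ["telomere"],
    "epigenetic alterations": ["histone", "chromatin", "demethylase", "methylation"],
    "loss of proteostasis": ["proteasom", "protein folding", "chaperone",
                             "unfolded protein"],
    "compromised autophagy": ["autophag", "lysosome"],
    "deregulated nutrient sensing": ["insulin", "tor signaling", "nutrient",
                                     "glucose homeostasis"],
    "mitochondrial dysfunction": ["mitochondri", "oxidative phosphorylation",
                                  "respiratory chain"],
    "cellular senescence": ["senescence", "cell cycle arrest"],
    "stem cell exhaustion": ["stem cell"],
    "altered intercellular communication": ["cytokine", "cell communication",
                                            "signal release"],
    "chronic inflammation": ["inflammat", "interleukin", "immune response"],
    "dysbiosis": ["microbio", "defense response to bacterium"],
}

LIFESPAN_MODELS = ("C. elegans", "D. melanogaster", "M. musculus")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the real study design at reduced scale: dozens of
    healthy tissues with ~150 donors each sampled over ages 20-79, several
    solid cancers with a handful of case-control datasets apiece, a
    27-process pathway hierarchy, and worm lifespan assays of 90 animals
    per group in three biological repeats with a +15.8% median shift.
    """

    # healthy tissues
    n_tissues: int = 8
    samples_per_tissue: int = 150
    n_genes: int = 2000
    frac_age_associated: float = 0.2
    age_effect_size: float = 0.5  # expression units per decade of age
    frac_age_down: float = 0.6
    sex_effect_sd: float = 0.3
    noise_sd: float = 1.0
    # cancers
    n_cancers: int = 4
    datasets_per_cancer: int = 3
    cases_per_dataset: int = 40
    controls_per_dataset: int = 40
    frac_de_genes: float = 0.1
    de_logfc_mean: float = 1.0  # log2 units
    # pathways
    n_pathways: int = 135
    genes_per_pathway: int = 20
    n_processes: int = 27
    frac_pathways_planted_up: float = 0.15
    frac_pathways_planted_down: float = 0.15
    pathway_signal_frac: float = 0.7
    coexpression_modules: bool = False
    # lifespan assay
    lifespan_control_median: float = 19.0  # days
    lifespan_shift_percent: float = 15.8
    worms_per_group: int = 90
    lifespan_repeats: int = 3
    gompertz_shape: float = 0.3  # per day
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_age_associated": self.frac_age_associated,
            "frac_age_down": self.frac_age_down,
            "frac_de_genes": self.frac_de_genes,
            "frac_pathways_planted_up": self.frac_pathways_planted_up,
            "frac_pathways_planted_down": self.frac_pathways_planted_down,
            "pathway_signal_frac": self.pathway_signal_frac,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {val}")
        counts = {
            "n_tissues": self.n_tissues,
            "samples_per_tissue": self.samples_per_tissue,
            "n_genes": self.n_genes,
            "n_cancers": self.n_cancers,
            "datasets_per_cancer": self.datasets_per_cancer,
            "n_pathways": self.n_pathways,
            "genes_per_pathway": self.genes_per_pathway,
            "n_processes": self.n_processes,
            "worms_per_group": self.worms_per_group,
            "lifespan_repeats": self.lifespan_repeats,
        }
        for name, val in counts.items():
            if val <= 0:
                raise ConfigError(f"{name} must be positive, got {val}")
        if self.samples_per_tissue <= 0:
            raise ConfigError("samples_per_tissue must be positive")
        if self.cases_per_dataset < 2 or self.controls_per_dataset < 2:
            raise ConfigError("need at least 2 cases and 2 controls per dataset")
        if self.frac_pathways_planted_up + self.frac_pathways_planted_down > 1.0:
            raise ConfigError("planted pathway fractions exceed 1 in total")
        if self.n_processes > self.n_pathways:
            raise ConfigError("n_processes must not exceed n_pathways")
        if self.genes_per_pathway > self.n_genes:
            raise ConfigError("genes_per_pathway exceeds the gene universe")
        if self.lifespan_control_median <= 0:
            raise ConfigError("lifespan control median must be positive")
        if self.lifespan_shift_percent <= -100:
            raise ConfigError("lifespan shift below -100% is impossible")
        if self.gompertz_shape <= 0:
            raise ConfigError("Gompertz shape must be positive")


@dataclass
class PlantedTruth:
    """Everything that was planted, recoverable without re-running generation."""

    genes: tuple
    age_slopes: dict  # gene -> expression units per year (signed)
    de_logfc: dict  # cancer label -> {gene: signed log2 FC}
    pathway_cancer_direction: dict  # pathway id -> "up" | "down"
    pathway_aging_direction: dict  # pathway id -> "up" | "down"
    pathway_members: dict  # pathway id -> tuple of genes
    pathway_process: dict  # pathway id -> process name
    lifespan_medians: dict  # arm -> true continuous median (days)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=list)

    @property
    def age_gene_ids(self) -> set:
        return set(self.age_slopes)

    def de_gene_ids(self, cancer: str) -> set:
        return set(self.de_logfc[cancer])


@dataclass
class AnnotationBundle:
    """GO annotation, hallmark keywords, TSG list, ranked target lists, and
    the lifespan-evidence ledger."""

    go_annotation: dict  # gene -> tuple of GO term names
    go_term_sets: dict  # term name -> frozenset of genes (BP universe)
    hallmark_keywords: dict
    tsg_ids: tuple
    rank_lists: pd.DataFrame  # columns cancer, gene_id, rank, setting
    ledger: pd.DataFrame  # columns gene_id, lifespan_effect, evidence_models, aging_direction


# ---------------------------------------------------------------------------
# shared planted structure
# ---------------------------------------------------------------------------

def _gene_ids(n: int) -> tuple:
    return tuple(f"G{i:05d}" for i in range(n))


def _cancer_label(index: int) -> str:
    return f"cancer{index:02d}"


def _tissue_label(index: int) -> str:
    return f"tissue{index:02d}"


def _process_names(n: int) -> tuple:
    base = list(PROCESS_NAMES_27[:n])
    for i in range(len(base), n):
        base.append(f"Process {i + 1:02d}")
    return tuple(base)


def planted_truth(config: SyntheticConfig) -> PlantedTruth:
    """Deterministically derive all planted structure from the config."""
    rng = np.random.default_rng([config.seed, 10])
    genes = _gene_ids(config.n_genes)
    perm = rng.permutation(config.n_genes)

    # age-associated genes: exact count, fixed slope magnitude, signed
    n_age = round(config.frac_age_associated * config.n_genes)
    age_idx = perm[:n_age]
    n_down = round(config.frac_age_down * n_age)
    slope = config.age_effect_size / 10.0  # per year
    age_slopes = {}
    for j, gi in enumerate(age_idx):
        sign = -1.0 if j < n_down else 1.0
        age_slopes[genes[gi]] = sign * slope

    # shared cancer "core": a subset of age genes with fixed cancer signs,
    # common to every cancer's DE set (carries the planted pathway signal)
    n_de = round(config.frac_de_genes * config.n_genes)
    n_core = min(n_de // 2, n_age)
    # stratify the core by aging sign so both directions are represented
    # (age_idx lists down-signed genes first)
    down_part, up_part = age_idx[:n_down], age_idx[n_down:]
    k_down = min(round(config.frac_age_down * n_core), len(down_part))
    k_up = min(n_core - k_down, len(up_part))
    core_idx = np.concatenate([down_part[:k_down], up_part[:k_up]]).astype(int)
    n_core = len(core_idx)
    core_sign = rng.choice([-1.0, 1.0], size=n_core)
    core_logfc = {
        genes[gi]: s * config.de_logfc_mean for gi, s in zip(core_idx, core_sign)
    }

    # per-cancer DE sets: core plus cancer-specific extras
    core_set = set(core_idx)
    non_core = np.array([i for i in range(config.n_genes) if i not in core_set])
    de_logfc: dict = {}
    for c in range(config.n_cancers):
        crng = np.random.default_rng([config.seed, 11, c])
        extras = crng.choice(non_core, size=n_de - n_core, replace=False) if n_de > n_core else []
        table = dict(core_logfc)
        for gi in extras:
            table[genes[gi]] = crng.choice([-1.0, 1.0]) * config.de_logfc_mean
        de_logfc[_cancer_label(c)] = table

    # pathways: planted directions realised through core-gene membership
    processes = _process_names(config.n_processes)
    n_up = round(config.frac_pathways_planted_up * config.n_pathways)
    n_dn = round(config.frac_pathways_planted_down * config.n_pathways)
    pperm = rng.permutation(config.n_pathways)
    planted = {int(p): "up" for p in pperm[:n_up]}
    planted.update({int(p): "down" for p in pperm[n_up:n_up + n_dn]})

    # pools of core genes by (cancer sign, aging sign)
    pools: dict = {}
    for gi, s in zip(core_idx, core_sign):
        g = genes[gi]
        combo = ("up" if s > 0 else "down", "up" if age_slopes[g] > 0 else "down")
        pools.setdefault(combo, []).append(g)

    members: dict = {}
    cancer_dir: dict = {}
    aging_dir: dict = {}
    process_of: dict = {}
    all_idx = np.arange(config.n_genes)
    for p in range(config.n_pathways):
        pid = f"P{p:04d}"
        process_of[pid] = processes[p % config.n_processes]
        if p in planted:
            cdir = planted[p]
            adir = "up" if rng.random() < 0.5 else "down"
            pool = pools.get((cdir, adir), [])
            n_signal = min(
                round(config.pathway_signal_frac * config.genes_per_pathway),
                len(pool),
            )
            signal = list(rng.choice(pool, size=n_signal, replace=False)) if n_signal else []
            rest_pool = np.array([i for i in all_idx if genes[i] not in set(signal)])
            rest = rng.choice(
                rest_pool, size=config.genes_per_pathway - n_signal, replace=False
            )
            members[pid] = tuple(signal) + tuple(genes[i] for i in rest)
            cancer_dir[pid] = cdir
            aging_dir[pid] = adir
        else:
            chosen = rng.choice(all_idx, size=config.genes_per_pathway, replace=False)
            members[pid] = tuple(genes[i] for i in chosen)

    m0 = config.lifespan_control_median
    return PlantedTruth(
        genes=genes,
        age_slopes=age_slopes,
        de_logfc=de_logfc,
        pathway_cancer_direction=cancer_dir,
        pathway_aging_direction=aging_dir,
        pathway_members=members,
        pathway_process=process_of,
        lifespan_medians={
            "control": m0,
            "treatment": m0 * (1.0 + config.lifespan_shift_percent / 100.0),
        },
    )


# ---------------------------------------------------------------------------
# expression generators
# ---------------------------------------------------------------------------

def _base_expression(
    rng: np.random.Generator, config: SyntheticConfig, n_samples: int
) -> tuple:
    baseline = rng.normal(6.0, 1.5, config.n_genes)
    sex_eff = rng.normal(0.0, config.sex_effect_sd, config.n_genes)
    sex = rng.integers(0, 2, n_samples)
    noise = rng.normal(0.0, config.noise_sd, (config.n_genes, n_samples))
    return baseline, sex_eff, sex, noise


def generate_tissue_study(
    config: SyntheticConfig, tissue_index: int, truth: PlantedTruth | None = None
) -> ExpressionStudy:
    """One healthy tissue: ages uniform on [20, 79], sex Bernoulli(1/2),
    expression = baseline + slope*age (planted genes) + sex effect + noise."""
    if not 0 <= tissue_index < config.n_tissues:
        raise ConfigError(f"tissue_index {tissue_index} outside [0, {config.n_tissues})")
    truth = truth or planted_truth(config)
    rng = np.random.default_rng([config.seed, 21, tissue_index])
    n = config.samples_per_tissue
    ages = rng.uniform(20.0, 79.0, n)
    baseline, sex_eff, sex, noise = _base_expression(rng, config, n)
    slopes = np.array([truth.age_slopes.get(g, 0.0) for g in truth.genes])
    X = (
        baseline[:, None]
        + slopes[:, None] * ages[None, :]
        + sex_eff[:, None] * sex[None, :]
        + noise
    )
    tissue = _tissue_label(tissue_index)
    sample_ids = [f"{tissue}_s{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "sex": sex,
            "tissue": tissue,
            "condition": "healthy",
            "dataset_id": tissue,
        }
    )
    matrix = pd.DataFrame(X, index=list(truth.genes), columns=sample_ids)
    return ExpressionStudy(matrix=matrix, samples=meta, platform="rnaseq")


def generate_cancer_dataset(
    config: SyntheticConfig,
    cancer_index: int,
    dataset_index: int,
    truth: PlantedTruth | None = None,
) -> ExpressionStudy:
    """One case-control dataset: planted DE genes of the cancer are shifted
    by their (cancer-shared) logFC in the case arm."""
    if not 0 <= cancer_index < config.n_cancers:
        raise ConfigError(f"cancer_index {cancer_index} outside [0, {config.n_cancers})")
    if not 0 <= dataset_index < config.datasets_per_cancer:
        raise ConfigError(
            f"dataset_index {dataset_index} outside [0, {config.datasets_per_cancer})"
        )
    truth = truth or planted_truth(config)
    cancer = _cancer_label(cancer_index)
    rng = np.random.default_rng([config.seed, 22, cancer_index, dataset_index])
    n_cases, n_controls = config.cases_per_dataset, config.controls_per_dataset
    n = n_cases + n_controls
    ages = rng.uniform(40.0, 80.0, n)
    baseline, sex_eff, sex, noise = _base_expression(rng, config, n)
    is_case = np.zeros(n)
    is_case[n_controls:] = 1.0
    logfc = np.array([truth.de_logfc[cancer].get(g, 0.0) for g in truth.genes])
    X = (
        baseline[:, None]
        + sex_eff[:, None] * sex[None, :]
        + logfc[:, None] * is_case[None, :]
        + noise
    )
    ds = f"{cancer}_ds{dataset_index:02d}"
    sample_ids = [f"{ds}_s{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "sex": sex,
            "tissue": cancer,
            "condition": np.where(is_case == 1.0, "case", "control"),
            "dataset_id": ds,
        }
    )
    matrix = pd.DataFrame(X, index=list(truth.genes), columns=sample_ids)
    return ExpressionStudy(matrix=matrix, samples=meta, platform="rnaseq")


def generate_pathway_collection(
    config: SyntheticConfig, truth: PlantedTruth | None = None
) -> PathwayCollection:
    """The two-level pathway hierarchy matching the planted truth."""
    truth = truth or planted_truth(config)
    pathways = {}
    for pid, genes in truth.pathway_members.items():
        modules = None
        if config.coexpression_modules and pid in truth.pathway_cancer_direction:
            # planted signal genes form one coexpression module
            n_signal = round(config.pathway_signal_frac * config.genes_per_pathway)
            modules = {g: "m1" for g in genes[:n_signal]}
        pathways[pid] = Pathway(
            pathway_id=pid,
            name=f"pathway {pid}",
            genes=genes,
            process=truth.pathway_process[pid],
            modules=modules,
        )
    return PathwayCollection(pathways)


# ---------------------------------------------------------------------------
# annotations, rank lists, ledger
# ---------------------------------------------------------------------------

_HALLMARK_TERM_TEMPLATES = {
    "genomic instability": ["positive regulation of DNA repair",
                            "cellular response to DNA damage stimulus"],
    "telomere attrition": ["telomere maintenance", "telomere organization"],
    "epigenetic alterations": ["histone modification", "chromatin remodeling"],
    "loss of proteostasis": ["proteasomal protein catabolic process",
                             "chaperone-mediated protein folding"],
    "compromised autophagy": ["macroautophagy", "autophagosome assembly"],
    "deregulated nutrient sensing": ["insulin receptor signaling pathway",
                                     "cellular response to nutrient levels"],
    "mitochondrial dysfunction": ["mitochondrial respiratory chain complex assembly",
                                  "oxidative phosphorylation"],
    "cellular senescence": ["cellular senescence", "cell cycle arrest"],
    "stem cell exhaustion": ["stem cell differentiation", "stem cell division"],
    "altered intercellular communication": ["cytokine production",
                                            "cell communication"],
    "chronic inflammation": ["inflammatory response",
                             "interleukin-6 production"],
    "dysbiosis": ["defense response to bacterium",
                  "response to microbiome"],
}


def generate_annotations(
    config: SyntheticConfig, truth: PlantedTruth | None = None
) -> AnnotationBundle:
    """GO annotation + term sets, hallmark keyword map, TSG list, per-cancer
    ranked target lists (100 per novelty setting), and the evidence ledger."""
    truth = truth or planted_truth(config)
    rng = np.random.default_rng([config.seed, 23])
    genes = truth.genes
    age_set = truth.age_gene_ids

    # GO biological-process term sets: two per hallmark + one per pathway
    term_sets: dict = {}
    for hallmark, names in _HALLMARK_TERM_TEMPLATES.items():
        for name in names:
            p = np.where(np.isin(genes, list(age_set)), 0.10, 0.02)
            mask = rng.random(config.n_genes) < p
            term_sets[name] = frozenset(np.array(genes)[mask])
    for pid, members in truth.pathway_members.items():
        term_sets[f"pathway {pid} process"] = frozenset(members)
    go_annotation = {
        g: tuple(sorted(t for t, s in term_sets.items() if g in s)) for g in genes
    }

    # tumor suppressor list: ~1.3% of the genome
    n_tsg = max(10, round(0.013 * config.n_genes))
    tsg_ids = tuple(sorted(rng.choice(genes, size=n_tsg, replace=False)))

    # per-cancer ranked target lists: planted DE genes rank high
    list_len = min(100, config.n_genes)
    rows = []
    for setting in ("high_confidence", "novel"):
        for c in range(config.n_cancers):
            cancer = _cancer_label(c)
            de = sorted(truth.de_gene_ids(cancer))
            rng.shuffle(de)
            chosen = list(de[:list_len])
            if len(chosen) < list_len:
                others = [g for g in genes if g not in set(chosen)]
                fill = rng.choice(others, size=list_len - len(chosen), replace=False)
                chosen.extend(fill)
            for rank, g in enumerate(chosen, start=1):
                rows.append(
                    {"cancer": cancer, "gene_id": g, "rank": rank, "setting": setting}
                )
    rank_lists = pd.DataFrame(rows)

    # lifespan-evidence ledger over every gene seen in a rank list
    ledger_genes = sorted(set(rank_lists["gene_id"]))
    effects = rng.choice(
        ["extends", "shortens", "no_effect", "none"],
        size=len(ledger_genes),
        p=[0.17, 0.10, 0.06, 0.67],
    )
    lrows = []
    for g, eff in zip(ledger_genes, effects):
        if eff == "none":
            models, direction = "", "unknown"
        else:
            k = int(rng.integers(1, len(LIFESPAN_MODELS) + 1))
            models = ";".join(sorted(rng.choice(LIFESPAN_MODELS, size=k, replace=False)))
            direction = (
                str(rng.choice(["agonism", "antagonism"]))
                if eff in ("extends", "shortens")
                else "unknown"
            )
        lrows.append(
            {
                "gene_id": g,
                "lifespan_effect": eff,
                "evidence_models": models,
                "aging_direction": direction,
            }
        )
    ledger = pd.DataFrame(lrows)

    return AnnotationBundle(
        go_annotation=go_annotation,
        go_term_sets=term_sets,
        hallmark_keywords=dict(HALLMARK_KEYWORDS),
        tsg_ids=tsg_ids,
        rank_lists=rank_lists,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# lifespan assay
# ---------------------------------------------------------------------------

def _gompertz_days(
    rng: np.random.Generator, median: float, shape: float, size: int
) -> np.ndarray:
    """Death times from a Gompertz law with the given shape, rate solved so
    the continuous median equals ``median``."""
    rate = shape * np.log(2.0) / np.expm1(shape * median)
    u = rng.random(size)
    return np.log1p(-(shape / rate) * np.log(u)) / shape


def generate_lifespan_assay(
    config: SyntheticConfig, truth: PlantedTruth | None = None
) -> pd.DataFrame:
    """Two-arm worm lifespan assay records (control vs treatment), with the
    treated median shifted by ``lifespan_shift_percent``.

    Returns the records table consumed by the lifespan module: one row per
    animal with arm, biological repeat, death day, and event flag (all
    deaths observed).
    """
    truth = truth or planted_truth(config)
    rng = np.random.default_rng([config.seed, 24])
    rows = []
    for arm in ("control", "treatment"):
        median = truth.lifespan_medians[arm]
        for rep in range(1, config.lifespan_repeats + 1):
            days = _gompertz_days(rng, median, config.gompertz_shape, config.worms_per_group)
            for i, day in enumerate(days):
                rows.append(
                    {
                        "animal_id": f"{arm[:1]}{rep}_{i:03d}",
                        "arm": arm,
                        "repeat_id": rep,
                        "day": float(day),
                        "event": 1,
                    }
                )
    return pd.DataFrame(rows)
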