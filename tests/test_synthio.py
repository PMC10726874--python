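"""Generator contracts: determinism, planted counts, and calibration."""

import numpy as np
import pandas as pd
import pytest

from gerotarget import synthio
from gerotarget.synthio import ConfigError, SyntheticConfig, planted_truth


class TestPlantedCounts:
    def test_age_gene_count_is_round_frac_times_genes(self):
        cfg = SyntheticConfig(n_genes=500, frac_age_associated=0.2)
        truth = planted_truth(cfg)
        assert len(truth.age_slopes) == 100

    def test_zero_fraction_plants_no_age_genes(self):
        cfg = SyntheticConfig(frac_age_associated=0.0)
        assert planted_truth(cfg).age_slopes == {}

    def test_de_gene_count_per_cancer(self):
        cfg = SyntheticConfig(n_genes=1000, frac_de_genes=0.1)
        truth = planted_truth(cfg)
        for cancer in truth.de_logfc:
            assert len(truth.de_logfc[cancer]) == 100

    def test_age_down_fraction(self):
        cfg = SyntheticConfig(n_genes=1000, frac_age_associated=0.3, frac_age_down=0.6)
        slopes = np.array(list(planted_truth(cfg).age_slopes.values()))
        assert (slopes < 0).sum() == round(0.6 * 300)

    def test_planted_ids_exist_in_matrices(self, small_config, small_truth):
        study = synthio.generate_tissue_study(small_config, 0, small_truth)
        assert small_truth.age_gene_ids <= set(study.gene_ids)
        for cancer, table in small_truth.de_logfc.items():
            assert set(table) <= set(small_truth.genes)


class TestDeterminism:
    def test_tissue_study_reproducible(self, small_config):
        a = synthio.generate_tissue_study(small_config, 0)
        b = synthio.generate_tissue_study(small_config, 0)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_different_tissues_differ(self, small_config):
        a = synthio.generate_tissue_study(small_config, 0)
        b = synthio.generate_tissue_study(small_config, 1)
        assert not np.allclose(a.matrix.to_numpy(), b.matrix.to_numpy())

    def test_lifespan_and_annotations_reproducible(self, small_config):
        r1 = synthio.generate_lifespan_assay(small_config)
        r2 = synthio.generate_lifespan_assay(small_config)
        pd.testing.assert_frame_equal(r1, r2)
        a1 = synthio.generate_annotations(small_config)
        a2 = synthio.generate_annotations(small_config)
        pd.testing.assert_frame_equal(a1.rank_lists, a2.rank_lists)
        assert a1.go_annotation == a2.go_annotation


class TestTissueStudy:
    def test_no_age_effect_when_fraction_zero(self):
        cfg = SyntheticConfig(frac_age_associated=0.0, n_genes=200,
                              samples_per_tissue=50)
        truth = planted_truth(cfg)
        assert not truth.age_slopes
        study = synthio.generate_tissue_study(cfg, 0, truth)
        assert study.matrix.shape == (200, 50)

    def test_age_range_and_sex_coding(self, small_config):
        study = synthio.generate_tissue_study(small_config, 0)
        assert study.samples["age"].between(20, 79).all()
        assert set(study.samples["sex"]) <= {0, 1}

    def test_planted_slope_recoverable_by_regression(self):
        cfg = SyntheticConfig(n_genes=100, samples_per_tissue=4000, noise_sd=0.3,
                              frac_age_associated=0.2, seed=3)
        truth = planted_truth(cfg)
        study = synthio.generate_tissue_study(cfg, 0, truth)
        gene, slope = next(iter(truth.age_slopes.items()))
        y = study.matrix.loc[gene].to_numpy()
        age = study.samples["age"].to_numpy()
        fitted = np.polyfit(age, y, 1)[0]
        assert fitted == pytest.approx(slope, abs=0.01)


class TestCancerDataset:
    def test_condition_labels_and_arm_sizes(self, small_config):
        ds = synthio.generate_cancer_dataset(small_config, 0, 0)
        counts = ds.samples["condition"].value_counts()
        assert counts["case"] == small_config.cases_per_dataset
        assert counts["control"] == small_config.controls_per_dataset

    def test_planted_sign_shared_across_datasets(self, small_config, small_truth):
        """The same (cancer, gene) keeps one planted sign in every dataset."""
        cancer = "cancer00"
        table = small_truth.de_logfc[cancer]
        gene = next(iter(table))
        diffs = []
        for d in range(small_config.datasets_per_cancer):
            ds = synthio.generate_cancer_dataset(small_config, 0, d, small_truth)
            case = ds.samples["condition"] == "case"
            y = ds.matrix.loc[gene].to_numpy()
            diffs.append(y[case.to_numpy()].mean() - y[(~case).to_numpy()].mean())
        assert all(np.sign(d) == np.sign(table[gene]) for d in diffs)

    def test_null_config_arms_exchangeable(self):
        cfg = SyntheticConfig(frac_de_genes=0.0, de_logfc_mean=0.0, n_genes=300,
                              cases_per_dataset=60, controls_per_dataset=60, seed=5)
        truth = planted_truth(cfg)
        assert truth.de_logfc["cancer00"] == {}
        ds = synthio.generate_cancer_dataset(cfg, 0, 0, truth)
        case = (ds.samples["condition"] == "case").to_numpy()
        X = ds.matrix.to_numpy()
        delta = X[:, case].mean() - X[:, ~case].mean()
        assert abs(delta) < 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(cases_per_dataset=1)


class TestPathwayCollection:
    def test_27_distinct_processes_by_default(self):
        cfg = SyntheticConfig(n_genes=600, n_pathways=54, genes_per_pathway=10)
        coll = synthio.generate_pathway_collection(cfg)
        assert len(coll.processes) == 27

    def test_membership_within_universe_and_nonempty(self, small_config):
        coll = synthio.generate_pathway_collection(small_config)
        genes = set(synthio.planted_truth(small_config).genes)
        for p in coll.pathways.values():
            assert len(p.genes) >= 1
            assert set(p.genes) <= genes

    def test_each_pathway_has_one_parent(self, small_config):
        coll = synthio.generate_pathway_collection(small_config)
        for p in coll.pathways.values():
            assert isinstance(p.process, str) and p.process

    def test_gmt_roundtrip(self, small_config, tmp_path):
        coll = synthio.generate_pathway_collection(small_config)
        coll.to_gmt(tmp_path / "p.gmt")
        coll.write_hierarchy(tmp_path / "h.tsv")
        back = type(coll).from_gmt(tmp_path / "p.gmt", tmp_path / "h.tsv")
        assert set(back.pathways) == set(coll.pathways)
        pid = next(iter(coll.pathways))
        assert back[pid].genes == coll[pid].genes
        assert back[pid].process == coll[pid].process


class TestAnnotations:
    def test_hallmark_map_has_12_keys(self, small_config):
        ann = synthio.generate_annotations(small_config)
        assert len(ann.hallmark_keywords) == 12

    def test_rank_lists_unique_genes_ranks_1_to_100(self, small_config):
        ann = synthio.generate_annotations(small_config)
        for (cancer, setting), lst in ann.rank_lists.groupby(["cancer", "setting"]):
            assert lst["gene_id"].is_unique
            assert sorted(lst["rank"]) == list(range(1, len(lst) + 1))
            assert len(lst) == 100

    def test_ledger_labels_and_model_consistency(self, small_config):
        ann = synthio.generate_annotations(small_config)
        assert set(ann.ledger["lifespan_effect"]) <= {
            "extends", "shortens", "no_effect", "none"
        }
        none_rows = ann.ledger[ann.ledger["lifespan_effect"] == "none"]
        assert (none_rows["evidence_models"] == "").all()


class TestLifespanAssay:
    def test_group_sizes_90_by_3_gives_270_per_arm(self):
        cfg = SyntheticConfig()  # defaults: 90 worms/group, 3 repeats
        rec = synthio.generate_lifespan_assay(cfg)
        assert (rec["arm"] == "control").sum() == 270
        assert (rec["arm"] == "treatment").sum() == 270
        assert (rec["day"] > 0).all()

    def test_zero_shift_arms_from_identical_law(self):
        cfg = SyntheticConfig(lifespan_shift_percent=0.0)
        truth = planted_truth(cfg)
        assert truth.lifespan_medians["control"] == truth.lifespan_medians["treatment"]

    def test_large_n_median_ratio_matches_planted_shift(self):
        """+15.8% planted shift: empirical median ratio within 2% of 1.158."""
        cfg = SyntheticConfig(worms_per_group=5000, lifespan_repeats=2,
                              lifespan_shift_percent=15.8, seed=17)
        rec = synthio.generate_lifespan_assay(cfg)
        med = rec.groupby("arm")["day"].median()
        ratio = med["treatment"] / med["control"]
        assert ratio == pytest.approx(1.158, rel=0.02)

    def test_impossible_shift_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(lifespan_shift_percent=-120.0)
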