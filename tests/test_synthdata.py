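"""Synthetic 450K-style generator: structure, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

from methylgsz.dataset import CELL_TYPES, DataError
from methylgsz.genesets import GeneSetCollection
from methylgsz.preprocess import beta_to_m, m_to_beta
from methylgsz.synthdata import (SynthConfig, generate_annotation,
                                 generate_dataset, generate_genesets)

SMALL = dict(n_probes=500, n_genes=120, n_sets=10, set_size_range=(5, 12),
             planted_cpg_ids=(3, 40), planted_set_name="set_0001")


class TestConfigValidation:
    def test_rejects_bad_configs(self):
        with pytest.raises(DataError):
            SynthConfig(n_samples=10, n_smokers=10)
        with pytest.raises(DataError):
            SynthConfig(frac_intergenic=1.2)
        with pytest.raises(DataError):
            SynthConfig(set_size_range=(1, 5))
        with pytest.raises(DataError):
            SynthConfig(n_probes=100, planted_cpg_ids=(100,))


class TestAnnotation:
    def test_all_intergenic_when_forced(self):
        cfg = SynthConfig(**{**SMALL, "frac_intergenic": 1.0, "n_genes": 1,
                             "planted_set_name": None})
        ann = generate_annotation(cfg)
        assert (ann.table["gene_names"] == "").all()
        assert (ann.table["island_relation"] == "OpenSea").all()

    def test_single_gene_is_annotated(self):
        cfg = SynthConfig(**{**SMALL, "n_genes": 1, "frac_intergenic": 0.5,
                             "planted_set_name": None})
        ann = generate_annotation(cfg)
        genic = ann.table["gene_names"] != ""
        assert genic.sum() >= 1
        assert set(g for f in ann.table.loc[genic, "gene_names"]
                   for g in f.split(";")) == {"GENE00001"}

    def test_intergenic_probes_are_open_sea(self):
        ann = generate_annotation(SynthConfig(**SMALL))
        inter = ann.table["gene_names"] == ""
        assert (ann.table.loc[inter, "island_relation"] == "OpenSea").all()

    def test_autosomes_only_and_parallel_region_fields(self):
        ann = generate_annotation(SynthConfig(**SMALL))
        assert ann.table["chromosome"].astype(int).between(1, 22).all()
        for _, row in ann.table.iterrows():
            genes = [g for g in row["gene_names"].split(";") if g]
            groups = [g for g in row["gene_region_groups"].split(";") if g]
            assert len(genes) == len(groups)

    def test_seeded_annotation_identical(self, tmp_path):
        cfg = SynthConfig(**SMALL)
        a, b = generate_annotation(cfg), generate_annotation(cfg)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.write_tsv(pa), b.write_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestGeneSets:
    def test_fixed_size_sets(self):
        cfg = SynthConfig(**{**SMALL, "set_size_range": (5, 5), "n_sets": 3,
                             "planted_set_name": None})
        ann = generate_annotation(cfg)
        sets = generate_genesets(cfg, ann)
        assert len(sets) == 3
        assert all(len(m) == 5 for _, m in sets)

    def test_gmt_round_trip_and_determinism(self, tmp_path):
        cfg = SynthConfig(**SMALL)
        ann = generate_annotation(cfg)
        p1, p2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        s1 = generate_genesets(cfg, ann, gmt_path=p1)
        generate_genesets(cfg, ann, gmt_path=p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = GeneSetCollection.read_gmt(p1)
        assert back.sets == s1.sets

    def test_universe_too_small_rejected(self):
        cfg = SynthConfig(**{**SMALL, "n_genes": 4, "set_size_range": (5, 40),
                             "planted_set_name": None})
        ann = generate_annotation(cfg)
        with pytest.raises(DataError):
            generate_genesets(cfg, ann)


class TestDataset:
    def test_beta_strictly_inside_unit_interval_and_round_trip(self):
        ds, _, _ = generate_dataset(SynthConfig(**SMALL))
        vals = ds.beta.to_numpy()
        assert ((vals > 0) & (vals < 1)).all()
        assert np.allclose(m_to_beta(beta_to_m(vals)), vals, rtol=1e-10)

    def test_cell_proportions_valid(self):
        ds, _, _ = generate_dataset(SynthConfig(**SMALL))
        props = ds.sample_sheet.table[list(CELL_TYPES)].to_numpy()
        assert (props >= 0).all()
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_smoker_count_and_missingness(self):
        cfg = SynthConfig(**SMALL)
        ds, _, _ = generate_dataset(cfg)
        sheet = ds.sample_sheet.table
        assert sheet["smoking"].sum() == cfg.n_smokers
        expected_missing = round(cfg.missing_covariate_rate * cfg.n_samples)
        assert sheet["alcohol"].isna().sum() == expected_missing
        assert sheet["ses"].isna().sum() == expected_missing

    def test_zeroed_plants_give_zero_truth(self):
        cfg = SynthConfig(**{**SMALL, "planted_cpg_ids": (),
                             "planted_set_name": None})
        _, _, truth = generate_dataset(cfg)
        assert (truth.true_effect == 0).all()
        assert truth.causal_probe_ids == [] and truth.causal_set_names == []

    def test_noiseless_plant_is_exact_group_difference(self):
        cfg = SynthConfig(**{**SMALL, "planted_cpg_ids": (3,),
                             "planted_cpg_delta_m": 0.7,
                             "planted_set_name": None, "noise_sd_m": 0.0,
                             "age_effect_sd": 0.0, "sex_effect_sd": 0.0,
                             "cell_effect_sd": 0.0, "chip_effect_sd": 0.0})
        ds, _, _ = generate_dataset(cfg)
        m = beta_to_m(ds.beta.loc["cg00000003"].to_numpy())
        smoke = ds.sample_sheet.table["smoking"].to_numpy() == 1
        assert m[smoke].mean() - m[~smoke].mean() == pytest.approx(0.7, abs=1e-9)

    def test_planted_set_members_carry_effect(self):
        cfg = SynthConfig(**SMALL)
        ds, _, truth = generate_dataset(cfg)
        sets = generate_genesets(cfg, ds.annotation)
        members = set(sets.sets[cfg.planted_set_name])
        ann = ds.probe_annotation()
        in_set = ann["gene_names"].map(
            lambda f: any(g in members for g in f.split(";") if g))
        effects = truth.true_effect[in_set.to_numpy()]
        assert (effects >= cfg.planted_set_delta_m - 1e-12).all()

    def test_unknown_planted_set_rejected(self):
        cfg = SynthConfig(**{**SMALL, "planted_set_name": "no_such_set"})
        with pytest.raises(DataError):
            generate_dataset(cfg)

    def test_full_determinism(self):
        cfg = SynthConfig(**SMALL)
        d1, c1, t1 = generate_dataset(cfg)
        d2, c2, t2 = generate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.beta, d2.beta)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(t1.true_effect, t2.true_effect)

    def test_seed_changes_data(self):
        d1, _, _ = generate_dataset(SynthConfig(**SMALL, seed=1))
        d2, _, _ = generate_dataset(SynthConfig(**SMALL, seed=2))
        assert not d1.beta.equals(d2.beta)

    def test_island_relation_baselines_ordered(self):
        """Islands are hypomethylated, open sea hypermethylated by design."""
        ds, _, _ = generate_dataset(SynthConfig(n_probes=4000, n_genes=800,
                                                n_sets=10, set_size_range=(5, 10),
                                                planted_cpg_ids=(),
                                                planted_set_name=None, seed=5))
        rel = ds.probe_annotation()["island_relation"]
        mean_beta = ds.beta.mean(axis=1)
        assert mean_beta[rel == "Island"].mean() < 0.35
        assert mean_beta[rel == "OpenSea"].mean() > 0.55
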