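import numpy as np
import pandas as pd
import pytest

from sedadna.simulate import (
    MAMMAL_MARKER,
    PLANT_MARKER,
    TABLE1_TOTAL_DIVERSITY,
    StudyConfig,
    generate_climate,
    generate_diversity_response,
    generate_meta,
    generate_predictors,
    generate_read_tables,
    generate_reference_library,
    homopolymer_variant,
    simulate_study,
)
from sedadna.tables import ValidationError, validate_meta
from sedadna.filters import run_length_compress


def _tiny(**kw):
    base = dict(
        n_lakes=2,
        samples_per_lake=6,
        n_plant_taxa=8,
        n_mammal_taxa=4,
        reads_per_replicate_mean=120.0,
        mammal_reads_per_replicate_mean=60.0,
        control_reads_mean=40.0,
        seed=1,
    )
    base.update(kw)
    return StudyConfig(**base)


class TestConfig:
    def test_probability_bounds_validated(self):
        with pytest.raises(ValidationError, match="replicate_dropout_prob"):
            _tiny(replicate_dropout_prob=1.5)
        with pytest.raises(ValidationError, match="contamination rate"):
            _tiny(contamination_rate_per_taxon={"Bos taurus": 2.0})

    def test_stream_rngs_independent(self):
        cfg = _tiny()
        a = cfg.rng(1).integers(0, 1 << 31, size=5)
        b = cfg.rng(2).integers(0, 1 << 31, size=5)
        assert not np.array_equal(a, b)
        assert np.array_equal(a, cfg.rng(1).integers(0, 1 << 31, size=5))


class TestReferenceLibrary:
    def test_taxon_count_and_libraries(self):
        panel = generate_reference_library(_tiny(n_plant_taxa=5, n_mammal_taxa=2))
        assert len(panel.plant_taxa) == 5
        assert len(panel.mammal_taxa) == 2
        assert len(panel.plant_libraries) == 4
        assert {l.name for l in panel.plant_libraries} == {
            "PhyloAlps", "ArctBorBryo", "PhyloNorway", "EMBL",
        }

    def test_seed_determinism(self):
        p1 = generate_reference_library(_tiny())
        p2 = generate_reference_library(_tiny())
        assert p1.plant_sequences == p2.plant_sequences
        assert p1.mammal_sequences == p2.mammal_sequences
        assert p1.taxonomy_frame.equals(p2.taxonomy_frame)

    def test_duplicated_taxon_across_libraries_same_label_distinct_rank(self):
        panel = generate_reference_library(_tiny())
        top = dict(panel.plant_libraries[0].records)
        embl = panel.plant_libraries[3]
        shared = [t for t, s in embl.records if t in top and top[t] == s]
        assert shared  # overlap exists
        assert embl.priority_rank != panel.plant_libraries[0].priority_rank


class TestReadTables:
    def test_contamination_rate_binomial(self):
        cfg = _tiny(
            n_lakes=1,
            samples_per_lake=2,
            n_mammal_taxa=8,
            control_counts={"C1": 50, "C2": 50},
            contamination_rate_per_taxon={"Bos taurus": 0.05},
            seed=5,
        )
        tables, meta, truth = generate_read_tables(cfg)
        panel = generate_reference_library(cfg)
        vid = f"mv{panel.mammal_taxa.index('Bos taurus'):04d}"
        c = tables[MAMMAL_MARKER].counts
        controls = set(meta.loc[meta["sample_type"] != "sediment", "sample_id"])
        hits = c[(c["variant_id"] == vid) & c["sample_id"].isin(controls)][
            "sample_id"
        ].nunique()
        # binomial(100, 0.05): wide tolerance, no seed tuning
        assert 0 <= hits <= 15

    def test_full_dropout_and_no_contamination_empties_sediments(self):
        cfg = _tiny(
            replicate_dropout_prob=1.0,
            contamination_rate_per_taxon={},
        )
        tables, meta, _ = generate_read_tables(cfg)
        sed = set(meta.loc[meta["sample_type"] == "sediment", "sample_id"])
        c = tables[PLANT_MARKER].counts
        assert c[c["sample_id"].isin(sed)].empty

    def test_zero_read_means_give_empty_tables_valid_meta(self):
        cfg = _tiny(
            reads_per_replicate_mean=0.0,
            mammal_reads_per_replicate_mean=0.0,
            control_reads_mean=0.0,
            contamination_rate_per_taxon={},
        )
        tables, meta, _ = generate_read_tables(cfg)
        assert tables[PLANT_MARKER].counts.empty
        assert tables[MAMMAL_MARKER].counts.empty
        validate_meta(meta)

    def test_read_conservation(self):
        cfg = _tiny()
        tables, _, truth = generate_read_tables(cfg)
        for marker in (PLANT_MARKER, MAMMAL_MARKER):
            assert tables[marker].total_reads == truth.reads_generated[marker]

    def test_determinism(self):
        t1, m1, _ = generate_read_tables(_tiny())
        t2, m2, _ = generate_read_tables(_tiny())
        assert t1[PLANT_MARKER].equals(t2[PLANT_MARKER])
        assert t1[MAMMAL_MARKER].equals(t2[MAMMAL_MARKER])
        assert m1.equals(m2)

    def test_error_variants_share_compressed_form(self):
        panel = generate_reference_library(_tiny())
        for t, seq in panel.plant_sequences.items():
            assert run_length_compress(homopolymer_variant(seq)) == \
                run_length_compress(seq)
            assert homopolymer_variant(seq) != seq

    def test_controls_contain_no_community_taxa(self):
        cfg = _tiny()
        tables, meta, _ = generate_read_tables(cfg)
        controls = set(meta.loc[meta["sample_type"] != "sediment", "sample_id"])
        c = tables[PLANT_MARKER].counts
        ctl = c[c["sample_id"].isin(controls)]
        community_vids = {f"pv{i:04d}" for i in range(cfg.n_plant_taxa)}
        assert not set(ctl["variant_id"]) & community_vids


class TestClimate:
    def test_offsets_reflected_in_lake_means(self):
        cfg = _tiny(n_lakes=2)
        clim = generate_climate(
            cfg,
            lake_offsets={"Lake01": (0.0, 0.0), "Lake02": (2.0, 0.0)},
            noise_sd=(0.0, 0.0),
        )
        means = clim.groupby("lake_id")["tjul_C"].mean()
        assert means["Lake02"] - means["Lake01"] == pytest.approx(2.0)

    def test_constant_trend_zero_noise_no_within_variation(self):
        cfg = _tiny(n_lakes=2)
        clim = generate_climate(
            cfg,
            lake_offsets={"Lake01": (0.0, 0.0), "Lake02": (1.0, 10.0)},
            temperature_trend=lambda t: np.full_like(t, 10.0),
            precipitation_trend=lambda t: np.full_like(t, 900.0),
            noise_sd=(0.0, 0.0),
        )
        assert clim.groupby("lake_id")["tjul_C"].std().max() == pytest.approx(0.0)

    def test_grid_and_determinism(self):
        cfg = _tiny()
        c1, c2 = generate_climate(cfg), generate_climate(cfg)
        assert c1.equals(c2)
        steps = np.diff(sorted(c1["time_ka"].unique()))
        assert np.allclose(steps, 0.1)
        assert c1["time_ka"].min() == 0.0
        assert c1["time_ka"].max() >= cfg.max_age_ka - 0.1


class TestDiversityResponse:
    def test_null_model_constant(self):
        cfg = _tiny()
        _, meta, truth = generate_read_tables(cfg)
        truth.true_coefficients = {}
        truth.residual_sd = 0.0
        truth.random_intercept_sd = 0.0
        pred = generate_predictors(cfg, meta)
        y = generate_diversity_response(truth, pred)
        assert np.allclose(y, truth.intercept)

    def test_single_coefficient_within_lake_differences(self):
        cfg = _tiny()
        _, meta, truth = generate_read_tables(cfg)
        truth.true_coefficients = {"cattle": 26.3}
        truth.residual_sd = 0.0
        pred = generate_predictors(cfg, meta)
        y = generate_diversity_response(truth, pred)
        one_lake = pred[pred["lake_id"] == "Lake01"].index
        i, j = one_lake[0], one_lake[1]
        assert y[i] - y[j] == pytest.approx(
            26.3 * (pred.loc[i, "cattle"] - pred.loc[j, "cattle"])
        )

    def test_residual_sd_recovered(self):
        cfg = _tiny(n_lakes=4, samples_per_lake=250)
        meta = generate_meta(cfg, cfg.rng(1))
        _, _, truth = generate_read_tables(_tiny())
        truth.true_coefficients = {}
        truth.residual_sd = 8.0
        truth.random_intercept_sd = 0.0
        pred = generate_predictors(cfg, meta)
        y = generate_diversity_response(truth, pred)
        assert np.std(y) == pytest.approx(8.0, rel=0.10)

    def test_missing_predictor_names_sample(self):
        cfg = _tiny()
        _, meta, truth = generate_read_tables(cfg)
        pred = generate_predictors(cfg, meta)
        pred.loc[pred.index[2], "cattle"] = np.nan
        bad_sample = pred.loc[pred.index[2], "sample_id"]
        with pytest.raises(ValidationError, match=str(bad_sample)):
            generate_diversity_response(truth, pred)


class TestStudyBundle:
    def test_simulate_study_consistent(self, small_study):
        study = small_study
        assert set(study.tables) == {PLANT_MARKER, MAMMAL_MARKER}
        validate_meta(study.meta)
        assert study.truth.true_contaminants == set(study.panel.contaminant_taxa)
        # table 1 coefficients are the default truth
        assert study.truth.true_coefficients == TABLE1_TOTAL_DIVERSITY

    def test_table1_row(self):
        assert TABLE1_TOTAL_DIVERSITY["temperature"] == pytest.approx(-5.99)
        assert TABLE1_TOTAL_DIVERSITY["cattle"] == pytest.approx(26.3)
        assert "horse" not in TABLE1_TOTAL_DIVERSITY
        assert "mountain_hare" not in TABLE1_TOTAL_DIVERSITY
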