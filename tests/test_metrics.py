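import numpy as np
import pandas as pd
import pytest

from sedadna.metrics import (
    aggregate_groups,
    build_taxon_sample_matrix,
    compute_rai,
    compute_wtrep,
    hill_n0,
    scale_rai,
    validate_annotations,
)
from sedadna.tables import ValidationError

from conftest import make_table


def _matrix(counts, n_replicates=8):
    return build_taxon_sample_matrix(make_table(counts, n_replicates=n_replicates))


class TestWtRep:
    def test_sole_occupant_all_replicates(self):
        counts = {("S1", r, "T"): 10 for r in range(1, 9)}
        m = compute_wtrep(make_table(counts))
        row = m.iloc[0]
        assert row["wtrep"] == pytest.approx(8.0)
        assert row["wtrep_prop"] == pytest.approx(1.0)

    def test_absent_taxon_absent_row(self):
        m = compute_wtrep(make_table({("S1", 1, "T"): 5}))
        assert set(m["taxon"]) == {"T"}

    def test_hand_summed_half_proportions(self):
        # T holds 50% of reads in 4 of 8 replicates, absent otherwise
        counts = {}
        for r in range(1, 5):
            counts[("S1", r, "T")] = 10
            counts[("S1", r, "U")] = 10
        for r in range(5, 9):
            counts[("S1", r, "U")] = 10
        m = compute_wtrep(make_table(counts)).set_index("taxon")
        assert m.loc["T", "wtrep"] == pytest.approx(2.0)
        assert m.loc["T", "wtrep_prop"] == pytest.approx(0.25)


class TestRai:
    def test_sole_taxon_everywhere_gives_one(self):
        counts = {("S1", r, "T"): 7 for r in range(1, 9)}
        m = _matrix(counts)
        assert m.iloc[0]["rai"] == pytest.approx(1.0)

    def test_product_of_factors(self):
        # read proportion 0.5, wtrep_prop 0.25 -> RAI 0.125
        counts = {}
        for r in range(1, 5):
            counts[("S1", r, "T")] = 10
            counts[("S1", r, "U")] = 10
        for r in range(5, 9):
            counts[("S1", r, "U")] = 10
        m = _matrix(counts).set_index("taxon")
        # T: reads 40/120 ... recompute: sample total = 40 + 80 = 120
        assert m.loc["T", "rai"] == pytest.approx((40 / 120) * 0.25)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        counts = {
            ("S1", int(rng.integers(1, 9)), f"T{i % 5}"): int(rng.integers(1, 40))
            for i in range(25)
        }
        m1 = _matrix(counts)
        m2 = _matrix({k: 7 * v for k, v in counts.items()})
        merged = m1.merge(m2, on=["taxon", "sample_id"], suffixes=("_1", "_2"))
        assert np.allclose(merged["rai_1"], merged["rai_2"])
        assert np.allclose(merged["wtrep_1"], merged["wtrep_2"])

    def test_bounds(self):
        rng = np.random.default_rng(5)
        counts = {
            (f"S{rng.integers(4)}", int(rng.integers(1, 9)), f"T{i % 7}"):
                int(rng.integers(1, 60))
            for i in range(60)
        }
        m = _matrix(counts)
        assert ((m["wtrep_prop"] >= 0) & (m["wtrep_prop"] <= 1)).all()
        assert ((m["rai"] >= 0) & (m["rai"] <= 1)).all()


class TestScaleRai:
    def test_symmetric_pair(self):
        counts = {("S1", 1, "A"): 10, ("S1", 2, "B"): 10}
        scaled = scale_rai(_matrix(counts), {"A", "B"}).set_index("taxon")
        assert scaled.loc["A", "rai_scaled"] == pytest.approx(0.5)
        assert scaled.loc["B", "rai_scaled"] == pytest.approx(0.5)

    def test_singleton_group(self):
        counts = {("S1", 1, "A"): 10, ("S1", 2, "B"): 10}
        scaled = scale_rai(_matrix(counts), {"A"}).set_index("taxon")
        assert scaled.loc["A", "rai_scaled"] == pytest.approx(1.0)
        assert np.isnan(scaled.loc["B", "rai_scaled"])

    def test_sums_to_one_random(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            counts = {
                (f"S{rng.integers(4)}", int(rng.integers(1, 9)), f"T{i % 8}"):
                    int(rng.integers(1, 60))
                for i in range(40)
            }
            m = _matrix(counts)
            group = set(m["taxon"].unique()[: 4])
            scaled = scale_rai(m, group)
            sums = (
                scaled[scaled["taxon"].isin(group)]
                .groupby("sample_id")["rai_scaled"].sum()
            )
            for s, total in sums.items():
                group_rai = m[(m["sample_id"] == s) & m["taxon"].isin(group)][
                    "rai"
                ].sum()
                if group_rai > 0:
                    assert total == pytest.approx(1.0, abs=1e-9)
                else:
                    assert total == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            scale_rai(_matrix({("S1", 1, "A"): 5}), set())


class TestHillN0:
    def test_count_definition(self):
        counts = {("S1", 1, "A"): 5, ("S1", 2, "B"): 5, ("S1", 1, "C"): 5}
        assert hill_n0(_matrix(counts), sample_id="S1") == 3

    def test_empty_sample(self):
        assert hill_n0(_matrix({("S1", 1, "A"): 5}), sample_id="S9") == 0

    def test_equals_detected_taxa_and_depth_invariant(self):
        rng = np.random.default_rng(7)
        counts = {
            (f"S{rng.integers(3)}", int(rng.integers(1, 9)), f"T{i % 6}"):
                int(rng.integers(1, 40))
            for i in range(40)
        }
        t = make_table(counts)
        m = _matrix(counts)
        detected = t.counts.groupby("sample_id")["variant_id"].nunique()
        for s, n in detected.items():
            assert hill_n0(m, sample_id=s) == n
        m_scaled = _matrix({k: 3 * v for k, v in counts.items()})
        for s in detected.index:
            assert hill_n0(m_scaled, sample_id=s) == hill_n0(m, sample_id=s)


class TestAggregateGroups:
    def _annotations(self):
        return pd.DataFrame(
            {
                "taxon": ["A", "B", "C", "D"],
                "growth_form": ["forb", "forb", "shrub", None],
                "light": [True, False, True, None],
                "grazing": [False, True, None, None],
                "elevation_belt": ["alpine", "subalpine", "alpine", None],
            }
        )

    def test_only_forbs_present(self):
        counts = {("S1", 1, "A"): 10, ("S1", 2, "B"): 10}
        out = aggregate_groups(_matrix(counts), self._annotations())
        row = out.set_index("sample_id").loc["S1"]
        assert row["rai_forb"] == pytest.approx(1.0)
        assert row["rai_shrub"] == 0.0
        assert row["rai_tree"] == 0.0

    def test_partition_property_when_fully_annotated(self):
        counts = {("S1", 1, "A"): 5, ("S1", 2, "B"): 5, ("S1", 3, "C"): 5}
        out = aggregate_groups(_matrix(counts), self._annotations())
        row = out.set_index("sample_id").loc["S1"]
        forms_sum = sum(
            row[f"n0_{f}"] for f in ("forb", "graminoid", "shrub", "tree")
        )
        assert row["n0_total"] == forms_sum == 3

    def test_unannotated_taxon_counts_in_total_only(self):
        counts = {("S1", 1, "A"): 5, ("S1", 2, "D"): 5}
        out = aggregate_groups(_matrix(counts), self._annotations())
        row = out.set_index("sample_id").loc["S1"]
        assert row["n0_total"] == 2
        assert row["n0_forb"] == 1
        assert (
            row["n0_graminoid"] + row["n0_shrub"] + row["n0_tree"]
        ) == 0

    def test_unknown_label_rejected(self):
        ann = self._annotations()
        ann.loc[0, "growth_form"] = "cactus"
        with pytest.raises(ValidationError, match="growth_form"):
            validate_annotations(ann)
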