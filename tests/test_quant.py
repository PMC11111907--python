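"""Metric definitions, aggregation semantics, and ground-truth evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synaptomap.classify import SynapseRecord
from synaptomap.quant import (
    aggregate_by_mouse,
    compute_stack_metrics,
    evaluate_against_truth,
    fraction_positive,
    intensity_ratio_per_field,
    intensity_ratio_per_record,
    normalize_intensities,
    record_density,
)
from synaptomap.synthgen import GroundTruthTable, PlantedSite, molecular_config

from conftest import make_cluster, make_cluster_set


def record(rid, label, positive=False, intensity=0.0, subclass=None, pos=(0.0, 0.0, 0.0)):
    return SynapseRecord(
        record_id=rid,
        class_label=label,
        subclass=subclass,
        defining={},
        anchor_centroid_zyx_nm=pos,
        antigen_positive=positive,
        antigen_cluster_id=0 if positive else None,
        antigen_intensity=intensity,
        antigen_distance_nm=0.0 if positive else None,
    )


class TestNormalization:
    def test_divides_by_mean(self, geometry):
        clusters = [
            make_cluster([(0, 0, i)], geometry, cluster_id=i, intensity=v)
            for i, v in enumerate((2.0, 4.0, 6.0))
        ]
        out = normalize_intensities(make_cluster_set(clusters, geometry))
        assert out.intensities().tolist() == [0.5, 1.0, 1.5]

    def test_single_cluster_becomes_one(self, geometry):
        out = normalize_intensities(
            make_cluster_set([make_cluster([(0, 0, 0)], geometry, intensity=17.3)], geometry)
        )
        assert out.intensities().tolist() == [1.0]

    def test_empty_set_rejected(self, geometry):
        with pytest.raises(ValueError):
            normalize_intensities(make_cluster_set([], geometry))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e6, allow_nan=False), min_size=1, max_size=30))
    def test_mean_is_exactly_one(self, values):
        from synaptomap.geometry import VoxelGeometry

        geometry = VoxelGeometry.from_xyz((50.0, 50.0, 190.0), 4.0)
        clusters = [
            make_cluster([(0, 0, i)], geometry, cluster_id=i, intensity=v)
            for i, v in enumerate(values)
        ]
        out = normalize_intensities(make_cluster_set(clusters, geometry))
        assert np.mean(out.intensities()) == pytest.approx(1.0, rel=1e-12)


class TestFractionPositive:
    def test_three_of_four(self):
        recs = [record(i, "PF-PC", positive=i < 3, intensity=1.0 if i < 3 else 0.0)
                for i in range(4)]
        assert fraction_positive(recs, "PF-PC") == 0.75

    def test_absent_class_is_undefined(self):
        assert fraction_positive([record(0, "PF-PC")], "nonPF-PC") is None

    def test_all_positive(self):
        recs = [record(i, "CF-PC", positive=True, intensity=1.0) for i in range(5)]
        assert fraction_positive(recs, "CF-PC") == 1.0

    def test_order_invariant(self):
        recs = [record(i, "PF-PC", positive=i % 2 == 0, intensity=float(i % 2 == 0))
                for i in range(10)]
        assert fraction_positive(recs, "PF-PC") == fraction_positive(recs[::-1], "PF-PC")

    def test_subclass_selection(self):
        recs = [
            record(0, "PF-PC", True, 1.0, subclass="PSD95+"),
            record(1, "PF-PC", False, 0.0, subclass="PSD95-"),
        ]
        assert fraction_positive(recs, "PF-PC", "PSD95+") == 1.0
        assert fraction_positive(recs, "PF-PC", "PSD95-") == 0.0
        assert fraction_positive(recs, "PF-PC") == 0.5


class TestIntensityRatios:
    def test_identical_distributions_give_one(self):
        recs = [record(i, "GCL-synaptic", True, v) for i, v in enumerate((1.0, 2.0, 3.0))]
        recs += [record(i + 3, "GCL-extrasynaptic", True, v) for i, v in enumerate((1.0, 2.0, 3.0))]
        assert intensity_ratio_per_record(recs, "GCL-synaptic", "GCL-extrasynaptic") == 1.0
        assert intensity_ratio_per_field(recs, "GCL-synaptic", "GCL-extrasynaptic") == 1.0

    def test_count_asymmetry_seen_only_per_field(self):
        recs = [
            record(0, "GCL-synaptic", True, 1.0),
            record(1, "GCL-synaptic", True, 1.0),
            record(2, "GCL-extrasynaptic", True, 1.0),
        ]
        assert intensity_ratio_per_record(recs, "GCL-synaptic", "GCL-extrasynaptic") == 1.0
        assert intensity_ratio_per_field(recs, "GCL-synaptic", "GCL-extrasynaptic") == 2.0

    def test_no_positives_is_undefined(self):
        recs = [record(0, "GCL-synaptic", True, 1.0), record(1, "GCL-extrasynaptic")]
        assert intensity_ratio_per_record(recs, "GCL-synaptic", "GCL-extrasynaptic") is None
        assert intensity_ratio_per_field(recs, "GCL-synaptic", "GCL-extrasynaptic") is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_field_ratio_identity(self, data):
        """per-field ratio == per-record ratio x positive-count ratio, exactly."""
        amounts_a = data.draw(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=20))
        amounts_b = data.draw(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=20))
        recs = [record(i, "GCL-synaptic", True, v) for i, v in enumerate(amounts_a)]
        recs += [record(100 + i, "GCL-extrasynaptic", True, v) for i, v in enumerate(amounts_b)]
        per_record = intensity_ratio_per_record(recs, "GCL-synaptic", "GCL-extrasynaptic")
        per_field = intensity_ratio_per_field(recs, "GCL-synaptic", "GCL-extrasynaptic")
        assert per_field == pytest.approx(
            per_record * len(amounts_a) / len(amounts_b), rel=1e-9
        )


class TestDensity:
    def test_zero_records(self):
        assert record_density([], "PF-PC", 100.0) == 0.0

    def test_ten_records_in_field_volume(self):
        # 53 x 53 x 7.41 um field at factor 4 -> 325.3 um^3 biological scale
        recs = [record(i, "PF-PC") for i in range(10)]
        assert record_density(recs, "PF-PC", 325.3) == pytest.approx(0.030741, rel=1e-4)

    def test_doubling_volume_halves_density(self):
        recs = [record(i, "PF-PC") for i in range(8)]
        assert record_density(recs, "PF-PC", 200.0) == 2 * record_density(recs, "PF-PC", 400.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            record_density([], "PF-PC", 0.0)


class TestAggregation:
    def _metrics(self):
        rows = []
        for stack, mouse, frac in [("s1", "m1", 0.2), ("s2", "m1", 0.4),
                                   ("s3", "m2", 0.6), ("s4", "m2", np.nan)]:
            rows.append(dict(stack_id=stack, mouse_id=mouse, layer="molecular",
                             antigen="antigen", class_label="PF-PC", subclass="",
                             n_records=10, n_positive=5, fraction_positive=frac,
                             mean_intensity_positive=1.0, total_intensity=5.0,
                             density_per_um3=0.1))
        return pd.DataFrame(rows)

    def test_mean_over_stacks(self):
        out = aggregate_by_mouse(self._metrics())
        m1 = out[out.mouse_id == "m1"].iloc[0]
        assert m1.fraction_positive == pytest.approx(0.3)
        assert m1.n_stacks == 2

    def test_undefined_values_excluded_from_mean(self):
        out = aggregate_by_mouse(self._metrics())
        m2 = out[out.mouse_id == "m2"].iloc[0]
        assert m2.fraction_positive == pytest.approx(0.6)  # NaN stack dropped
        assert m2.n_undefined_fraction_positive == 1

    def test_single_stack_mouse_equals_stack_value(self):
        df = self._metrics().iloc[:1]
        out = aggregate_by_mouse(df)
        assert out.iloc[0].fraction_positive == pytest.approx(0.2)

    def test_unmapped_stack_rejected(self):
        with pytest.raises(ValueError):
            aggregate_by_mouse(self._metrics(), mouse_map={"s1": "m1"})

    def test_metrics_table_conservation(self):
        recs = [record(i, "PF-PC", True, float(i + 1)) for i in range(4)]
        df = compute_stack_metrics(recs, [("PF-PC", None)], 100.0)
        row = df.iloc[0]
        assert row.total_intensity == pytest.approx(sum(r.antigen_intensity for r in recs))
        assert row.n_positive == 4


class TestEvaluation:
    def _truth(self, positions, classes):
        cfg = molecular_config(field_size_um=(6.0, 6.0, 3.0))
        sites = tuple(
            PlantedSite(i, c, p, {"GluD2": p}, {"GluD2": 1.0})
            for i, (p, c) in enumerate(zip(positions, classes))
        )
        return GroundTruthTable(sites=sites, config=cfg)

    CLASS_MAP = {"PF-PC(PSD95-)": ("PF-PC", "PSD95-"), "PF-MLI": ("nonPF-PC", None)}

    def test_perfect_matching(self):
        pos = [(1000.0, 1000.0, 500.0), (3000.0, 3000.0, 1500.0)]
        truth = self._truth(pos, ["PF-PC(PSD95-)", "PF-MLI"])
        recs = [
            record(0, "PF-PC", subclass="PSD95-", pos=(500.0, 1000.0, 1000.0)),
            record(1, "nonPF-PC", pos=(1500.0, 3000.0, 3000.0)),
        ]
        ev = evaluate_against_truth(recs, truth, self.CLASS_MAP)
        assert ev["precision"] == ev["recall"] == ev["class_accuracy"] == 1.0

    def test_empty_detection_has_zero_recall(self):
        truth = self._truth([(1000.0, 1000.0, 500.0)], ["PF-PC(PSD95-)"])
        ev = evaluate_against_truth([], truth, self.CLASS_MAP)
        assert ev["recall"] == 0.0
        assert np.isnan(ev["precision"])

    def test_matches_independent_greedy_matcher(self):
        rng = np.random.default_rng(42)
        n = 40
        pos = rng.uniform(500, 5500, size=(n, 3))
        truth = self._truth([tuple(p) for p in pos], ["PF-PC(PSD95-)"] * n)
        # jittered detections for 30 truths + 8 spurious records
        recs = []
        for i in range(30):
            x, y, z = pos[i] + rng.normal(0, 60, 3)
            recs.append(record(i, "PF-PC", subclass="PSD95-", pos=(z, y, x)))
        for j in range(8):
            x, y, z = rng.uniform(500, 5500, 3)
            recs.append(record(100 + j, "PF-PC", subclass="PSD95-", pos=(z, y, x)))
        ev = evaluate_against_truth(recs, truth, self.CLASS_MAP, match_radius_nm=300.0)

        # oracle: exhaustive greedy matching by ascending pair distance
        t_pos = np.array([[s.anchor_xyz_nm[2], s.anchor_xyz_nm[1], s.anchor_xyz_nm[0]]
                          for s in truth.sites])
        r_pos = np.array([r.anchor_centroid_zyx_nm for r in recs])
        pairs = []
        for ti in range(len(t_pos)):
            for ri in range(len(r_pos)):
                d = float(np.linalg.norm(t_pos[ti] - r_pos[ri]))
                if d <= 300.0:
                    pairs.append((d, ti, ri))
        used_t, used_r, n_matched = set(), set(), 0
        for d, ti, ri in sorted(pairs):
            if ti not in used_t and ri not in used_r:
                used_t.add(ti)
                used_r.add(ri)
                n_matched += 1
        assert ev["n_matched"] == n_matched
        assert ev["precision"] == pytest.approx(n_matched / len(recs))
        assert ev["recall"] == pytest.approx(n_matched / n)
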