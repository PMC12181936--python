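"""Physical state, A–D designations, production-volume bins, list tagging
and the data-collection triage workflow."""

import numpy as np
import pandas as pd
import pytest

from pfascat.annotate import (AnnotationRecord, PropertyRecord,
                              assign_designation, bin_production_volume,
                              data_availability_matrix, data_poor_categories,
                              physical_state, select_candidates, tag_lists)
from pfascat.registry import Registry, make_record
from pfascat.select import select_category
from pfascat.similarity import DistanceMatrix
from .conftest import random_distance_matrix


class TestPhysicalState:
    @pytest.mark.parametrize("mp,bp,expected", [
        (None, -10.0, "gas"),
        (120.0, None, "solid"),
        (10.0, 150.0, "liquid"),
        (None, None, "unknown"),
        (25.0, 300.0, "solid"),   # mp boundary: >= 25 is solid
        (10.0, 24.9, "gas"),      # bp < 25 wins
    ])
    def test_rules_at_25C(self, mp, bp, expected):
        rec = PropertyRecord("x", melting_point=mp, boiling_point=bp)
        assert physical_state(rec) == expected


class TestDesignation:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(melting_point=100, water_solubility=0.001), "A"),
        (dict(melting_point=100, water_solubility=100), "B"),
        (dict(melting_point=10, boiling_point=150, water_solubility=100,
              vapour_pressure=1), "B"),
        (dict(melting_point=10, boiling_point=150, water_solubility=100,
              vapour_pressure=80), "C"),
        (dict(melting_point=10, boiling_point=150,
              water_solubility=0.001), "C"),
        (dict(boiling_point=-10, water_solubility=100), "C"),
        (dict(boiling_point=-10, water_solubility=0.0001), "D"),
        (dict(boiling_point=-10, water_solubility=100, henrys_law=0.5), "D"),
        (dict(), "not determined"),
    ])
    def test_rule_table(self, kwargs, expected):
        assert assign_designation(PropertyRecord("x", **kwargs)) == expected

    def test_boundary_uses_ge(self):
        solid = PropertyRecord("x", melting_point=100, water_solubility=0.5)
        assert assign_designation(solid) == "B"  # WS exactly at cutoff: soluble

    def test_designations_partition_fully_annotated(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rec = PropertyRecord(
                "x",
                melting_point=float(rng.uniform(-150, 300)),
                boiling_point=float(rng.uniform(-150, 400)),
                water_solubility=float(10 ** rng.uniform(-5, 5)),
                vapour_pressure=float(10 ** rng.uniform(-6, 3)),
                henrys_law=float(10 ** rng.uniform(-8, 1)),
            )
            assert assign_designation(rec) in {"A", "B", "C", "D"}


class TestProductionVolume:
    @pytest.mark.parametrize("value,expected", [
        (30_000, "25,000–<100,000 lbs"),
        (25_000, "25,000–<100,000 lbs"),   # boundary joins its lower bound
        (10, "<25,000 lbs"),
        (750_000, "500,000–<1,000,000 lbs"),
        (5_000_000, "1,000,000–<10,000,000 lbs"),
        (60_000_000, "50,000,000–<100,000,000 lbs"),
    ])
    def test_numeric_binning(self, value, expected):
        assert bin_production_volume(value) == expected

    def test_source_range_string_passes_through(self):
        assert (bin_production_volume("1,000,000–<20,000,000 lbs")
                == "1,000,000–<20,000,000 lbs")

    def test_unparseable_returns_none(self):
        assert bin_production_volume("confidential") is None


class TestTagLists:
    @pytest.fixture
    def registry(self):
        reg = Registry()
        reg.add(make_record("A", "OC(=O)C(F)(F)C(F)(F)C(F)(F)F"))
        reg.add(make_record("B", "CCO"))
        reg.add(make_record("C", "OC(=O)C(F)(F)C(F)(F)C(F)(F)F"))  # same structure as A
        return reg

    def test_membership_counts(self, registry):
        ann = tag_lists(registry, {"L1": ["A"], "L2": ["A", "B"]})
        assert ann["A"].list_tags == {"L1", "L2"}
        assert ann["B"].list_tags == {"L2"}
        assert ann["C"].list_tags == set()

    def test_structure_key_matching_tags_all_records(self, registry):
        key = registry["A"].structure_key
        ann = tag_lists(registry, {"L1": [key]})
        assert ann["A"].list_tags == {"L1"}
        assert ann["C"].list_tags == {"L1"}

    def test_inventory_status(self, registry):
        ann = tag_lists(registry, {}, inventory_active=["A"],
                        inventory_inactive=["B"])
        assert ann["A"].inventory_status == "active"
        assert ann["B"].inventory_status == "inactive"
        assert ann["C"].inventory_status == "unclassified"


class TestDataPoor:
    @staticmethod
    def records(rows):
        return pd.DataFrame(rows, columns=["substance_id", "route",
                                           "effect_type"])

    def test_oral_noael_member_not_data_poor(self):
        members = {"cat": ["a", "b"]}
        recs = self.records([("a", "oral", "NOAEL")])
        assert data_poor_categories(members, recs) == set()

    def test_dermal_only_is_data_poor(self):
        members = {"cat": ["a"]}
        recs = self.records([("a", "dermal", "LOAEL")])
        assert data_poor_categories(members, recs) == {"cat"}

    def test_no_records_is_data_poor(self):
        members = {"cat": ["a"], "other": ["b"]}
        recs = self.records([("b", "inhalation", "LEL")])
        assert data_poor_categories(members, recs) == {"cat"}


class TestDataAvailabilityMatrix:
    def test_study_type_and_list_columns(self):
        members = {"catA": ["a", "b"], "catB": ["c"]}
        tox = pd.DataFrame([
            ("a", "oral", "chronic"), ("c", "dermal", "chronic"),
        ], columns=["substance_id", "route", "study_type"])
        ann = {s: AnnotationRecord(s) for s in "abc"}
        ann["c"].list_tags = {"TRI"}
        matrix = data_availability_matrix(members, tox, ann)
        assert matrix.loc["catA", "study:chronic"] == 1
        assert matrix.loc["catB", "study:chronic"] == 0  # dermal excluded
        assert matrix.loc["catB", "list:TRI"] == 1
        assert matrix.loc["catA", "list:TRI"] == 0
        assert set(matrix.to_numpy().ravel()) <= {0, 1}


class TestTriage:
    @staticmethod
    def build(n=8, active=(), inactive=(), listed=(), seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        d = DistanceMatrix(ids, random_distance_matrix(rng, n))
        members = {"cat": ids}
        selections = {"cat": select_category(d, "cat")}
        annotations = {}
        for sid in ids:
            ann = AnnotationRecord(sid)
            if sid in active:
                ann.inventory_status = "active"
            elif sid in inactive:
                ann.inventory_status = "inactive"
            if sid in listed:
                ann.list_tags = {"monitoring"}
            annotations[sid] = ann
        return members, selections, d, annotations

    def test_centroid_on_inventory_nominated_directly(self):
        members, selections, d, ann = self.build()
        c = selections["cat"].centroid_id
        ann[c].inventory_status = "active"
        ann["s0"].list_tags = {"monitoring"}
        res = select_candidates(members, selections, d, ann, {"cat"})
        nominated = res["cat"].nominated_candidates
        assert (c, "centroid on inventory") in nominated

    def test_gate_failure_yields_no_candidates(self):
        members, selections, d, ann = self.build(active=("s0",),
                                                 listed=("s0",))
        res = select_candidates(members, selections, d, ann, data_poor=set())
        assert res["cat"].nominated_candidates == []
        assert not res["cat"].triaged

    def test_constrained_fallback_nominates_constrained_centroid(self):
        members, selections, d, ann = self.build(seed=4)
        # picks and the next-closest member are all off-inventory; two
        # other members are active, so the constrained recompute fires
        picks = set(selections["cat"].picks)
        index = {s: i for i, s in enumerate(members["cat"])}
        ci = index[selections["cat"].centroid_id]
        non_centroid = [s for s in members["cat"]
                        if s != selections["cat"].centroid_id]
        next_closest = min(non_centroid, key=lambda s: (d.d[ci, index[s]],
                                                        index[s]))
        active = [s for s in members["cat"]
                  if s not in picks and s != next_closest][:2]
        for s in active:
            ann[s].inventory_status = "active"
        ann["s0"].list_tags = {"monitoring"}
        res = select_candidates(members, selections, d, ann, {"cat"},
                                require_active=True)
        nominated = res["cat"].nominated_candidates
        assert nominated
        assert all(s in active for s, _ in nominated)
        expected_centroid = select_category(d.subset(active), "cat").centroid_id
        assert nominated[0] == (expected_centroid,
                                "constrained-landscape centroid")

    def test_monotone_in_evidence(self):
        # adding a qualifying tox record can only remove a category
        members, selections, d, ann = self.build(active=("s0",),
                                                 listed=("s0",))
        recs_before = pd.DataFrame(columns=["substance_id", "route",
                                            "effect_type"])
        poor_before = data_poor_categories(members, recs_before)
        res_before = select_candidates(members, selections, d, ann,
                                       poor_before)
        recs_after = pd.DataFrame([("s0", "oral", "NOAEL")],
                                  columns=["substance_id", "route",
                                           "effect_type"])
        poor_after = data_poor_categories(members, recs_after)
        res_after = select_candidates(members, selections, d, ann, poor_after)
        assert res_before["cat"].triaged
        assert not res_after["cat"].triaged
        assert res_after["cat"].nominated_candidates == []
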