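import itertools

import pytest

from holohost.confidence import (ClassificationError, ConfidenceContext,
                                 apply_ratings, build_context,
                                 classify_confidence, classify_with_rule,
                                 confidence_tally)
from holohost.records import EVIDENCE_FLAGS, Evidence, RecordSet
from conftest import make_record

EMPTY = ConfidenceContext()


def rec(**kw):
    return make_record("c1", **kw)


class TestRuleExamples:
    """Anchor cases of the three-tier classification."""

    def test_confirmed_excavation_is_high(self):
        assert classify_confidence(
            Evidence(excavated_confirmed=True), rec(), EMPTY) == "high"

    def test_host_material_on_sheet_is_high(self):
        assert classify_with_rule(
            Evidence(host_material_on_sheet=True), rec(), EMPTY) == ("high", "H3")

    def test_database_obs_without_photo_or_backing_is_low(self):
        ev = Evidence(database_observation=True)
        assert classify_with_rule(ev, rec(), EMPTY) == ("low", "L3")

    def test_database_obs_with_congeneric_high_backing_is_medium(self):
        ev = Evidence(database_observation=True)
        ctx = ConfidenceContext(
            high_host_genera={"Hydnora africana": {"Euphorbia"}})
        assert classify_with_rule(ev, rec(), ctx) == ("medium", "M4")

    def test_dubious_flag_dominates_high_evidence(self):
        ev = Evidence(author_flags_dubious=True, excavated_confirmed=True)
        assert classify_with_rule(ev, rec(), EMPTY) == ("low", "L1")

    def test_pre_1950_caps_high_at_medium(self):
        ev = Evidence(pre_1950=True, expert_report=True)
        assert classify_with_rule(ev, rec(), EMPTY) == ("medium", "M2")

    def test_explicit_excavation_lifts_pre_1950_cap(self):
        ev = Evidence(pre_1950=True, excavated_confirmed=True,
                      excavation_explicit=True)
        assert classify_confidence(ev, rec(), EMPTY) == "high"

    def test_unrelated_family_unconfirmed_report_is_low(self):
        # parasite otherwise recorded only on Fabales hosts
        ctx = ConfidenceContext(recorded_families={
            "Hydnora africana": {("Euphorbiaceae", "Malpighiales"),
                                 ("Fabaceae", "Fabales")}})
        ev = Evidence(pre_1950=True)
        assert classify_with_rule(ev, rec(), ctx) == ("low", "L2")

    def test_related_family_plain_report_is_medium(self):
        ctx = ConfidenceContext(recorded_families={
            "Hydnora africana": {("Euphorbiaceae", "Malpighiales"),
                                 ("Phyllanthaceae", "Malpighiales")}})
        assert classify_with_rule(Evidence(pre_1950=True), rec(), ctx) == \
            ("medium", "M1")

    def test_empty_evidence_raises(self):
        with pytest.raises(ClassificationError):
            classify_confidence(None, rec(), EMPTY)


def all_valid_evidence():
    for bits in itertools.product([False, True], repeat=len(EVIDENCE_FLAGS)):
        ev = Evidence(**dict(zip(EVIDENCE_FLAGS, bits)))
        if ev.is_valid():
            yield ev


def context_cases():
    p = "Hydnora africana"
    yield ConfidenceContext()
    yield ConfidenceContext(high_host_genera={p: {"Euphorbia"}})
    yield ConfidenceContext(recorded_families={
        p: {("Euphorbiaceae", "Malpighiales"), ("Fabaceae", "Fabales")}})
    yield ConfidenceContext(
        high_host_genera={p: {"Euphorbia"}},
        recorded_families={p: {("Euphorbiaceae", "Malpighiales"),
                               ("Fabaceae", "Fabales")}})


class TestEngineTotality:
    def test_every_valid_flag_combination_gets_exactly_one_rating(self):
        """The engine is total and deterministic: every evidence state in
        every context yields one of the three tiers."""
        n = 0
        for ev in all_valid_evidence():
            for ctx in context_cases():
                r1 = classify_confidence(ev, rec(), ctx)
                r2 = classify_confidence(ev, rec(), ctx)
                assert r1 in ("low", "medium", "high")
                assert r1 == r2
                n += 1
        assert n >= 4 * 2 ** 8  # enough coverage of the flag lattice


class TestContext:
    def test_high_record_contributes_host_genus(self):
        rs = RecordSet([make_record(
            "c1", evidence=Evidence(excavated_confirmed=True))])
        ctx = build_context(rs)
        assert ctx.high_host_genera == {"Hydnora africana": {"Euphorbia"}}

    def test_empty_set_gives_empty_context(self):
        ctx = build_context(RecordSet())
        assert not ctx.high_host_genera and not ctx.recorded_families

    def test_medium_only_parasite_absent_from_high_map(self):
        rs = RecordSet([make_record(
            "c1", evidence=Evidence(herbarium_host_named_no_material=True))])
        assert "Hydnora africana" not in build_context(rs).high_host_genera

    def test_preset_high_confidence_contributes_without_evidence(self):
        rs = RecordSet([make_record("c1", confidence="high")])
        assert build_context(rs).high_host_genera == {
            "Hydnora africana": {"Euphorbia"}}


class TestApplyRatings:
    def test_preset_ratings_kept_unless_overwrite(self):
        rs = RecordSet([make_record(
            "c1", confidence="low",
            evidence=Evidence(excavated_confirmed=True))])
        kept, _ = apply_ratings(rs, overwrite=False)
        assert kept[0].confidence == "low"
        over, _ = apply_ratings(rs, overwrite=True)
        assert over[0].confidence == "high"

    def test_unratable_records_reported_not_dropped(self):
        rs = RecordSet([make_record("c1")])
        out, errs = apply_ratings(rs)
        assert errs.unratable_record_ids == ["c1"]
        assert len(out) == 1

    def test_idempotent(self, small_dataset):
        rs, _, _ = small_dataset
        once, _ = apply_ratings(rs, overwrite=True)
        twice, _ = apply_ratings(once, overwrite=True)
        assert [r.confidence for r in twice] == [r.confidence for r in once]

    def test_rating_is_record_order_invariant(self, small_dataset):
        rs, _, _ = small_dataset
        fwd, _ = apply_ratings(rs, overwrite=True)
        rev, _ = apply_ratings(RecordSet(list(reversed(rs.records))),
                               overwrite=True)
        by_id = {r.record_id: r.confidence for r in rev}
        assert all(by_id[r.record_id] == r.confidence for r in fwd)


class TestTally:
    def test_counts_sum_to_total(self):
        rs = RecordSet([make_record("c1", confidence="high"),
                        make_record("c2", confidence="high"),
                        make_record("c3", confidence="low")])
        t = confidence_tally(rs)
        assert (t["low"], t["medium"], t["high"]) == (1, 0, 2)
        assert t["total"] == 3

    def test_empty_set_all_zero(self):
        t = confidence_tally(RecordSet())
        assert t == {"low": 0, "medium": 0, "high": 0, "total": 0}

    def test_unrated_record_raises(self):
        with pytest.raises(ClassificationError):
            confidence_tally(RecordSet([make_record("c1")]))
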