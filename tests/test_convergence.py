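import pytest

from holohost.convergence import (CladeMap, DiversityShares, TribeMap,
                                  clade_partition, disproportionality,
                                  habit_summary, host_family_summary,
                                  parasite_family_breadth, tribe_breakdown)
from holohost.records import RecordSet
from conftest import make_record


@pytest.fixture
def mixed_set():
    """Three lineages, four host families (one monocot), one Asteraceae
    host with a mapped tribe."""
    return RecordSet([
        make_record("m1", confidence="high"),  # Hydnoraceae on Euphorbiaceae
        make_record("m2", parasite="Cytinus hypocistis", pgenus="Cytinus",
                    pfamily="Cytinaceae", host_family="Euphorbiaceae",
                    host_genus="Euphorbia", host_species="Euphorbia dendroides",
                    confidence="medium", host_habit="shrub"),
        make_record("m3", parasite="Orobanche minor", pgenus="Orobanche",
                    pfamily="Orobanchaceae", host_family="Asteraceae",
                    host_genus="Helichrysum",
                    host_species="Helichrysum stoechas",
                    host_order="Asterales", confidence="medium",
                    host_habit="perennial_herb"),
        make_record("m4", parasite="Orobanche minor", pgenus="Orobanche",
                    pfamily="Orobanchaceae", host_family="Fabaceae",
                    host_genus="Trifolium", host_species="Trifolium pratense",
                    host_order="Fabales", confidence="high",
                    host_habit="perennial_herb"),
        make_record("m5", parasite="Aeginetia indica", pgenus="Aeginetia",
                    pfamily="Orobanchaceae", host_family="Poaceae",
                    host_genus="Saccharum", host_species="",
                    host_order="Poales", confidence="medium",
                    host_habit="unknown"),
    ])


class TestHostFamilySummary:
    def test_counts_distinct_parasites_per_family(self, mixed_set):
        rows = {s.host_family: s for s in host_family_summary(mixed_set)}
        euph = rows["Euphorbiaceae"]
        assert (euph.n_parasite_species, euph.n_parasite_genera,
                euph.n_parasite_lineages) == (2, 2, 2)
        assert rows["Poaceae"].n_parasite_species == 1

    def test_single_record_gives_1_1_1(self):
        rows = host_family_summary(RecordSet([make_record("x")]))
        s = rows[0]
        assert (s.n_parasite_species, s.n_parasite_genera,
                s.n_parasite_lineages) == (1, 1, 1)

    def test_lineages_never_exceed_genera_or_species(self, small_dataset):
        rs, _, _ = small_dataset
        for s in host_family_summary(rs):
            assert s.n_parasite_lineages <= s.n_parasite_genera \
                <= s.n_parasite_species


class TestBreadth:
    def test_per_lineage_host_family_counts(self, mixed_set):
        df = parasite_family_breadth(mixed_set).set_index("parasite_family")
        assert df.loc["Orobanchaceae", "n_host_families"] == 3
        assert df.loc["Orobanchaceae", "n_parasite_species"] == 2
        assert df.loc["Hydnoraceae", "n_host_families"] == 1

    def test_empty_set(self):
        assert parasite_family_breadth(RecordSet()).empty


class TestDisproportionality:
    def test_overrepresented_group_ratio(self):
        # a group holding 10 % of diversity but 31 % of parasitized species
        from holohost.convergence import HostFamilySummary
        s = HostFamilySummary("Asteraceae", 31, 10, 5)
        disproportionality([s], DiversityShares({"Asteraceae": 0.10}), 100)
        assert s.disproportionality == pytest.approx(3.1)

    def test_equal_shares_give_unity(self):
        from holohost.convergence import HostFamilySummary
        s = HostFamilySummary("Fabaceae", 23, 5, 2)
        disproportionality([s], DiversityShares({"Fabaceae": 0.23}), 100)
        assert s.disproportionality == pytest.approx(1.0)

    def test_missing_share_left_empty(self):
        from holohost.convergence import HostFamilySummary
        s = HostFamilySummary("Rosaceae", 5, 2, 1)
        disproportionality([s], DiversityShares({"Fabaceae": 0.23}), 100)
        assert s.disproportionality is None

    def test_invalid_share_rejected(self):
        with pytest.raises(ValueError):
            DiversityShares({"Fabaceae": 0.0})


class TestCladePartition:
    def test_monocot_and_eudicot_rows(self, mixed_set):
        cm = CladeMap.default()
        df = clade_partition(mixed_set, cm).set_index("clade")
        assert df.loc["monocot", "n_host_families"] == 1
        assert df.loc["monocot", "n_parasite_species"] == 1
        assert df.loc["eudicot", "n_host_families"] == 3
        assert df.attrs["unmapped_families"] == []

    def test_all_eudicot_set_zeroes_monocots(self):
        df = clade_partition(RecordSet([make_record("x")]),
                             CladeMap.default()).set_index("clade")
        assert df.loc["monocot", "n_host_families"] == 0

    def test_unmapped_family_reported_not_dropped(self):
        rs = RecordSet([make_record("x", host_family="Nonexistaceae")])
        df = clade_partition(rs, CladeMap.default())
        assert df.attrs["unmapped_families"] == ["Nonexistaceae"]

    def test_clade_family_counts_sum_to_total(self, small_dataset):
        rs, _, truth = small_dataset
        cm = CladeMap({f: c for f, c in truth.clade_map.items()})
        df = clade_partition(rs, cm)
        total = len({r.host_family for r in rs})
        assert df["n_host_families"].sum() == total


class TestTribeBreakdown:
    def test_asteraceae_hosts_grouped_by_tribe(self, mixed_set):
        df = tribe_breakdown(mixed_set, TribeMap.default())
        assert df.set_index("tribe").loc["Inuleae", "n_parasite_species"] == 1

    def test_no_asteraceae_hosts_gives_empty_table(self):
        df = tribe_breakdown(RecordSet([make_record("x")]),
                             TribeMap.default())
        assert df.empty


class TestHabitSummary:
    def test_proportions_sum_to_one(self, mixed_set):
        df = habit_summary(mixed_set)
        assert df["proportion"].sum() == pytest.approx(1.0)
        assert df.set_index("host_habit").loc["perennial_herb", "count"] == 2

    def test_all_trees_toy(self):
        rs = RecordSet([make_record("x", host_habit="tree")])
        df = habit_summary(rs).set_index("host_habit")
        assert df.loc["tree", "proportion"] == pytest.approx(1.0)

    def test_empty_set(self):
        assert habit_summary(RecordSet()).empty

    def test_per_host_counting_collapses_repeat_records(self):
        rs = RecordSet([
            make_record("a", host_habit="shrub"),
            make_record("b", host_habit="shrub"),  # same host species
            make_record("c", parasite="Cytinus hypocistis", pgenus="Cytinus",
                        pfamily="Cytinaceae", host_species="Cistus albidus",
                        host_genus="Cistus", host_family="Cistaceae",
                        host_habit="shrub"),
        ])
        per_host = habit_summary(rs, per="host").set_index("host_habit")
        per_rec = habit_summary(rs, per="record").set_index("host_habit")
        assert per_host.loc["shrub", "count"] == 2
        assert per_rec.loc["shrub", "count"] == 3
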