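import pytest

from holohost.records import Evidence, HostRecord, RecordSet
from holohost.simulate import SyntheticConfig, generate


def make_record(rid, parasite="Hydnora africana", pgenus="Hydnora",
                pfamily="Hydnoraceae", host_species="Euphorbia mauritanica",
                host_genus="Euphorbia", host_family="Euphorbiaceae",
                host_order="Malpighiales", confidence="", evidence=None,
                **kw):
    return HostRecord(
        record_id=rid, parasite_species=parasite, parasite_genus=pgenus,
        parasite_family=pfamily, host_species=host_species,
        host_genus=host_genus, host_family=host_family,
        host_order=host_order, confidence=confidence, evidence=evidence,
        **kw)


@pytest.fixture
def toy_records():
    """Small hand-built rated set: one low record, one unrescued medium
    singleton, and four solid records across two parasite genera."""
    recs = [
        make_record("t1", confidence="high"),
        make_record("t2", host_species="Euphorbia gregaria",
                    confidence="medium"),
        make_record("t3", host_species="Euphorbia gummifera",
                    confidence="low"),
        # singleton medium, congener Hydnora africana has high record in
        # Euphorbiaceae -> rescued
        make_record("t4", parasite="Hydnora visseri",
                    host_species="Euphorbia dregeana", confidence="medium"),
        # singleton medium in Fabaceae, no congeneric high there -> removed
        make_record("t5", parasite="Hydnora abyssinica",
                    host_species="Vachellia tortilis", host_genus="Vachellia",
                    host_family="Fabaceae", host_order="Fabales",
                    confidence="medium"),
        make_record("t6", parasite="Cytinus hypocistis", pgenus="Cytinus",
                    pfamily="Cytinaceae", host_species="Cistus albidus",
                    host_genus="Cistus", host_family="Cistaceae",
                    host_order="Malvales", confidence="high"),
    ]
    return RecordSet(records=recs, provenance="toy")


def small_config(seed=1, **overrides):
    base = dict(
        seed=seed,
        lineages={"Orobanchaceae": (4, 30), "Hydnoraceae": (2, 10),
                  "Cytinaceae": (1, 5)},
        host_taxonomy={"families_per_clade": {"eudicot": 12, "monocot": 3,
                                              "other_angiosperm": 2,
                                              "gymnosperm": 2}},
        geo={"n_points_per_species": 12},
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_config(seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-conditions dataset (the generator's defaults)."""
    return generate(SyntheticConfig(seed=11))
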