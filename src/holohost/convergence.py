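"""Host-side statistics: which plant groups attract parasitism, and from
how many independent parasite lineages.

The central objects are per-host-family counts of the parasite species,
genera and lineages (parasite families) recorded on them.  A host family
hit by several of the nine independent holoparasite lineages is a case of
evolutionary convergence in host preference.  Disproportionality relates
a host group's share of parasitized species to its share of angiosperm
diversity (ratio > 1 means over-parasitized for its size).  Further
summaries partition hosts by major clade (monocot / eudicot / ...), break
Asteraceae hosts down by tribe, and tabulate host growth habit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .records import HABITS, RecordSet

logger = logging.getLogger(__name__)

#: Number of monocot families (used for "x of the N monocot families" shares).
N_MONOCOT_FAMILIES = 77

MAJOR_CLADES = ("monocot", "eudicot", "other_angiosperm", "gymnosperm",
                "fern_lycopod")


@dataclass
class HostFamilySummary:
    host_family: str
    n_parasite_species: int
    n_parasite_genera: int
    n_parasite_lineages: int
    disproportionality: float | None = None


class CladeMap:
    """host_family -> major clade mapping."""

    def __init__(self, mapping: dict[str, str]):
        bad = {f: c for f, c in mapping.items() if c not in MAJOR_CLADES}
        if bad:
            raise ValueError(f"unknown clade label(s): {bad}")
        self.mapping = dict(mapping)

    @classmethod
    def from_csv(cls, path) -> "CladeMap":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["host_family"], df["clade"])))

    @classmethod
    def default(cls) -> "CladeMap":
        with resources.files("holohost.data").joinpath("clade_map.csv").open() as fh:
            df = pd.read_csv(fh, dtype=str)
        return cls(dict(zip(df["host_family"], df["clade"])))

    def get(self, family: str) -> str | None:
        return self.mapping.get(family)


class TribeMap:
    """Asteraceae host genus -> tribe mapping."""

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)

    @classmethod
    def from_csv(cls, path) -> "TribeMap":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["host_genus"], df["tribe"])))

    @classmethod
    def default(cls) -> "TribeMap":
        with resources.files("holohost.data").joinpath("asteraceae_tribes.csv").open() as fh:
            df = pd.read_csv(fh, dtype=str)
        return cls(dict(zip(df["host_genus"], df["tribe"])))

    def get(self, genus: str) -> str | None:
        return self.mapping.get(genus)


@dataclass
class DiversityShares:
    """Fractions of angiosperm species diversity per host group."""

    shares: dict[str, float]

    def __post_init__(self):
        for g, s in self.shares.items():
            if not (0 < s <= 1):
                raise ValueError(f"share for {g} outside (0, 1]: {s}")

    @classmethod
    def default(cls) -> "DiversityShares":
        # Asteraceae hold ~10 % of angiosperm species, monocots ~23 %
        return cls({"Asteraceae": 0.10, "monocot": 0.23})


def _records_frame(rs: RecordSet) -> pd.DataFrame:
    return pd.DataFrame([{
        "parasite_species": r.parasite_species,
        "parasite_genus": r.parasite_genus,
        "parasite_family": r.parasite_family,
        "host_species": r.host_species,
        "host_genus": r.host_genus,
        "host_family": r.host_family,
        "host_habit": r.host_habit,
    } for r in rs])


def host_family_summary(analysis_set: RecordSet) -> list[HostFamilySummary]:
    """Distinct parasite species / genera / lineages per host family."""
    if not len(analysis_set):
        return []
    df = _records_frame(analysis_set)
    g = df.groupby("host_family").agg(
        n_parasite_species=("parasite_species", "nunique"),
        n_parasite_genera=("parasite_genus", "nunique"),
        n_parasite_lineages=("parasite_family", "nunique"))
    g = g.sort_values(["n_parasite_species", "host_family"],
                      ascending=[False, True])
    return [HostFamilySummary(host_family=fam, **row)
            for fam, row in g.to_dict("index").items()]


def parasite_family_breadth(analysis_set: RecordSet) -> pd.DataFrame:
    """Per parasite lineage: species with data and distinct host families."""
    if not len(analysis_set):
        return pd.DataFrame(columns=["parasite_family", "n_parasite_species",
                                     "n_host_families"])
    df = _records_frame(analysis_set)
    out = df.groupby("parasite_family").agg(
        n_parasite_species=("parasite_species", "nunique"),
        n_host_families=("host_family", "nunique")).reset_index()
    return out.sort_values("n_host_families", ascending=False,
                           ignore_index=True)


def disproportionality(summaries: list[HostFamilySummary],
                       shares: DiversityShares,
                       total_parasite_species: int) -> list[HostFamilySummary]:
    """Attach (parasite share) / (diversity share) ratios where a
    diversity share is known; families without a share keep ``None``."""
    if total_parasite_species <= 0:
        raise ValueError("total_parasite_species must be positive")
    for s in summaries:
        share = shares.shares.get(s.host_family)
        if share is not None:
            s.disproportionality = (
                s.n_parasite_species / total_parasite_species) / share
    return summaries


def clade_partition(analysis_set: RecordSet, cm: CladeMap) -> pd.DataFrame:
    """Distinct host families and parasite species per major host clade.

    Every clade appears in the output (zero rows included).  Records whose
    host family is missing from the map are collected in an
    ``unmapped_families`` attribute on the returned frame, never silently
    dropped.
    """
    df = _records_frame(analysis_set) if len(analysis_set) else \
        pd.DataFrame(columns=["host_family", "parasite_species"])
    df = df.copy()
    df["clade"] = df["host_family"].map(cm.mapping)
    unmapped = sorted(df.loc[df["clade"].isna(), "host_family"].unique())
    if unmapped:
        logger.warning("host families missing from clade map: %s",
                       ", ".join(unmapped))
    mapped = df.dropna(subset=["clade"])
    g = mapped.groupby("clade").agg(
        n_host_families=("host_family", "nunique"),
        n_parasite_species=("parasite_species", "nunique"))
    g = g.reindex(MAJOR_CLADES, fill_value=0).reset_index(names="clade")
    g.attrs["unmapped_families"] = unmapped
    return g


def tribe_breakdown(analysis_set: RecordSet, tm: TribeMap) -> pd.DataFrame:
    """Asteraceae-host records grouped by tribe of the host genus, with
    counts of parasite species and parasite families per tribe."""
    if not len(analysis_set):
        return pd.DataFrame(columns=["tribe", "n_parasite_species",
                                     "n_parasite_families"])
    df = _records_frame(analysis_set)
    ast = df[df["host_family"] == "Asteraceae"].copy()
    if ast.empty:
        return pd.DataFrame(columns=["tribe", "n_parasite_species",
                                     "n_parasite_families"])
    ast["tribe"] = ast["host_genus"].map(tm.mapping)
    unmapped = sorted(ast.loc[ast["tribe"].isna() & (ast["host_genus"] != ""),
                              "host_genus"].unique())
    if unmapped:
        logger.warning("Asteraceae host genera missing from tribe map: %s",
                       ", ".join(unmapped))
    out = (ast.dropna(subset=["tribe"]).groupby("tribe")
           .agg(n_parasite_species=("parasite_species", "nunique"),
                n_parasite_families=("parasite_family", "nunique"))
           .sort_values("n_parasite_species", ascending=False)
           .reset_index())
    out.attrs["unmapped_genera"] = unmapped
    return out


def habit_summary(analysis_set: RecordSet, per: str = "host"
                  ) -> pd.DataFrame:
    """Counts and proportions of hosts per growth-habit class.

    ``per="host"`` (default) counts distinct host species (hosts not
    identified to species fall under their records' habit, normally
    ``unknown``, keyed by family); ``per="record"`` counts raw records.
    Proportions sum to 1.
    """
    if not len(analysis_set):
        return pd.DataFrame(columns=["host_habit", "count", "proportion"])
    df = _records_frame(analysis_set).copy()
    if per == "record":
        counts = df["host_habit"].value_counts()
    elif per == "host":
        df["host_key"] = df["host_species"].where(
            df["host_species"] != "", df["host_family"] + ":unidentified")
        counts = (df.drop_duplicates(["host_key", "host_habit"])
                  ["host_habit"].value_counts())
    else:
        raise ValueError(f"unknown counting basis {per!r}")
    counts = counts.reindex(HABITS, fill_value=0)
    out = counts.rename_axis("host_habit").reset_index(name="count")
    out["proportion"] = out["count"] / out["count"].sum()
    return out


def summary_frame(summaries: list[HostFamilySummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "host_family": s.host_family,
        "n_parasite_species": s.n_parasite_species,
        "n_parasite_genera": s.n_parasite_genera,
        "n_parasite_lineages": s.n_parasite_lineages,
        "disproportionality": s.disproportionality,
    } for s in summaries])
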