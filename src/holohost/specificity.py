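"""Per-parasite host-specificity profiles and lineage-level summaries.

Host specificity is counted at three taxonomic ranks: unique host
species, genera and families per parasite species.  Hosts identified only
to genus contribute to the genus and family counts but not the species
count; hosts identified only to family contribute to the family count
only — partial identification never manufactures phantom names.

For distribution plots and medians the profiles are subset to parasites
with reasonably supported data: a parasite is retained iff some single
host species has at least two records for it, or it has at least one
high-confidence record.  An alternative reading (at least two records
overall) is available via ``mode="any_two_records"``.

Extreme ends of the spectrum are flagged: an *extreme specialist* has a
single exclusive host species (all its hosts identified to species, and
either two records of that host or one high-confidence record — species
known from one unsupported report are not flagged); an *extreme
generalist* has recorded hosts in six or more families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median

import pandas as pd

from .records import HostRecord, RecordSet

logger = logging.getLogger(__name__)


@dataclass
class SpecificityProfile:
    parasite_species: str
    parasite_family: str
    n_records: int
    n_host_species: int
    n_host_genera: int
    n_host_families: int
    is_extreme_specialist: bool = False
    is_extreme_generalist: bool = False


@dataclass
class LineageSummary:
    parasite_family: str
    n_parasite_species_with_data: int
    median_host_species: float
    median_host_genera: float
    median_host_families: float


class ParasiteNotFound(KeyError):
    pass


def _profile(recs: list[HostRecord]) -> tuple[int, int, int]:
    species = {r.host_species for r in recs if r.host_species}
    genera = {r.host_genus for r in recs if r.host_genus}
    families = {r.host_family for r in recs}
    return len(species), len(genera), len(families)


def host_counts(analysis_set: RecordSet, parasite_species: str
                ) -> SpecificityProfile:
    """Unique-host counts at species, genus and family rank for one parasite."""
    recs = [r for r in analysis_set if r.parasite_species == parasite_species]
    if not recs:
        raise ParasiteNotFound(parasite_species)
    n_sp, n_gen, n_fam = _profile(recs)
    return SpecificityProfile(
        parasite_species=parasite_species,
        parasite_family=recs[0].parasite_family,
        n_records=len(recs),
        n_host_species=n_sp,
        n_host_genera=n_gen,
        n_host_families=n_fam,
    )


def all_profiles(analysis_set: RecordSet) -> list[SpecificityProfile]:
    """One profile per parasite species present in the analysis set."""
    out = []
    for sp, recs in analysis_set.by_parasite().items():
        n_sp, n_gen, n_fam = _profile(recs)
        out.append(SpecificityProfile(
            parasite_species=sp, parasite_family=recs[0].parasite_family,
            n_records=len(recs), n_host_species=n_sp,
            n_host_genera=n_gen, n_host_families=n_fam))
    return out


def _is_supported(recs: list[HostRecord], mode: str) -> bool:
    if any(r.confidence == "high" for r in recs):
        return True
    if mode == "any_two_records":
        return len(recs) >= 2
    counts: dict[str, int] = {}
    for r in recs:
        if r.host_species:
            counts[r.host_species] = counts.get(r.host_species, 0) + 1
    return any(c >= 2 for c in counts.values())


def supported_subset(profiles: list[SpecificityProfile],
                     analysis_set: RecordSet,
                     mode: str = "same_species") -> list[SpecificityProfile]:
    """Subset profiles to parasites with adequately supported host data.

    ``mode="same_species"`` (default): keep a parasite iff some host
    species has >=2 records for it, or it has >=1 high-confidence record.
    ``mode="any_two_records"``: >=2 records overall, or >=1 high record.
    """
    if mode not in ("same_species", "any_two_records"):
        raise ValueError(f"unknown subset mode {mode!r}")
    by_parasite = analysis_set.by_parasite()
    out = []
    for p in profiles:
        recs = by_parasite.get(p.parasite_species, [])
        if recs and _is_supported(recs, mode):
            out.append(p)
    return out


def lineage_medians(profiles: list[SpecificityProfile]
                    ) -> list[LineageSummary]:
    """Median host species/genus/family counts per parasite lineage, with
    an "overall" row across every profile.  Standard medians (mean of the
    two central order statistics when n is even)."""
    by_fam: dict[str, list[SpecificityProfile]] = {}
    for p in profiles:
        by_fam.setdefault(p.parasite_family, []).append(p)
    out = []
    for fam in sorted(by_fam):
        ps = by_fam[fam]
        if not ps:
            logger.warning("lineage %s has no profiles; omitted", fam)
            continue
        out.append(LineageSummary(
            parasite_family=fam,
            n_parasite_species_with_data=len(ps),
            median_host_species=median(p.n_host_species for p in ps),
            median_host_genera=median(p.n_host_genera for p in ps),
            median_host_families=median(p.n_host_families for p in ps)))
    if profiles:
        out.append(LineageSummary(
            parasite_family="overall",
            n_parasite_species_with_data=len(profiles),
            median_host_species=median(p.n_host_species for p in profiles),
            median_host_genera=median(p.n_host_genera for p in profiles),
            median_host_families=median(p.n_host_families for p in profiles)))
    return out


def flag_extremes(profiles: list[SpecificityProfile],
                  analysis_set: RecordSet) -> list[SpecificityProfile]:
    """Set the extreme-specialist / extreme-generalist flags in place.

    Specialist: exactly one host species, every record identified to
    species, and either >=2 records of that host or one high-confidence
    record.  Generalist: hosts in >=6 families.  Mutually exclusive by
    construction (1 species implies 1 family).
    """
    by_parasite = analysis_set.by_parasite()
    for p in profiles:
        recs = by_parasite.get(p.parasite_species, [])
        p.is_extreme_generalist = p.n_host_families >= 6
        p.is_extreme_specialist = False
        if p.n_host_species == 1 and recs and all(r.host_species for r in recs):
            supported = (len(recs) >= 2
                         or any(r.confidence == "high" for r in recs))
            p.is_extreme_specialist = supported
    return profiles


def profiles_frame(profiles: list[SpecificityProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame (per-parasite unique host families, genera
    and species), ready for CSV export."""
    return pd.DataFrame([{
        "parasite_species": p.parasite_species,
        "parasite_family": p.parasite_family,
        "n_records": p.n_records,
        "n_host_families": p.n_host_families,
        "n_host_genera": p.n_host_genera,
        "n_host_species": p.n_host_species,
        "extreme_specialist": p.is_extreme_specialist,
        "extreme_generalist": p.is_extreme_generalist,
    } for p in profiles])


def medians_frame(summaries: list[LineageSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parasite_family": s.parasite_family,
        "n_parasite_species_with_data": s.n_parasite_species_with_data,
        "median_host_species": s.median_host_species,
        "median_host_genera": s.median_host_genera,
        "median_host_families": s.median_host_families,
    } for s in summaries])
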