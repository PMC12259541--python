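"""Analysis-set construction from a rated record database.

Two filtering steps produce the set used by all downstream statistics:

1. every low-confidence record is dropped;
2. a parasite species left with exactly one record, of medium confidence,
   is excluded — unless that record's host family also features in a
   high-confidence record of at least one *other* parasite species in the
   same parasite genus (the "congeneric rescue", which avoids discarding
   plausible hosts purely for lack of data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import HostRecord, RecordSet
from .confidence import ClassificationError

logger = logging.getLogger(__name__)


@dataclass
class FilterResult:
    kept: RecordSet
    removed_record_ids: list[str] = field(default_factory=list)
    removed_parasite_species: list[str] = field(default_factory=list)
    #: (parasite kept, host family, congeneric parasite providing the
    #: high-confidence backing)
    rescue_log: list[tuple[str, str, str]] = field(default_factory=list)
    #: record ids dropped in the low-confidence step (empty when the
    #: result comes from single_medium_filter alone)
    dropped_low_record_ids: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_record_ids)


def drop_low(rs: RecordSet) -> tuple[RecordSet, list[str]]:
    """Remove every low-confidence record, preserving order.

    Raises on unrated records: rating must precede filtering.
    """
    kept, dropped = [], []
    for r in rs:
        if r.confidence not in ("low", "medium", "high"):
            raise ClassificationError(f"record {r.record_id} is unrated")
        (dropped if r.confidence == "low" else kept).append(r)
    return (RecordSet(records=kept, provenance=rs.provenance),
            [r.record_id for r in dropped])


def single_medium_filter(rs: RecordSet) -> FilterResult:
    """Apply the single-medium-report exclusion with congeneric rescue.

    Precondition: ``rs`` contains no low-confidence records.  A parasite
    species is excluded iff its record set is exactly one record of
    medium confidence and no other species of the same parasite genus has
    a high-confidence record in that record's host family.
    """
    high_families_by_genus: dict[str, dict[str, set[str]]] = {}
    for r in rs:
        if r.confidence == "high":
            high_families_by_genus.setdefault(
                r.parasite_genus, {}).setdefault(r.host_family, set()).add(
                r.parasite_species)

    by_parasite = rs.by_parasite()
    res = FilterResult(kept=RecordSet(provenance=rs.provenance))
    drop_species: set[str] = set()
    for sp, recs in by_parasite.items():
        if len(recs) == 1 and recs[0].confidence == "medium":
            r = recs[0]
            backers = {
                b for b in high_families_by_genus
                .get(r.parasite_genus, {}).get(r.host_family, set())
                if b != sp
            }
            if backers:
                rescuer = sorted(backers)[0]
                res.rescue_log.append((sp, r.host_family, rescuer))
                logger.info("kept singleton-medium %s: host family %s backed "
                            "by high record of congener %s",
                            sp, r.host_family, rescuer)
            else:
                drop_species.add(sp)
                res.removed_parasite_species.append(sp)
                res.removed_record_ids.append(r.record_id)
                logger.info("removed %s: single unrescued medium record %s",
                            sp, r.record_id)

    res.kept.records = [r for r in rs if r.parasite_species not in drop_species]
    return res


def build_analysis_set(rs: RecordSet) -> FilterResult:
    """drop_low followed by single_medium_filter; the kept set is the
    analysis set consumed by every downstream statistic."""
    no_low, low_ids = drop_low(rs)
    res = single_medium_filter(no_low)
    res.dropped_low_record_ids = low_ids
    return res


def filter_log_frame(res: FilterResult) -> pd.DataFrame:
    """Removal/rescue log as a tidy DataFrame (for CSV export)."""
    rows = [
        {"action": "drop_low", "record_id": rid, "parasite_species": "",
         "host_family": "", "rescuer": ""}
        for rid in res.dropped_low_record_ids
    ]
    id_by_species = dict(zip(res.removed_parasite_species,
                             res.removed_record_ids))
    for sp in res.removed_parasite_species:
        rows.append({"action": "remove_single_medium",
                     "record_id": id_by_species[sp], "parasite_species": sp,
                     "host_family": "", "rescuer": ""})
    for sp, fam, rescuer in res.rescue_log:
        rows.append({"action": "rescue", "record_id": "",
                     "parasite_species": sp, "host_family": fam,
                     "rescuer": rescuer})
    return pd.DataFrame(
        rows, columns=["action", "record_id", "parasite_species",
                       "host_family", "rescuer"])
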