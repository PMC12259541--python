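"""Three-tier confidence rating of host records as a deterministic rule engine.

Every record's provenance flags are mapped to exactly one of
``low`` / ``medium`` / ``high``.  Two rules are *contextual* — they look at
the rest of the database for the same parasite — so rating is a two-pass
procedure: a first pass applies only context-free rules and collects, per
parasite, the host genera backed by high-confidence evidence and the full
set of recorded host families; the second pass then applies the contextual
rules against that fixed context.  No fixed-point iteration is needed and
the result is independent of record order.

Rule inventory (stable ids used in logs):

``high`` criteria
    H1  parasite excavated and host contact confirmed
    H2  report made by an expert in the group
    H3  herbarium sheet carries identified host material
    H4  public-database observation with the host connection visible in a
        photograph

``medium`` criteria
    M1  plain report where excavation is unclear (the host may simply be
        the nearest plant)
    M2  pre-1950 publication cap: any otherwise-high report published
        before 1950 is capped at medium unless excavation is explicit
    M3  herbarium sheet names a host but carries no host material
    M4  database observation with the host visible in a photo, or whose
        host genus matches a high-confidence record of the same parasite

``low`` criteria
    L1  the author flags the report as dubious (dominates everything)
    L2  unconfirmed report from a family unrelated (no shared order) to
        every other recorded host family for that parasite
    L3  database observation with no photo and no congeneric
        high-confidence backing

Precedence: L1, then high (with the M2 cap), then medium, then low
fallbacks, then a logged medium default ("unmatched-evidence").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import Evidence, HostRecord, RecordSet

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    pass


@dataclass
class ConfidenceContext:
    """Per-parasite dataset context consumed by the contextual rules.

    ``high_host_genera``: host genera appearing in records of a parasite
    that rate high under context-free rules (or arrive pre-rated high).
    ``recorded_families``: every (host_family, host_order) pair recorded
    for the parasite at any confidence.
    """

    high_host_genera: dict[str, set[str]] = field(default_factory=dict)
    recorded_families: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def genus_is_high(self, parasite: str, genus: str) -> bool:
        return bool(genus) and genus in self.high_host_genera.get(parasite, set())

    def family_unrelated(self, parasite: str, family: str, order: str) -> bool:
        """True when `family` shares no order with any *other* recorded
        host family of the parasite (order-level proxy for "completely
        unrelated").  Vacuously false when there are no other families or
        when orders are unknown."""
        others = {
            (f, o) for (f, o) in self.recorded_families.get(parasite, set())
            if f != family
        }
        if not others or not order:
            return False
        other_orders = {o for _, o in others}
        if "" in other_orders:
            return False  # cannot establish unrelatedness with unknown orders
        return order not in other_orders


def _high_rule(e: Evidence) -> str | None:
    if e.excavated_confirmed:
        return "H1"
    if e.expert_report:
        return "H2"
    if e.host_material_on_sheet:
        return "H3"
    if e.database_observation and e.photo_connection_visible:
        return "H4"
    return None


def _classify(e: Evidence, rec: HostRecord, ctx: ConfidenceContext,
              contextual: bool = True) -> tuple[str, str]:
    """Return (rating, rule_id).  With ``contextual`` off the two dataset
    rules are not consulted (first-pass mode)."""
    if e.author_flags_dubious:
        return "low", "L1"

    high = _high_rule(e)
    if high is not None:
        if e.pre_1950 and not e.excavation_explicit:
            return "medium", "M2"
        return "high", high

    # medium criteria
    if e.herbarium_host_named_no_material:
        return "medium", "M3"
    if e.database_observation:
        if e.photo_host_visible:
            return "medium", "M4"
        if contextual and ctx.genus_is_high(rec.parasite_species, rec.host_genus):
            return "medium", "M4"
    else:
        # a plain (non-database, non-herbarium) report without confirmed
        # excavation: the host may be the nearest plant by observation
        if contextual and ctx.family_unrelated(
                rec.parasite_species, rec.host_family, rec.host_order):
            return "low", "L2"
        return "medium", "M1"

    # low fallbacks (only database observations reach this point)
    if not e.has_photo:
        return "low", "L3"

    logger.info("record %s: unmatched-evidence, defaulting to medium",
                rec.record_id)
    return "medium", "M-default"


def classify_confidence(e: Evidence, rec: HostRecord,
                        ctx: ConfidenceContext) -> str:
    """Rate a single record. Raises ClassificationError on empty evidence."""
    if e is None:
        raise ClassificationError(
            f"record {rec.record_id}: no evidence; supply confidence directly")
    return _classify(e, rec, ctx)[0]


def classify_with_rule(e: Evidence, rec: HostRecord,
                       ctx: ConfidenceContext) -> tuple[str, str]:
    """As :func:`classify_confidence` but also returns the rule id."""
    if e is None:
        raise ClassificationError(
            f"record {rec.record_id}: no evidence; supply confidence directly")
    return _classify(e, rec, ctx)


def build_context(rs: RecordSet) -> ConfidenceContext:
    """First pass: collect the contextual maps using context-free rules only.

    A record contributes its host genus to the high-genus map if the
    context-free engine rates it high, or if it arrived with a pre-set
    high confidence and no evidence.  Every record contributes its
    (host_family, host_order) pair.  Deterministic for a fixed RecordSet.
    """
    ctx = ConfidenceContext()
    empty = ConfidenceContext()
    for r in rs:
        ctx.recorded_families.setdefault(r.parasite_species, set()).add(
            (r.host_family, r.host_order))
        if r.evidence is not None:
            rating, _ = _classify(r.evidence, r, empty, contextual=False)
        else:
            rating = r.confidence
        if rating == "high" and r.host_genus:
            ctx.high_host_genera.setdefault(r.parasite_species, set()).add(
                r.host_genus)
    return ctx


@dataclass
class RatingErrorReport:
    unratable_record_ids: list[str] = field(default_factory=list)


def apply_ratings(rs: RecordSet, overwrite: bool = False
                  ) -> tuple[RecordSet, RatingErrorReport]:
    """Second pass: rate every record that carries evidence.

    Records with a pre-set confidence keep it unless ``overwrite``.
    Records with neither evidence nor a pre-set confidence are listed in
    the error report.  Idempotent and deterministic.
    """
    ctx = build_context(rs)
    out: list[HostRecord] = []
    errs = RatingErrorReport()
    for r in rs:
        if r.confidence and not overwrite:
            out.append(r)
            continue
        if r.evidence is None:
            if not r.confidence:
                errs.unratable_record_ids.append(r.record_id)
            out.append(r)
            continue
        rating, rule = _classify(r.evidence, r, ctx)
        out.append(r.copy(confidence=rating))
        logger.debug("record %s rated %s by %s", r.record_id, rating, rule)
    return RecordSet(records=out, provenance=rs.provenance), errs


def confidence_tally(rs: RecordSet) -> dict[str, int]:
    """Counts per rating plus total.  Raises if any record is unrated."""
    counts = {"low": 0, "medium": 0, "high": 0}
    for r in rs:
        if r.confidence not in counts:
            raise ClassificationError(f"record {r.record_id} is unrated")
        counts[r.confidence] += 1
    counts["total"] = len(rs)
    return counts
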