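"""Host-record data model, table I/O, validation and deduplication.

One :class:`HostRecord` is one documented report of a host for a
holoparasitic plant species: who parasitizes whom, where the report comes
from, and how trustworthy it is.  A database of such records (the shape of
a curated host-preference spreadsheet) is held in a :class:`RecordSet`.

Missing values are represented by the empty string throughout; the record
table on disk is a UTF-8 CSV or TSV with fixed snake_case column names in
any column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed host habit classes ("unknown" = host not identified to species).
HABITS = (
    "annual_herb",
    "biennial_herb",
    "perennial_herb",
    "liana",
    "shrub",
    "tree",
    "unknown",
)

#: Allowed provenance classes for a record.
RECORD_TYPES = (
    "protologue",
    "flora",
    "monograph",
    "article",
    "herbarium",
    "database_obs",
    "other",
)

#: The three confidence tiers.
CONFIDENCE_LEVELS = ("low", "medium", "high")

#: Boolean provenance flags, in canonical order.
EVIDENCE_FLAGS = (
    "excavated_confirmed",
    "expert_report",
    "host_material_on_sheet",
    "photo_connection_visible",
    "photo_host_visible",
    "pre_1950",
    "excavation_explicit",
    "herbarium_host_named_no_material",
    "database_observation",
    "has_photo",
    "author_flags_dubious",
)


@dataclass(frozen=True)
class Evidence:
    """Provenance flags feeding the confidence rule engine.

    Internal consistency: a visible photo of the host or of the
    host--parasite connection implies a photo exists, and an explicit
    statement of excavation implies excavation was confirmed.
    """

    excavated_confirmed: bool = False
    expert_report: bool = False
    host_material_on_sheet: bool = False
    photo_connection_visible: bool = False
    photo_host_visible: bool = False
    pre_1950: bool = False
    excavation_explicit: bool = False
    herbarium_host_named_no_material: bool = False
    database_observation: bool = False
    has_photo: bool = False
    author_flags_dubious: bool = False

    def violations(self) -> list[str]:
        out = []
        if self.photo_connection_visible and not self.has_photo:
            out.append("photo-connection-implies-photo")
        if self.photo_host_visible and not self.has_photo:
            out.append("photo-host-implies-photo")
        if self.excavation_explicit and not self.excavated_confirmed:
            out.append("explicit-excavation-implies-confirmed")
        return out

    def is_valid(self) -> bool:
        return not self.violations()

    def any_flag(self) -> bool:
        return any(getattr(self, f) for f in EVIDENCE_FLAGS)


@dataclass
class HostRecord:
    """One documented parasite-on-host report."""

    record_id: str
    parasite_species: str
    parasite_genus: str
    parasite_family: str
    host_family: str
    host_species: str = ""
    host_genus: str = ""
    host_order: str = ""
    host_habit: str = "unknown"
    region: str = ""
    record_type: str = "other"
    reference_id: str = ""
    evidence: Evidence | None = None
    confidence: str = ""  # "", "low", "medium" or "high"

    def copy(self, **changes) -> "HostRecord":
        return replace(self, **changes)


@dataclass
class RecordSet:
    """Ordered collection of host records with a provenance note."""

    records: list[HostRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HostRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def by_parasite(self) -> dict[str, list[HostRecord]]:
        out: dict[str, list[HostRecord]] = {}
        for r in self.records:
            out.setdefault(r.parasite_species, []).append(r)
        return out

    def parasite_species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.parasite_species)
        return list(seen)


@dataclass
class Violation:
    record_id: str
    rule: str
    detail: str = ""


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


class SchemaError(ValueError):
    """The table on disk does not match the documented schema."""


class IntegrityError(ValueError):
    """Duplicate record ids or similar structural corruption."""


_REQUIRED_COLUMNS = (
    "record_id",
    "parasite_species",
    "parasite_genus",
    "parasite_family",
    "host_family",
)
_OPTIONAL_COLUMNS = (
    "host_species",
    "host_genus",
    "host_order",
    "host_habit",
    "region",
    "record_type",
    "reference_id",
    "confidence",
)


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_records(path, strict: bool = False) -> RecordSet:
    """Read a host-record table (CSV or TSV; delimiter auto-detected).

    Evidence flags are read from optional ``ev_<flag>`` columns holding
    0/1; a row with no ``ev_`` column set and all flags absent carries no
    evidence.  Unknown habit or record-type vocabulary maps to
    ``unknown``/``other`` with a logged warning unless ``strict``.

    Raises
    ------
    SchemaError
        if a required column is missing.
    IntegrityError
        if two rows share a ``record_id``.
    ValueError
        in strict mode, for out-of-vocabulary enum values (names the row).
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    ev_cols = [c for c in df.columns if c.startswith("ev_")]
    for c in ev_cols:
        flag = c[3:]
        if flag not in EVIDENCE_FLAGS:
            raise SchemaError(f"unknown evidence column: {c}")

    records: list[HostRecord] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        rid = row["record_id"].strip()
        if rid in seen_ids:
            raise IntegrityError(f"duplicate record_id {rid!r} (row {idx + 2})")
        seen_ids.add(rid)

        habit = row.get("host_habit", "unknown").strip() or "unknown"
        if habit not in HABITS:
            if strict:
                raise ValueError(
                    f"row {idx + 2} (record {rid!r}): unknown habit {habit!r}"
                )
            logger.warning("record %s: habit %r not in vocabulary, using 'unknown'",
                           rid, habit)
            habit = "unknown"

        rtype = row.get("record_type", "other").strip() or "other"
        if rtype not in RECORD_TYPES:
            if strict:
                raise ValueError(
                    f"row {idx + 2} (record {rid!r}): unknown record_type {rtype!r}"
                )
            logger.warning("record %s: record_type %r not in vocabulary, using "
                           "'other'", rid, rtype)
            rtype = "other"

        conf = row.get("confidence", "").strip().lower()
        if conf and conf not in CONFIDENCE_LEVELS:
            raise ValueError(
                f"row {idx + 2} (record {rid!r}): unknown confidence {conf!r}"
            )

        evidence = None
        if ev_cols:
            flags = {c[3:]: str(row[c]).strip() in ("1", "true", "True")
                     for c in ev_cols}
            if any(flags.values()):
                evidence = Evidence(**flags)

        records.append(HostRecord(
            record_id=rid,
            parasite_species=row["parasite_species"].strip(),
            parasite_genus=row["parasite_genus"].strip(),
            parasite_family=row["parasite_family"].strip(),
            host_family=row["host_family"].strip(),
            host_species=row.get("host_species", "").strip(),
            host_genus=row.get("host_genus", "").strip(),
            host_order=row.get("host_order", "").strip(),
            host_habit=habit,
            region=row.get("region", "").strip(),
            record_type=rtype,
            reference_id=row.get("reference_id", "").strip(),
            evidence=evidence,
            confidence=conf,
        ))
    return RecordSet(records=records, provenance=str(path))


def to_frame(rs: RecordSet) -> pd.DataFrame:
    """RecordSet as a DataFrame in the on-disk schema (evidence expanded)."""
    rows = []
    any_evidence = any(r.evidence is not None for r in rs)
    for r in rs:
        d = {
            "record_id": r.record_id,
            "parasite_species": r.parasite_species,
            "parasite_genus": r.parasite_genus,
            "parasite_family": r.parasite_family,
            "host_species": r.host_species,
            "host_genus": r.host_genus,
            "host_family": r.host_family,
            "host_order": r.host_order,
            "host_habit": r.host_habit,
            "region": r.region,
            "record_type": r.record_type,
            "reference_id": r.reference_id,
            "confidence": r.confidence,
        }
        if any_evidence:
            ev = r.evidence or Evidence()
            for f in EVIDENCE_FLAGS:
                d[f"ev_{f}"] = int(getattr(ev, f)) if r.evidence else 0
        rows.append(d)
    cols = list(rows[0]) if rows else list(_REQUIRED_COLUMNS)
    return pd.DataFrame(rows, columns=cols)


def write_records(rs: RecordSet, path) -> None:
    """Write a RecordSet as CSV in the documented schema."""
    to_frame(rs).to_csv(path, index=False)


def validate_records(rs: RecordSet) -> ValidationReport:
    """Check every record against the data-model invariants.

    Report-only: all violations are listed with record id and rule name;
    nothing raises.  An empty report means the set is fully valid.
    """
    report = ValidationReport()
    seen: set[str] = set()
    for r in rs:
        if r.record_id in seen:
            report.violations.append(Violation(r.record_id, "unique-id"))
        seen.add(r.record_id)
        if not r.record_id:
            report.violations.append(Violation(r.record_id, "empty-record-id"))
        if not r.host_family:
            report.violations.append(Violation(r.record_id, "host-family-required"))
        if r.host_species and not r.host_genus:
            report.violations.append(Violation(r.record_id, "species-implies-genus"))
        for f in ("parasite_species", "parasite_genus", "parasite_family"):
            if not getattr(r, f):
                report.violations.append(
                    Violation(r.record_id, "parasite-fields-required", f))
        if r.confidence and r.confidence not in CONFIDENCE_LEVELS:
            report.violations.append(Violation(r.record_id, "confidence-level"))
        if r.host_habit not in HABITS:
            report.violations.append(Violation(r.record_id, "habit-vocabulary"))
        if r.record_type not in RECORD_TYPES:
            report.violations.append(Violation(r.record_id, "record-type-vocabulary"))
        if r.evidence is not None:
            for v in r.evidence.violations():
                report.violations.append(Violation(r.record_id, f"evidence:{v}"))
    return report


def _dedup_key(r: HostRecord) -> tuple[str, str, str]:
    host = r.host_species if r.host_species else r.host_family
    return (r.parasite_species, host, r.reference_id)


def deduplicate(rs: RecordSet) -> tuple[RecordSet, list[str]]:
    """Collapse exact duplicates of (parasite, host, reference).

    The host component of the key is the host species, falling back to the
    host family when the host was not identified to species.  Duplicates
    within one reference are collapsed to the first occurrence.  The same
    parasite--host pair reported under *different* references is kept: an
    original report is a new record even for a known host.  Suspected
    cross-reference reiterations are a curatorial judgement and are only
    flagged in the log, never removed automatically.
    """
    kept: list[HostRecord] = []
    removed: list[str] = []
    seen: set[tuple[str, str, str]] = set()
    pair_refs: dict[tuple[str, str], set[str]] = {}
    for r in rs:
        key = _dedup_key(r)
        if key in seen:
            removed.append(r.record_id)
            continue
        seen.add(key)
        kept.append(r)
        pair = key[:2]
        refs = pair_refs.setdefault(pair, set())
        if refs and r.reference_id not in refs:
            logger.info(
                "possible reiteration (kept): %s on %s also reported in %s",
                pair[0], pair[1], ", ".join(sorted(refs)))
        refs.add(r.reference_id)
    return RecordSet(records=kept, provenance=rs.provenance), removed
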