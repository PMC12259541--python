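# Methods

This note documents the models, rules and numerical choices behind
`holohost`, in the package's own terms: what each stage assumes, which
parameters matter, and what the synthetic-data tests do and do not
demonstrate about real curated databases.

## Record model and deduplication

A record is a single documented report of a host for a holoparasite
species, not a parasite–host pair: the same interaction reported
independently in two sources is two records. Missing values are empty
strings; `host_family` and the three parasite fields are mandatory, and
a host identified to species must also carry its genus. The
deduplication key is (parasite species, host species — falling back to
host family when the host is unidentified to species, reference id).
Duplicates are collapsed only *within* a reference; cross-reference
repeats are flagged in the log but never removed, because deciding that
a later source merely reiterates an earlier one is a curatorial
judgement that automation should surface, not make.

## Confidence rule engine

Each record's provenance is encoded as eleven boolean evidence flags
with three internal-consistency constraints (a visible host or
connection photo implies a photo; explicit excavation implies confirmed
excavation). The engine maps a flag vector to exactly one of
`low`/`medium`/`high` via a fixed precedence:

P0. `author_flags_dubious` → low (**L1**; dominates everything).
P1. any high criterion — excavation with confirmed host contact
    (**H1**), expert report (**H2**), host material on the herbarium
    sheet (**H3**), database observation with the connection visible in
    a photo (**H4**) — → high, **except** that a pre-1950 publication
    without explicit excavation caps the result at medium (**M2**).
P2. medium criteria: herbarium sheet naming a host without material
    (**M3**); database observation with the host visible in a photo or
    with the host genus backed by a high-confidence record of the same
    parasite (**M4**); otherwise a plain report whose excavation status
    is unclear (**M1**).
P3. low fallbacks: a plain unconfirmed report from a host family
    unrelated to every other family recorded for that parasite
    (**L2**); a database observation with no photo and no congeneric
    high-confidence backing (**L3**).
P4. anything left → medium, logged as `unmatched-evidence`.

The source criteria carry no explicit precedence; dubious-flag dominance
and a *logged* medium default are this package's resolution, chosen so
that conflicts never silently produce a high rating. "Completely
unrelated family" is operationalized at order level — the record's host
family shares no order with any other host family recorded for that
parasite — because order is the finest rank reliably present; when any
order is unknown, or the parasite has no other recorded family, the rule
abstains (conservative: no low rating on unverifiable isolation).

The two contextual rules (M4's genus clause, L2, L3) see a context built
in a first pass that applies only context-free rules, so rating is
deterministic, order-independent and needs no fixed-point iteration. A
consequence tested exhaustively: every valid flag combination in every
context state maps to exactly one tier, and adding a high-confidence
record for a congeneric host genus can only raise other ratings (low →
medium via L3 → M4), never lower them.

## Analysis-set filtering

All low-confidence records are dropped; then a parasite species whose
entire record set is one medium-confidence record is excluded unless a
*different* parasite species of the same genus has a high-confidence
record in the same host family (rescue). A species with one medium plus
one high record is kept — the high record alone justifies retention.
Every removal and rescue is logged; the operation is idempotent and
adding a high-confidence record can only grow the kept set. The
pipeline reports its own post-drop base count rather than forcing
agreement with any externally published base.

## Host specificity

Counts are of unique names per rank. Partially identified hosts count
only at the ranks they are known at ("Asteraceae sp." adds a family,
never a phantom genus or species), so the monotonicity
families ≤ genera ≤ species is guaranteed only when all of a parasite's
hosts are identified to species — the property the tests assert on that
subset. Medians are standard order-statistic medians (mean of the two
central values for even n), matching the default of mainstream
statistical environments.

Distribution summaries use a supported subset: a parasite enters iff
some single host species has ≥ 2 records for it, or it has ≥ 1
high-confidence record. A defensible alternative reading — ≥ 2 records
overall — is available as `mode="any_two_records"`; the default
implements the literal single-host-species reading, without endorsing
either scientifically.

Extreme specialist: exactly one host species, all records identified to
species, and that host supported (≥ 2 records or one high-confidence
record) — a species known from one unsupported report is flagged
neither way. Extreme generalist: hosts in ≥ 6 families. The flags are
mutually exclusive by construction.

## Convergence and host-side summaries

Host-family summaries count *distinct* parasite species, genera and
families (lineages) per host family, so lineages ≤ genera ≤ species
always. Disproportionality divides a family's share of parasitized
species by its share of angiosperm diversity; shares ship as an
editable table (defaults: Asteraceae 0.10, monocots 0.23). The
monocot/eudicot/other-angiosperm/gymnosperm/fern partition and the
Asteraceae genus → tribe assignment are editable CSV configuration, not
code, because host classifications change while the analysis should
not; unmapped families or genera are reported, never dropped silently.
Habit proportions are counted per distinct host species by default
(records of the same host collapse; unidentified hosts enter as one
family-level entry), with per-record counting available, and both
always sum to 1.

## Extent of occurrence

Points (decimal lon/lat, WGS84) are projected with a spherical Lambert
azimuthal equal-area projection on the authalic sphere
(R = 6371.0072 km), centred on the point centroid (circular mean for
longitude, so point sets straddling the antimeridian are rotated before
projection), and the planar convex-hull area is returned in km². Fewer
than three distinct non-collinear points yield area 0 with a
`degenerate` flag. The test oracle computes the same quantity by an
independent route — geodesic polygon area by spherical excess
(l'Huilier triangulation) — and the two agree within 1 % for ranges
spanning ≤ 10°, the regime of almost all species-level EOOs; the
equal-area projection keeps the systematic error far below the noise of
occurrence sampling at continental scales too. For plotting against
specificity the area is transformed as log10(area + 1) so degenerate
(single-locality) species remain at 0 rather than −∞. Regional record
counts use the WGSRPD (TDWG) Level-2 vocabulary shipped as CSV; unknown
codes are counted and warned about, records without a region aggregate
under `unassigned`.

## Interaction matrices

The presence matrix has one row per parasite genus (rows grouped by
parasite family, alphabetical within) and one column per recorded host
family, in the left-to-right tip order of the supplied family-level
newick tree as written — no ladderization, since tip rotation is
cosmetic. Families recorded but absent from the tree are appended after
the ordered columns and listed in a mismatch report. Name matching is
exact after whitespace normalization. Row sums equal genus-level
distinct-host-family counts, which the suite cross-checks against the
specificity module on every synthetic seed.

## Synthetic data generator

The generator emulates the *structure* of a curated holoparasite
host-record database, with defaults fixed at the survey's study
conditions; it makes no claim to reproduce the real data's content.

- **Lineages**: the nine real lineage names with sizes mirroring their
  real asymmetry (Orobanchaceae-dominated; ~357 parasite species
  total, ~3000 records).
- **Host ranges**: zero-truncated negative binomial (mean 5,
  dispersion 1.2) — right-skewed counts ≥ 1 with a long generalist
  tail, qualitatively matching the observed skew; `p_generalist`
  = 0.035 routes a species through an explicit ≥ 6-family branch.
- **Host taxonomy**: nested species ⊂ genus ⊂ family ⊂ order ⊂ clade
  with 40 eudicot / 8 monocot / 4 other-angiosperm / 3 gymnosperm
  families; hosts are drawn with within-genus clustering (60 % stay in
  the genus, 30 % in the family, 10 % jump) under heavily
  eudicot-biased clade weights, echoing the near-absence of monocot
  hosts.
- **Confidence**: the mixture defaults to the 94 : 2071 : 682
  low/medium/high proportions of a 2847-record survey. Evidence flags
  are emitted so *exactly one* rule fires per record and so that the
  contextual rules cannot misfire (no plain-report evidence in an
  order-isolated family; no bare database observation when a
  congeneric high record exists), making 100 % engine agreement the
  correct expectation rather than a tuned outcome.
- **Habits and regions**: habit fixed per host species (36 % shrub,
  31 % perennial herb, 16 % tree, remainder herbs/lianas/unknown);
  regions drawn from a 12-code TDWG Level-2 pool.
- **Geography**: one range disc per parasite (centre in ±170° lon,
  −55…65° lat; radius 100–1500 km) with points uniform on the
  spherical cap; the true cap area 2πR²(1 − cos(r/R)) goes into the
  ground truth, so hull ⊆ disc is an exact invariant.

What the generator does **not** emulate: taxonomic synonymy and
misidentification, spatial and historical recording bias, correlated
evidence within references, real phylogenetic signal in host choice
beyond the clade weights, and overlap of host ranges between related
parasites beyond genus-level clustering. Passing recovery tests
therefore demonstrates the pipeline's correctness and calibration on
structurally realistic inputs — not that the rule engine would
reproduce a human curator's judgements on real literature.

## Problem sizes and determinism

Unit and property tests run on reduced configurations (a few dozen
parasite species, 10–12 occurrence points per species) chosen to
exercise every code path in seconds; the parameter-recovery check uses
300 parasite species over seeds 1–10 under noise-free confidence, where
exact median recovery and perfect extreme-flag recall are the provable
expectation. `scripts/acceptance.py` runs the full default-scale
database (~3000 records) plus the recovery configuration; a single seed
drives every random draw, and fixed seeds reproduce all outputs byte
for byte.

## Known limitations

- The confidence engine encodes one defensible precedence; real
  curators may weigh conflicting evidence differently, and the engine
  deliberately refuses records with no evidence rather than guessing.
- Host and parasite names are assumed pre-resolved; there is no
  synonym matching against nomenclatural backbones.
- The order-level proxy for "unrelated family" misses
  within-order heterogeneity and abstains when orders are missing.
- EOO is a coarse range proxy by design (convex hulls overestimate
  fragmented ranges); the projection is fixed rather than matching any
  particular external tool version, and small differences from other
  EOO implementations are expected at the ~0.1 % level.
- Asteraceae tribe and clade maps ship as small seed tables covering
  common host genera/families; real analyses should supply complete
  maps for their data.
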