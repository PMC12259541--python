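"""Synthetic host-record databases with known ground truth.

The generator emulates the structure of a curated holoparasite
host-preference database: nine parasite lineages of very unequal size,
per-species host ranges drawn from a right-skewed (zero-truncated
negative binomial) distribution with rare many-family generalists, hosts
sampled from a nested taxonomy (species within genus within family
within order within major clade) with within-genus clustering, a
low/medium/high confidence mixture, host habits, recording regions, and
per-species occurrence point clouds on uniform spherical caps.

Evidence flags are emitted so that exactly one classification rule fires
per record and the engine reproduces the generating label, which makes
rule-engine agreement a sharp recovery test.  Every quantity needed to
score the pipeline's output — true host sets, true specialist/generalist
status, true confidence labels, true range disc areas — is returned as
:class:`GroundTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .records import Evidence, HostRecord, RecordSet
from .geo import EARTH_RADIUS_KM, OccurrenceSet

#: The nine independent origins of holoparasitism at family level
#: (Lennooideae, within Boraginaceae, counted as a lineage).
DEFAULT_LINEAGES = {
    # lineage: (n_genera, n_species) -- sizes mirror the real lineages
    "Orobanchaceae": (20, 220),
    "Balanophoraceae": (16, 58),
    "Rafflesiaceae": (3, 30),
    "Hydnoraceae": (2, 18),
    "Cytinaceae": (2, 12),
    "Apodanthaceae": (2, 10),
    "Lennooideae": (2, 5),
    "Mitrastemonaceae": (1, 2),
    "Cynomoriaceae": (1, 2),
}

_DEFAULT_HABITS = {
    "shrub": 0.36,
    "perennial_herb": 0.31,
    "tree": 0.16,
    "annual_herb": 0.08,
    "liana": 0.04,
    "biennial_herb": 0.02,
    "unknown": 0.03,
}

_DEFAULT_REGIONS = ["10", "12", "13", "20", "27", "34", "36", "40",
                    "50", "76", "79", "84"]


class HostTaxonomyConfig(BaseModel):
    """Nested host taxonomy: families per major clade, genera per family,
    species per genus, and per-clade host-draw weights."""

    families_per_clade: dict[str, int] = Field(
        default={"eudicot": 40, "monocot": 8, "other_angiosperm": 4,
                 "gymnosperm": 3})
    genera_per_family: int = 8
    species_per_genus: int = 6
    families_per_order: int = 3
    clade_weights: dict[str, float] = Field(
        default={"eudicot": 0.95, "monocot": 0.02, "other_angiosperm": 0.02,
                 "gymnosperm": 0.01})

    @model_validator(mode="after")
    def _check(self):
        if self.genera_per_family < 1 or self.species_per_genus < 1:
            raise ValueError("taxonomy counts must be >= 1")
        if any(n < 1 for n in self.families_per_clade.values()):
            raise ValueError("families_per_clade must be >= 1")
        return self


class GeoConfig(BaseModel):
    n_points_per_species: int = 20
    radius_km_min: float = 100.0
    radius_km_max: float = 1500.0
    lat_min: float = -55.0
    lat_max: float = 65.0


class SyntheticConfig(BaseModel):
    """Generator configuration; defaults are the study conditions.

    ``host_range_mean`` / ``host_range_dispersion`` parametrize the
    zero-truncated negative binomial of per-parasite host-range sizes
    (mean of the untruncated distribution; dispersion = NB size k, small
    k = heavier right skew).  ``confidence_mixture`` is (p_low, p_medium,
    p_high); the default reproduces the 94 : 2071 : 682 proportions of a
    2847-record survey.
    """

    seed: int = 1
    lineages: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: dict(DEFAULT_LINEAGES))
    host_taxonomy: HostTaxonomyConfig = Field(
        default_factory=HostTaxonomyConfig)
    host_range_mean: float = 5.0
    host_range_dispersion: float = 1.2
    p_generalist: float = 0.035
    extra_records_rate: float = 0.55  # records per interaction = 1 + Poisson
    confidence_mixture: tuple[float, float, float] = (
        94 / 2847, 2071 / 2847, 682 / 2847)
    p_host_identified_to_species: float = 0.9
    habit_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_HABITS))
    region_pool: list[str] = Field(
        default_factory=lambda: list(_DEFAULT_REGIONS))
    geo: GeoConfig = Field(default_factory=GeoConfig)

    @model_validator(mode="after")
    def _check(self):
        if abs(sum(self.confidence_mixture) - 1.0) > 1e-9:
            raise ValueError("confidence_mixture must sum to 1")
        if any(p < 0 for p in self.confidence_mixture):
            raise ValueError("confidence_mixture probabilities must be >= 0")
        if abs(sum(self.habit_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("habit_distribution must sum to 1")
        if not (0 <= self.p_generalist <= 1):
            raise ValueError("p_generalist outside [0, 1]")
        if not (0 <= self.p_host_identified_to_species <= 1):
            raise ValueError("p_host_identified_to_species outside [0, 1]")
        if self.host_range_mean <= 0 or self.host_range_dispersion <= 0:
            raise ValueError("host range parameters must be positive")
        if any(g < 1 or s < 1 for g, s in self.lineages.values()):
            raise ValueError("lineage genus/species counts must be >= 1")
        return self


@dataclass
class HostSpecies:
    species: str
    genus: str
    family: str
    order: str
    clade: str
    habit: str


@dataclass
class GroundTruth:
    """Per-parasite truth the pipeline should recover."""

    #: parasite species -> list of HostSpecies drawn for it
    host_sets: dict[str, list[HostSpecies]] = field(default_factory=dict)
    #: parasite species -> generated via the >=6-family generalist branch
    generalist: dict[str, bool] = field(default_factory=dict)
    #: parasite species -> single exclusive host species
    specialist: dict[str, bool] = field(default_factory=dict)
    #: record_id -> generating confidence label
    confidence_labels: dict[str, str] = field(default_factory=dict)
    #: parasite species -> (lon, lat, radius_km, disc_area_km2)
    ranges: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict)
    #: host family -> clade (for clade_partition on synthetic data)
    clade_map: dict[str, str] = field(default_factory=dict)
    #: host family -> order
    order_map: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "host_sets": {p: [h.__dict__ for h in hs]
                          for p, hs in self.host_sets.items()},
            "generalist": self.generalist,
            "specialist": self.specialist,
            "confidence_labels": self.confidence_labels,
            "ranges": self.ranges,
            "clade_map": self.clade_map,
            "order_map": self.order_map,
        }, indent=1)


def build_host_taxonomy(cfg: HostTaxonomyConfig) -> list[HostSpecies]:
    """Deterministic nested host taxonomy (habits assigned separately)."""
    out: list[HostSpecies] = []
    fam_idx = 0
    for clade in sorted(cfg.families_per_clade):
        n_fam = cfg.families_per_clade[clade]
        for i in range(n_fam):
            family = f"Hostfam{fam_idx:03d}aceae"
            order = f"Hostorder{fam_idx // cfg.families_per_order:02d}ales"
            for g in range(cfg.genera_per_family):
                genus = f"Hostgenus{fam_idx:03d}_{g}"
                for s in range(cfg.species_per_genus):
                    out.append(HostSpecies(
                        species=f"{genus} sp{s}", genus=genus, family=family,
                        order=order, clade=clade, habit="unknown"))
            fam_idx += 1
    return out


def taxonomy_tree_newick(truth: GroundTruth) -> str:
    """Family-level newick tree consistent with the synthetic taxonomy:
    families cluster within orders, orders within clades."""
    by_clade: dict[str, dict[str, list[str]]] = {}
    for fam, clade in truth.clade_map.items():
        by_clade.setdefault(clade, {}).setdefault(
            truth.order_map[fam], []).append(fam)
    clade_strs = []
    for clade in sorted(by_clade):
        order_strs = []
        for order in sorted(by_clade[clade]):
            fams = ",".join(sorted(by_clade[clade][order]))
            order_strs.append(f"({fams}){order}")
        clade_strs.append("(" + ",".join(order_strs) + ")" if
                          len(order_strs) > 1 else order_strs[0])
    return "(" + ",".join(clade_strs) + ");"


def _ztnb(rng: np.random.Generator, mean: float, k: float) -> int:
    """Zero-truncated negative binomial draw (rejection on zeros)."""
    p = k / (k + mean)
    while True:
        x = int(rng.negative_binomial(k, p))
        if x > 0:
            return x


# -- evidence emitters: each sets exactly the flags for one rule ----------

def _emit_high(rng) -> tuple[Evidence, str, str]:
    rule = ["H1", "H2", "H3", "H4"][rng.integers(4)]
    if rule == "H1":
        return Evidence(excavated_confirmed=True,
                        excavation_explicit=bool(rng.random() < 0.5)), rule, "article"
    if rule == "H2":
        return Evidence(expert_report=True), rule, "article"
    if rule == "H3":
        return Evidence(host_material_on_sheet=True), rule, "herbarium"
    return Evidence(database_observation=True, has_photo=True,
                    photo_connection_visible=True), rule, "database_obs"


def _emit_medium(rng, allow_plain: bool) -> tuple[Evidence, str, str]:
    rules = ["M2", "M3", "M4"] + (["M1"] if allow_plain else [])
    rule = rules[rng.integers(len(rules))]
    if rule == "M1":
        # plain pre-1950 report, excavation unclear
        return Evidence(pre_1950=True), rule, "flora"
    if rule == "M2":
        # would be high (excavated) but pre-1950 without explicit excavation
        return Evidence(excavated_confirmed=True, pre_1950=True), rule, "monograph"
    if rule == "M3":
        return Evidence(herbarium_host_named_no_material=True), rule, "herbarium"
    return Evidence(database_observation=True, has_photo=True,
                    photo_host_visible=True), rule, "database_obs"


def _emit_low(rng, allow_l3: bool) -> tuple[Evidence, str, str]:
    if allow_l3 and rng.random() < 0.5:
        return Evidence(database_observation=True), "L3", "database_obs"
    return Evidence(author_flags_dubious=True,
                    pre_1950=bool(rng.random() < 0.3)), "L1", "article"


def _sample_host_set(rng, k: int, taxonomy: list[HostSpecies],
                     by_genus: dict[str, list[HostSpecies]],
                     by_family: dict[str, list[HostSpecies]],
                     clades: dict[str, list[str]],
                     weights: dict[str, float]) -> list[HostSpecies]:
    """Draw k distinct hosts with within-genus clustering."""
    clade_names = sorted(weights)
    w = np.array([weights[c] for c in clade_names], dtype=float)
    w /= w.sum()
    clade = clade_names[rng.choice(len(clade_names), p=w)]
    family = clades[clade][rng.integers(len(clades[clade]))]
    genera = sorted({h.genus for h in by_family[family]})
    genus = genera[rng.integers(len(genera))]

    chosen: list[HostSpecies] = []
    chosen_keys: set[str] = set()

    def pick_from(pool: list[HostSpecies]) -> bool:
        avail = [h for h in pool if h.species not in chosen_keys]
        if not avail:
            return False
        h = avail[rng.integers(len(avail))]
        chosen.append(h)
        chosen_keys.add(h.species)
        return True

    pick_from(by_genus[genus])
    while len(chosen) < k:
        u = rng.random()
        if u < 0.6 and pick_from(by_genus[genus]):
            continue
        if u < 0.9 and pick_from(by_family[family]):
            continue
        # jump to a new family (same clade-weighted draw)
        clade = clade_names[rng.choice(len(clade_names), p=w)]
        family = clades[clade][rng.integers(len(clades[clade]))]
        genera = sorted({h.genus for h in by_family[family]})
        genus = genera[rng.integers(len(genera))]
        if not pick_from(by_family[family]):
            if len(chosen_keys) >= len(taxonomy):
                break
    return chosen


def _sample_generalist_set(rng, taxonomy, by_family, clades, weights,
                           n_families: int) -> list[HostSpecies]:
    clade_names = sorted(weights)
    w = np.array([weights[c] for c in clade_names], dtype=float)
    w /= w.sum()
    fams: list[str] = []
    while len(fams) < n_families:
        clade = clade_names[rng.choice(len(clade_names), p=w)]
        f = clades[clade][rng.integers(len(clades[clade]))]
        if f not in fams:
            fams.append(f)
    chosen: list[HostSpecies] = []
    keys: set[str] = set()
    for f in fams:
        n_in_fam = 1 + int(rng.integers(3))
        pool = by_family[f]
        for _ in range(n_in_fam):
            avail = [h for h in pool if h.species not in keys]
            if not avail:
                break
            h = avail[rng.integers(len(avail))]
            chosen.append(h)
            keys.add(h.species)
    return chosen


def _cap_points(rng, lon0, lat0, radius_km, n) -> list[tuple[float, float]]:
    """n points uniform on the spherical cap of angular radius r/R."""
    R = EARTH_RADIUS_KM
    cmax = radius_km / R
    cosc = rng.uniform(math.cos(cmax), 1.0, size=n)
    c = np.arccos(np.clip(cosc, -1, 1))
    theta = rng.uniform(0, 2 * math.pi, size=n)
    phi0, lam0 = math.radians(lat0), math.radians(lon0)
    lat = np.arcsin(np.sin(phi0) * np.cos(c)
                    + np.cos(phi0) * np.sin(c) * np.cos(theta))
    lon = lam0 + np.arctan2(np.sin(theta) * np.sin(c) * math.cos(phi0),
                            np.cos(c) - math.sin(phi0) * np.sin(lat))
    lon = (np.degrees(lon) + 180.0) % 360.0 - 180.0
    return list(zip(lon.tolist(), np.degrees(lat).tolist()))


def generate(cfg: SyntheticConfig
             ) -> tuple[RecordSet, list[OccurrenceSet], GroundTruth]:
    """Generate a record database, occurrence sets and ground truth.

    Deterministic for a fixed config (one seed drives everything).
    Raises on an infeasible config (host range exceeding the host pool).
    """
    rng = np.random.default_rng(cfg.seed)
    taxonomy = build_host_taxonomy(cfg.host_taxonomy)
    pool = len(taxonomy)
    # mean + 6 sd of the NB comfortably inside the pool
    m, k = cfg.host_range_mean, cfg.host_range_dispersion
    if m + 6 * math.sqrt(m + m * m / k) > pool:
        raise ValueError(
            f"infeasible config: host-range distribution (mean {m}) too "
            f"large for a host pool of {pool} species")

    by_genus: dict[str, list[HostSpecies]] = {}
    by_family: dict[str, list[HostSpecies]] = {}
    clades: dict[str, list[str]] = {}
    truth = GroundTruth()
    for h in taxonomy:
        by_genus.setdefault(h.genus, []).append(h)
        by_family.setdefault(h.family, []).append(h)
        if h.family not in truth.clade_map:
            truth.clade_map[h.family] = h.clade
            truth.order_map[h.family] = h.order
            clades.setdefault(h.clade, []).append(h.family)
    # habits fixed per host species
    habit_names = sorted(cfg.habit_distribution)
    hw = np.array([cfg.habit_distribution[h] for h in habit_names])
    hw /= hw.sum()
    for h in taxonomy:
        h.habit = habit_names[rng.choice(len(habit_names), p=hw)]

    records: list[HostRecord] = []
    occ_sets: list[OccurrenceSet] = []
    rid = 0
    ref_serial = 0
    weights = cfg.host_taxonomy.clade_weights
    p_low, p_med, p_high = cfg.confidence_mixture

    for lineage in sorted(cfg.lineages):
        n_gen, n_sp = cfg.lineages[lineage]
        for si in range(n_sp):
            genus_i = int(si % n_gen)
            pgenus = f"{lineage[:-4]}genus{genus_i}"
            pspecies = f"{pgenus} synsp{si}"

            if rng.random() < cfg.p_generalist:
                n_fam = 6 + int(rng.poisson(2))
                hosts = _sample_generalist_set(
                    rng, taxonomy, by_family, clades, weights, n_fam)
                truth.generalist[pspecies] = True
            else:
                k_hosts = _ztnb(rng, m, k)
                hosts = _sample_host_set(
                    rng, k_hosts, taxonomy, by_genus, by_family, clades,
                    weights)
                truth.generalist[pspecies] = (
                    len({h.family for h in hosts}) >= 6)
            truth.host_sets[pspecies] = hosts
            truth.specialist[pspecies] = len(hosts) == 1

            # confidence labels per interaction record
            interactions = [(h, 1 + int(rng.poisson(cfg.extra_records_rate)))
                            for h in hosts]
            labels: list[tuple[HostSpecies, str]] = []
            for h, n_rec in interactions:
                for _ in range(n_rec):
                    u = rng.random()
                    lab = ("low" if u < p_low
                           else "medium" if u < p_low + p_med else "high")
                    labels.append((h, lab))
            high_genera = {h.genus for h, lab in labels if lab == "high"}
            parasite_orders = {h.order for h in hosts}
            order_counts: dict[str, int] = {}
            fam_order: dict[str, str] = {}
            for h in hosts:
                fam_order[h.family] = h.order
            for f, o in fam_order.items():
                order_counts[o] = order_counts.get(o, 0) + 1

            for h, lab in labels:
                # family "unrelated" iff no other recorded family shares
                # its order: avoid emitting plain-report evidence there,
                # the engine's unrelated-family rule would fire
                related = (order_counts.get(h.order, 0) > 1
                           or len(fam_order) == 1)
                if lab == "high":
                    ev, rule, rtype = _emit_high(rng)
                elif lab == "medium":
                    ev, rule, rtype = _emit_medium(rng, allow_plain=related)
                else:
                    ev, rule, rtype = _emit_low(
                        rng, allow_l3=h.genus not in high_genera)
                identified = rng.random() < cfg.p_host_identified_to_species
                ref_serial += 1
                rid += 1
                records.append(HostRecord(
                    record_id=f"r{rid:05d}",
                    parasite_species=pspecies,
                    parasite_genus=pgenus,
                    parasite_family=lineage,
                    host_species=h.species if identified else "",
                    host_genus=h.genus if identified else "",
                    host_family=h.family,
                    host_order=h.order,
                    host_habit=h.habit if identified else "unknown",
                    region=cfg.region_pool[rng.integers(len(cfg.region_pool))],
                    record_type=rtype,
                    reference_id=f"ref{ref_serial:05d}",
                    evidence=ev,
                    confidence="",
                ))
                truth.confidence_labels[f"r{rid:05d}"] = lab

            # occurrence points on a uniform spherical cap
            lon0 = float(rng.uniform(-170, 170))
            lat0 = float(rng.uniform(cfg.geo.lat_min, cfg.geo.lat_max))
            radius = float(rng.uniform(cfg.geo.radius_km_min,
                                       cfg.geo.radius_km_max))
            disc_area = 2 * math.pi * EARTH_RADIUS_KM ** 2 * (
                1 - math.cos(radius / EARTH_RADIUS_KM))
            truth.ranges[pspecies] = (lon0, lat0, radius, disc_area)
            occ_sets.append(OccurrenceSet(
                parasite_species=pspecies,
                points=_cap_points(rng, lon0, lat0, radius,
                                   cfg.geo.n_points_per_species)))

    rs = RecordSet(records=records,
                   provenance=f"synthetic seed={cfg.seed}")
    return rs, occ_sets, truth


@dataclass
class RecoveryReport:
    n_parasites_truth: int
    n_parasites_recovered: int
    true_median_host_species: float
    recovered_median_host_species: float
    median_abs_error: float
    confidence_agreement: float
    specialist_precision: float
    specialist_recall: float
    generalist_precision: float
    generalist_recall: float
    eoo_area_ratio_mean: float | None = None
    eoo_all_within_disc: bool | None = None


def _prf(truth_pos: set[str], pred_pos: set[str], universe: set[str]
         ) -> tuple[float, float]:
    tp = len(truth_pos & pred_pos)
    precision = tp / len(pred_pos) if pred_pos else 1.0
    recall = tp / len(truth_pos & universe) if truth_pos & universe else 1.0
    return precision, recall


def recovery_report(truth: GroundTruth, rated: RecordSet, profiles,
                    eoo_results=None) -> RecoveryReport:
    """Score pipeline output against the generator's ground truth.

    ``rated`` must be the engine-rated version of the generated set (for
    rule agreement); ``profiles`` the flagged specificity profiles from
    the analysis set.  Raises on record ids unknown to the truth.
    """
    from statistics import median

    unknown = [r.record_id for r in rated
               if r.record_id not in truth.confidence_labels]
    if unknown:
        raise ValueError(f"record ids not in ground truth: {unknown[:5]}")
    agree = sum(1 for r in rated
                if r.confidence == truth.confidence_labels[r.record_id])
    agreement = agree / len(rated) if len(rated) else 1.0

    true_counts = [len({h.species for h in hs})
                   for hs in truth.host_sets.values()]
    rec_by_sp = {p.parasite_species: p for p in profiles}
    unknown_sp = [s for s in rec_by_sp if s not in truth.host_sets]
    if unknown_sp:
        raise ValueError(f"parasite ids not in ground truth: {unknown_sp[:5]}")
    rec_counts = [p.n_host_species for p in profiles]
    t_med = float(median(true_counts)) if true_counts else 0.0
    r_med = float(median(rec_counts)) if rec_counts else 0.0

    universe = set(rec_by_sp)
    spec_truth = {s for s, v in truth.specialist.items() if v}
    gen_truth = {s for s, v in truth.generalist.items() if v}
    spec_pred = {p.parasite_species for p in profiles
                 if p.is_extreme_specialist}
    gen_pred = {p.parasite_species for p in profiles
                if p.is_extreme_generalist}
    sp_p, sp_r = _prf(spec_truth, spec_pred, universe)
    ge_p, ge_r = _prf(gen_truth, gen_pred, universe)

    ratio_mean = within = None
    if eoo_results is not None:
        ratios = []
        within = True
        for e in eoo_results:
            if e.parasite_species not in truth.ranges:
                raise ValueError(
                    f"occurrence species not in ground truth: "
                    f"{e.parasite_species}")
            disc = truth.ranges[e.parasite_species][3]
            ratios.append(e.area_km2 / disc)
            if e.area_km2 > disc * (1 + 1e-9):
                within = False
        ratio_mean = float(np.mean(ratios)) if ratios else None

    return RecoveryReport(
        n_parasites_truth=len(truth.host_sets),
        n_parasites_recovered=len(profiles),
        true_median_host_species=t_med,
        recovered_median_host_species=r_med,
        median_abs_error=abs(t_med - r_med),
        confidence_agreement=agreement,
        specialist_precision=sp_p, specialist_recall=sp_r,
        generalist_precision=ge_p, generalist_recall=ge_r,
        eoo_area_ratio_mean=ratio_mean, eoo_all_within_disc=within)


def recovery_config(seed: int = 1, n_parasites: int = 300) -> SyntheticConfig:
    """Noise-free parameter-recovery conditions: mean host range 5, all
    records high confidence, every host identified to species."""
    per = max(1, n_parasites // 3)
    lineages = {"Orobanchaceae": (10, n_parasites - 2 * per),
                "Balanophoraceae": (5, per),
                "Hydnoraceae": (2, per)}
    return SyntheticConfig(
        seed=seed, lineages=lineages,
        confidence_mixture=(0.0, 0.0, 1.0),
        p_host_identified_to_species=1.0)
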