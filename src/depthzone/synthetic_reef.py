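"""Synthetic stratified reef-fish communities with planted depth zonation.

Every downstream stage of the pipeline (pooling, clustering, SIMPROF,
PERMANOVA, beta partitioning, affinity, segregation) is exercised against
data whose vertical structure is known exactly. The generator plants a
shallow-to-deep sequence of depth zones over bin-aligned boundaries and fills
each with its own species pool.

Each species' expected sighting rate across depth is a unimodal niche: a flat
plateau core spanning the species' planted zone with Gaussian shoulders of
standard deviation ``edge_sd`` outside it (a core of width zero is a pure
Gaussian niche). The flat core makes samples within a zone exchangeable up to
counting noise, so the planted zones are the true cluster structure;
shoulders control how crisp the between-zone breaks are. Congeneric species
sets use pure Gaussian niches with depth centers offset by a configurable
delta (default 40 m) to plant depth segregation within genera. Species whose
zone lies at or below ``deep_zone_start`` (default 300 m) are drawn from a
deep-sea family pool, emulating the transition from reef-affiliated to
deep-sea taxa at the foot of the reef slope.

Expected counts per (site, bin, species) are
``base_intensity x site_multiplier x niche(depth) x effort_hours`` with
Poisson noise by default (a negative-binomial option models overdispersed
schooling species). Effort per bin is lognormal around a configurable mean;
dives are simulated so that rarefaction has real dive identities to resample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ConfigurationError, ContractError
from .obsdata import OBS_COLUMNS

REEF_FAMILIES = [
    "Serranidae_s", "Gobiidae_s", "Labridae_s", "Pomacentridae_s",
    "Grammatidae_s", "Tetraodontidae_s",
]
DEEP_SEA_FAMILIES = ["Epigonidae_s", "Triacanthodidae_s", "Trachichthyidae_s"]


@dataclass(frozen=True)
class SpeciesNiche:
    """Unimodal depth niche of one synthetic species."""

    species_id: str
    genus: str
    family: str
    family_pool: str          # "reef" | "deep_sea"
    depth_center: float       # m
    depth_sd: float           # m, Gaussian shoulder/overall sd (> 0)
    core_halfwidth: float     # m, half-width of the flat plateau (0 = pure Gaussian)
    site_multipliers: dict    # site -> nonnegative scalar
    base_intensity: float     # expected individuals per hour at the niche center

    def __post_init__(self):
        if self.depth_sd <= 0:
            raise ConfigurationError("depth_sd must be > 0")
        if self.base_intensity < 0 or self.core_halfwidth < 0:
            raise ConfigurationError("base_intensity and core_halfwidth must be >= 0")
        if any(v < 0 for v in self.site_multipliers.values()):
            raise ConfigurationError("site multipliers must be >= 0")

    def intensity(self, depth) -> np.ndarray:
        """Expected individuals per hour at the given depth(s)."""
        depth = np.asarray(depth, dtype=float)
        excess = np.maximum(np.abs(depth - self.depth_center) - self.core_halfwidth, 0.0)
        return self.base_intensity * np.exp(-(excess**2) / (2.0 * self.depth_sd**2))


@dataclass
class PlantedTruth:
    """Ground truth of a simulated community."""

    zone_boundaries: list     # internal break depths (first bin of each deeper zone)
    species_zone: dict        # species -> planted zone index (0 = shallowest;
                              #            -1 = range-wide generalist)
    congener_sets: list       # [{genus, species: [...], centers: [...]}, ...]
    depth_range: tuple
    bin_width: int

    @property
    def n_zones(self) -> int:
        return len(self.zone_boundaries) + 1

    def zone_of_bin(self, depth_bin: int) -> int:
        return int(np.searchsorted(self.zone_boundaries, depth_bin, side="right"))

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["depth_range"] = list(payload["depth_range"])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class SimulationConfig:
    """Study conditions for the generator (defaults follow a four-site,
    four-zone deep-reef survey over 40-300 m with heterogeneous dive effort)."""

    n_sites: int = 4
    site_names: list | None = None
    depth_range: tuple = (40, 300)
    bin_width: int = 10
    n_zones: int = 4
    zone_edges: list | None = None       # explicit internal break depths
    species_per_zone: int = 30
    n_generalist_species: int = 10       # range-wide species shared by all zones
    edge_sd: float = 1.0                 # m, zone-shoulder sharpness (strong separation)
    base_intensity_mean: float = 5.0     # individuals/hour at niche center (lognormal median-ish)
    base_intensity_sigma: float = 0.7
    site_multiplier_sigma: float = 0.4
    effort_mean_hours: float = 2.0
    effort_dispersion: float = 0.15      # lognormal sigma; 0 = constant effort
    n_dives_per_site: int = 12
    count_noise: str = "poisson"         # "poisson" | "negative_binomial"
    nb_dispersion: float = 0.5           # NB shape k (smaller = more overdispersed)
    n_congener_genera: int = 5
    congener_species_range: tuple = (2, 4)
    congener_style: str = "zone"         # "zone" (one member per consecutive zone) |
                                         # "offset_gaussian" (centers offset by delta)
    congener_delta: float = 40.0         # m, offset between centers (offset_gaussian)
    congener_sd: float = 15.0            # m, niche sd (offset_gaussian)
    deep_zone_start: float = 300.0
    site_depth_ranges: dict | None = None  # site -> (lo, hi) surveyed subrange
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.depth_range
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if not (0 <= lo < hi <= 500):
            raise ConfigurationError("depth_range must be within [0, 500] with lo < hi")
        if lo % self.bin_width or hi % self.bin_width:
            raise ConfigurationError("depth_range edges must be bin-aligned")
        if self.n_zones < 2:
            raise ConfigurationError("n_zones must be >= 2")
        if self.count_noise not in ("poisson", "negative_binomial"):
            raise ConfigurationError(f"unknown count_noise {self.count_noise!r}")
        if self.effort_dispersion < 0 or self.effort_mean_hours <= 0:
            raise ConfigurationError("effort parameters out of range")

    @property
    def sites(self) -> list:
        return self.site_names or [f"site_{i + 1}" for i in range(self.n_sites)]

    @property
    def bins(self) -> list:
        return list(range(self.depth_range[0], self.depth_range[1], self.bin_width))

    def site_bins(self, site: str) -> list:
        if self.site_depth_ranges and site in self.site_depth_ranges:
            lo, hi = self.site_depth_ranges[site]
            return [b for b in self.bins if lo <= b < hi]
        return self.bins

    def zone_spans(self) -> list:
        """Zone spans [(first_bin, last_bin)], bin-aligned, shallow to deep."""
        bins = self.bins
        if self.zone_edges is not None:
            edges = list(self.zone_edges)
            if sorted(edges) != edges or len(edges) != self.n_zones - 1:
                raise ConfigurationError("zone_edges must be increasing, n_zones - 1 long")
            groups = []
            for i in range(self.n_zones):
                lo = self.depth_range[0] if i == 0 else edges[i - 1]
                hi = self.depth_range[1] if i == self.n_zones - 1 else edges[i]
                groups.append([b for b in bins if lo <= b < hi])
            if any(not g for g in groups):
                raise ConfigurationError("a zone span contains no bins")
        else:
            groups = [list(g) for g in np.array_split(bins, self.n_zones)]
        return [(g[0], g[-1]) for g in groups]


def _rng_streams(seed: int):
    effort_ss, species_ss, counts_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(effort_ss),
        np.random.default_rng(species_ss),
        np.random.default_rng(counts_ss),
    )


def generate_effort(config: SimulationConfig) -> pd.DataFrame:
    """Sampling effort (hours) per (site, depth bin); lognormal with the
    configured mean, exactly the mean when dispersion is 0."""
    config.validate()
    rng, _, _ = _rng_streams(config.seed)
    rows = []
    sig = config.effort_dispersion
    for site in config.sites:
        for b in config.site_bins(site):
            if sig == 0:
                hours = config.effort_mean_hours
            else:
                hours = config.effort_mean_hours * np.exp(
                    sig * rng.standard_normal() - sig**2 / 2.0
                )
            rows.append({"site": site, "depth_bin": b, "hours": hours})
    return pd.DataFrame(rows)


def _draw_species(config: SimulationConfig, rng: np.random.Generator):
    spans = config.zone_spans()
    deep_zone = [i for i, (lo, hi) in enumerate(spans) if lo >= config.deep_zone_start]
    niches: list[SpeciesNiche] = []
    species_zone: dict[str, int] = {}
    congener_sets = []
    w = config.bin_width

    def site_mults():
        return {
            s: float(np.exp(config.site_multiplier_sigma * rng.standard_normal()))
            for s in config.sites
        }

    def intensity():
        return float(
            config.base_intensity_mean
            * np.exp(config.base_intensity_sigma * rng.standard_normal())
        )

    for zi, (lo, hi) in enumerate(spans):
        pool = "deep_sea" if zi in deep_zone else "reef"
        families = DEEP_SEA_FAMILIES if pool == "deep_sea" else REEF_FAMILIES
        center = (lo + hi + w) / 2.0
        halfw = (hi + w - lo) / 2.0
        for k in range(config.species_per_zone):
            fam = families[rng.integers(len(families))]
            genus = f"{fam[:-2]}us{zi}{k % 7}"
            sp = f"{genus} z{zi}s{k}"
            niches.append(
                SpeciesNiche(
                    species_id=sp, genus=genus, family=fam, family_pool=pool,
                    depth_center=center, depth_sd=config.edge_sd,
                    core_halfwidth=halfw, site_multipliers=site_mults(),
                    base_intensity=intensity(),
                )
            )
            species_zone[sp] = zi

    # range-wide generalists: flat across every surveyed bin (zone index -1),
    # so adjacent zones share species without adding within-zone structure
    lo_all, hi_all = config.depth_range
    for gk in range(config.n_generalist_species):
        fam = REEF_FAMILIES[rng.integers(len(REEF_FAMILIES))]
        genus = f"Ubiquus{gk % 5}"
        sp = f"{genus} g{gk}"
        niches.append(
            SpeciesNiche(
                species_id=sp, genus=genus, family=fam, family_pool="reef",
                depth_center=(lo_all + hi_all) / 2.0, depth_sd=config.edge_sd,
                core_halfwidth=(hi_all - lo_all) / 2.0 + w,
                site_multipliers=site_mults(), base_intensity=intensity(),
            )
        )
        species_zone[sp] = -1

    for gi in range(config.n_congener_genera):
        k = int(rng.integers(config.congener_species_range[0],
                             config.congener_species_range[1] + 1))
        genus = f"Congenus{gi + 1}"
        members, centers, zone_ids = [], [], []
        if config.congener_style == "zone":
            # one plateau member per consecutive zone: segregation across zones
            k = min(k, len(spans))
            z0 = int(rng.integers(0, len(spans) - k + 1))
            for j in range(k):
                zi = z0 + j
                lo, hi = spans[zi]
                centers.append((lo + hi + w) / 2.0)
                zone_ids.append(zi)
        elif config.congener_style == "offset_gaussian":
            span_needed = (k - 1) * config.congener_delta
            c0_lo, c0_hi = lo_all + 2 * w, hi_all - 2 * w - span_needed
            if c0_hi <= c0_lo:
                continue
            c0 = float(rng.uniform(c0_lo, c0_hi))
            for j in range(k):
                center = c0 + j * config.congener_delta
                centers.append(center)
                zone_ids.append(int(np.searchsorted([s[0] for s in spans[1:]], center,
                                                    side="right")))
        else:
            raise ConfigurationError(f"unknown congener_style {config.congener_style!r}")
        for j, (center, zi) in enumerate(zip(centers, zone_ids)):
            pool = "deep_sea" if zi in deep_zone else "reef"
            families = DEEP_SEA_FAMILIES if pool == "deep_sea" else REEF_FAMILIES
            if config.congener_style == "zone":
                lo, hi = spans[zi]
                sd, halfw = config.edge_sd, (hi + w - lo) / 2.0
            else:
                sd, halfw = config.congener_sd, 0.0
            sp = f"{genus} sp{j + 1}"
            niches.append(
                SpeciesNiche(
                    species_id=sp, genus=genus, family=families[rng.integers(len(families))],
                    family_pool=pool, depth_center=center, depth_sd=sd,
                    core_halfwidth=halfw, site_multipliers=site_mults(),
                    base_intensity=intensity(),
                )
            )
            species_zone[sp] = zi
            members.append(sp)
        congener_sets.append({"genus": genus, "species": members, "centers": centers})

    boundaries = [int(s[0]) for s in spans[1:]]
    truth = PlantedTruth(
        zone_boundaries=boundaries,
        species_zone=species_zone,
        congener_sets=congener_sets,
        depth_range=tuple(config.depth_range),
        bin_width=config.bin_width,
    )
    return niches, truth


@dataclass
class SimulatedDataset:
    """A generated survey: observations, effort, ground truth and side tables."""

    observations: pd.DataFrame
    effort: pd.DataFrame
    truth: PlantedTruth
    niches: list
    shallow_flags: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    deep_sea_species: set = field(default_factory=set)
    family_ranges: pd.DataFrame = field(default_factory=pd.DataFrame)


def generate_community(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full synthetic survey under the configured study conditions."""
    config.validate()
    _, species_rng, counts_rng = _rng_streams(config.seed)
    effort = generate_effort(config)
    niches, truth = _draw_species(config, species_rng)

    hours = effort.set_index(["site", "depth_bin"])["hours"]
    w = config.bin_width
    records = []
    for site in config.sites:
        bins = np.array(config.site_bins(site))
        if not len(bins):
            continue
        centers = bins + w / 2.0
        dive_ids = [f"{site}_dive{j + 1}" for j in range(config.n_dives_per_site)]
        dive_w = counts_rng.dirichlet(np.ones(config.n_dives_per_site))
        site_hours = hours.loc[site].reindex(bins).to_numpy()
        for niche in niches:
            lam = niche.site_multipliers[site] * niche.intensity(centers) * site_hours
            if config.count_noise == "poisson":
                counts = counts_rng.poisson(lam)
            else:
                k = config.nb_dispersion
                p = k / (k + np.maximum(lam, 1e-12))
                counts = np.where(lam > 0, counts_rng.negative_binomial(k, p), 0)
            for b, c in zip(bins, counts):
                if c == 0:
                    continue
                split = counts_rng.multinomial(c, dive_w)
                for dive, cnt in zip(dive_ids, split):
                    if cnt == 0:
                        continue
                    depth = float(b + counts_rng.uniform(0, w))
                    records.append(
                        (site, dive, depth, niche.species_id, niche.genus,
                         niche.family, int(cnt))
                    )
    obs = pd.DataFrame(records, columns=OBS_COLUMNS[:2] + ["depth_m"] + OBS_COLUMNS[3:])
    obs = obs[OBS_COLUMNS] if len(obs) else pd.DataFrame(columns=OBS_COLUMNS)

    shallow = {
        n.species_id: bool(
            (n.depth_center - n.core_halfwidth - 2 * n.depth_sd) < 40.0
        )
        for n in niches
    }
    deep_sea = {n.species_id for n in niches if n.family_pool == "deep_sea"}
    fam_rows = []
    for fam in sorted({n.family for n in niches}):
        members = [n for n in niches if n.family == fam]
        fam_rows.append(
            {
                "family": fam,
                "min_depth": max(min(n.depth_center - n.core_halfwidth - 2 * n.depth_sd
                                     for n in members), 0.0),
                "max_depth": max(n.depth_center + n.core_halfwidth + 2 * n.depth_sd
                                 for n in members),
            }
        )
    return SimulatedDataset(
        observations=obs,
        effort=effort,
        truth=truth,
        niches=niches,
        shallow_flags=pd.Series(shallow),
        deep_sea_species=deep_sea,
        family_ranges=pd.DataFrame(fam_rows),
    )


def recovery_score(assignment, truth: PlantedTruth) -> float:
    """Fraction of depth bins assigned to their planted zone, after optimal
    one-to-one matching of assigned zone labels to planted zones."""
    bins = sorted(assignment.mapping)
    if any(isinstance(b, tuple) for b in bins):
        raise ContractError("recovery_score expects a single-site assignment")
    truth_bins = [b for b in range(truth.depth_range[0], truth.depth_range[1],
                                   truth.bin_width)]
    if set(bins) != set(truth_bins):
        raise ContractError(
            f"assignment bins {bins[:3]}..{bins[-3:]} do not match the planted bins"
        )
    zones_assigned = sorted({assignment.mapping[b] for b in bins})
    confusion = np.zeros((truth.n_zones, len(zones_assigned)))
    for b in bins:
        confusion[truth.zone_of_bin(b), zones_assigned.index(assignment.mapping[b])] += 1
    r, c = linear_sum_assignment(-confusion)
    return float(confusion[r, c].sum() / len(bins))
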