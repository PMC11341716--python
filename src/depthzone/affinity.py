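"""Species depth-affinity classification and zone composition profiles.

A species is a depth specialist when more than 75% of its observed abundance
falls inside one depth zone (zones mapped with each site's own break depths
before pooling across sites). Species-level depth-affinity categories are:

* ``altiphotic_mesophotic`` -- mesophotic-dominant (>= 75% of abundance in the
  mesophotic zones) but also known to commonly occur above 40 m;
* ``mesophotic`` -- mesophotic-dominant without shallow occurrence;
* ``rariphotic`` -- rariphotic-dominant (>= 75% in the rariphotic zones);
* ``mesophotic_rariphotic`` -- spanning both without dominance;
* ``deep_sea`` -- species of deep-sea affiliated taxa observed on the survey.

Family-level depth dominance uses published depth ranges: predominantly
shallower than 130 m -> altiphotic/mesophotic, 130-500 m -> rariphotic, below
500 m -> deep-sea, and spanning several of those strata -> depth generalist.
"Predominantly" is operationalized by the range midpoint (a documented
stand-in for the expert judgement used with real trait tables).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cluster_zone import DepthZoneAssignment, ZONES
from .errors import ContractError, ValidationError
from .obsdata import bin_depth, validate_observations

logger = logging.getLogger(__name__)

MESOPHOTIC_ZONES = ("upper_mesophotic", "lower_mesophotic")
RARIPHOTIC_ZONES = ("upper_rariphotic", "lower_rariphotic")

AFFINITY_CATEGORIES = [
    "altiphotic_mesophotic",
    "mesophotic",
    "mesophotic_rariphotic",
    "rariphotic",
    "deep_sea",
]

FAMILY_CATEGORIES = ["altiphotic_mesophotic", "rariphotic", "deep_sea", "depth_generalist"]


def zone_proportions(
    obs: pd.DataFrame,
    assignments: dict,
    bin_width: int = 10,
    on_unmapped: str = "error",
) -> pd.DataFrame:
    """Per-species fraction of total abundance in each depth zone.

    ``assignments`` maps site -> DepthZoneAssignment (site-specific breaks).
    Observations are mapped to zones through their own site's assignment,
    then pooled across sites. ``on_unmapped``: "error" raises on a (site,
    bin) without a zone; "drop" silently excludes such records.
    Rows sum to 1.
    """
    obs = validate_observations(obs)
    obs = obs.assign(depth_bin=bin_depth(obs["depth_m"].to_numpy(), bin_width))
    zones = []
    keep = []
    for site, dbin in zip(obs["site"], obs["depth_bin"]):
        if site not in assignments:
            if on_unmapped == "error":
                raise ContractError(f"no zone assignment for site {site!r}")
            keep.append(False)
            zones.append(None)
            continue
        try:
            zones.append(assignments[site].zone_of(int(dbin)))
            keep.append(True)
        except ContractError:
            if on_unmapped == "error":
                raise
            keep.append(False)
            zones.append(None)
    obs = obs.assign(zone=zones)[np.asarray(keep)]
    table = obs.pivot_table(index="species", columns="zone", values="count",
                            aggfunc="sum", fill_value=0)
    zone_cols = [z for z in ZONES if z in table.columns] + [
        z for z in table.columns if z not in ZONES
    ]
    table = table[zone_cols]
    props = table.div(table.sum(axis=1), axis=0)
    props.columns.name = None
    return props


def classify_specialist(
    proportions: pd.Series, threshold: float = 0.75, strict: bool = True
):
    """Zone holding > threshold (or >= when strict=False) of abundance, else None."""
    top = proportions.idxmax()
    value = proportions[top]
    if value == threshold:
        logger.info("species proportion exactly at the %.0f%% threshold", threshold * 100)
    passed = value > threshold if strict else value >= threshold
    return top if passed else None


def specialist_table(
    props: pd.DataFrame, threshold: float = 0.75, strict: bool = True
) -> pd.Series:
    """classify_specialist applied to every row of a zone-proportion table."""
    return props.apply(lambda row: classify_specialist(row, threshold, strict), axis=1)


def classify_affinity(
    proportions: pd.Series,
    shallow_occurrence: bool = False,
    family_category: str | None = None,
    is_deep_sea_species: bool = False,
    threshold: float = 0.75,
) -> str:
    """Depth-affinity category of one species from its zone proportions.

    Precedence: deep-sea affiliation first; then mesophotic dominance split
    by the shallow-occurrence flag; then rariphotic dominance; everything
    else is mesophotic/rariphotic. Dominance pools upper+lower zones and
    uses >= threshold.
    """
    if is_deep_sea_species or family_category == "deep_sea":
        return "deep_sea"
    meso = sum(proportions.get(z, 0.0) for z in MESOPHOTIC_ZONES)
    rari = sum(proportions.get(z, 0.0) for z in RARIPHOTIC_ZONES)
    if meso >= threshold:
        return "altiphotic_mesophotic" if shallow_occurrence else "mesophotic"
    if rari >= threshold:
        return "rariphotic"
    return "mesophotic_rariphotic"


def affinity_table(
    props: pd.DataFrame,
    shallow_flags: pd.Series | None = None,
    family_of: pd.Series | None = None,
    family_categories: pd.Series | None = None,
    deep_sea_species: set | None = None,
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Specialist zone and affinity category for every species.

    ``shallow_flags`` (species -> bool), ``family_of`` (species -> family),
    ``family_categories`` (family -> category) and ``deep_sea_species`` are
    user-supplied side tables; absent entries default to False/None.
    """
    deep_sea_species = deep_sea_species or set()
    rows = []
    for sp, row in props.iterrows():
        fam_cat = None
        if family_of is not None and family_categories is not None:
            fam = family_of.get(sp)
            fam_cat = family_categories.get(fam) if fam is not None else None
        rows.append(
            {
                "species": sp,
                "specialist_zone": classify_specialist(row, threshold),
                "affinity": classify_affinity(
                    row,
                    shallow_occurrence=bool(shallow_flags.get(sp, False))
                    if shallow_flags is not None
                    else False,
                    family_category=fam_cat,
                    is_deep_sea_species=sp in deep_sea_species,
                    threshold=threshold,
                ),
            }
        )
    return pd.DataFrame(rows).set_index("species")


def family_categories_from_ranges(ranges: pd.DataFrame) -> pd.Series:
    """Family depth-dominance category from (family, min_depth, max_depth) rows.

    Midpoint rule: midpoint < 130 m -> altiphotic_mesophotic, 130-500 m ->
    rariphotic, > 500 m -> deep_sea; a range reaching both above 130 m and
    below 500 m spans multiple depth strata -> depth_generalist.
    """
    for col in ("family", "min_depth", "max_depth"):
        if col not in ranges.columns:
            raise ValidationError(f"family range table missing column {col!r}")
    out = {}
    for _, r in ranges.iterrows():
        lo, hi = float(r["min_depth"]), float(r["max_depth"])
        if hi < lo:
            raise ValidationError(f"family {r['family']!r}: max_depth < min_depth")
        mid = (lo + hi) / 2.0
        if lo < 130 and hi > 500:
            cat = "depth_generalist"
        elif mid < 130:
            cat = "altiphotic_mesophotic"
        elif mid <= 500:
            cat = "rariphotic"
        else:
            cat = "deep_sea"
        out[r["family"]] = cat
    return pd.Series(out, name="category")


def zone_composition_profile(
    obs: pd.DataFrame,
    assignments: dict,
    categories: pd.Series,
    by: str = "species",
    bin_width: int = 10,
    on_unmapped: str = "error",
) -> pd.DataFrame:
    """Per-zone richness and abundance fractions by affinity/family category.

    ``categories`` maps species (``by='species'``) or family (``by='family'``)
    to a category label. Returns tidy rows (zone, category, richness_fraction,
    abundance_fraction); fractions sum to 1 within a zone.
    """
    obs = validate_observations(obs)
    obs = obs.assign(depth_bin=bin_depth(obs["depth_m"].to_numpy(), bin_width))
    recs = []
    for _, r in obs.iterrows():
        site = r["site"]
        if site not in assignments:
            if on_unmapped == "error":
                raise ContractError(f"no zone assignment for site {site!r}")
            continue
        try:
            zone = assignments[site].zone_of(int(r["depth_bin"]))
        except ContractError:
            if on_unmapped == "error":
                raise
            continue
        key = r["species"] if by == "species" else r["family"]
        cat = categories.get(key)
        recs.append({"zone": zone, "species": r["species"], "category": cat,
                     "count": r["count"]})
    df = pd.DataFrame(recs)
    rows = []
    for zone, grp in df.groupby("zone"):
        total_abund = grp["count"].sum()
        total_rich = grp["species"].nunique()
        for cat, sub in grp.groupby("category", dropna=False):
            rows.append(
                {
                    "zone": zone,
                    "category": cat,
                    "richness_fraction": sub["species"].nunique() / total_rich,
                    "abundance_fraction": sub["count"].sum() / total_abund,
                }
            )
    return pd.DataFrame(rows)


def specialist_counts(table: pd.DataFrame, zone_order: list | None = None) -> pd.Series:
    """Number of depth specialists per zone (plus a 'none' bucket)."""
    counts = table["specialist_zone"].fillna("none").value_counts()
    if zone_order:
        counts = counts.reindex(zone_order + ["none"], fill_value=0)
    return counts
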