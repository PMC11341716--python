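"""Bray-Curtis dissimilarity, square-root transform and beta-diversity partitioning.

Community distances use Bray-Curtis, BC(u, v) = 1 - 2 * sum(min(u, v)) /
sum(u + v), on square-root transformed abundances (the transform damps the
influence of schooling species without discarding abundance information).

Pairwise compositional dissimilarity between depth zones is partitioned into
turnover and nestedness with the Sorensen family of presence/absence indices:

    beta_sor = (b + c) / (2a + b + c)          total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))     turnover (Simpson index)
    beta_nes = beta_sor - beta_sim             nestedness-resultant

with a = shared species, b / c = species exclusive to either group. Presence
is judged on raw counts: a species is present wherever at least one
individual was recorded, regardless of effort normalization or transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import ValidationError
from .obsdata import AbundanceMatrix


# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------

def sqrt_transform(m: AbundanceMatrix, force: bool = False) -> AbundanceMatrix:
    """Cell-wise square root; recorded in the transform history.

    A second application is refused unless ``force=True`` (which yields the
    fourth root) so a pipeline cannot double-transform by accident.
    """
    if "sqrt" in m.transforms and not force:
        raise ValidationError("matrix already square-root transformed (use force=True to repeat)")
    return m.with_data(np.sqrt(m.data), transform="sqrt")


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValidationError("abundances must be nonnegative")
    denom = (u + v).sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(u, v).sum() / denom)


def _bc_condensed(x: np.ndarray, zero_zero: float = 0.0) -> np.ndarray:
    """Condensed (upper-triangle) Bray-Curtis distances of a samples x species array.

    Pairs of all-zero rows are assigned ``zero_zero`` -- permutation nulls can
    produce empty rows, and two empty communities are treated as identical.
    """
    mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=-1)
    totals = x.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * mins / denom
    d[denom == 0] = zero_zero
    iu = np.triu_indices(len(x), k=1)
    return d[iu]


def _euclidean_condensed(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(x), k=1)
    return d[iu]


def distance_matrix(m: AbundanceMatrix, metric: str = "braycurtis") -> DistanceMatrix:
    """All pairwise sample dissimilarities as a scikit-bio DistanceMatrix."""
    x = m.values()
    if len(x) < 2:
        raise ValidationError("need at least 2 samples for a distance matrix")
    if metric == "braycurtis":
        zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
        if len(zero_rows):
            raise ValidationError(
                f"all-zero sample(s) {[m.data.index[i] for i in zero_rows]}: "
                "Bray-Curtis undefined (pool sparse bins first)"
            )
        cond = _bc_condensed(x)
    elif metric == "euclidean":
        cond = _euclidean_condensed(x)
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    n = len(x)
    sq = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    sq[iu] = cond
    sq.T[iu] = cond
    return DistanceMatrix(sq, ids=[str(i) for i in m.data.index])


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaPartition:
    """Sorensen dissimilarity of two species sets, split into turnover + nestedness."""

    a: int
    b: int
    c: int
    beta_sor: float
    beta_sim: float
    beta_nes: float


def beta_partition(group1, group2) -> BetaPartition:
    """Partition the compositional dissimilarity of two presence sets."""
    s1, s2 = set(group1), set(group2)
    if not s1 and not s2:
        raise ValidationError("beta_partition: both groups are empty")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    beta_sor = (b + c) / (2 * a + b + c)
    beta_sim = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else 0.0
    return BetaPartition(a=a, b=b, c=c, beta_sor=beta_sor, beta_sim=beta_sim,
                         beta_nes=beta_sor - beta_sim)


def presence_by_zone(m: AbundanceMatrix, assignment) -> dict:
    """Pooled species-presence set per depth zone for one site's raw matrix."""
    zones: dict[str, set] = {}
    arr = m.values()
    for i, (lbl, meta) in enumerate(m.sample_meta.iterrows()):
        zone = assignment.zone_of(meta["bins"][0])
        present = {sp for sp, v in zip(m.species, arr[i]) if v > 0}
        zones.setdefault(zone, set()).update(present)
    return zones


def zone_beta_table(
    matrices: dict,
    assignments: dict,
    zone_order: list | None = None,
) -> pd.DataFrame:
    """Per-site, per-zone-pair beta partition table.

    ``matrices`` and ``assignments`` map site -> raw (untransformed)
    AbundanceMatrix and site -> DepthZoneAssignment. Zones absent at a site
    are skipped; a pair present at no site raises a warning and is omitted.
    Returns tidy rows: site, zone_a, zone_b, adjacent, a, b, c, beta_sor,
    beta_sim, beta_nes.
    """
    rows = []
    all_zones = zone_order or sorted(
        {z for a in assignments.values() for z in a.zone_order},
        key=lambda z: min(
            a.zone_order.index(z) for a in assignments.values() if z in a.zone_order
        ),
    )
    for site, m in matrices.items():
        zones = presence_by_zone(m, assignments[site])
        order = [z for z in all_zones if z in zones]
        for i, za in enumerate(order):
            for zb in order[i + 1:]:
                part = beta_partition(zones[za], zones[zb])
                rows.append(
                    {
                        "site": site,
                        "zone_a": za,
                        "zone_b": zb,
                        "adjacent": abs(all_zones.index(za) - all_zones.index(zb)) == 1,
                        **part.__dict__,
                    }
                )
    if not rows:
        warnings.warn("zone_beta_table: no zone pair present at any site")
    return pd.DataFrame(rows)


def summarize_beta(table: pd.DataFrame) -> pd.DataFrame:
    """Cross-site mean and standard error per zone pair.

    SE is NaN for pairs available at a single site (as when only one site
    reaches the deepest zones).
    """
    def se(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    g = table.groupby(["zone_a", "zone_b"], sort=False)
    out = g.agg(
        n_sites=("site", "size"),
        adjacent=("adjacent", "first"),
        beta_sor_mean=("beta_sor", "mean"),
        beta_sor_se=("beta_sor", se),
        beta_sim_mean=("beta_sim", "mean"),
        beta_sim_se=("beta_sim", se),
        beta_nes_mean=("beta_nes", "mean"),
        beta_nes_se=("beta_nes", se),
    ).reset_index()
    return out


def crosssite_beta(
    matrices: dict,
    assignments: dict,
    zone_order: list | None = None,
) -> pd.DataFrame:
    """Between-site compositional dissimilarity within each depth zone.

    For every zone and site pair, the Sorensen partition of the two sites'
    pooled presence sets (the cross-site dissimilarity panel's analogue).
    """
    per_site = {site: presence_by_zone(m, assignments[site]) for site, m in matrices.items()}
    zones = zone_order or sorted({z for d in per_site.values() for z in d})
    rows = []
    sites = list(per_site)
    for zone in zones:
        having = [s for s in sites if zone in per_site[s] and per_site[s][zone]]
        for i, sa in enumerate(having):
            for sb in having[i + 1:]:
                part = beta_partition(per_site[sa][zone], per_site[sb][zone])
                rows.append({"zone": zone, "site_a": sa, "site_b": sb, **part.__dict__})
    return pd.DataFrame(rows)
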