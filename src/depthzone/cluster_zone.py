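"""Agglomerative clustering, SIMPROF cluster delimitation and depth-zone pooling.

Depth bins are clustered on Bray-Curtis dissimilarities of square-root
transformed abundances with complete linkage (site level) or Ward linkage
(cross-site). Whether a dendrogram node contains real multivariate structure
is decided by a similarity-profile permutation test (SIMPROF):

* the observed profile is the sorted vector of pairwise dissimilarities among
  the node's samples;
* an expected profile under the null of no structure is the rank-wise mean of
  profiles from matrices in which each species' values are independently
  permuted across samples;
* the statistic pi is the summed absolute deviation between observed and
  expected profiles; its null distribution comes from further permuted
  matrices scored against the same expected profile, and the Monte-Carlo
  p-value is (1 + #{pi_null >= pi_obs}) / (1 + n_null).

The test runs top-down from the root: a significant node is opened and its
children tested; non-significant nodes (and nodes with fewer than three
samples, which have at most one pairwise distance) become final clusters.
Significant clusters are then pooled into named depth zones by cutting the
dendrogram at its highest merges, and community break depths are read off the
zone boundaries.

The linkage is a Lance-Williams agglomerator written here rather than taken
from a library so that exact ties merge deterministically (smallest pair of
leaf positions in the input ordering) and so Ward on non-Euclidean input can
run in either dialect: ``squared`` applies the update to squared
dissimilarities and reports square-rooted heights (ward.D2 semantics, the
default), ``raw`` applies it to the dissimilarities as given (ward.D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, to_tree

from .dissim import _bc_condensed, distance_matrix
from .errors import ConfigurationError, ContractError, ValidationError
from .obsdata import AbundanceMatrix

#: Canonical depth-zone names, shallow to deep.
ZONES = [
    "altiphotic",
    "upper_mesophotic",
    "lower_mesophotic",
    "upper_rariphotic",
    "lower_rariphotic",
    "below_rariphotic",
]


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage-matrix form.

    ``linkage_matrix`` rows are (cluster_a, cluster_b, height, size); leaves
    are numbered 0..n-1 in ``labels`` order.
    """

    linkage_matrix: np.ndarray
    labels: list
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_merge_table(self) -> pd.DataFrame:
        z = self.linkage_matrix
        return pd.DataFrame(
            {
                "node_id": np.arange(self.n_leaves, self.n_leaves + len(z)),
                "child_a": z[:, 0].astype(int),
                "child_b": z[:, 1].astype(int),
                "height": z[:, 2],
                "n_members": z[:, 3].astype(int),
            }
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        tree = to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
            if node.is_leaf():
                name = str(self.labels[node.id]).replace(" ", "_").replace(":", "|")
                return f"{name}:{parent_height:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def _lance_williams(d: np.ndarray, method: str, ward_dialect: str) -> np.ndarray:
    """Agglomerate a square dissimilarity matrix; returns a scipy-format Z."""
    n = d.shape[0]
    if method == "ward" and ward_dialect == "squared":
        work = d.astype(float) ** 2
    else:
        work = d.astype(float).copy()
    np.fill_diagonal(work, np.inf)

    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}     # smallest leaf position, for tie-breaking
    row = {i: i for i in range(n)}     # cluster id -> row in `work`
    active = list(range(n))
    z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        best = None
        for ai, ci in enumerate(active):
            for cj in active[ai + 1:]:
                w = work[row[ci], row[cj]]
                key = (w, min(rep[ci], rep[cj]), max(rep[ci], rep[cj]))
                if best is None or key < best[0]:
                    best = (key, ci, cj)
        (w, _, _), ci, cj = best
        if not np.isfinite(w):
            raise ValidationError("non-finite dissimilarity during agglomeration")
        ni, nj = size[ci], size[cj]
        new = n + step
        height = np.sqrt(w) if (method == "ward" and ward_dialect == "squared") else w
        z[step] = [min(ci, cj), max(ci, cj), height, ni + nj]

        ri, rj = row[ci], row[cj]
        for ck in active:
            if ck in (ci, cj):
                continue
            rk = row[ck]
            dik, djk = work[ri, rk], work[rj, rk]
            if method == "complete":
                new_d = max(dik, djk)
            elif method == "ward":
                nk = size[ck]
                new_d = ((ni + nk) * dik + (nj + nk) * djk - nk * work[ri, rj]) / (ni + nj + nk)
            else:
                raise ConfigurationError(f"unknown linkage {method!r}")
            work[ri, rk] = work[rk, ri] = new_d
        # reuse ci's row for the merged cluster; retire cj's
        size[new] = ni + nj
        rep[new] = min(rep[ci], rep[cj])
        row[new] = ri
        work[rj, :] = np.inf
        work[:, rj] = np.inf
        active.remove(ci)
        active.remove(cj)
        active.append(new)
    return z


def hierarchical_cluster(
    dm, linkage: str = "complete", ward_dialect: str = "squared"
) -> Dendrogram:
    """Cluster a distance matrix (scikit-bio DistanceMatrix) agglomeratively."""
    d = np.asarray(dm.data, dtype=float)
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN")
    if d.shape[0] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    z = _lance_williams(d, linkage, ward_dialect)
    return Dendrogram(linkage_matrix=z, labels=list(dm.ids), method=linkage)


# ---------------------------------------------------------------------------
# SIMPROF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimprofResult:
    node_id: int
    n_samples: int
    pi_statistic: float
    p_value: float
    n_permutations: int
    decision: str  # "heterogeneous" | "homogeneous"


def _permute_within_species(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each species' (column's) values across samples."""
    order = np.argsort(rng.random(x.shape), axis=0)
    return np.take_along_axis(x, order, axis=0)


def simprof_statistic(
    x,
    n_perm_expected: int = 999,
    n_perm_null: int = 999,
    seed=None,
    alpha: float = 1e-7,
    node_id: int = -1,
) -> SimprofResult:
    """SIMPROF permutation test of multivariate structure in one sample group.

    ``x`` is a samples x species abundance array (an AbundanceMatrix is also
    accepted). Groups of fewer than three samples are homogeneous by
    construction. The decision rejects (declares heterogeneity) when alpha > 0
    and p <= alpha_effective, with alpha_effective = max(alpha,
    1/(n_perm_null + 1)) -- a nominal alpha below the Monte-Carlo resolution
    degrades to the smallest attainable p-value.
    """
    if n_perm_expected < 1 or n_perm_null < 1:
        raise ConfigurationError("permutation counts must be >= 1")
    if isinstance(x, AbundanceMatrix):
        x = x.values()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        return SimprofResult(node_id, n, 0.0, 1.0, 0, "homogeneous")
    rng = np.random.default_rng(seed)

    observed = np.sort(_bc_condensed(x))
    expected = np.zeros_like(observed)
    for _ in range(n_perm_expected):
        expected += np.sort(_bc_condensed(_permute_within_species(x, rng)))
    expected /= n_perm_expected

    pi_obs = float(np.abs(observed - expected).sum())
    pi_null = np.empty(n_perm_null)
    for i in range(n_perm_null):
        prof = np.sort(_bc_condensed(_permute_within_species(x, rng)))
        pi_null[i] = np.abs(prof - expected).sum()
    p = (1.0 + np.sum(pi_null >= pi_obs)) / (1.0 + n_perm_null)

    alpha_eff = max(alpha, 1.0 / (n_perm_null + 1.0))
    reject = alpha > 0 and p <= alpha_eff
    return SimprofResult(
        node_id=node_id,
        n_samples=n,
        pi_statistic=pi_obs,
        p_value=float(p),
        n_permutations=n_perm_null,
        decision="heterogeneous" if reject else "homogeneous",
    )


@dataclass
class ClusterSet:
    """SIMPROF-significant clusters: a partition of the sample labels."""

    clusters: list  # list of lists of sample labels
    alpha: float
    alpha_effective: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def simprof_clusters(
    m: AbundanceMatrix,
    linkage: str = "complete",
    alpha: float = 1e-7,
    n_perm_expected: int = 999,
    n_perm_null: int = 999,
    seed: int = 0,
    ward_dialect: str = "squared",
    metric: str = "braycurtis",
):
    """Delimit significant clusters by recursive SIMPROF down a dendrogram.

    Returns (Dendrogram, ClusterSet, list of SimprofResult). Each node's
    permutation stream is seeded from (seed, node_id) so results for one node
    do not depend on how many other nodes were tested.
    """
    dm = distance_matrix(m, metric=metric)
    dendro = hierarchical_cluster(dm, linkage=linkage, ward_dialect=ward_dialect)
    tree = to_tree(dendro.linkage_matrix)
    x = m.values()
    labels = list(m.data.index)
    results: list[SimprofResult] = []
    clusters: list[list] = []

    def recurse(node):
        leaf_ids = node.pre_order(lambda leaf: leaf.id)
        if node.is_leaf() or len(leaf_ids) < 3:
            clusters.append(sorted(leaf_ids))
            return
        res = simprof_statistic(
            x[leaf_ids],
            n_perm_expected=n_perm_expected,
            n_perm_null=n_perm_null,
            seed=np.random.SeedSequence([int(seed), int(node.id)]),
            alpha=alpha,
            node_id=int(node.id),
        )
        results.append(res)
        if res.decision == "heterogeneous":
            recurse(node.left)
            recurse(node.right)
        else:
            clusters.append(sorted(leaf_ids))

    recurse(tree)
    clusters.sort(key=lambda ids: ids[0])
    cluster_labels = [[labels[i] for i in ids] for ids in clusters]
    alpha_eff = max(alpha, 1.0 / (n_perm_null + 1.0))
    return dendro, ClusterSet(cluster_labels, alpha, alpha_eff), results


# ---------------------------------------------------------------------------
# depth zones
# ---------------------------------------------------------------------------

@dataclass
class DepthZoneAssignment:
    """Mapping of 10-m depth bins to named, depth-ordered zones for one site."""

    site: str
    mapping: dict          # bin label (int), or (site, bin) cross-site -> zone name
    zone_order: list
    contiguous: bool = True

    def zone_of(self, depth_bin: int, site: str | None = None) -> str:
        key = depth_bin if (site is None or self.site is not None) else (site, depth_bin)
        try:
            return self.mapping[key]
        except KeyError:
            raise ContractError(
                f"depth bin {depth_bin} at site {site or self.site!r} has no zone assignment"
            ) from None

    def for_site(self, site: str) -> "DepthZoneAssignment":
        """Single-site view of a cross-site assignment."""
        if self.site is not None:
            return self
        mapping = {b: z for (s, b), z in self.mapping.items() if s == site}
        return DepthZoneAssignment(site=site, mapping=mapping, zone_order=list(self.zone_order),
                                   contiguous=self.contiguous)

    def bins_of(self, zone: str) -> list:
        return sorted(b for b, z in self.mapping.items() if z == zone)

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.mapping, key=lambda k: (k if isinstance(k, tuple) else ("", k)))
        return pd.DataFrame(
            {
                "site": [k[0] if isinstance(k, tuple) else self.site for k in keys],
                "depth_bin": [k[1] if isinstance(k, tuple) else k for k in keys],
                "zone": [self.mapping[k] for k in keys],
            }
        )


def default_zone_names(n_zones: int) -> list:
    """Conventional names for a shallow-to-deep sequence of n zones.

    Four zones get the deep-reef ladder (upper/lower mesophotic, upper/lower
    rariphotic); six adds the altiphotic above and below-rariphotic beneath;
    five assumes the survey starts below the altiphotic.
    """
    if n_zones == 6:
        return list(ZONES)
    if n_zones == 5:
        return list(ZONES[1:])
    if n_zones == 4:
        return list(ZONES[1:5])
    return [f"zone_{i + 1}" for i in range(n_zones)]


def pool_clusters_to_zones(
    dendro: Dendrogram,
    m: AbundanceMatrix,
    n_zones: int,
    zone_names: list | None = None,
    force: bool = False,
) -> DepthZoneAssignment:
    """Pool samples into n depth zones by cutting the dendrogram's top merges.

    Cutting at the ``n_zones - 1`` highest merge heights groups the SIMPROF
    clusters (or splits one at its main internal branch when more zones than
    clusters are requested, mirroring how an ambiguous large cluster is
    divided at its main branching event). Zone membership must be depth-
    contiguous; violations raise unless ``force=True``, which assigns anyway
    with a warning (one site in the source data shows a single such inversion).
    """
    if n_zones < 1 or n_zones > dendro.n_leaves:
        raise ConfigurationError("n_zones must be in [1, n_samples]")
    names = zone_names or default_zone_names(n_zones)
    if len(names) != n_zones:
        raise ConfigurationError("zone_names length must equal n_zones")

    groups = cut_tree(dendro.linkage_matrix, n_clusters=n_zones).ravel()
    meta = m.sample_meta
    lead_bins = meta["depth_bin"].to_numpy()
    # order groups by their mean leading depth
    group_ids = sorted(set(groups), key=lambda g: lead_bins[groups == g].mean())
    zone_by_row = {}
    for name, g in zip(names, group_ids):
        for i in np.flatnonzero(groups == g):
            zone_by_row[i] = name

    # contiguity: per site, along depth order the zone sequence must be constant blocks
    offending = []
    site_col = meta["site"].to_numpy()
    for s in pd.unique(site_col):
        rows = np.flatnonzero(site_col == s)
        order = rows[np.argsort(lead_bins[rows], kind="stable")]
        seen, last = set(), None
        for i in order:
            zname = zone_by_row[i]
            if zname != last:
                if zname in seen:
                    offending.append(int(lead_bins[i]))
                seen.add(zname)
                last = zname
    contiguous = not offending
    if offending:
        msg = f"non-contiguous zone grouping; offending bin(s) {offending} at site"
        if not force:
            raise ValidationError(msg + " (pass force=True to assign anyway)")
        warnings.warn(msg)

    sites = meta["site"].unique()
    site = sites[0] if len(sites) == 1 else None
    mapping = {}
    for i, (lbl, row) in enumerate(meta.iterrows()):
        for b in row["bins"]:
            key = int(b) if site is not None else (row["site"], int(b))
            mapping[key] = zone_by_row[i]
    return DepthZoneAssignment(site=site, mapping=mapping, zone_order=list(names),
                               contiguous=contiguous)


def depth_breaks(assignment: DepthZoneAssignment) -> list:
    """Break depths between consecutive zones (the deeper zone's first bin)."""
    breaks = []
    for za, zb in zip(assignment.zone_order, assignment.zone_order[1:]):
        bins_b = assignment.bins_of(zb)
        if assignment.bins_of(za) and bins_b:
            breaks.append(bins_b[0])
    return breaks


def crosssite_cluster(
    matrices,
    linkage: str = "ward",
    alpha: float = 1e-6,
    n_perm_expected: int = 999,
    n_perm_null: int = 999,
    seed: int = 0,
    ward_dialect: str = "squared",
):
    """SIMPROF clustering of (site, depth-bin) samples pooled across sites.

    ``matrices`` is a list of per-site AbundanceMatrix objects (already
    transformed) or a single combined matrix. Default linkage is Ward and the
    default alpha matches the cross-site analysis preset (1e-6).
    """
    from .obsdata import combine_matrices

    m = combine_matrices(matrices) if isinstance(matrices, (list, tuple)) else matrices
    return simprof_clusters(
        m,
        linkage=linkage,
        alpha=alpha,
        n_perm_expected=n_perm_expected,
        n_perm_null=n_perm_null,
        seed=seed,
        ward_dialect=ward_dialect,
    )
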