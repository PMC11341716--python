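"""Observation tables, depth binning, abundance matrices and sparse-bin pooling.

The long-format observation table is the package's primary input: one row per
sighting event, ``site, dive_id, depth_m, species, genus, family, count``.
Community analyses operate on :class:`AbundanceMatrix` objects -- samples
(site x 10-m depth bin, possibly pooled spans of bins) by species -- built by
summing counts over dives.

Depth bins are labeled by their minimum depth and are half-open: an
observation at 49 m belongs to the 40 m bin, one at exactly 40 m likewise.
Bins too sparse to support a community comparison (fewer than five individuals
by default) are pooled with the next deeper bin until the pooled total reaches
the threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Required columns of an observation CSV, in canonical order.
OBS_COLUMNS = ["site", "dive_id", "depth_m", "species", "genus", "family", "count"]

#: Columns that must be present on read; ``genus`` may be derived from species.
OBS_REQUIRED = ["site", "dive_id", "depth_m", "species", "family", "count"]

EFFORT_COLUMNS = ["site", "depth_bin", "hours"]


# ---------------------------------------------------------------------------
# observation and effort tables
# ---------------------------------------------------------------------------

def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly coerce) a long-format observation table.

    Returns a copy with canonical dtypes and a ``genus`` column (first token
    of the species label when not supplied explicitly).
    """
    missing = [c for c in OBS_REQUIRED if c not in obs.columns]
    if missing:
        raise SchemaError(f"observation table is missing column(s): {', '.join(missing)}")
    out = obs.copy()
    out["count"] = pd.to_numeric(out["count"])
    out["depth_m"] = pd.to_numeric(out["depth_m"])
    bad_count = out.index[(out["count"] < 1) | (out["count"] != out["count"].astype(int))]
    if len(bad_count):
        raise ValidationError(
            f"counts must be integers >= 1; offending row index(es): {list(bad_count[:5])}"
        )
    bad_depth = out.index[out["depth_m"] < 0]
    if len(bad_depth):
        raise ValidationError(f"negative depth at row index(es): {list(bad_depth[:5])}")
    out["count"] = out["count"].astype(int)
    if "genus" not in out.columns or out["genus"].isna().any():
        derived = out["species"].astype(str).str.split().str[0]
        if "genus" in out.columns:
            out["genus"] = out["genus"].fillna(derived)
        else:
            out["genus"] = derived
    return out


def read_observations(path) -> pd.DataFrame:
    """Read an observation CSV (UTF-8, header row) and validate it."""
    obs = validate_observations(pd.read_csv(path))
    logger.info("read %d observation records from %s", len(obs), path)
    return obs


def validate_effort(effort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EFFORT_COLUMNS if c not in effort.columns]
    if missing:
        raise SchemaError(f"effort table is missing column(s): {', '.join(missing)}")
    out = effort.copy()
    out["hours"] = pd.to_numeric(out["hours"])
    out["depth_bin"] = pd.to_numeric(out["depth_bin"]).astype(int)
    if (out["hours"] <= 0).any():
        bad = out.loc[out["hours"] <= 0, ["site", "depth_bin"]].iloc[0]
        raise ValidationError(
            f"effort hours must be > 0 (site={bad['site']}, depth_bin={bad['depth_bin']})"
        )
    if out.duplicated(["site", "depth_bin"]).any():
        raise ValidationError("effort table has duplicate (site, depth_bin) rows")
    return out


def read_effort(path) -> pd.DataFrame:
    return validate_effort(pd.read_csv(path))


def bin_depth(depth, bin_width: int = 10):
    """Depth -> bin label (the minimum depth of the containing interval).

    Bins are half-open ``[label, label + bin_width)``: 49 m -> 40, 40 m -> 40.
    Accepts scalars or arrays.
    """
    arr = np.asarray(depth, dtype=float)
    if np.any(arr < 0):
        raise ValidationError("depth must be >= 0")
    labels = (np.floor(arr / bin_width) * bin_width).astype(int)
    return labels if arr.ndim else int(labels)


# ---------------------------------------------------------------------------
# abundance matrices
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Samples x species abundance matrix with provenance metadata.

    ``data`` rows are samples ordered shallow to deep; ``sample_meta`` (same
    index) records each sample's ``site``, leading ``depth_bin`` and the tuple
    of constituent 10-m ``bins`` (more than one after pooling). ``transforms``
    is the history of numeric transforms applied (e.g. ``effort_norm``,
    ``sqrt``).
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame
    transforms: list = field(default_factory=list)

    def __post_init__(self):
        if not self.data.index.equals(self.sample_meta.index):
            raise ValidationError("data and sample_meta must share an index")
        if (np.asarray(self.data.to_numpy(), dtype=float) < 0).any():
            raise ValidationError("abundance cells must be nonnegative")
        if self.data.index.has_duplicates:
            raise ValidationError("sample labels must be unique")

    # -- conveniences -------------------------------------------------------
    @property
    def species(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, transform: str | None = None) -> "AbundanceMatrix":
        transforms = list(self.transforms) + ([transform] if transform else [])
        return replace(self, data=data, transforms=transforms)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "sample", out.index)
        out.to_csv(path, index=False)


def _sample_label(site: str | None, bins: tuple) -> str:
    span = str(bins[0]) if len(bins) == 1 else f"{bins[0]}-{bins[-1]}"
    return span if site is None else f"{site}:{span}"


def build_abundance_matrix(
    obs: pd.DataFrame,
    site: str | None = None,
    depth_window: tuple = (40, 300),
    bin_width: int = 10,
    effort: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Sum counts over dives into a (depth bin x species) matrix for one site.

    The depth window is half-open ``[lo, hi)`` with bin-aligned edges. Rows
    are every bin of the site's surveyed span inside the window: the bins of
    the effort table when one is given, otherwise the contiguous range from
    the shallowest to the deepest observed bin. Bins with no observations
    appear as all-zero rows.
    """
    lo, hi = depth_window
    if lo % bin_width or hi % bin_width:
        raise ValidationError("depth_window edges must be multiples of bin_width")
    obs = validate_observations(obs)
    if site is not None:
        obs = obs[obs["site"] == site]
        site_label = site
    else:
        sites = obs["site"].unique()
        if len(sites) > 1:
            raise ValidationError(
                "build_abundance_matrix is per-site; pass site=... or use combine_matrices"
            )
        site_label = sites[0] if len(sites) else None

    obs = obs.assign(depth_bin=bin_depth(obs["depth_m"].to_numpy(), bin_width))
    obs = obs[(obs["depth_bin"] >= lo) & (obs["depth_bin"] < hi)]

    if effort is not None:
        eff = validate_effort(effort)
        if site is not None:
            eff = eff[eff["site"] == site]
        bins = sorted(b for b in eff["depth_bin"].unique() if lo <= b < hi)
    elif len(obs):
        bins = list(range(int(obs["depth_bin"].min()), int(obs["depth_bin"].max()) + bin_width, bin_width))
    else:
        bins = []
    if not bins:
        warnings.warn("no observations or effort inside the depth window; empty matrix")

    wide = (
        obs.pivot_table(index="depth_bin", columns="species", values="count", aggfunc="sum", fill_value=0)
        .reindex(bins, fill_value=0)
    )
    wide.columns.name = None
    labels = [_sample_label(site_label, (b,)) for b in bins]
    data = pd.DataFrame(wide.to_numpy(dtype=float), index=labels, columns=list(wide.columns))
    meta = pd.DataFrame(
        {"site": site_label, "depth_bin": bins, "bins": [(b,) for b in bins]}, index=labels
    )
    return AbundanceMatrix(data=data, sample_meta=meta)


def combine_matrices(mats: list[AbundanceMatrix]) -> AbundanceMatrix:
    """Stack per-site matrices into one cross-site matrix (union of species)."""
    if not mats:
        raise ValidationError("no matrices to combine")
    species = sorted(set().union(*[set(m.species) for m in mats]))
    datas, metas = [], []
    for m in mats:
        d = m.data.reindex(columns=species, fill_value=0.0)
        d.index = [
            _sample_label(m.sample_meta.loc[lbl, "site"], m.sample_meta.loc[lbl, "bins"])
            for lbl in d.index
        ]
        meta = m.sample_meta.copy()
        meta.index = d.index
        datas.append(d)
        metas.append(meta)
    transforms = mats[0].transforms
    if any(m.transforms != transforms for m in mats):
        raise ValidationError("matrices to combine have differing transform histories")
    return AbundanceMatrix(
        data=pd.concat(datas), sample_meta=pd.concat(metas), transforms=list(transforms)
    )


def pool_sparse_bins(m: AbundanceMatrix, min_total: float = 5) -> AbundanceMatrix:
    """Pool sparse rows with the next deeper row until each total >= min_total.

    Scanning shallow to deep, a row whose running total is below the threshold
    is merged (cell-wise sum) into the next deeper row; the merged row's label
    spans its constituent bins. If the deepest surviving row still falls below
    the threshold it is retained with a warning (pooling is downward only).
    Column sums are conserved.
    """
    if len(m.sample_meta["site"].unique()) > 1:
        raise ValidationError("pool_sparse_bins operates on a single-site matrix")
    order = np.argsort(m.sample_meta["depth_bin"].to_numpy(), kind="stable")
    data = m.data.iloc[order]
    meta = m.sample_meta.iloc[order]
    site = meta["site"].iloc[0] if len(meta) else None

    pooled_rows, pooled_bins = [], []
    acc = None
    acc_bins: list = []
    for i in range(len(data)):
        row = data.iloc[i].to_numpy(dtype=float)
        acc = row if acc is None else acc + row
        acc_bins = acc_bins + list(meta["bins"].iloc[i])
        if acc.sum() >= min_total:
            pooled_rows.append(acc)
            pooled_bins.append(tuple(acc_bins))
            acc, acc_bins = None, []
    if acc is not None:
        if pooled_rows and acc.sum() < min_total and len(pooled_rows) >= 1 and acc.sum() > 0:
            # deepest remainder kept as its own row, below threshold
            warnings.warn(
                f"deepest pooled bin {acc_bins[0]}-{acc_bins[-1]} retains only "
                f"{acc.sum():.0f} individuals (< {min_total}); kept without upward pooling"
            )
        elif not pooled_rows:
            warnings.warn(
                f"matrix total {acc.sum():.0f} is below the pooling threshold {min_total}; "
                "single pooled row retained"
            )
        if acc.sum() > 0 or not pooled_rows:
            pooled_rows.append(acc)
            pooled_bins.append(tuple(acc_bins))
        else:
            # all-zero trailing remainder folds into the previous row's span
            pooled_bins[-1] = tuple(list(pooled_bins[-1]) + acc_bins)

    labels = [_sample_label(site, b) for b in pooled_bins]
    new_data = pd.DataFrame(np.array(pooled_rows), index=labels, columns=m.species)
    new_meta = pd.DataFrame(
        {"site": site, "depth_bin": [b[0] for b in pooled_bins], "bins": pooled_bins},
        index=labels,
    )
    return AbundanceMatrix(data=new_data, sample_meta=new_meta, transforms=list(m.transforms))
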