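"""Sampling-effort normalization, depth profiles and sample-based rarefaction.

Dive time per 10-m depth bin varies with slope steepness and logistics, so
raw counts are not comparable across depth. Each bin's abundance is rescaled
by a sampling coefficient

    coefficient(x, z) = max_x t(x, z) / t(x, z)

(t = hours of effort in bin x at site z), i.e. counts are inflated to the
effort of the best-sampled bin of that site. Site comparisons further rescale
normalized bin totals into relative abundance, percent of the site maximum
over a reference depth window (40-300 m by default).

Rarefaction is sample-based over dives and exact: the expected richness after
n of N dives is a sum of hypergeometric inclusion probabilities, so curves
are deterministic. A resampling mode with a seed is kept for parity with
common practice.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .obsdata import AbundanceMatrix, bin_depth, validate_effort, validate_observations


def sampling_coefficients(effort: pd.DataFrame, site: str) -> pd.Series:
    """Per-bin effort coefficients for one site: max(hours) / hours(bin).

    Coefficients are >= 1, and exactly 1 at the bin of maximal effort.
    """
    eff = validate_effort(effort)
    eff = eff[eff["site"] == site]
    if eff.empty:
        raise ValidationError(f"no effort rows for site {site!r}")
    hours = eff.set_index("depth_bin")["hours"].sort_index()
    coeff = hours.max() / hours
    coeff.name = "coefficient"
    return coeff


def _row_hours(m: AbundanceMatrix, effort: pd.DataFrame) -> pd.Series:
    """Total effort hours per matrix row (summing hours of pooled bins)."""
    eff = validate_effort(effort)
    hours = {}
    for lbl, meta in m.sample_meta.iterrows():
        sel = eff[(eff["site"] == meta["site"]) & (eff["depth_bin"].isin(meta["bins"]))]
        if len(sel) != len(meta["bins"]):
            missing = set(meta["bins"]) - set(sel["depth_bin"])
            raise ContractError(
                f"no effort for site {meta['site']!r} bin(s) {sorted(missing)} (row {lbl!r})"
            )
        hours[lbl] = sel["hours"].sum()
    return pd.Series(hours).reindex(m.data.index)


def normalize_abundance(m: AbundanceMatrix, coefficients) -> AbundanceMatrix:
    """Scale each matrix row by its sampling coefficient (Eq.-1-style).

    ``coefficients`` is either a Series indexed by depth bin (single-site
    matrices of unpooled 10-m bins) or a full effort table DataFrame, in which
    case a row's coefficient is max(row hours)/row hours with pooled rows
    using their summed constituent-bin hours.
    """
    if isinstance(coefficients, pd.DataFrame):
        hours = _row_hours(m, coefficients)
        coeff_per_row = hours.max() / hours
    else:
        bins = m.sample_meta["depth_bin"]
        missing = sorted(set(bins) - set(coefficients.index))
        if missing:
            raise ContractError(f"no sampling coefficient for depth bin(s) {missing}")
        coeff_per_row = pd.Series(
            coefficients.reindex(bins).to_numpy(), index=m.data.index
        )
    data = m.data.mul(coeff_per_row, axis=0)
    return m.with_data(data, transform="effort_norm")


def relative_abundance(totals: pd.Series, window: tuple = (40, 300)) -> pd.Series:
    """Normalized bin totals -> percent of the window maximum (Eq.-3-style).

    ``totals`` is indexed by depth bin. The maximum is taken over bins inside
    the half-open window ``[lo, hi]`` (inclusive hi per the printed formula's
    closed interval); the best bin maps to 100.
    """
    lo, hi = window
    in_win = totals[(totals.index >= lo) & (totals.index <= hi)]
    if in_win.empty:
        raise ValidationError("relative_abundance: window contains no bins")
    peak = in_win.max()
    if peak <= 0:
        raise ValidationError("relative_abundance: all-zero profile in window")
    out = totals / peak * 100.0
    out.name = "relative_abundance_pct"
    return out


def abundance_profile(m: AbundanceMatrix) -> pd.Series:
    """Row totals indexed by leading depth bin (shallow to deep)."""
    totals = m.row_totals()
    totals.index = m.sample_meta["depth_bin"].to_numpy()
    return totals.sort_index()


def richness_profile(m: AbundanceMatrix) -> pd.Series:
    """Species richness (count of species with abundance > 0) per sample row.

    Meaningful on raw counts; richness is not effort-normalized because a
    species tally has no time-rescaled analogue.
    """
    rich = (m.data > 0).sum(axis=1)
    rich.index = m.sample_meta["depth_bin"].to_numpy()
    rich.name = "richness"
    return rich.sort_index()


def rarefaction_curve(
    obs: pd.DataFrame,
    site: str | None = None,
    method: str = "exact",
    n_resample: int = 200,
    seed: int | None = None,
    depth_window: tuple | None = None,
    bin_width: int = 10,
) -> pd.DataFrame:
    """Sample-based rarefaction over dives.

    Exact mode: E[S(n)] = sum_i [1 - C(N - N_i, n) / C(N, n)] where N is the
    number of dives and N_i the number of dives in which species i occurs.
    Resample mode draws ``n_resample`` random dive subsets per n instead.
    Returns a DataFrame with columns ``n_dives, expected_richness``.
    """
    obs = validate_observations(obs)
    if site is not None:
        obs = obs[obs["site"] == site]
    if depth_window is not None:
        b = bin_depth(obs["depth_m"].to_numpy(), bin_width)
        obs = obs[(b >= depth_window[0]) & (b < depth_window[1])]
    if obs.empty:
        raise ValidationError("rarefaction_curve: no observations selected")

    incidence = obs.groupby("species")["dive_id"].nunique()
    dives = obs["dive_id"].unique()
    N = len(dives)

    ns = np.arange(1, N + 1)
    if method == "exact":
        expected = [
            float(sum(1.0 - comb(N - Ni, n) / comb(N, n) if N - Ni >= n else 1.0
                      for Ni in incidence))
            for n in ns
        ]
    elif method == "resample":
        rng = np.random.default_rng(seed)
        present = {
            d: set(obs.loc[obs["dive_id"] == d, "species"]) for d in dives
        }
        expected = []
        for n in ns:
            draws = [
                len(set().union(*[present[d] for d in rng.choice(dives, n, replace=False)]))
                for _ in range(n_resample)
            ]
            expected.append(float(np.mean(draws)))
    else:
        raise ValidationError(f"unknown rarefaction method {method!r}")
    return pd.DataFrame({"n_dives": ns, "expected_richness": expected})


def profiles_to_tidy(site: str, **profiles: pd.Series) -> pd.DataFrame:
    """Assemble named per-bin profiles into tidy (site, depth_bin, metric, value) rows."""
    frames = []
    for metric, series in profiles.items():
        frames.append(
            pd.DataFrame(
                {
                    "site": site,
                    "depth_bin": series.index,
                    "metric": metric,
                    "value": series.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
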