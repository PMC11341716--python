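"""PERMANOVA and SIMPER: testing and decomposing between-zone differences.

PERMANOVA partitions the total sum of squares of a distance matrix (computed
from Gower-centered squared distances) among grouping factors; significance
comes from permuting raw sample identities. The one-way design tests depth
zones a posteriori; the two-way crossed design (depth zone, site and their
interaction) uses sequential (Type I) sums of squares in that order, the
simplest published scheme -- the choice is echoed in the result table.

SIMPER decomposes the average between-group Bray-Curtis dissimilarity into
per-species contributions: for each between-group sample pair (i, j) species
k contributes |x_ik - x_jk| / sum_k(x_ik + x_jk), averaged over pairs. A
species' permutation p-value is the fraction of group-label permutations in
which its contribution is at least the observed one (with the +1 Monte-Carlo
correction). Indicator species are those contributing more than 5% of the
dissimilarity with p < 0.05, annotated with the group in which they are more
abundant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .obsdata import AbundanceMatrix


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _dummies(values) -> np.ndarray:
    values = pd.Series(values).astype(str)
    return pd.get_dummies(values, drop_first=True).to_numpy(dtype=float)


def permanova(
    dm,
    factors,
    interaction: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    ``factors`` maps term name -> grouping vector (aligned with the distance
    matrix ids); one entry gives a one-way design, two entries a crossed
    design, with an interaction term when requested. Returns an ANOVA-style
    table (term, df, SS, pseudo_F, R2, p_value) including Residual and Total
    rows; SS, pseudo-F and R2 are permutation-invariant, only p varies with
    the seed.
    """
    d = np.asarray(dm.data, dtype=float)
    n = len(d)
    names = list(factors)
    if not 1 <= len(names) <= 2:
        raise ConfigurationError("permanova supports one or two factors")
    if interaction and len(names) < 2:
        raise ConfigurationError("interaction requires two factors")
    columns = {}
    for name in names:
        vec = np.asarray(pd.Series(factors[name]).astype(str))
        if len(vec) != n:
            raise ValidationError(f"factor {name!r} length {len(vec)} != {n} samples")
        if len(set(vec)) < 2:
            raise ValidationError(f"factor {name!r} has fewer than 2 levels")
        columns[name] = vec

    g = _gower_center(d)
    ss_total = float(np.trace(g))

    # sequential designs: intercept, +A, +B, +A:B
    terms = list(names) + (["interaction"] if interaction else [])
    designs = [np.ones((n, 1))]
    blocks = [_dummies(columns[names[0]])]
    df_terms = [blocks[0].shape[1]]
    if len(names) == 2:
        b2 = _dummies(columns[names[1]])
        blocks.append(b2)
        df_terms.append(b2.shape[1])
        if interaction:
            inter = np.einsum("ij,ik->ijk", blocks[0], b2).reshape(n, -1)
            blocks.append(inter)
            df_terms.append(df_terms[0] * df_terms[1])
    for blk in blocks:
        designs.append(np.hstack([designs[-1], blk]))
    hats = [_hat(x) for x in designs]

    def term_ss(gmat):
        traces = [float(np.sum(h * gmat)) for h in hats]
        return np.diff(traces), ss_total_of(gmat) - traces[-1]

    def ss_total_of(gmat):
        return float(np.trace(gmat))

    ss_seq, ss_res = term_ss(g)
    df_res = n - 1 - sum(df_terms)
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom (saturated design)")
    ms_res = ss_res / df_res
    f_obs = np.array([ss / df / ms_res for ss, df in zip(ss_seq, df_terms)])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ssp, ssrp = term_ss(gp)
        fp = np.array([ss / df / (ssrp / df_res) for ss, df in zip(ssp, df_terms)])
        exceed += fp >= f_obs
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for t, df, ss, f, p in zip(terms, df_terms, ss_seq, f_obs, p_vals):
        rows.append({"term": t, "df": df, "SS": ss, "pseudo_F": f,
                     "R2": ss / ss_total, "p_value": p})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res, "pseudo_F": np.nan,
                 "R2": ss_res / ss_total, "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "pseudo_F": np.nan,
                 "R2": 1.0, "p_value": np.nan})
    table = pd.DataFrame(rows)
    table.attrs["n_permutations"] = n_perm
    table.attrs["seed"] = seed
    table.attrs["ss_type"] = "sequential (Type I), raw-observation permutation"
    return table


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def _mean_contributions(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Per-species mean contribution to between-group Bray-Curtis dissimilarity."""
    diff = np.abs(x1[:, None, :] - x2[None, :, :])            # n1 x n2 x p
    denom = x1.sum(axis=1)[:, None] + x2.sum(axis=1)[None, :]  # n1 x n2
    if (denom == 0).any():
        raise ValidationError("SIMPER: a between-group sample pair is entirely empty")
    return (diff / denom[:, :, None]).mean(axis=(0, 1))


def simper(
    m: AbundanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Species contributions to the dissimilarity between two sample groups.

    ``grouping`` assigns each matrix row to one of exactly two groups. Uses
    the matrix as given (square-root transformed upstream, matching the
    clustering input). Returns one row per species with mean contribution,
    percent of total, direction (group with higher mean abundance) and
    permutation p-value; the contributions sum to the average between-group
    Bray-Curtis dissimilarity (stored in ``attrs['mean_dissimilarity']``).
    """
    groups = pd.Series(list(grouping), index=m.data.index)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError(f"SIMPER needs exactly 2 groups, got {levels}")
    x = m.values()
    idx1 = np.flatnonzero((groups == levels[0]).to_numpy())
    idx2 = np.flatnonzero((groups == levels[1]).to_numpy())
    if x[idx1].sum() == 0 or x[idx2].sum() == 0:
        raise ValidationError("SIMPER: a group has zero total abundance")

    contrib = _mean_contributions(x[idx1], x[idx2])
    total = contrib.sum()

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([idx1, idx2])
    exceed = np.zeros_like(contrib)
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        c = _mean_contributions(x[perm[: len(idx1)]], x[perm[len(idx1):]])
        exceed += c >= contrib
    p_vals = (1.0 + exceed) / (1.0 + n_perm)

    mean1 = x[idx1].mean(axis=0)
    mean2 = x[idx2].mean(axis=0)
    out = pd.DataFrame(
        {
            "species": m.species,
            "contribution": contrib,
            "percent": contrib / total * 100.0 if total > 0 else np.zeros_like(contrib),
            "mean_abundance_a": mean1,
            "mean_abundance_b": mean2,
            "direction": np.where(mean1 >= mean2, str(levels[0]), str(levels[1])),
            "p_value": p_vals,
        }
    )
    absent = (mean1 == 0) & (mean2 == 0)
    out = out[~absent].sort_values("contribution", ascending=False).reset_index(drop=True)
    out.attrs["mean_dissimilarity"] = float(total)
    out.attrs["groups"] = (str(levels[0]), str(levels[1]))
    out.attrs["n_permutations"] = n_perm
    return out


def indicator_species(
    simper_result: pd.DataFrame,
    contrib_threshold: float = 5.0,
    p_threshold: float = 0.05,
    direction: str | None = None,
) -> pd.DataFrame:
    """Species passing the SIMPER indicator rule (> contrib% and p < threshold)."""
    sel = (simper_result["percent"] > contrib_threshold) & (
        simper_result["p_value"] < p_threshold
    )
    if direction is not None:
        sel &= simper_result["direction"] == direction
    return simper_result[sel].reset_index(drop=True)
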