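"""Congener depth-segregation tests.

Species of the same genus often occupy distinct depth strata. For every genus
with at least two species each represented by at least ten individuals, the
per-individual depth observations (a record with count k contributes k
identical depths) are compared with:

* a Shapiro-Wilk normality check per species (recorded; depth distributions
  are rarely normal, which motivates the rank-based tests);
* a Kruskal-Wallis omnibus test of depth ~ species;
* pairwise two-sided Wilcoxon rank-sum (Mann-Whitney) tests between species,
  exact for small samples without ties, with a compact letter display
  (species sharing a letter are not significantly different). Raw pairwise
  p-values are reported; a Holm adjustment is available but off by default.

Mean depths of occurrence shown alongside the tests are corrected for
sampling effort by weighting each observation with its (site, bin) sampling
coefficient; the tests themselves run on the original depth observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ValidationError
from .obsdata import bin_depth, validate_observations


def eligible_genera(
    obs: pd.DataFrame, min_species: int = 2, min_individuals: int = 10
) -> list:
    """Genera with >= min_species species of >= min_individuals individuals each."""
    obs = validate_observations(obs)
    totals = obs.groupby(["genus", "species"])["count"].sum()
    ok = totals[totals >= min_individuals]
    counts = ok.groupby("genus").size()
    return sorted(counts[counts >= min_species].index)


def expand_depths(obs: pd.DataFrame) -> pd.Series:
    """Per-individual depths: each record repeated ``count`` times."""
    return pd.Series(
        np.repeat(obs["depth_m"].to_numpy(dtype=float), obs["count"].to_numpy()),
    )


def mean_depth_of_occurrence(
    obs: pd.DataFrame,
    coefficients: dict | None = None,
    bin_width: int = 10,
) -> float:
    """Effort-corrected mean depth of a species' observations (meters).

    ``coefficients`` maps site -> per-bin sampling-coefficient Series (from
    :func:`depthzone.effort_norm.sampling_coefficients`); weights are
    count x coefficient. With no coefficients the mean is count-weighted only.
    """
    obs = validate_observations(obs)
    if obs.empty:
        raise ValidationError("mean_depth_of_occurrence: no observations")
    depths = obs["depth_m"].to_numpy(dtype=float)
    weights = obs["count"].to_numpy(dtype=float)
    if coefficients is not None:
        bins = bin_depth(depths, bin_width)
        coeff = np.empty(len(obs))
        for i, (site, b) in enumerate(zip(obs["site"], bins)):
            try:
                coeff[i] = coefficients[site][b]
            except KeyError:
                raise ContractError(
                    f"no sampling coefficient for site {site!r} bin {b}"
                ) from None
        weights = weights * coeff
    return float(np.average(depths, weights=weights))


def _compact_letters(species: list, significant: dict) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant[(a, b)]`` is True when a and b differ significantly.
    Species sharing a letter are never significantly different.
    """
    def differ(a, b):
        return significant.get((a, b), significant.get((b, a), False))

    groups: list[set] = []
    for sp in species:
        placed = False
        for grp in groups:
            if not any(differ(sp, other) for other in grp):
                grp.add(sp)
                placed = True
        if not placed:
            groups.append({sp})
    # absorb groups contained in others
    groups = [g for g in groups if not any(g < h for h in groups)]
    letters = {sp: "" for sp in species}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for sp in sorted(grp):
            letters[sp] += letter
    return {sp: "".join(sorted(lets)) for sp, lets in letters.items()}


@dataclass
class GenusTestResult:
    genus: str
    species: list
    n_individuals: dict
    normality_p: dict
    omnibus_test: str
    omnibus_p: float
    pairwise_p: pd.DataFrame
    letters: dict
    mean_depths: dict

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.species):
            for b in self.species[i + 1:]:
                rows.append(
                    {"genus": self.genus, "species_a": a, "species_b": b,
                     "p_value": self.pairwise_p.loc[a, b]}
                )
        return pd.DataFrame(rows)


def genus_depth_test(
    obs: pd.DataFrame,
    genus: str,
    alpha: float = 0.05,
    min_individuals: int = 10,
    coefficients: dict | None = None,
    holm: bool = False,
) -> GenusTestResult:
    """Depth-segregation test battery for the species of one genus."""
    obs = validate_observations(obs)
    gobs = obs[obs["genus"] == genus]
    totals = gobs.groupby("species")["count"].sum()
    keep = list(totals[totals >= min_individuals].index)
    dropped = sorted(set(totals.index) - set(keep))
    if dropped:
        warnings.warn(f"genus {genus!r}: dropping under-sampled species {dropped}")
    if len(keep) < 2:
        raise ValidationError(f"genus {genus!r} has fewer than 2 eligible species")
    gobs = gobs[gobs["species"].isin(keep)]

    depths = {sp: expand_depths(gobs[gobs["species"] == sp]).to_numpy() for sp in keep}
    order = sorted(keep, key=lambda sp: depths[sp].mean())

    normality = {}
    for sp in order:
        d = depths[sp]
        if len(np.unique(d)) < 3:
            normality[sp] = np.nan
        else:
            normality[sp] = float(stats.shapiro(d).pvalue)

    kw = stats.kruskal(*[depths[sp] for sp in order])

    pmat = pd.DataFrame(np.nan, index=order, columns=order)
    raw = {}
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            combined = np.concatenate([depths[a], depths[b]])
            # exact null distribution when it is well defined (no ties) and
            # cheap; normal approximation with tie correction otherwise
            no_ties = len(np.unique(combined)) == len(combined)
            method = "exact" if no_ties and len(combined) <= 80 else "asymptotic"
            res = stats.mannwhitneyu(depths[a], depths[b], alternative="two-sided",
                                     method=method)
            raw[(a, b)] = float(res.pvalue)
    if holm:
        pairs = list(raw)
        adjusted = _holm([raw[p] for p in pairs])
        raw = dict(zip(pairs, adjusted))
    for (a, b), p in raw.items():
        pmat.loc[a, b] = pmat.loc[b, a] = p

    significant = {pair: p < alpha for pair, p in raw.items()}
    letters = _compact_letters(order, significant)
    means = {
        sp: mean_depth_of_occurrence(gobs[gobs["species"] == sp], coefficients)
        for sp in order
    }
    return GenusTestResult(
        genus=genus,
        species=order,
        n_individuals={sp: int(totals[sp]) for sp in order},
        normality_p=normality,
        omnibus_test="kruskal_wallis",
        omnibus_p=float(kw.pvalue),
        pairwise_p=pmat,
        letters=letters,
        mean_depths=means,
    )


def _holm(pvalues: list) -> list:
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted.tolist()


def segregation_report(
    obs: pd.DataFrame,
    alpha: float = 0.05,
    min_species: int = 2,
    min_individuals: int = 10,
    coefficients: dict | None = None,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Run genus_depth_test over all eligible genera.

    Returns (results, pairwise table, per-species summary table).
    """
    results = []
    for genus in eligible_genera(obs, min_species, min_individuals):
        results.append(
            genus_depth_test(obs, genus, alpha=alpha, min_individuals=min_individuals,
                             coefficients=coefficients)
        )
    pair_rows = pd.concat([r.pairwise_frame() for r in results], ignore_index=True) \
        if results else pd.DataFrame(columns=["genus", "species_a", "species_b", "p_value"])
    summary_rows = []
    for r in results:
        for sp in r.species:
            summary_rows.append(
                {
                    "genus": r.genus,
                    "species": sp,
                    "n_individuals": r.n_individuals[sp],
                    "normality_p": r.normality_p[sp],
                    "kruskal_p": r.omnibus_p,
                    "letters": r.letters[sp],
                    "mean_depth_m": r.mean_depths[sp],
                }
            )
    return results, pair_rows, pd.DataFrame(summary_rows)
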