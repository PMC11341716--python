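"""End-to-end orchestration: observations -> zones -> statistics -> reports.

The site analysis runs, per site: depth binning, abundance-matrix
construction, sparse-bin pooling, square-root transform, Bray-Curtis
distances, SIMPROF cluster delimitation, pooling into named depth zones,
one-way PERMANOVA over zones, SIMPER with the indicator rule for adjacent
zone pairs, and effort-normalized depth profiles with rarefaction. Pooled
across sites it then computes the beta-diversity table, species depth
affinities (site-specific breaks) and congener segregation tests.

The cross-site analysis stacks all sites' pooled matrices, clusters with Ward
linkage under the cross-site SIMPROF preset, and runs the two-way PERMANOVA
(depth zone, site, interaction) plus the between-site beta table per zone.

All randomness flows from the single config seed; rerunning a config
regenerates every output file byte-for-byte (checksums are recorded in the
run report).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import affinity as aff
from . import cluster_zone as cz
from . import dissim, effort_norm, groupstats, obsdata, segregation
from .errors import DepthZoneError, ValidationError

logger = logging.getLogger(__name__)


class PipelineStageError(DepthZoneError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults carry the survey's canonical values
    (10-m bins, 5-individual pooling, sqrt transform, conservative SIMPROF
    alpha, 75% specialist threshold, 5%/0.05 SIMPER indicator rule)."""

    observations_csv: str = ""
    effort_csv: str = ""
    sites: list | None = None
    depth_window: tuple = (40, 300)
    site_depth_windows: dict = field(default_factory=dict)
    bin_width: int = 10
    min_total: float = 5
    normalize_before_cluster: bool = True
    transform: str = "sqrt"
    linkage: str = "complete"
    crosssite_linkage: str = "ward"
    alpha: float = 1e-7
    crosssite_alpha: float = 1e-6
    n_perm_expected: int = 999
    n_perm_null: int = 999
    permanova_permutations: int = 999
    simper_permutations: int = 999
    n_zones: int = 4
    zone_names: list | None = None
    force_zone_assignment: bool = False
    specialist_threshold: float = 0.75
    simper_contrib_threshold: float = 5.0
    simper_p_threshold: float = 0.05
    segregation_min_species: int = 2
    segregation_min_individuals: int = 10
    shallow_flags_csv: str | None = None
    family_ranges_csv: str | None = None
    deep_sea_species_csv: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**known)
        if isinstance(cfg.depth_window, list):
            cfg.depth_window = tuple(cfg.depth_window)
        cfg.site_depth_windows = {
            k: tuple(v) for k, v in (cfg.site_depth_windows or {}).items()
        }
        return cfg

    def window_for(self, site: str) -> tuple:
        return self.site_depth_windows.get(site, self.depth_window)


@dataclass
class RunReport:
    """Provenance of one pipeline run: parameters, outputs, timings."""

    kind: str
    seed: int
    version: str
    params: dict
    stages: list = field(default_factory=list)    # [{stage, seconds}]
    files: dict = field(default_factory=dict)     # path -> sha256
    warnings: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Run:
    """Small helper that times stages and checksums written files."""

    def __init__(self, report: RunReport, out_dir: Path):
        self.report = report
        self.out = out_dir
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(self, name):
        run = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                self.caught = warnings.catch_warnings(record=True)
                self.wlist = self.caught.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                for w in self.wlist:
                    run.report.warnings.append(f"{name}: {w.message}")
                self.caught.__exit__(None, None, None)
                run.report.stages.append(
                    {"stage": name, "seconds": round(time.perf_counter() - self.t0, 3)}
                )
                if exc is not None and not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, exc) from exc
                return False

        return _Ctx()

    def save(self, name: str, df: pd.DataFrame) -> Path:
        path = self.out / name
        df.to_csv(path, index=False)
        self.report.files[name] = _sha256(path)
        return path

    def save_text(self, name: str, text: str) -> Path:
        path = self.out / name
        path.write_text(text)
        self.report.files[name] = _sha256(path)
        return path


def _load_inputs(config: PipelineConfig):
    obs = obsdata.read_observations(config.observations_csv)
    effort = obsdata.read_effort(config.effort_csv)
    sites = config.sites or sorted(obs["site"].unique())
    return obs, effort, sites


def _site_zone_pass(config: PipelineConfig, obs, effort, site):
    """Matrix -> pooled -> sqrt -> SIMPROF -> zones for one site."""
    raw = obsdata.build_abundance_matrix(
        obs, site=site, depth_window=config.window_for(site),
        bin_width=config.bin_width, effort=effort,
    )
    pooled = obsdata.pool_sparse_bins(raw, min_total=config.min_total)
    mat = pooled
    if config.normalize_before_cluster:
        mat = effort_norm.normalize_abundance(mat, effort)
    if config.transform == "sqrt":
        mat = dissim.sqrt_transform(mat)
    dendro, clusters, simprof = cz.simprof_clusters(
        mat, linkage=config.linkage, alpha=config.alpha,
        n_perm_expected=config.n_perm_expected, n_perm_null=config.n_perm_null,
        seed=config.seed,
    )
    n_zones = min(config.n_zones, mat.n_samples)
    assignment = cz.pool_clusters_to_zones(
        dendro, mat, n_zones, zone_names=config.zone_names,
        force=config.force_zone_assignment,
    )
    return raw, pooled, mat, dendro, clusters, simprof, assignment


def _zone_factor(mat, assignment):
    return [assignment.zone_of(meta["bins"][0]) for _, meta in mat.sample_meta.iterrows()]


def run_site_analysis(config: PipelineConfig, out_dir) -> RunReport:
    """Full per-site analysis for every site in the observation table."""
    out_dir = Path(out_dir)
    report = RunReport(kind="site", seed=config.seed, version=__version__,
                       params=asdict(config))
    run = _Run(report, out_dir)

    with run.stage("read_inputs"):
        obs, effort, sites = _load_inputs(config)

    per_site = {}
    raw_mats, assignments = {}, {}
    for site in sites:
        with run.stage(f"cluster_zones[{site}]"):
            raw, pooled, mat, dendro, clusters, simprof, assignment = _site_zone_pass(
                config, obs, effort, site
            )
            per_site[site] = (raw, pooled, mat, dendro, clusters, simprof, assignment)
            raw_mats[site] = raw
            assignments[site] = assignment

        with run.stage(f"profiles[{site}]"):
            coeff = effort_norm.sampling_coefficients(effort, site)
            norm = effort_norm.normalize_abundance(raw, coeff)
            totals = effort_norm.abundance_profile(norm)
            profiles = effort_norm.profiles_to_tidy(
                site,
                normalized_abundance=totals,
                relative_abundance_pct=effort_norm.relative_abundance(
                    totals, window=config.window_for(site)
                ),
                richness=effort_norm.richness_profile(raw),
            )
            run.save(f"{site}_profiles.csv", profiles)
            run.save(f"{site}_rarefaction.csv",
                     effort_norm.rarefaction_curve(obs, site=site))

        with run.stage(f"write_cluster_outputs[{site}]"):
            raw.to_csv(out_dir / f"{site}_matrix_raw.csv")
            report.files[f"{site}_matrix_raw.csv"] = _sha256(out_dir / f"{site}_matrix_raw.csv")
            run.save_text(f"{site}_dendrogram.nwk", dendro.to_newick())
            run.save(f"{site}_merge_table.csv", dendro.to_merge_table())
            run.save(
                f"{site}_simprof.csv",
                pd.DataFrame([r.__dict__ for r in simprof]),
            )
            run.save(
                f"{site}_clusters.csv",
                pd.DataFrame(
                    [
                        {"cluster": i + 1, "sample": s}
                        for i, cl in enumerate(clusters.clusters)
                        for s in cl
                    ]
                ),
            )
            run.save(f"{site}_zones.csv", assignment.to_frame())
            run.save(
                f"{site}_breaks.csv",
                pd.DataFrame({"site": site, "break_depth_m": cz.depth_breaks(assignment)}),
            )

        with run.stage(f"permanova[{site}]"):
            mat = per_site[site][2]
            dm = dissim.distance_matrix(mat)
            zones = _zone_factor(mat, assignments[site])
            if len(set(zones)) > 1:
                table = groupstats.permanova(
                    dm, {"depth_zone": zones},
                    n_perm=config.permanova_permutations, seed=config.seed,
                )
                run.save(f"{site}_permanova.csv", table)
            else:
                report.warnings.append(f"permanova[{site}]: single zone, test skipped")

        with run.stage(f"simper[{site}]"):
            mat = per_site[site][2]
            zones = _zone_factor(mat, assignments[site])
            zone_seq = assignments[site].zone_order
            frames = []
            for za, zb in zip(zone_seq, zone_seq[1:]):
                rows = [i for i, z in enumerate(zones) if z in (za, zb)]
                if not rows or len({zones[i] for i in rows}) < 2:
                    continue
                sub = mat.data.iloc[rows]
                sub_m = obsdata.AbundanceMatrix(
                    data=sub, sample_meta=mat.sample_meta.iloc[rows],
                    transforms=list(mat.transforms),
                )
                res = groupstats.simper(
                    sub_m, [zones[i] for i in rows],
                    n_perm=config.simper_permutations, seed=config.seed,
                )
                res.insert(0, "zone_pair", f"{za}|{zb}")
                res.insert(0, "site", site)
                frames.append(res)
            if frames:
                simper_all = pd.concat(frames, ignore_index=True)
                run.save(f"{site}_simper.csv", simper_all)
                run.save(
                    f"{site}_indicators.csv",
                    groupstats.indicator_species(
                        simper_all,
                        contrib_threshold=config.simper_contrib_threshold,
                        p_threshold=config.simper_p_threshold,
                    ),
                )

    with run.stage("beta_diversity"):
        table = dissim.zone_beta_table(raw_mats, assignments)
        run.save("beta_table.csv", table)
        if len(table):
            run.save("beta_summary.csv", dissim.summarize_beta(table))

    with run.stage("affinity"):
        props = aff.zone_proportions(obs, assignments, bin_width=config.bin_width,
                                     on_unmapped="drop")
        shallow = (
            pd.read_csv(config.shallow_flags_csv).set_index("species")["shallow"]
            if config.shallow_flags_csv
            else None
        )
        fam_cats = (
            aff.family_categories_from_ranges(pd.read_csv(config.family_ranges_csv))
            if config.family_ranges_csv
            else None
        )
        deep_sea = (
            set(pd.read_csv(config.deep_sea_species_csv)["species"])
            if config.deep_sea_species_csv
            else None
        )
        family_of = obs.drop_duplicates("species").set_index("species")["family"]
        table = aff.affinity_table(
            props, shallow_flags=shallow, family_of=family_of,
            family_categories=fam_cats, deep_sea_species=deep_sea,
            threshold=config.specialist_threshold,
        )
        run.save("affinity.csv", table.reset_index())
        counts = aff.specialist_counts(table)
        run.save("specialist_counts.csv",
                 counts.rename_axis("zone").reset_index(name="n_species"))
        report.summary["n_species"] = int(obs["species"].nunique())
        report.summary["n_specialists"] = int(table["specialist_zone"].notna().sum())

    with run.stage("segregation"):
        coeffs = {s: effort_norm.sampling_coefficients(effort, s) for s in sites}
        _, pairs, summary = segregation.segregation_report(
            obs,
            min_species=config.segregation_min_species,
            min_individuals=config.segregation_min_individuals,
            coefficients=coeffs,
        )
        run.save("segregation_pairs.csv", pairs)
        run.save("segregation_summary.csv", summary)

    report.summary["n_sites"] = len(sites)
    report.summary["clusters_per_site"] = {
        s: per_site[s][4].n_clusters for s in sites
    }
    report.summary["breaks_per_site"] = {
        s: cz.depth_breaks(assignments[s]) for s in sites
    }
    report.write(out_dir / "report.json")
    return report


def run_crosssite_analysis(config: PipelineConfig, out_dir) -> RunReport:
    """Ward-linkage SIMPROF and two-way PERMANOVA across all sites."""
    out_dir = Path(out_dir)
    report = RunReport(kind="crosssite", seed=config.seed, version=__version__,
                       params=asdict(config))
    run = _Run(report, out_dir)

    with run.stage("read_inputs"):
        obs, effort, sites = _load_inputs(config)
        if len(sites) < 2:
            raise ValidationError("cross-site analysis needs at least 2 sites")

    mats, raw_mats, assignments = [], {}, {}
    for site in sites:
        with run.stage(f"site_zones[{site}]"):
            raw, pooled, mat, *_, assignment = _site_zone_pass(config, obs, effort, site)
            mats.append(mat)
            raw_mats[site] = raw
            assignments[site] = assignment

    with run.stage("crosssite_simprof"):
        combined = obsdata.combine_matrices(mats)
        dendro, clusters, simprof = cz.crosssite_cluster(
            combined, linkage=config.crosssite_linkage, alpha=config.crosssite_alpha,
            n_perm_expected=config.n_perm_expected, n_perm_null=config.n_perm_null,
            seed=config.seed,
        )
        run.save_text("crosssite_dendrogram.nwk", dendro.to_newick())
        run.save("crosssite_merge_table.csv", dendro.to_merge_table())
        run.save("crosssite_simprof.csv", pd.DataFrame([r.__dict__ for r in simprof]))
        run.save(
            "crosssite_clusters.csv",
            pd.DataFrame(
                [
                    {"cluster": i + 1, "sample": s}
                    for i, cl in enumerate(clusters.clusters)
                    for s in cl
                ]
            ),
        )
        report.summary["n_crosssite_clusters"] = clusters.n_clusters

    with run.stage("two_way_permanova"):
        dm = dissim.distance_matrix(combined)
        zones = [
            assignments[meta["site"]].zone_of(meta["bins"][0])
            for _, meta in combined.sample_meta.iterrows()
        ]
        site_factor = list(combined.sample_meta["site"])
        table = groupstats.permanova(
            dm, {"depth_zone": zones, "site": site_factor}, interaction=True,
            n_perm=config.permanova_permutations, seed=config.seed,
        )
        run.save("crosssite_permanova.csv", table)

    with run.stage("crosssite_beta"):
        run.save("crosssite_beta.csv", dissim.crosssite_beta(raw_mats, assignments))

    report.write(out_dir / "report.json")
    return report
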