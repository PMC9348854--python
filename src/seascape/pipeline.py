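"""End-to-end pipeline orchestration with a single validated config.

Stages: synthetic seascape -> transport -> communities/reads/environment
-> beta-diversity -> provinces -> PCoA-RGB colors -> cumulative
correlations -> turnover fit, per organismal size fraction, with a
global seed deriving deterministic per-stage seeds and a JSON run
manifest recording output hashes.

Full-scale parameter defaults follow the published analysis scale
(k = 31, entropy threshold 1.5, 100 million reads per sample, 1000
bootstrap replications, 1000 Mantel permutations, 200 km capture radius,
1000 trajectories of 10,000 years, significance threshold p < 0.01,
turnover window 1.5 years); :func:`PipelineConfig.toy_profile` returns
the scaled-down profile used for the synthetic seascape.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import beta as beta_mod
from . import synth as synth_mod
from . import transport as transport_mod
from .matrices import DissimilarityMatrix, write_square_tsv
from .ordination import pcoa, rgb_from_ordination
from .provinces import bootstrap_support, cut_provinces, kruskal_wallis_screen, upgma
from .stats import (
    cumulative_correlation,
    env_distance,
    mantel,
    partial_spearman,
    spearman,
    turnover_fit_from_matrices,
)
from . import io as io_mod

__version__ = "0.1.0"

log = logging.getLogger("seascape")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SynthConfig(_Strict):
    grid_rows: int = Field(64, ge=16)
    grid_cols: int = Field(128, ge=16)
    n_months: int = 24
    seasonal_amplitude: float = Field(0.3, ge=0)
    n_stations: int = Field(20, ge=6)
    n_taxa: int = Field(2000, ge=10)
    genome_length: int = Field(2000, ge=200)
    reads_per_sample: int = Field(20_000, ge=1000)
    read_length: int = Field(100, ge=30)
    error_rate: float = Field(0.01, ge=0, lt=0.1)

    @field_validator("n_months")
    @classmethod
    def _months(cls, v: int) -> int:
        if v < 12 or v % 12:
            raise ValueError("n_months must be a positive multiple of 12")
        return v


class FractionConfig(_Strict):
    """One organismal size fraction: its designed turnover structure."""

    name: str = "fraction_a"
    tau_true: float = Field(1.0, gt=0)
    basin_pool_divergence: float = Field(1.0, ge=0)


class BetaConfig(_Strict):
    metric: str = "kmer"  # kmer | jaccard | bray_curtis
    k: int = 31
    entropy_threshold: float = Field(1.5, ge=0, le=2)
    n_reads: int = Field(100_000_000, ge=1)

    @field_validator("k")
    @classmethod
    def _odd_k(cls, v: int) -> int:
        if not (3 <= v <= 31) or v % 2 == 0:
            raise ValueError("k must be odd and in [3, 31]")
        return v

    @field_validator("metric")
    @classmethod
    def _metric(cls, v: str) -> str:
        if v not in ("kmer", "jaccard", "bray_curtis"):
            raise ValueError("metric must be kmer, jaccard, or bray_curtis")
        return v


class ProvincesConfig(_Strict):
    n_boot: int = Field(1000, ge=100)
    min_support: float = Field(0.5, ge=0, le=1)
    k_max: int = Field(15, ge=2)
    kw_alpha: float = Field(1e-5, gt=0, lt=1)


class TransportConfig(_Strict):
    radius_cells: float = Field(11.0, gt=0)  # ~200 km at 18 km grid scale
    n_trajectories: int = Field(1000, ge=1)
    n_years: int = Field(10_000, ge=1)
    diffusivity: float = Field(100.0, ge=0)  # m^2/s
    dt_per_month: int = Field(600, ge=10)
    min_connections: int = Field(1000, ge=0)


class CorrelateConfig(_Strict):
    n_perm: int = Field(1000, ge=99)
    n_boot_ci: int = Field(0, ge=0)
    threshold_step: float = Field(1 / 12, gt=0)
    threshold_max: float = Field(5.0, gt=0)
    min_pairs: int = Field(10, ge=3)
    alpha: float = Field(0.01, gt=0, lt=1)


class TurnoverConfig(_Strict):
    t_max: float = Field(1.5, gt=0)


class FilterConfig(_Strict):
    surface_only: bool = True
    coastal_ids: list[str] = Field(default_factory=list)
    southern_ocean_ids: list[str] = Field(default_factory=list)


class StagesConfig(_Strict):
    synth: bool = True
    beta: bool = True
    provinces: bool = True
    colors: bool = True
    transport: bool = True
    correlate: bool = True
    turnover: bool = True


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "seascape_out"
    stages: StagesConfig = Field(default_factory=StagesConfig)
    synth: SynthConfig = Field(default_factory=SynthConfig)
    fractions: list[FractionConfig] = Field(
        default_factory=lambda: [FractionConfig()]
    )
    beta: BetaConfig = Field(default_factory=BetaConfig)
    provinces: ProvincesConfig = Field(default_factory=ProvincesConfig)
    transport: TransportConfig = Field(default_factory=TransportConfig)
    correlate: CorrelateConfig = Field(default_factory=CorrelateConfig)
    turnover: TurnoverConfig = Field(default_factory=TurnoverConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)

    @classmethod
    def toy_profile(cls, **overrides) -> "PipelineConfig":
        """Desk-scale profile: full pipeline in minutes on one CPU."""
        cfg = cls(
            beta={"k": 15, "n_reads": 20_000},
            provinces={"n_boot": 200},
            transport={
                "radius_cells": 2.0,
                "n_trajectories": 100,
                "n_years": 20,
                "min_connections": 5,
            },
            correlate={"n_perm": 199, "threshold_max": 4.0},
        )
        return cfg.model_copy(update=overrides) if overrides else cfg


def _suggest(bad_key: str, model: type[BaseModel]) -> str:
    options = list(model.model_fields)
    close = [o for o in options if bad_key.startswith(o) or o.startswith(bad_key)]
    if not close:
        close = difflib.get_close_matches(bad_key, options, n=1, cutoff=0.5)
    return f"; did you mean {close[0]!r}?" if close else ""


def validate_config(path) -> PipelineConfig:
    """Load, default, and range-check a YAML pipeline config.

    Unknown keys are rejected (with a spelling suggestion where one is
    close); an empty file yields all defaults.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    try:
        return PipelineConfig(**data)
    except ValidationError as e:
        msgs = []
        for err in e.errors():
            loc = ".".join(str(p) for p in err["loc"])
            msg = err["msg"]
            if err["type"] == "extra_forbidden":
                sub: type[BaseModel] = PipelineConfig
                for p in err["loc"][:-1]:
                    ann = sub.model_fields[str(p)].annotation
                    if isinstance(ann, type) and issubclass(ann, BaseModel):
                        sub = ann
                msg = f"unknown key{_suggest(str(err['loc'][-1]), sub)}"
            msgs.append(f"{loc}: {msg}")
        raise ValueError("invalid config: " + "; ".join(msgs)) from e


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class RunManifest:
    """Per-stage record of outputs, parameters, seeds, and timings."""

    seed: int
    version: str = __version__
    stages: dict = dc_field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], params: dict, seed: int, wall: float):
        self.stages[stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "params": params,
            "seed": seed,
            "wall_clock_s": round(wall, 3),
            "version": self.version,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "version": self.version, "stages": self.stages}, fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def apply_station_filters(
    stations: pd.DataFrame, filters: FilterConfig
) -> pd.DataFrame:
    """Drop DCM, coastal, and Southern Ocean stations, logging each rule."""
    keep = pd.Series(True, index=stations.index)
    if filters.surface_only:
        dropped = stations.loc[stations["depth_layer"] != "surface", "station_id"]
        for sid in dropped:
            log.info("excluding %s: not a surface sample", sid)
        keep &= stations["depth_layer"] == "surface"
    for rule, ids in (
        ("coastal", filters.coastal_ids),
        ("southern_ocean", filters.southern_ocean_ids),
    ):
        if ids:
            hit = stations["station_id"].isin(ids)
            for sid in stations.loc[hit, "station_id"]:
                log.info("excluding %s: %s list", sid, rule)
            keep &= ~hit
    return stations[keep].reset_index(drop=True)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    sc = config.synth

    # --- synth: velocity field and stations -------------------------------
    t0 = time.time()
    s_seed = stage_seed(config.seed, "synth")
    field = synth_mod.make_velocity_field(
        sc.grid_rows, sc.grid_cols, sc.n_months, sc.seasonal_amplitude, seed=s_seed
    )
    stations = synth_mod.place_stations(field, sc.n_stations, seed=s_seed)
    stations = apply_station_filters(stations, config.filters)
    field_path = out / "field.nc"
    field.to_netcdf(field_path)
    stations_path = out / "stations.tsv"
    io_mod.write_stations(stations, stations_path)
    synth_outputs = [field_path, stations_path]

    # --- transport --------------------------------------------------------
    tc = config.transport
    t_seed = stage_seed(config.seed, "transport")
    t_start = time.time()
    log.info("transport: precomputing %d monthly tables", field.n_months)
    tables = transport_mod.precompute_monthly_tables(
        field, dt=field.month_length / tc.dt_per_month, K=tc.diffusivity, seed=t_seed
    )
    ensembles = transport_mod.stitch_all_stations(
        tables,
        field,
        stations,
        radius_cells=tc.radius_cells,
        n_trajectories=tc.n_trajectories,
        n_years=tc.n_years,
        seed=t_seed,
    )
    tmin = transport_mod.tmin_matrix(ensembles, stations, tc.min_connections)
    tsym = tmin.symmetrized()
    geo = transport_mod.overwater_distance(
        stations, field.landmask, field.dx / 1000.0, field.dy / 1000.0
    )
    tmin_path = out / "tmin_directed.tsv"
    write_square_tsv(tmin_path, tmin.ids, tmin.tmin)
    tsym_path = out / "tmin_symmetrized.tsv"
    write_square_tsv(tsym_path, tmin.ids, tsym)
    geo_path = out / "geo_distance_km.tsv"
    write_square_tsv(geo_path, geo.ids, geo.values_km)
    if config.stages.transport:
        manifest.record(
            "transport",
            [tmin_path, tsym_path, geo_path],
            tc.model_dump(),
            t_seed,
            time.time() - t_start,
        )

    # --- per-fraction: communities, env, reads, beta, ... -----------------
    env = synth_mod.emit_env(stations, field, seed=stage_seed(config.seed, "env"))
    env_path = out / "environment.tsv"
    env.to_csv(env_path, sep="\t", index=False)
    env_station = synth_mod.env_at_sampling(env, stations)
    synth_outputs.append(env_path)

    for fr in config.fractions:
        fr_dir = out / fr.name
        fr_dir.mkdir(exist_ok=True)
        fr_seed = stage_seed(config.seed, f"communities:{fr.name}")
        communities = synth_mod.simulate_communities(
            stations,
            tsym,
            tau_true=fr.tau_true,
            n_taxa=sc.n_taxa,
            basin_pool_divergence=fr.basin_pool_divergence,
            seed=fr_seed,
        )
        comm_path = fr_dir / "communities.tsv"
        communities.presence.to_csv(comm_path, sep="\t")
        truth_path = fr_dir / "truth.json"
        io_mod.write_truth(
            truth_path,
            tau_true=fr.tau_true,
            basin_pool_divergence=fr.basin_pool_divergence,
            basins=communities.basins.to_dict(),
        )
        synth_outputs += [comm_path, truth_path]

        # --- beta ---------------------------------------------------------
        b_start = time.time()
        bc = config.beta
        b_seed = stage_seed(config.seed, f"beta:{fr.name}")
        if bc.metric == "kmer":
            genomes = synth_mod.make_genomes(sc.n_taxa, sc.genome_length, seed=b_seed)
            readsets = synth_mod.emit_reads(
                communities,
                genomes,
                reads_per_sample=sc.reads_per_sample,
                read_length=sc.read_length,
                error_rate=sc.error_rate,
                seed=b_seed,
            )
            reads_dir = fr_dir / "reads"
            reads_dir.mkdir(exist_ok=True)
            profiles = []
            for sid, rs in readsets.items():
                io_mod.write_fastq(rs, reads_dir / f"{sid}.fastq.gz")
                rs = beta_mod.filter_low_complexity(rs, bc.entropy_threshold)
                rs = beta_mod.subsample_prefix(rs, bc.n_reads)
                profiles.append(beta_mod.build_kmer_profile(rs, k=bc.k))
            D = beta_mod.kmer_dissimilarity(profiles)
            feature_table = beta_mod.kmer_feature_table(profiles, seed=b_seed)
        elif bc.metric == "jaccard":
            D = beta_mod.jaccard_dissimilarity(communities.presence)
            feature_table = communities.presence
        else:
            D = beta_mod.bray_curtis_dissimilarity(communities.abundance)
            feature_table = communities.presence
        D_path = fr_dir / f"beta_{bc.metric}.tsv"
        D.to_tsv(D_path)
        if config.stages.beta:
            manifest.record(
                f"beta:{fr.name}", [D_path], bc.model_dump(), b_seed, time.time() - b_start
            )

        # --- provinces ------------------------------------------------------
        if config.stages.provinces:
            p_start = time.time()
            pc = config.provinces
            p_seed = stage_seed(config.seed, f"provinces:{fr.name}")
            tree = upgma(D)
            tree = bootstrap_support(
                tree, feature_table, n_boot=pc.n_boot, seed=p_seed,
                metric="jaccard",
            )
            part = cut_provinces(
                tree, D, min_support=pc.min_support, k_max=min(pc.k_max, D.n - 1)
            )
            part_path = fr_dir / "provinces.tsv"
            pd.DataFrame(
                {"province": part.labels, "silhouette": part.silhouette}
            ).to_csv(part_path, sep="\t", index_label="station_id")
            nwk_path = fr_dir / "dendrogram.nwk"
            nwk_path.write_text(tree.to_newick() + "\n")
            kw_path = fr_dir / "kruskal_wallis.tsv"
            try:
                kw = kruskal_wallis_screen(
                    env_station.drop(columns=["station_id"], errors="ignore"),
                    part,
                    alpha=pc.kw_alpha,
                )
                pd.DataFrame([vars(r) for r in kw]).to_csv(kw_path, sep="\t", index=False)
            except ValueError as e:
                log.warning("provinces:%s KW screen skipped: %s", fr.name, e)
                kw_path.write_text("parameter\th_statistic\tdf\tp_value\tsignificant\n")
            manifest.record(
                f"provinces:{fr.name}",
                [part_path, nwk_path, kw_path],
                pc.model_dump(),
                p_seed,
                time.time() - p_start,
            )

        # --- colors ---------------------------------------------------------
        if config.stages.colors:
            c_start = time.time()
            ordn = pcoa(D)
            colors = rgb_from_ordination(ordn, use_eigenvalue_ratios=True)
            colors_path = fr_dir / "colors.tsv"
            colors.to_csv(colors_path, sep="\t", index_label="station_id")
            manifest.record(
                f"colors:{fr.name}", [colors_path], {}, 0, time.time() - c_start
            )

        # --- correlations ----------------------------------------------------
        if config.stages.correlate:
            cc = config.correlate
            co_start = time.time()
            co_seed = stage_seed(config.seed, f"correlate:{fr.name}")
            thresholds = np.arange(
                cc.threshold_step, cc.threshold_max + 1e-9, cc.threshold_step
            )
            curve = cumulative_correlation(
                D,
                tsym,
                thresholds,
                min_pairs=cc.min_pairs,
                n_perm=0,
                n_boot=cc.n_boot_ci,
                seed=co_seed,
            )
            curve_path = fr_dir / "cumulative_correlation.tsv"
            curve.to_frame().to_csv(curve_path, sep="\t", index=False)

            rho_global, p_global = mantel(D, tsym, n_perm=cc.n_perm, seed=co_seed)
            temp_d = env_distance(env_station, ["temperature"])
            nutrient_d = env_distance(env_station, ["no3_no2", "po4", "fe"])
            summary = {
                "rho_beta_tmin": rho_global,
                "mantel_p": p_global,
                "significant": bool(p_global < cc.alpha),
                "rho_beta_tmin_partial_temperature": partial_spearman(
                    D, tsym, temp_d.values
                ),
                "rho_beta_tmin_partial_nutrients": partial_spearman(
                    D, tsym, nutrient_d.values
                ),
                "rho_beta_temperature": spearman(D, temp_d.values),
                "rho_beta_nutrients": spearman(D, nutrient_d.values),
            }
            summary_path = fr_dir / "correlation_summary.json"
            with open(summary_path, "w") as fh:
                json.dump(summary, fh, indent=2)
            manifest.record(
                f"correlate:{fr.name}",
                [curve_path, summary_path],
                cc.model_dump(),
                co_seed,
                time.time() - co_start,
            )

        # --- turnover --------------------------------------------------------
        if config.stages.turnover:
            tu_start = time.time()
            fit = turnover_fit_from_matrices(D, tsym, t_max=config.turnover.t_max)
            fit_path = fr_dir / "turnover_fit.json"
            with open(fit_path, "w") as fh:
                json.dump(vars(fit), fh, indent=2)
            manifest.record(
                f"turnover:{fr.name}",
                [fit_path],
                config.turnover.model_dump(),
                0,
                time.time() - tu_start,
            )

    if config.stages.synth:
        manifest.record(
            "synth", synth_outputs, sc.model_dump(), s_seed, time.time() - t0
        )
    manifest.write(out / "manifest.json")
    return manifest
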