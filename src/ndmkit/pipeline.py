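"""End-to-end pipeline: simulate (or load) -> directionality -> atrophy ->
seed search -> permutation nulls, with a JSON run manifest.

The manifest echoes the full configuration, library versions and RNG seeds,
so a run can be reproduced exactly from the manifest alone.  All artifacts
are plain CSV/JSON.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas
from .atrophy import AtrophyVector, compute_atrophy
from .connectome import (Connectome, laplacian_directional,
                         laplacian_nondirectional, remove_regions)
from .directionality import (HomologMap, aggregate_to_human, anterograde_ratio,
                             apply_direction, export_ratio, projection_density)
from .evaluation import curves_to_long_frame, repeated_seeding
from .ndm import DiffusionParams
from .nulls import NULL_KINDS, empirical_pvalue, null_distribution
from .synthetic import (SyntheticSpec, gen_atlas, gen_cohort_volumes,
                        gen_connectome, gen_tracer_connectome)

log = logging.getLogger("ndmkit")

KINDS = ("nondirectional", "anterograde", "retrograde")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one data source: a synthetic spec (default) or explicit input
    paths (``connectome_csv`` + ``volumes_csv`` + ``atlas_csv``, optionally
    ``ratio_csv`` for directional kinds).
    """

    synthetic: dict = field(default_factory=dict)
    connectome_csv: str | None = None
    volumes_csv: str | None = None
    atlas_csv: str | None = None
    ratio_csv: str | None = None
    remove_labels: list[str] = field(default_factory=list)
    beta: float = 0.15
    t_max: float = 50.0
    n_times: int = 100
    kinds: list[str] = field(default_factory=lambda: list(KINDS))
    true_seed: str | None = None   # synthetic planting seed (pair label member)
    t_true: float = 15.0
    logistic_slope: float = 1.0
    n_permutations: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        paths = [self.connectome_csv, self.volumes_csv, self.atlas_csv]
        have_paths = any(p is not None for p in paths)
        if have_paths and not all(p is not None for p in paths):
            raise ValueError("connectome_csv, volumes_csv and atlas_csv must "
                             "be given together")
        if have_paths and self.synthetic:
            raise ValueError("give either input paths or a synthetic spec, not both")
        bad = set(self.kinds) - set(KINDS)
        if bad:
            raise ValueError(f"unknown laplacian kind(s): {sorted(bad)}")
        needs_ratio = set(self.kinds) & {"anterograde", "retrograde"}
        if have_paths and needs_ratio and self.ratio_csv is None:
            raise ValueError("directional kinds require ratio_csv with file inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def params(self) -> DiffusionParams:
        return DiffusionParams.with_grid(self.beta, self.t_max, self.n_times)


def _load_inputs(config: RunConfig, outdir: Path):
    """Return (atlas, connectome, volumes table, ratio-or-None), generating
    synthetic data when no paths are configured."""
    from .connectome import read_matrix_csv
    from .directionality import RatioTable

    if config.connectome_csv is not None:
        atlas = RegionAtlas.from_csv(config.atlas_csv)
        conn = Connectome.from_csv(config.connectome_csv, atlas=atlas)
        volumes = pd.read_csv(config.volumes_csv)
        ratio = None
        if config.ratio_csv is not None:
            _, r = read_matrix_csv(config.ratio_csv)
            ratio = RatioTable(values=r, defaulted=np.zeros_like(r, dtype=bool))
        return atlas, conn, volumes, ratio

    spec = SyntheticSpec(**{**config.synthetic, "rng_seed":
                            config.synthetic.get("rng_seed", config.rng_seed)})
    atlas = gen_atlas(spec)
    conn = gen_connectome(atlas, spec)
    true_seed = config.true_seed or next(
        lab for lab, lb in zip(atlas.labels, atlas.lobe) if lb == "subcortical")
    cohort = gen_cohort_volumes(atlas, conn, true_seed, config.beta,
                                config.t_true, spec)
    bundle = gen_tracer_connectome(atlas, spec)

    atlas.to_csv(outdir / "atlas.csv")
    conn.to_csv(outdir / "connectome.csv")
    cohort.to_csv(outdir / "volumes.csv")
    bundle.to_csv(outdir / "tracer_matrix.csv", outdir / "tracer_voxels.csv",
                  outdir / "homolog_map.csv")

    density = projection_density(bundle.matrix, bundle.voxels)
    agg = aggregate_to_human(density, bundle.homolog_map, atlas,
                             list(bundle.labels))
    ratio = anterograde_ratio(agg)
    export_ratio(ratio, atlas, outdir / "ratio.csv",
                 outdir / "ratio_defaulted.csv")
    return atlas, conn, cohort.table, ratio


def _laplacian_for(kind: str, conn: Connectome, ratio):
    if kind == "nondirectional":
        return laplacian_nondirectional(conn)
    if ratio is None:
        raise ValueError(f"kind {kind!r} requires a directionality ratio")
    cdir = apply_direction(conn, ratio, mode=kind)
    return laplacian_directional(cdir)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage for each requested Laplacian kind; returns (and
    writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    manifest: dict = {
        "config": _config_dict(config),
        "versions": {"ndmkit": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "outputs": [],
    }

    current = {"stage": "setup"}

    def _stage(name):
        log.info("stage: %s", name)
        current["stage"] = name
        timings[name] = time.time()

    def _done(name):
        timings[name] = round(time.time() - timings[name], 3)

    try:
        _stage("simulate")
        atlas, conn, volumes, ratio = _load_inputs(config, outdir)
        if config.remove_labels:
            conn = remove_regions(conn, config.remove_labels)
            keep = [c for c in volumes.columns if c not in config.remove_labels]
            volumes = volumes[keep]
            atlas = conn.atlas
        _done("simulate")

        _stage("atrophy")
        atrophy = compute_atrophy(volumes, atlas, slope=config.logistic_slope)
        atrophy.to_csv(outdir / "atrophy.csv")
        manifest["outputs"].append("atrophy.csv")
        _done("atrophy")

        params = config.params()
        rankings: dict[str, dict] = {}
        for kind in config.kinds:
            _stage(f"seedsearch[{kind}]")
            H = _laplacian_for(kind, conn, ratio)
            ranking, curves = repeated_seeding(H, atlas, atrophy, params,
                                               return_curves=True)
            ranking.to_csv(outdir / f"ranking_{kind}.csv")
            curves_to_long_frame(curves).to_csv(
                outdir / f"rt_curves_{kind}.csv", index=False)
            manifest["outputs"] += [f"ranking_{kind}.csv", f"rt_curves_{kind}.csv"]
            best = ranking.best
            rankings[kind] = {"best_seed": str(best["seed"]),
                              "r_max": float(best["r_max"]),
                              "t_max": float(best["t_max"]),
                              "n_rows": int(len(ranking.table))}
            _done(f"seedsearch[{kind}]")

            _stage(f"nulls[{kind}]")
            best_member = _pair_member(atlas, str(best["seed"]))
            builder = (laplacian_nondirectional if kind == "nondirectional"
                       else (lambda c, k=kind: _laplacian_for(k, c, ratio)))
            pvals = {}
            for null_kind in NULL_KINDS:
                nd = null_distribution(conn, atrophy, best_member, params,
                                       kind=null_kind,
                                       n_permutations=config.n_permutations,
                                       rng_seed=config.rng_seed,
                                       laplacian_builder=builder)
                stem = f"null_{kind}_{null_kind}"
                nd.to_csv(outdir / f"{stem}.csv", outdir / f"{stem}.json")
                manifest["outputs"] += [f"{stem}.csv", f"{stem}.json"]
                pvals[null_kind] = empirical_pvalue(nd)
            rankings[kind]["p_values"] = pvals
            _done(f"nulls[{kind}]")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {current['stage']!r}: {exc}") from exc

    manifest["results"] = rankings
    manifest["timings_s"] = timings
    manifest["total_s"] = round(time.time() - t_start, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["outputs"].append("manifest.json")
    return manifest


def _pair_member(atlas: RegionAtlas, pair_label: str) -> str:
    """A region label belonging to the named bilateral pair."""
    for pid, li, _ in atlas.pairs():
        if atlas.pair_label(pid) == pair_label:
            return atlas.labels[li]
    raise KeyError(f"no bilateral pair named {pair_label!r}")


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
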