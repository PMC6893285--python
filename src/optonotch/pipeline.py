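"""Configuration, orchestration and reporting for the full analysis demo.

``run_pipeline`` executes the requested stages in dependency order on
synthetic inputs generated from the configured parameters, writing CSV
tables, a JSON summary and plots into the output directory.  One top-level
seed governs every stochastic stage through spawned NumPy seed sequences,
so a rerun with the same config and seed is byte-identical.

Stages and their outputs:

``synth``     spot movie TIFF + onset_times.csv (ground truth)
``spots``     spots.csv (detected spots)
``kinetics``  curves.csv + fits.csv (+ activation plot)
``clusters``  clusters.csv + half-time fit (+ index plot)
``membrane``  interfaces.csv, bands.csv, coloc.csv
``clones``    tallies.csv + summary statistics

Every output row is traceable to an embryo/condition id, and the summary
JSON records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonescore, clusterquant, kinetics, memquant, spotcall, synthgen
from .stack import write_stack

logger = logging.getLogger("optonotch")

ALL_STAGES = ("synth", "spots", "kinetics", "clusters", "membrane", "clones")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "optonotch_out"
    seed: int = 0
    spot_movie: synthgen.SpotMovieParams = field(default_factory=synthgen.SpotMovieParams)
    spotcall: spotcall.SpotCallConfig = field(
        default_factory=lambda: spotcall.SpotCallConfig(min_intensity=3000.0)
    )
    cluster_movie: synthgen.ClusterMovieParams = field(default_factory=synthgen.ClusterMovieParams)
    cluster_seg: clusterquant.ClusterConfig = field(default_factory=clusterquant.ClusterConfig)
    interface_image: synthgen.InterfaceImageParams = field(default_factory=synthgen.InterfaceImageParams)
    vesicle_field: synthgen.VesicleFieldParams = field(default_factory=synthgen.VesicleFieldParams)
    clone_tissue: synthgen.CloneTissueParams = field(default_factory=synthgen.CloneTissueParams)
    n_clone_pupae: int = 5
    band_um: float = 0.3
    alignment_time_min: float = 55.0
    write_tiffs: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {}
        sections = {
            "spot_movie": synthgen.SpotMovieParams,
            "spotcall": spotcall.SpotCallConfig,
            "cluster_movie": synthgen.ClusterMovieParams,
            "cluster_seg": clusterquant.ClusterConfig,
            "interface_image": synthgen.InterfaceImageParams,
            "vesicle_field": synthgen.VesicleFieldParams,
            "clone_tissue": synthgen.CloneTissueParams,
        }
        for key, value in raw.items():
            if key in sections:
                kwargs[key] = sections[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        # identifies the analysis parameters; where the output lands is
        # deliberately not part of the hash
        payload = _as_jsonable(self)
        payload.pop("out_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


def _sub_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages in dependency order; return the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    if "spots" in stages and "synth" not in stages:
        logger.warning("stage 'spots' needs 'synth'; skipping dependents")
        stages = [s for s in stages if s not in ("spots", "kinetics")]
    if "kinetics" in stages and "spots" not in stages:
        logger.warning("stage 'kinetics' needs 'spots'; skipping it")
        stages = [s for s in stages if s != "kinetics"]

    movie = truth = None
    if "synth" in stages:
        params = dataclasses.replace(config.spot_movie, seed=_sub_seed(config.seed, "spot_movie"))
        movie, truth = synthgen.gen_spot_movie(params)
        truth.onset_table().to_csv(out / "onset_times.csv", index=False)
        if config.write_tiffs:
            write_stack(out / "spot_movie.tif", movie)
        results["synth"] = {
            "n_nuclei": params.n_nuclei,
            "n_frames": movie.n_frames,
            "n_on_by_end": truth.n_on(params.movie_end),
        }

    spots = None
    if "spots" in stages:
        spots = spotcall.detect_spots(movie, config.spotcall)
        df = spots.table.copy()
        df.insert(0, "embryo_id", "synthetic-0")
        df.insert(1, "config_hash", results["config_hash"])
        df.to_csv(out / "spots.csv", index=False)
        results["spots"] = {"n_spots": spots.n_spots}

    if "kinetics" in stages:
        curve = kinetics.build_activation_curve(
            spots,
            region_length_um=config.spot_movie.region_length_um,
            alignment_time=config.alignment_time_min,
            embryo_id="synthetic-0",
            condition="control",
        )
        fit = kinetics.fit_activation(curve, n_max=config.spot_movie.n_nuclei)
        pd.DataFrame(
            {
                "embryo_id": "synthetic-0",
                "condition": "control",
                "time_min": curve.times,
                "count": curve.counts,
                "density_per_um": curve.density,
            }
        ).to_csv(out / "curves.csv", index=False)
        pd.DataFrame(
            [
                {
                    "embryo_id": "synthetic-0",
                    "condition": "control",
                    "config_hash": results["config_hash"],
                    "n_max": fit.n_max,
                    "k_per_min": fit.k,
                    "t0_min": fit.t0,
                    "rss": fit.rss,
                    "converged": fit.converged,
                }
            ]
        ).to_csv(out / "fits.csv", index=False)
        _plot_activation(out / "activation.png", curve, fit)
        results["kinetics"] = {
            "k_per_min": fit.k, "t0_min": fit.t0, "converged": fit.converged,
            "true_k": config.spot_movie.onset_rate_k,
            "true_t0": config.spot_movie.onset_delay_t0 - config.alignment_time_min,
        }

    if "clusters" in stages:
        params = dataclasses.replace(config.cluster_movie, seed=_sub_seed(config.seed, "cluster_movie"))
        cmovie, ctruth = synthgen.gen_cluster_movie(params)
        series = clusterquant.build_cluster_series(cmovie, config.cluster_seg)
        half = clusterquant.estimate_half_time(series)
        df = series.to_frame()
        df.insert(0, "embryo_id", "synthetic-cluster-0")
        df.to_csv(out / "clusters.csv", index=False)
        _plot_clusters(out / "clustering_index.png", series, half)
        results["clusters"] = {
            "t_half_s": half.t_half_s,
            "true_t_half_s": params.half_time_s,
            "plateau": half.plateau,
        }

    if "membrane" in stages:
        results["membrane"] = _run_membrane(config, out, results["config_hash"])

    if "clones" in stages:
        results["clones"] = _run_clones(config, out)

    with open(out / "summary.json", "w") as fh:
        json.dump(_as_jsonable(results), fh, indent=2, sort_keys=True)
    return results


def _run_membrane(config: RunConfig, out: Path, config_hash: str) -> dict:
    params = dataclasses.replace(config.interface_image, seed=_sub_seed(config.seed, "interface"))
    istack, labels, itruth = synthgen.gen_interface_image(params)
    img = istack.frame(0)
    bands = memquant.membrane_band_quant(
        img, labels["cells"], pixel_size_um=params.pixel_size_um,
        band_um=config.band_um, region_labels=labels["regions"],
    )
    bands.insert(0, "embryo_id", "synthetic-interface-0")
    bands.insert(1, "config_hash", config_hash)
    bands.to_csv(out / "bands.csv", index=False)

    # one horizontal profile per cell row, crossing a vertical interface
    ms = []
    cell = params.cell_size_px
    for j in range(params.n_cells_y):
        y = j * cell + cell // 2
        for i in range(1, params.n_cells_x):
            x = i * cell
            region = "ectoderm" if i < params.n_cells_x // 2 else "mesoderm"
            ms.append(
                memquant.measure_interface(
                    img, (x - cell // 2, y), (x + cell // 2, y),
                    pixel_size_um=params.pixel_size_um,
                    line_id=f"r{j}c{i}", region=region,
                    embryo_id="synthetic-interface-0",
                )
            )
    memquant.normalize_to_reference(ms, "ectoderm")
    pd.DataFrame(
        [
            {
                "embryo_id": m.embryo_id,
                "line_id": m.line_id,
                "region": m.region,
                "peak_position_um": m.peak_position_um,
                "integrated_intensity": m.integrated_intensity,
                "normalized_intensity": m.normalized_intensity,
                "flagged": m.flagged,
            }
            for m in ms
        ]
    ).to_csv(out / "interfaces.csv", index=False)

    vparams = dataclasses.replace(config.vesicle_field, seed=_sub_seed(config.seed, "vesicles"))
    va, vb, vtruth = synthgen.gen_vesicle_field(vparams)
    coloc = memquant.coloc_percent(va, vb, config.spotcall)
    pd.DataFrame(
        [
            {
                "embryo_id": "synthetic-vesicles-0",
                "n_a": coloc.n_a,
                "n_b": coloc.n_b,
                "n_a_overlapping_b": coloc.n_a_overlapping_b,
                "percent_coloc": coloc.percent_coloc,
                "true_percent": vtruth.realized_overlap_percent,
            }
        ]
    ).to_csv(out / "coloc.csv", index=False)

    meso = bands.loc[(bands["region"] == "mesoderm") & ~bands["flagged"], "membrane_band_mean"].mean()
    ecto = bands.loc[(bands["region"] == "ectoderm") & ~bands["flagged"], "membrane_band_mean"].mean()
    return {
        "mesoderm_to_ectoderm_membrane_ratio": float(meso / ecto),
        "true_depletion_factor": params.depletion_factor,
        "coloc_percent": coloc.percent_coloc,
        "coloc_true_percent": vtruth.realized_overlap_percent,
    }


def _run_clones(config: RunConfig, out: Path) -> dict:
    tallies = []
    rows = []
    for i in range(config.n_clone_pupae):
        params = dataclasses.replace(
            config.clone_tissue, seed=_sub_seed(config.seed, f"clone{i}")
        )
        mask, sops, truth = synthgen.gen_clone_tissue(params)
        tally = clonescore.score_border_sops(
            mask, sops, border_band_px=params.cluster_radius_px,
            pupa_id=f"pupa-{i}", condition="simulated",
        )
        tallies.append(tally)
        rows.append(
            {
                "pupa_id": tally.pupa_id,
                "condition": tally.condition,
                "n_sop_border": tally.n_sop_border,
                "n_inside": tally.n_inside,
                "percent_inside": tally.percent_inside,
            }
        )
    pd.DataFrame(rows).to_csv(out / "tallies.csv", index=False)
    summary = clonescore.summarize_tallies(tallies)
    row = summary.table.iloc[0]
    return {
        "mean_percent_inside": float(row["mean_percent_inside"]),
        "sd_percent_inside": float(row["sd_percent_inside"]),
        "p_binomial_vs_half": float(row["p_binomial_vs_half"]),
        "true_p_inside": config.clone_tissue.p_inside,
    }


def _plot_activation(path, curve, fit) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.times, curve.density, "o", ms=3, label="spot density")
    if np.isfinite(fit.k):
        tt = np.linspace(curve.times[0], curve.times[-1], 300)
        ax.plot(tt, fit.predict(tt), "-", label=f"fit: k={fit.k:.3g}/min, t0={fit.t0:.3g} min")
    ax.set_xlabel("time (min, ventral furrow = 0)")
    ax.set_ylabel("spots per um")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_clusters(path, series, half) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(series.times_s, series.index, ".", ms=2, label="clustering index")
    if np.isfinite(half.t_half_s):
        tt = np.linspace(0, series.times_s[-1], 300)
        ax.plot(tt, half.predict(tt), "-", label=f"fit: t1/2 = {half.t_half_s:.3g} s")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("clustering index")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
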