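"""End-to-end analysis orchestration.

``analyze_experiment`` is the in-memory core: given trials + landmarks it
runs detection, morphing, heatmaps and statistics and returns result
tables.  ``run_pipeline`` wraps it with file I/O, a validated config, stage
logging and a reproducibility manifest; ``render_report`` turns the result
tables into summary figures.

Stage order follows the analysis dependencies: trial inclusion ->
saccade detection -> morphing/heatmaps -> statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

import gazemorph
from gazemorph.heatmaps import (
    Heatmap,
    average_heatmaps,
    build_fixation_heatmap,
    heatmap_from_points,
    resample_for_analysis,
)
from gazemorph.io import Trial, filter_trials, read_landmarks, read_trials, write_landmarks, write_trials
from gazemorph.kinematics import (
    SaccadeDetector,
    compare_main_sequences,
    fit_main_sequence,
)
from gazemorph.morphing import compute_mean_shape, triangulate, warp_trial_gaze
from gazemorph.stats import (
    baseline_normalize,
    baseline_pattern_variation,
    bh_adjust,
    bootstrap_ci,
    face_detection_metrics,
    ipsi_contra_difference,
    paired_difference_test,
    pattern_change_indices,
    permutation_test,
    two_sample_shift_ci,
)
from gazemorph.synth import Experiment, GeneratorSpec, eye_rois_from_landmarks, generate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "analyze_experiment", "run_pipeline", "render_report"]


class SimulateConfig(BaseModel):
    """Synthetic-experiment knobs exposed to the pipeline config."""

    model_config = ConfigDict(extra="forbid")

    n_images: int = 8
    n_baseline_sessions: int = 14
    trials_per_session: int = 10
    right_eye_baseline_bias_s: float = 1.1
    main_sequence_beta: float = 30.0


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "results"
    # inputs: either simulate, or point at existing tables
    simulate: SimulateConfig | None = None
    traces_path: str | None = None
    meta_path: str | None = None
    landmarks_path: str | None = None
    # inclusion rules
    min_on_image_s: float = 7.0
    max_gap_ms: int = 500
    # saccade detection
    k_on: float = 6.0
    k_off: float = 2.0
    # heatmaps
    sigma_dva: float = 0.25
    exclude_amp_dva: float = 1.0
    display_px_per_deg: int = 20
    analysis_px_per_deg: int = 5
    analysis_sigma_px: float = 2.5
    # ROIs and statistics
    eye_roi_scale: float = 1.6
    n_resamples: int = Field(default=10_000, ge=1)
    normalize_baseline: bool = True
    write_warped: bool = False

    @field_validator("min_on_image_s")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("min_on_image_s must be >= 0")
        return v


def _trial_analysis_heatmap(trial: Trial, saccades, cfg: PipelineConfig) -> Heatmap:
    """Analysis-resolution (5 px/deg) heatmap for one trial, image frame."""
    hm = build_fixation_heatmap(
        trial,
        saccades,
        sigma_dva=cfg.sigma_dva,
        exclude_amp_dva=cfg.exclude_amp_dva,
        px_per_deg=cfg.display_px_per_deg,
    )
    return resample_for_analysis(
        hm, px_per_deg=cfg.analysis_px_per_deg, sigma_px=cfg.analysis_sigma_px
    )


def analyze_experiment(
    exp: Experiment, cfg: PipelineConfig | None = None
) -> dict:
    """Run the full analysis on an in-memory experiment.

    Returns a dict of result tables (DataFrames) and arrays:
    ``looking_times``, ``stat_results``, ``pattern_change``,
    ``main_sequence``, ``face_detection``, ``exclusions``, plus mean-face
    heatmap objects for rendering.
    """
    cfg = cfg or PipelineConfig()
    ss = np.random.SeedSequence(cfg.seed)
    streams = iter(ss.spawn(64))

    def next_rng():
        return np.random.default_rng(next(streams))

    # --- stage: inclusion -------------------------------------------------
    trials, exclusions = filter_trials(exp.trials, cfg.min_on_image_s, cfg.max_gap_ms)
    logger.info("inclusion: kept %d / %d trials", len(trials), len(exp.trials))

    # --- stage: saccade detection ----------------------------------------
    saccades: dict[str, list] = {}
    for tr in trials:
        det = SaccadeDetector(k_on=cfg.k_on, k_off=cfg.k_off)
        det.fit(tr.fixation_samples)
        saccades[tr.trial_id] = det.detect(tr.viewing_samples)

    # --- stage: morphing --------------------------------------------------
    used_ids = sorted({tr.image_id for tr in trials})
    mean_shape = compute_mean_shape([exp.landmarks[i] for i in used_ids])
    mesh = triangulate(mean_shape)
    rois = eye_rois_from_landmarks(mean_shape.points, scale=cfg.eye_roi_scale)

    warped: dict[str, pd.DataFrame] = {}
    for tr in trials:
        warped[tr.trial_id] = warp_trial_gaze(
            tr,
            saccades[tr.trial_id],
            exp.landmarks[tr.image_id],
            mesh,
            mean_shape,
            exclude_amp_dva=cfg.exclude_amp_dva,
        )

    # --- stage: looking times --------------------------------------------
    from gazemorph.stats import roi_dwell_time

    lt_rows = []
    fd_rows = []
    hm_analysis: dict[str, Heatmap] = {}
    for tr in trials:
        w = warped[tr.trial_id]
        t_right = roi_dwell_time(w, rois["right_eye"])
        t_left = roi_dwell_time(w, rois["left_eye"])
        t_total = float(tr.viewing_samples["on_image"].sum()) / 1000.0
        fd = face_detection_metrics(
            tr, saccades[tr.trial_id], exp.landmarks[tr.image_id].face_polygon
        )
        lt_rows.append(
            {
                "trial_id": tr.trial_id,
                "monkey_id": tr.monkey_id,
                "session_id": tr.session_id,
                "session_date": tr.session_date,
                "phase": tr.condition.phase,
                "site": tr.condition.site,
                "hemisphere": tr.condition.hemisphere,
                "volume_ul": tr.condition.volume_ul,
                "condition": tr.condition.label,
                "image_id": tr.image_id,
                "t_right_eye": t_right,
                "t_left_eye": t_left,
                "t_face": fd["frac_time_on_face"] * t_total,
                "t_total": t_total,
                "frac_out_of_mesh": w.attrs.get("frac_out_of_mesh", float("nan")),
            }
        )
        fd_rows.append(
            {
                "trial_id": tr.trial_id,
                "condition": tr.condition.label,
                "phase": tr.condition.phase,
                "found": fd["found"],
                "latency_ms": fd["latency_ms"],
                "frac_time_on_face": fd["frac_time_on_face"],
            }
        )
        hm_analysis[tr.trial_id] = _trial_analysis_heatmap(tr, saccades[tr.trial_id], cfg)
    looking = pd.DataFrame(lt_rows)
    face_det = pd.DataFrame(fd_rows)

    # --- stage: looking-time statistics ----------------------------------
    stat_rows = []
    base = looking[looking["phase"] == "baseline"]
    base_delta_rl = (base["t_right_eye"] - base["t_left_eye"]).to_numpy()
    if len(base_delta_rl) >= 2:
        res = paired_difference_test(base_delta_rl, n_resamples=cfg.n_resamples, seed=next_rng())
        ci = bootstrap_ci(base_delta_rl, n_resamples=cfg.n_resamples, seed=next_rng())
        stat_rows.append(
            {
                "comparison": "baseline_right_minus_left_eye",
                "observed": float(np.mean(base_delta_rl)),
                "p_perm": res.p_perm,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "n": len(base_delta_rl),
            }
        )

    norm_deltas_by_cond: dict[str, np.ndarray] = {}
    inj = looking[looking["phase"] == "injection"]
    for cond_label, g in inj.groupby("condition", sort=True):
        if len(g) < 2:
            continue
        hemisphere = g["hemisphere"].iloc[0]
        sign = 1.0 if hemisphere == "right" else -1.0
        raw = ipsi_contra_difference(g, hemisphere).to_numpy()
        if cfg.normalize_baseline:
            norm = baseline_normalize(g, base)["delta_ipsi_contra_norm"].to_numpy()
            # CI resamples both pools: the subtracted baseline bias is
            # itself estimated from baseline trials
            ci = two_sample_shift_ci(
                raw,
                sign * base_delta_rl,
                n_resamples=cfg.n_resamples,
                seed=next_rng(),
            )
        else:
            norm = raw
            ci = bootstrap_ci(norm, n_resamples=cfg.n_resamples, seed=next_rng())
        norm_deltas_by_cond[cond_label] = norm
        res = paired_difference_test(norm, n_resamples=cfg.n_resamples, seed=next_rng())
        stat_rows.append(
            {
                "comparison": f"{cond_label}_ipsi_minus_contra_eye",
                "observed": float(np.mean(norm)),
                "raw_observed": float(np.mean(raw)),
                "p_perm": res.p_perm,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "n": len(norm),
            }
        )

    # face patch vs control at 10 uL (pooled over hemispheres)
    fp10 = np.concatenate(
        [v for k, v in norm_deltas_by_cond.items() if k.startswith("face_patch_10uL")]
        or [np.empty(0)]
    )
    ct10 = np.concatenate(
        [v for k, v in norm_deltas_by_cond.items() if k.startswith("control_10uL")]
        or [np.empty(0)]
    )
    if len(fp10) >= 2 and len(ct10) >= 2:
        res = permutation_test(fp10, ct10, n_resamples=cfg.n_resamples, seed=next_rng())
        stat_rows.append(
            {
                "comparison": "face_patch_10uL_vs_control_10uL",
                "observed": res.observed,
                "p_perm": res.p_perm,
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "n": len(fp10) + len(ct10),
            }
        )

    stat_results = pd.DataFrame(stat_rows)
    if len(stat_results):
        stat_results["p_adj"] = bh_adjust(stat_results["p_perm"].to_numpy())

    # --- stage: pattern change --------------------------------------------
    base_hms_by_stim: dict[str, list[Heatmap]] = {}
    for _, row in base.iterrows():
        base_hms_by_stim.setdefault(row["image_id"], []).append(hm_analysis[row["trial_id"]])
    pc_rows = []
    for cond_label, g in inj.groupby("condition", sort=True):
        by_stim: dict[str, list[Heatmap]] = {}
        for _, row in g.iterrows():
            by_stim.setdefault(row["image_id"], []).append(hm_analysis[row["trial_id"]])
        idx = pattern_change_indices(by_stim, base_hms_by_stim)
        if len(idx) < 2:
            continue
        ci = bootstrap_ci(idx, n_resamples=cfg.n_resamples, seed=next_rng())
        pc_rows.append(
            {
                "condition": cond_label,
                "mean_index": float(idx.mean()),
                "ci_low": ci[0],
                "ci_high": ci[1],
                "n_trials": len(idx),
            }
        )
    base_var = baseline_pattern_variation(base_hms_by_stim, seed=next_rng())
    if len(base_var):
        pc_rows.append(
            {
                "condition": "baseline_expected_variation",
                "mean_index": float(base_var.mean()),
                "ci_low": float(np.quantile(base_var, 0.025)),
                "ci_high": float(np.quantile(base_var, 0.975)),
                "n_trials": len(base_var),
            }
        )
    pattern_change = pd.DataFrame(pc_rows)

    # --- stage: main sequence ---------------------------------------------
    def _saccades_for(mask) -> list:
        out = []
        for tid in looking[mask]["trial_id"]:
            out.extend(saccades[tid])
        return out

    ms_rows = []
    base_sacc = _saccades_for(looking["phase"] == "baseline")
    groups = {"baseline": base_sacc}
    fp10_mask = (looking["site"] == "face_patch") & (looking["volume_ul"] == 10)
    fp10_sacc = _saccades_for(fp10_mask)
    if len(fp10_sacc) >= 2:
        groups["face_patch_10uL"] = fp10_sacc
    for name, sacc in groups.items():
        if len(sacc) < 2:
            continue
        fit = fit_main_sequence(sacc)
        ms_rows.append(
            {"group": name, "beta": fit.beta, "r_squared": fit.r_squared, "n_saccades": fit.n_saccades}
        )
    main_sequence = pd.DataFrame(ms_rows)
    ms_compare = None
    if len(base_sacc) >= 2 and len(fp10_sacc) >= 2:
        ms_compare = compare_main_sequences(
            base_sacc, fp10_sacc, n_resamples=min(cfg.n_resamples, 2000), seed=next_rng()
        )

    # --- rendering inputs: mean-face average heatmaps ----------------------
    extent = trials[0].image_extent if trials else (28.0, 21.0)
    mean_face_hms: dict[str, Heatmap] = {}
    for label, g in looking.groupby("condition", sort=True):
        hms = []
        for tid in g["trial_id"]:
            w = warped[tid]
            w_in = w[w["in_mesh"]]
            if len(w_in) == 0:
                continue
            hms.append(
                heatmap_from_points(
                    w_in["x_dva"].to_numpy(),
                    w_in["y_dva"].to_numpy(),
                    extent,
                    px_per_deg=cfg.analysis_px_per_deg,
                    sigma_dva=cfg.sigma_dva * 4,
                )
            )
        if hms:
            mean_face_hms[label] = average_heatmaps(hms)

    return {
        "looking_times": looking,
        "stat_results": stat_results,
        "pattern_change": pattern_change,
        "main_sequence": main_sequence,
        "main_sequence_compare": ms_compare,
        "face_detection": face_det,
        "exclusions": pd.DataFrame(exclusions),
        "saccades": saccades,
        "warped": warped,
        "mean_shape": mean_shape,
        "mesh": mesh,
        "rois": rois,
        "mean_face_heatmaps": mean_face_hms,
    }


# ---------------------------------------------------------------------------
# file-level pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


def _experiment_from_config(cfg: PipelineConfig) -> Experiment:
    if cfg.simulate is not None:
        spec = GeneratorSpec(
            seed=cfg.seed,
            n_images=cfg.simulate.n_images,
            n_baseline_sessions=cfg.simulate.n_baseline_sessions,
            trials_per_session=cfg.simulate.trials_per_session,
            right_eye_baseline_bias_s=cfg.simulate.right_eye_baseline_bias_s,
            main_sequence_beta=cfg.simulate.main_sequence_beta,
        )
        return generate_experiment(spec)
    if not (cfg.traces_path and cfg.meta_path and cfg.landmarks_path):
        raise ValueError("config must provide either `simulate` or input table paths")
    trials, flagged = read_trials(cfg.traces_path, cfg.meta_path)
    if flagged:
        logger.warning("flagged trials skipped: %s", flagged)
    landmarks = read_landmarks(cfg.landmarks_path)
    rois = {iid: eye_rois_from_landmarks(lm.points) for iid, lm in landmarks.items()}
    return Experiment(
        trials=trials,
        landmarks=landmarks,
        rois_by_image=rois,
        design=pd.DataFrame(),
        ground_truth={},
        spec=GeneratorSpec(seed=cfg.seed),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the pipeline end to end, writing result tables + manifest.

    Returns the in-memory results dict (see :func:`analyze_experiment`)
    augmented with the manifest.  Stage outputs are written as each stage
    completes, so a failure leaves earlier outputs intact.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    exp = _experiment_from_config(cfg)
    if cfg.simulate is not None:
        write_trials(exp.trials, out / "traces.tsv", out / "meta.tsv")
        write_landmarks(exp.landmarks, out / "landmarks.tsv")
        exp.design.to_csv(out / "design.tsv", sep="\t", index=False)

    results = analyze_experiment(exp, cfg)

    sacc_rows = []
    for tid, evs in results["saccades"].items():
        for ev in evs:
            sacc_rows.append(
                {
                    "trial_id": tid,
                    "onset_ms": ev.onset_ms,
                    "offset_ms": ev.offset_ms,
                    "A_dva": round(ev.amplitude, 4),
                    "PV_dva_s": round(ev.peak_velocity, 3),
                    "x0": round(ev.start_point[0], 4),
                    "y0": round(ev.start_point[1], 4),
                    "x1": round(ev.end_point[0], 4),
                    "y1": round(ev.end_point[1], 4),
                    "direction_rad": round(ev.direction, 5),
                }
            )
    pd.DataFrame(sacc_rows).to_csv(out / "saccades.tsv", sep="\t", index=False)

    results["looking_times"].to_csv(out / "looking_times.tsv", sep="\t", index=False)
    results["stat_results"].to_csv(out / "stat_results.tsv", sep="\t", index=False)
    results["pattern_change"].to_csv(out / "pattern_change.tsv", sep="\t", index=False)
    results["main_sequence"].to_csv(out / "main_sequence.tsv", sep="\t", index=False)
    results["face_detection"].to_csv(out / "face_detection.tsv", sep="\t", index=False)
    results["exclusions"].to_csv(out / "exclusions.tsv", sep="\t", index=False)

    shape_df = pd.DataFrame(results["mean_shape"].points, columns=["x_dva", "y_dva"])
    shape_df.to_csv(out / "mean_shape.tsv", sep="\t", index=False)
    pd.DataFrame(results["mesh"].vertex_indices, columns=["i", "j", "k"]).to_csv(
        out / "mesh.tsv", sep="\t", index=False
    )

    if cfg.write_warped:
        frames = []
        for tid, w in results["warped"].items():
            w = w.copy()
            w.insert(0, "trial_id", tid)
            frames.append(w)
        pd.concat(frames, ignore_index=True).to_csv(out / "warped.tsv", sep="\t", index=False)

    for label, hm in results["mean_face_heatmaps"].items():
        np.savetxt(out / f"heatmap_{label}.txt", hm.grid, fmt="%.6g")
        (out / f"heatmap_{label}.json").write_text(
            json.dumps(
                {
                    "px_per_deg": hm.px_per_deg,
                    "origin": list(hm.origin),
                    "extent": list(hm.extent),
                }
            )
        )

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.suffix in (".tsv", ".txt", ".json"))
    manifest = {
        "package_version": gazemorph.__version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_trials_input": len(exp.trials),
        "n_trials_kept": len(results["looking_times"]),
        "digests": {p.name: _sha256(p) for p in artifacts if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def render_report(results_dir) -> list[Path]:
    """Render summary figures + a text report from a results directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(results_dir)
    needed = ["looking_times.tsv", "stat_results.tsv", "pattern_change.tsv", "main_sequence.tsv"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing result tables: {', '.join(missing)}")
    figures: list[Path] = []
    notes: list[str] = []

    # mean-face heatmap (baseline)
    hm_path = out / "heatmap_baseline.txt"
    if hm_path.exists():
        grid = np.loadtxt(hm_path)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        hdr = json.loads((out / "heatmap_baseline.json").read_text())
        ox, oy = hdr["origin"]
        w, h = hdr["extent"]
        ax.imshow(grid, origin="lower", extent=(ox, ox + w, oy, oy + h), cmap="inferno")
        shape = pd.read_csv(out / "mean_shape.tsv", sep="\t")
        ax.plot(shape["x_dva"], shape["y_dva"], ".", color="cyan", ms=3)
        ax.set_title("Baseline gaze on the mean face")
        fig.savefig(out / "fig_baseline_mean_face.png", dpi=110)
        plt.close(fig)
        figures.append(out / "fig_baseline_mean_face.png")
    else:
        notes.append("baseline heatmap panel omitted: no baseline condition")

    # condition difference heatmaps
    cond_maps = sorted(
        p for p in out.glob("heatmap_*.txt") if "baseline" not in p.stem
    )
    if hm_path.exists() and cond_maps:
        base_grid = np.loadtxt(hm_path)
        fig, axes = plt.subplots(1, len(cond_maps), figsize=(4 * len(cond_maps), 3.4), squeeze=False)
        for ax, p in zip(axes[0], cond_maps):
            diff = np.loadtxt(p) - base_grid
            lim = np.abs(diff).max() or 1.0
            ax.imshow(diff, origin="lower", cmap="coolwarm", vmin=-lim, vmax=lim)
            ax.set_title(p.stem.replace("heatmap_", ""), fontsize=8)
        fig.savefig(out / "fig_condition_differences.png", dpi=110)
        plt.close(fig)
        figures.append(out / "fig_condition_differences.png")
    else:
        notes.append("difference panel omitted: no injection conditions")

    # looking-time bars
    stats = pd.read_csv(out / "stat_results.tsv", sep="\t")
    lt = stats[stats["comparison"].str.contains("ipsi_minus_contra")]
    if len(lt):
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(lt))
        ax.bar(x, lt["observed"], color="steelblue")
        ax.errorbar(
            x,
            lt["observed"],
            yerr=[lt["observed"] - lt["ci_low"], lt["ci_high"] - lt["observed"]],
            fmt="none",
            ecolor="k",
        )
        ax.set_xticks(x)
        ax.set_xticklabels(
            [c.replace("_ipsi_minus_contra_eye", "") for c in lt["comparison"]],
            rotation=30,
            ha="right",
            fontsize=7,
        )
        ax.set_ylabel("ipsi - contra eye dwell (s)")
        fig.tight_layout()
        fig.savefig(out / "fig_looking_time.png", dpi=110)
        plt.close(fig)
        figures.append(out / "fig_looking_time.png")
    else:
        notes.append("looking-time panel omitted: no injection comparisons")

    # pattern change bars
    pc = pd.read_csv(out / "pattern_change.tsv", sep="\t")
    if len(pc):
        fig, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(pc))
        ax.bar(x, pc["mean_index"], color="darkorange")
        ax.errorbar(
            x,
            pc["mean_index"],
            yerr=[pc["mean_index"] - pc["ci_low"], pc["ci_high"] - pc["mean_index"]],
            fmt="none",
            ecolor="k",
        )
        ax.set_xticks(x)
        ax.set_xticklabels(pc["condition"], rotation=30, ha="right", fontsize=7)
        ax.set_ylabel("pattern change index")
        fig.tight_layout()
        fig.savefig(out / "fig_pattern_change.png", dpi=110)
        plt.close(fig)
        figures.append(out / "fig_pattern_change.png")
    else:
        notes.append("pattern-change panel omitted: no conditions with enough trials")

    # main sequence
    ms = pd.read_csv(out / "main_sequence.tsv", sep="\t")
    sacc = pd.read_csv(out / "saccades.tsv", sep="\t")
    if len(ms) and len(sacc):
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(sacc["A_dva"], sacc["PV_dva_s"], ".", ms=2, alpha=0.4)
        a = np.linspace(0, sacc["A_dva"].max(), 50)
        for _, row in ms.iterrows():
            ax.plot(a, row["beta"] * a, label=f"{row['group']} (beta={row['beta']:.1f})")
        ax.set_xlabel("amplitude (dva)")
        ax.set_ylabel("peak velocity (dva/s)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_main_sequence.png", dpi=110)
        plt.close(fig)
        figures.append(out / "fig_main_sequence.png")
    else:
        notes.append("main-sequence panel omitted: no saccades")

    (out / "report.txt").write_text(
        "gazemorph report\n================\n"
        + f"figures: {', '.join(p.name for p in figures)}\n"
        + ("notes:\n" + "\n".join(f"- {n}" for n in notes) + "\n" if notes else "")
    )
    return figures
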