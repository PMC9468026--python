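"""End-to-end pipeline: frames → spots → transform → counts → calibration.

Composes the stages in acquisition order: detect spots in each half of every
stitched frame, apply the per-FOV quality filter, estimate (or load) the
inter-channel transform, count colocalized pairs, normalize by the capture
count, fit the Langmuir calibration, compute the limit of detection from the
blank FOVs, bootstrap the quantification error (MAPLE), and — when a 0 pM
control and a positive condition are both present — bootstrap the binary
classification ROC/AUC. All outputs are written alongside a manifest
recording the seed, configuration and per-FOV quality decisions, so a rerun
with the same seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .classification import bootstrap_classification
from .colocalization import FovCounts, colocalize, normalize
from .detection import ImageFrame, detect_both, qc_filter
from .quantification import LangmuirModel, bootstrap_maple
from .registration import (
    AffineTransform2D,
    average_transforms,
    estimate_affine,
    match_beads,
)
from .synthetic import SimulationConfig, simulate_bead_frames, simulate_titration

logger = logging.getLogger("simca")

__all__ = ["run_pipeline", "estimate_channel_transform", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and FOV where it occurred."""


def estimate_channel_transform(
    bead_frames: list[ImageFrame],
    max_distance_px: float = 5.0,
    **detect_kwargs,
) -> AffineTransform2D:
    """Detection→capture affine from bead frames, averaged over frames."""
    transforms = []
    for frame in bead_frames:
        cap, det = detect_both(frame, **detect_kwargs)
        cap_xy, det_xy = match_beads(cap.xy, det.xy, max_distance_px)
        transforms.append(estimate_affine(det_xy, cap_xy))
    return average_transforms(transforms)


def _counts_for_frame(
    frame: ImageFrame,
    concentration: float | None,
    transform: AffineTransform2D,
    cfg: io.RunConfig,
) -> tuple[FovCounts, bool]:
    kwargs = dict(
        sigma=cfg.denoise_sigma,
        h=cfg.reconstruction_h,
        asinh_scale=cfg.asinh_scale,
        threshold_multiplier=cfg.threshold_multiplier,
    )
    cap, det = detect_both(frame, **kwargs)
    kept = qc_filter(cap, frame.height)
    if cfg.colocalization_enabled:
        counts, _ = colocalize(cap, det, transform, cfg.coloc_radius_px)
    else:
        counts = FovCounts(
            fov_id=frame.fov_id, cab_count=len(cap), dab_count=len(det), coloc_count=0
        )
    counts = normalize(counts)
    counts = dataclasses.replace(counts, concentration_pm=concentration)
    return counts, kept


def run_pipeline(config: io.RunConfig, out_dir: str | Path) -> dict:
    """Run the full assay analysis; returns the results bundle as a dict.

    Input frames come from ``config.images`` (with a labels CSV mapping
    fov_id to concentration_pm) or, when unset, from the synthetic titration
    generator at ``config.concentrations_pm``. The transform comes from
    ``config.transform`` (JSON), from ``config.bead_images``, or — in
    synthetic mode — from simulated bead frames put through the same
    registration stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ------------------------------------------------------------------ input
    if config.images is not None:
        frames = io.read_frames(config.images)
        labels: dict[str, float] = {}
        if config.labels is not None:
            lab = pd.read_csv(config.labels)
            labels = dict(zip(lab["fov_id"].astype(str), lab["concentration_pm"]))
        dataset = [(f, labels.get(f.fov_id)) for f in frames]
        sim_cfg = None
    else:
        sim_cfg = SimulationConfig(
            **{"seed": int(rng.integers(2**31)), **config.synthetic}
        )
        titration = simulate_titration(
            sim_cfg, config.concentrations_pm, config.fovs_per_concentration
        )
        dataset = [(t.frame, t.concentration) for t in titration]

    # -------------------------------------------------------------- transform
    if config.transform is not None:
        transform = io.read_transform(config.transform)
    elif config.bead_images is not None:
        transform = estimate_channel_transform(
            io.read_frames(config.bead_images), config.bead_match_max_distance_px
        )
    elif sim_cfg is not None:
        beads = simulate_bead_frames(
            sim_cfg.true_transform, n_frames=5, beads_per_frame=50,
            jitter_sd_px=0.0, rng_seed=int(rng.integers(2**31)),
            image_height_px=sim_cfg.image_height_px,
            image_width_px=sim_cfg.image_width_px,
        )
        transform = estimate_channel_transform(
            [f for f, _ in beads], config.bead_match_max_distance_px
        )
    elif config.colocalization_enabled:
        raise PipelineError(
            "stage=registration: no transform, bead frames or synthetic truth"
        )
    else:
        transform = AffineTransform2D.identity()
    io.write_transform(out / "transform.json", transform)

    # ----------------------------------------------------------------- counts
    all_counts: list[FovCounts] = []
    qc_rows = []
    for frame, conc in dataset:
        try:
            counts, kept = _counts_for_frame(frame, conc, transform, config)
        except Exception as exc:
            raise PipelineError(f"stage=counting fov={frame.fov_id}: {exc}") from exc
        qc_rows.append({"fov_id": frame.fov_id, "kept": kept})
        logger.info("fov=%s qc_kept=%s cab=%d dab=%d coloc=%d",
                    frame.fov_id, kept, counts.cab_count, counts.dab_count,
                    counts.coloc_count)
        if kept:
            all_counts.append(counts)
    io.write_counts(out / "counts.csv", all_counts)
    pd.DataFrame(qc_rows).to_csv(out / "qc_report.csv", index=False)

    df = pd.DataFrame([vars(c) for c in all_counts])
    df = df[df["valid"]]
    signal_kind = (
        config.signal_kind if config.colocalization_enabled else "dab_count"
    )
    bundle: dict = {"counts": df, "transform": transform, "signal_kind": signal_kind}

    # ------------------------------------------------ calibration / LOD / MAPLE
    labeled = df[df["concentration_pm"].notna()]
    if len(labeled["concentration_pm"].unique()) >= 3:
        try:
            fit = LangmuirModel.from_dataframe(labeled, signal_kind).fit()
        except Exception as exc:
            raise PipelineError(f"stage=calibration: {exc}") from exc
        (out / "calibration.json").write_text(json.dumps({
            "signal_kind": signal_kind,
            "kd_pm": fit.kd, "bmax": fit.bmax,
            "sigma_kd_pm": fit.sigma_kd, "sigma_bmax": fit.sigma_bmax,
            "covariance": fit.covariance.tolist(), "n_fov": fit.nobs,
        }, indent=2))
        bundle["calibration"] = fit

        blanks = labeled.loc[labeled["concentration_pm"] == 0, signal_kind]
        if len(blanks) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lod = fit.lod(blanks.to_numpy())
            (out / "lod.json").write_text(json.dumps({
                "lod_signal": lod.lod_signal,
                "lod_concentration_pm": lod.lod_concentration,
                "sigma_lod_pm": lod.sigma_lod,
                "blank_mean": lod.blank_mean, "blank_sd": lod.blank_sd,
            }, indent=2))
            bundle["lod"] = lod

        maple_res = bootstrap_maple(
            labeled["concentration_pm"].to_numpy(),
            labeled[signal_kind].to_numpy(),
            signal_kind, n_boot=config.n_boot,
            rng_seed=int(rng.integers(2**31)),
        )
        pd.DataFrame({
            "iteration": np.arange(len(maple_res.samples)),
            "maple_percent": maple_res.samples,
        }).to_csv(out / "maple.csv", index=False)
        bundle["maple"] = maple_res

    # ---------------------------------------------------------- classification
    concs = sorted(labeled["concentration_pm"].unique())
    if 0.0 in concs and len(concs) > 1:
        pos_conc = min(c for c in concs if c > 0)
        pos = labeled.loc[labeled["concentration_pm"] == pos_conc, signal_kind]
        neg = labeled.loc[labeled["concentration_pm"] == 0, signal_kind]
        if len(pos) >= 5 and len(neg) >= 5:
            roc = bootstrap_classification(
                pos.to_numpy(), neg.to_numpy(), n_boot=config.n_boot,
                rng_seed=int(rng.integers(2**31)),
            )
            pd.DataFrame({"auc": roc.auc_samples}).to_csv(
                out / "auc_samples.csv", index=False
            )
            q1, med, q3 = roc.quartiles
            (out / "roc_summary.json").write_text(json.dumps({
                "positive_concentration_pm": pos_conc,
                "statistic": signal_kind,
                "auc_full": roc.auc,
                "auc_median": med, "auc_q1": q1, "auc_q3": q3,
            }, indent=2))
            bundle["roc"] = roc

    # --------------------------------------------------------------- manifest
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    (out / "manifest.json").write_text(json.dumps({
        "package": "simca", "version": __version__,
        "seed": config.seed, "signal_kind": signal_kind,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config.to_dict(),
        "n_fov_total": len(dataset),
        "n_fov_kept": int(sum(r["kept"] for r in qc_rows)),
    }, indent=2))
    return bundle
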