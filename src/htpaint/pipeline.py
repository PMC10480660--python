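"""End-to-end orchestration: simulate, reconstruct, train, predict, assess.

`run_experiment` chains every stage of the acceleration workflow on a
simulated acquisition pair (low-density ground truth + high-density stack)
and returns both the numbers and the intermediate artifacts; `run_demo` is
the desk-scale preset behind the ``htpaint demo`` CLI command.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import deepdense, densitydata, imqual, locfit, sim
from .core import CameraModel, substream_seed


@dataclass
class ExperimentResult:
    """Artifacts and metrics of one simulated acceleration experiment."""

    pcc_pred: float
    pcc_widefield: float
    resolution_pred_nm: float
    resolution_widefield_nm: float
    resolution_gt_nm: float
    n_gt_locs: int
    n_pred_locs: int
    threshold: float
    nena_px: float
    gt_render: np.ndarray
    pred_render: np.ndarray
    widefield_render: np.ndarray
    model: object
    maps: list
    tables: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)


def run_experiment(seed: int = 0, field_px: int = 48, gt_frames: int = 5000,
                   hd_frames: int = 1000, gt_density: float = 0.109,
                   hd_density: float = 1.3, n_low_patches: int = 4000,
                   n_train_patches: int = 2000, k_per_sum: int = 12,
                   photon_rate: float = 2000.0, bg_photons: float = 10.0,
                   psf_sigma_px: float = 1.2, structure_kind: str = "filaments",
                   train_config: deepdense.TrainConfig | None = None,
                   camera: CameraModel | None = None) -> ExperimentResult:
    """Simulated acceleration experiment: low-density GT vs predicted HD.

    A structure is imaged twice — a long low-density acquisition that is
    localized frame by frame (the ground truth) and a short high-density
    acquisition reconstructed by the network trained on summed patches of the
    low-density data.  The prediction render and a widefield baseline (mean
    of the high-density stack, bilinearly upsampled) are both referenced
    against the GT render.
    """
    cam = camera or CameraModel()
    cfg = train_config or deepdense.desk_config(upsampling=8, seed=seed)
    u = cfg.upsampling
    field_um = field_px * cam.pixel_size_nm / 1e3
    t0 = time.time()
    timings = {}

    def mark(key):
        timings[key] = round(time.time() - t0 - sum(timings.values()), 2)

    st = sim.generate_structure(structure_kind, field_um,
                                {"n_filaments": 7, "length_um": 0.8 * field_um},
                                seed=substream_seed(seed, "structure"))
    ev_gt = sim.sample_binding_events(st, gt_density, gt_frames,
                                      photon_rate=photon_rate,
                                      seed=substream_seed(seed, "gt-events"))
    gt_stack = sim.render_frames(ev_gt, psf_sigma_px, cam, bg_photons=bg_photons,
                                 frame_shape=(field_px, field_px),
                                 seed=substream_seed(seed, "gt-camera"))
    ev_hd = sim.sample_binding_events(st, hd_density, hd_frames,
                                      photon_rate=photon_rate,
                                      seed=substream_seed(seed, "hd-events"))
    hd_stack = sim.render_frames(ev_hd, psf_sigma_px, cam, bg_photons=bg_photons,
                                 frame_shape=(field_px, field_px),
                                 seed=substream_seed(seed, "hd-camera"))
    mark("simulate")

    table = locfit.localize(gt_stack, box_px=7, min_net_gradient=400.0)
    table = locfit.filter_table(table, locfit.DEFAULT_FILTER_RANGES)
    nena = locfit.estimate_nena(table)
    linked = locfit.link_localizations(table, radius_px=4 * nena.nena_px,
                                       max_dark_frames=5)
    gt_render = locfit.render_locs(table, oversampling=u, blur_sigma_px=1.0,
                                   shape=(field_px, field_px))
    mark("gt_reconstruction")

    low = densitydata.extract_patches(gt_stack, table, patch_px=17,
                                      n=n_low_patches,
                                      seed=substream_seed(seed, "patches"))
    hi = densitydata.sum_patches(low, k_per_sum=k_per_sum, n_out=n_train_patches,
                                 seed=substream_seed(seed, "summing"))
    hi = densitydata.adjust_background(
        hi, densitydata.background_stats(hd_stack.photons(slice(0, 50))))
    mark("training_data")

    model = deepdense.build_model(cfg)
    model = deepdense.train(model, hi, cfg)
    mark("training")

    hd_corr, _ = locfit.frame_xcorr_drift(hd_stack, reference="mean")
    maps = deepdense.predict(model, hd_corr, batch_size=16)
    ref_count = len(hd_stack.true_locs)
    threshold = deepdense.calibrate_threshold(maps, ref_count)
    pred_table = deepdense.extract_localizations(maps, threshold,
                                                 pixel_size_nm=cam.pixel_size_nm)
    pred_render = locfit.render_locs(pred_table, oversampling=u, blur_sigma_px=1.0,
                                     shape=(field_px, field_px))
    mark("prediction")

    widefield = ndimage.zoom(hd_stack.photons().mean(axis=0), u, order=1,
                             mode="nearest", grid_mode=True)
    gt8, pred8 = imqual.preprocess_pair(gt_render, pred_render)
    _, wf8 = imqual.preprocess_pair(gt_render, widefield)
    # resolution on the float renders: min-max 8-bit quantization injects a
    # flat noise floor that decorrelation would read as pixel-scale detail
    px_nm = cam.pixel_size_nm / u
    res_pred = imqual.decorrelation_resolution(pred_render, px_nm)
    res_wf = imqual.decorrelation_resolution(widefield, px_nm)
    res_gt = imqual.decorrelation_resolution(gt_render, px_nm)
    mark("assessment")

    return ExperimentResult(
        pcc_pred=imqual.pearson(gt8, pred8),
        pcc_widefield=imqual.pearson(gt8, wf8),
        resolution_pred_nm=res_pred.resolution_nm,
        resolution_widefield_nm=res_wf.resolution_nm,
        resolution_gt_nm=res_gt.resolution_nm,
        n_gt_locs=len(table), n_pred_locs=len(pred_table), threshold=threshold,
        nena_px=nena.nena_px,
        gt_render=gt_render, pred_render=pred_render, widefield_render=widefield,
        model=model, maps=maps,
        tables=dict(gt=table, gt_linked=linked, pred=pred_table,
                    gt_truth=gt_stack.true_locs, hd_truth=hd_stack.true_locs),
        timings_s=timings)


def run_demo(seed: int = 0, outdir="htpaint_demo") -> dict:
    """Minutes-scale end-to-end demonstration; writes artifacts to ``outdir``.

    Uses a small field and a shortened training schedule — the numbers are
    illustrative, not the desk-scale evaluation profile.
    """
    import tifffile

    from . import io, livemovie

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = deepdense.desk_config(upsampling=8, seed=seed)
    cfg.epochs = 6
    res = run_experiment(seed=seed, field_px=32, gt_frames=1200, hd_frames=200,
                         n_low_patches=800, n_train_patches=400,
                         train_config=cfg)

    io.write_locs(outdir / "gt_locs.hdf5", res.tables["gt"])
    io.write_locs(outdir / "pred_locs.hdf5", res.tables["pred"])
    io.save_model(outdir / "model.npz", res.model)
    tifffile.imwrite(outdir / "gt_render.tif", res.gt_render.astype(np.float32))
    tifffile.imwrite(outdir / "pred_render.tif", res.pred_render.astype(np.float32))

    movie_cfg = livemovie.MovieConfig(window_frames=100, step_frames=20,
                                      oversampling=8, integration_time_ms=50.0)
    frames, t, _ = livemovie.make_movie_frames(res.tables["pred"], 200, (32, 32),
                                               movie_cfg)
    manifest = livemovie.stitch_movie(frames, outdir / "movie.mp4", movie_cfg,
                                      timestamps=t)

    report = dict(
        pcc_prediction=res.pcc_pred, pcc_widefield=res.pcc_widefield,
        resolution_pred_nm=res.resolution_pred_nm,
        resolution_widefield_nm=res.resolution_widefield_nm,
        nena_px=res.nena_px, n_gt_locs=res.n_gt_locs,
        n_pred_locs=res.n_pred_locs, movie_frames=len(frames),
        movie_output=manifest["output"], timings_s=res.timings_s)
    (outdir / "report.json").write_text(
        __import__("json").dumps(report, indent=2, default=float))
    return report
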