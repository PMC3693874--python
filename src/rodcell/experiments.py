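"""Canonical validation experiments on synthetic phantoms.

Each function sets up one of the package's standard benchmark scenes —
PSF-kernel fitting, the 38-spot intensity-estimation comparison, noisy-cell
segmentation, low-PSNR tracking, loss-frame detection, repeated-run
variability — runs the method under test, and returns the measured
quantities.  The test suite and the reproduction script both call these, so
the numbers they report come from one code path.

All randomness is derived from an integer seed via ``numpy``'s
``SeedSequence``; every experiment is reproducible.
"""

from __future__ import annotations

import numpy as np

from . import phantom as ph
from . import rodscule as rod
from . import spots as sp
from . import tracking as tk
from .io import PipelineConfig
from .pipeline import run_pipeline


def fit_reference_kernel(with_offset: bool = False) -> sp.SpotFit:
    """Fit the PSF model to the printed 5x5 reference kernel.

    Noise-free; recovers amplitude ~95.9719 and offset 0 (or 80 for the
    offset variant) to sub-1e-3 accuracy.
    """
    img = (ph.REFERENCE_PSF_KERNEL_OFFSET if with_offset
           else ph.REFERENCE_PSF_KERNEL)
    return sp.fit_gaussian(img, (2, 2), window=5, sigma0=1.0)


def _spot_grid_scene(n_cells: int = 19, noise_std: float = 15.0,
                     seed: int = 0) -> ph.PhantomSpec:
    """A plate of rod cells, two reference-kernel spots each (38 spots)."""
    cells, spots_ = [], []
    k = 0
    for row in range(5):
        for col in range(4):
            if k >= n_cells:
                break
            cx, cy = 40 + col * 70, 30 + row * 40
            cells.append(ph.CellPhantom(center=(cx, cy), length=56, width=16,
                                        interior_intensity=80.0))
            spots_.append(ph.SpotPhantom(position=(cx - 18.0, float(cy))))
            spots_.append(ph.SpotPhantom(position=(cx + 18.0, float(cy))))
            k += 1
    return ph.PhantomSpec(image_shape=(240, 330), cells=tuple(cells),
                          spots=tuple(spots_), background_intensity=10.0,
                          noise_std=noise_std, seed=seed)


def spot_intensity_experiment(seed: int = 0, n_seeds: int = 10,
                              window: int = 9):
    """Intensity-estimation comparison on 38 noisy reference-kernel spots.

    For each seed, renders the spot-grid phantom with additive Gaussian
    noise (std 15), locates each spot near its true position, and estimates
    its intensity with (a) the Gaussian-PSF fit (amplitude A, with the
    optics-informed lower σ bound) and (b) the 5x5 neighborhood maximum.
    Returns per-seed mean absolute errors against the true amplitude.
    """
    true_a = ph.REFERENCE_PSF_AMPLITUDE
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    mae_fit, mae_max = [], []
    for s in seeds:
        spec = _spot_grid_scene(noise_std=15.0, seed=int(s))
        _clean, noisy, truth = ph.render(spec)
        resp = sp.log_filter(noisy, 1.0)
        h, w = spec.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        fit_est, max_est = [], []
        for (pos, _amp, sig) in truth["spots"]:
            near = (np.abs(xx - pos[0]) <= 3) & (np.abs(yy - pos[1]) <= 3)
            cand = sp.detect_spots(resp, 1, min_separation=2.0, mask=near)
            c = cand[0] if cand else tuple(pos)
            f = sp.fit_gaussian(noisy, c, window=window, sigma0=sig,
                                sigma_bounds=(sig, window / 2))
            fit_est.append(f.amplitude)
            max_est.append(sp.baseline_max_intensity(noisy, c))
        mae_fit.append(ph.mean_abs_error(fit_est, true_a))
        mae_max.append(ph.mean_abs_error(max_est, true_a))
    return np.asarray(mae_fit), np.asarray(mae_max)


SEGMENTATION_NOISE_LEVELS = (10.0, 30.0, 60.0, 90.0, 120.0)


def segmentation_experiment(noise_std: float, seed: int = 0,
                            n_seeds: int = 10):
    """Rodscule recovery on a noisy stadium phantom, fixed initialization.

    One 60x14 px cell; the same deliberately offset, overlapping
    initialization for every seed; additive noise of the given std on the
    8-bit scale.  Returns the mean distance from the converged inner-rod
    boundary to the ground-truth cell boundary, per seed, and the scene SNR
    in dB.
    """
    cell = ph.CellPhantom(center=(48, 32), length=60, width=14)
    gt_rod = cell.stadium()
    init = rod.initialize_from_spots((30, 30), (66, 35), 18, 6)
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    dists = []
    snr_db = None
    for s in seeds:
        spec = ph.PhantomSpec(image_shape=(64, 96), cells=(cell,),
                              noise_std=noise_std, seed=int(s))
        clean, noisy, _ = ph.render(spec)
        if snr_db is None:
            h, w = spec.image_shape
            yy, xx = np.mgrid[0:h, 0:w]
            support = gt_rod.contains(
                np.stack([xx, yy], -1).astype(float))
            snr_db = ph.snr(clean, noise_std,
                            background=spec.background_intensity,
                            support=support)
        res = rod.optimize(noisy, init)
        inner = rod.geometry_from_points(res.state).inner_rod
        d = np.abs(gt_rod.signed_distance(inner.boundary_points(240)))
        dists.append(float(d.mean()))
    return np.asarray(dists), float(snr_db)


def tracking_low_psnr_experiment(seed: int = 0, n_replicates: int = 20,
                                 n_frames: int = 50, psnr_db: float = 0.0,
                                 noise_std: float = 40.0):
    """Positional accuracy of dense-grid DP tracking at a given PSNR.

    One spot of width σ = 2.5 px (the diffraction-limited width under the
    default microscope parameters) random-walks inside a rod cell for
    ``n_frames`` frames; its amplitude A is set from the target PSNR via
    A = σ_noise · 10^(PSNR/20).  Tracking starts from the grid point nearest
    the true frame-1 position.  Returns the per-replicate positional RMSE in
    px between the recovered and true track.
    """
    amplitude = noise_std * 10.0 ** (psnr_db / 20.0)
    spot_sigma = 2.5
    cell = ph.CellPhantom(center=(32, 32), length=56, width=16,
                          interior_intensity=80.0)
    rodc = cell.stadium()
    ss = np.random.SeedSequence(seed).generate_state(3 * n_replicates)
    ss = ss % (2 ** 31)
    rmses = []
    for r in range(n_replicates):
        rng = np.random.default_rng(int(ss[3 * r]))
        gt = ph.random_walk_track((20, 32), n_frames, 1.0, rng, cell=rodc,
                                  max_step=4.0)
        spec = ph.PhantomSpec(image_shape=(64, 64), cells=(cell,),
                              background_intensity=10.0, noise_std=noise_std,
                              bit_depth=16, seed=int(ss[3 * r + 1]))
        tl = ph.TimeLapseSpec(base=spec, n_frames=n_frames,
                              spot_tracks=gt[None],
                              amplitudes=np.full((1, n_frames), amplitude),
                              sigma=spot_sigma, max_displacement=4.0,
                              seed=int(ss[3 * r + 2]))
        frames, _ = ph.generate_timelapse(tl)
        h, w = spec.image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        mask = rodc.contains(np.stack([xx, yy], -1).astype(float))
        pos = tk.track_spot_dense(frames, mask, gt[0],
                                  spot_sigma=spot_sigma,
                                  max_displacement=4.0)
        rmses.append(float(np.sqrt(np.mean(
            np.sum((pos - gt) ** 2, axis=1)))))
    return np.asarray(rmses)


def loss_frame_experiment(seed: int = 0, n_seeds: int = 20,
                          n_frames: int = 42, noise_std: float = 4.0):
    """Loss-frame detection error on constructed amplitude fades.

    Half the seeds use an abrupt step to zero, half a linear fade, with the
    true crossing frame drawn at random; amplitudes carry additive Gaussian
    noise.  Returns the per-seed absolute error |F_t0 − t*| (the true t* is
    the last frame at or above the detection threshold).
    """
    ss = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    errors = []
    for i, s in enumerate(ss):
        rng = np.random.default_rng(int(s))
        t_change = int(rng.integers(12, n_frames - 8))
        high = 12.0 * noise_std
        threshold = 3.0 * noise_std
        t = np.arange(n_frames)
        if i % 2 == 0:
            clean = np.where(t < t_change, high, 0.0)
        else:
            # linear fade from full amplitude to zero over 4 frames
            clean = high * np.clip((t_change - t) / 4.0, 0.0, 1.0)
        a = clean + rng.normal(0.0, noise_std, n_frames)
        true_last = int(np.nonzero(clean >= threshold)[0][-1])
        f, flag = tk.detect_loss_frame(a, noise_std=noise_std, k=3.0)
        if f is None:
            errors.append(float(n_frames))  # missed detection counts big
        else:
            errors.append(float(abs(f - true_last)))
    return np.asarray(errors)


def repeatability_experiment(seed: int = 0, n_runs: int = 3) -> float:
    """Run-to-run variability of the automated intensity estimation.

    The full detection + segmentation + PSF-fit pipeline is run ``n_runs``
    times on one identical phantom image with identical configuration; the
    returned value is the mean absolute pairwise difference of the fitted
    spot amplitudes across runs (the automated analogue of an observer
    repeating a manual measurement).  The pipeline is deterministic, so the
    expected value is exactly 0.
    """
    cell = ph.CellPhantom(center=(48, 32), length=60, width=14,
                          interior_intensity=80.0)
    spec = ph.PhantomSpec(
        image_shape=(64, 96), cells=(cell,),
        spots=(ph.SpotPhantom(position=(30.0, 32.0)),
               ph.SpotPhantom(position=(66.0, 32.0))),
        background_intensity=10.0, noise_std=15.0, seed=seed)
    _clean, noisy, _ = ph.render(spec)
    cfg = PipelineConfig(pixel_size=0.1, diffraction_limit=0.065,
                         n_cells=1, default_width=18.0)
    amp_runs = []
    for _ in range(n_runs):
        result = run_pipeline(cfg, noisy)
        amps = np.sort(result["table"].spots["amplitude"].to_numpy())
        amp_runs.append(amps)
    diffs = []
    for i in range(n_runs):
        for j in range(i + 1, n_runs):
            diffs.append(np.mean(np.abs(amp_runs[i] - amp_runs[j])))
    return float(np.mean(diffs))
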