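"""End-to-end pipeline: detection → segmentation → tracking → measurement →
kymographs.

Static inputs (a single time point) get spot detection, cell segmentation
and per-cell/per-spot measurements; dynamic inputs (time lapse) additionally
get DP tracking, loss-frame detection and both kymograph kinds.  All steps
are deterministic given the configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import kymograph as _kymo
from . import rodscule as _rod
from . import spots as _spots
from . import tracking as _track

log = logging.getLogger("rodcell")


def _as_channel_stacks(images) -> list[np.ndarray]:
    """Normalize input to a list of (T, H, W) float arrays, one per
    channel."""
    if isinstance(images, (list, tuple)):
        stacks = [np.asarray(im, float) for im in images]
    else:
        arr = np.asarray(images, float)
        if arr.ndim == 2:
            stacks = [arr[None]]
        elif arr.ndim == 3:
            stacks = [arr]
        elif arr.ndim == 4:
            stacks = [arr[c] for c in range(arr.shape[0])]
        else:
            raise ValueError("expected 2D, 3D (t, y, x) or 4D (c, t, y, x)")
        return stacks
    return [s[None] if s.ndim == 2 else s for s in stacks]


def pair_spots(candidates, max_pair_distance: float):
    """Greedy mutual pairing of detected spots into per-cell SPB pairs."""
    pos = np.array([c.position for c in candidates], float)
    n = len(candidates)
    pairs = []
    if n < 2:
        return pairs
    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d <= max_pair_distance:
                dists.append((d, i, j))
    used = set()
    for d, i, j in sorted(dists):
        if i in used or j in used:
            continue
        pairs.append((candidates[i], candidates[j]))
        used.update((i, j))
    return pairs


def run_pipeline(config: _io.PipelineConfig, images, *,
                 output_dir=None):
    """Run the full analysis on one (multi-channel) image or time lapse.

    ``images``: a 2D image, a (t, y, x) stack, a (c, t, y, x) array or a list
    of per-channel stacks; channel 0 is the reference channel.  Returns a
    dict with the results table, the per-cell segmentations, tracks and
    kymographs (dynamic input only).  When ``output_dir`` is set, tables and
    kymographs are also written there.
    """
    stacks = _as_channel_stacks(images)
    T = stacks[0].shape[0]
    dynamic = T > 1
    ref = stacks[0]
    sigma0 = config.diffraction_limit / config.pixel_size
    weights = _track.CostWeights(
        intensity=config.lambda_intensity,
        intensity_variation=config.lambda_intensity_variation,
        distance=config.lambda_distance,
        direction=config.lambda_direction,
        outside_cell=config.lambda_outside_cell)

    # --- detection on the reference channel's first frame ----------------
    frame1 = _rod.preprocess(ref[0])
    resp = _spots.log_filter(frame1, config.log_sigma)
    cands = _spots.detect_spots(
        resp, n_max=config.n_cells * config.n_spots_per_cell,
        min_separation=3.0, threshold=0.0)
    pairs = pair_spots(cands, config.max_pair_distance)
    log.info("detected %d candidates, %d spot pairs", len(cands), len(pairs))

    # --- segmentation -----------------------------------------------------
    inits = [_rod.initialize_from_spots(a.position, b.position,
                                        config.default_width,
                                        config.init_margin)
             for a, b in pairs]
    seg = _rod.segment_all(frame1, inits, grad_tol=config.grad_tol,
                           max_iter=config.max_iter)
    cells_rows, geometries = [], []
    for cid, ((a, b), (res, _m, status)) in enumerate(zip(pairs, seg)):
        row = {"cell_id": cid, "status": status}
        if res is not None:
            st = res.state
            meas = _rod.measurements(
                st, ref[0], spot_positions=[a.position, b.position])
            geo = _rod.geometry_from_points(st)
            geometries.append((cid, st, geo, status))
            row.update({
                "Px": st.P[0], "Py": st.P[1], "Qx": st.Q[0], "Qy": st.Q[1],
                "Rx": st.R[0], "Ry": st.R[1],
                "length_px": meas.length, "width_px": meas.width,
                "length_um": meas.length * config.pixel_size,
                "width_um": meas.width * config.pixel_size,
                "orientation_deg": np.degrees(meas.orientation),
                "tip1_x": meas.extremities[0][0],
                "tip1_y": meas.extremities[0][1],
                "tip2_x": meas.extremities[1][0],
                "tip2_y": meas.extremities[1][1],
                "barycenter_x": meas.barycenter[0],
                "barycenter_y": meas.barycenter[1],
                "background_fluorescence": meas.background_fluorescence,
                "energy": meas.energy,
            })
        cells_rows.append(row)
        log.info("cell %d: %s", cid, status)

    spot_rows = []
    kymographs = []
    tracks_out = []

    if not dynamic:
        # static: per-channel spot fits inside each segmented cell
        for cid, st, geo, status in geometries:
            if status != "ok":
                continue
            h, w = ref[0].shape
            ys, xs = np.mgrid[0:h, 0:w]
            mask = geo.outer_rod.contains(
                np.stack([xs, ys], -1).astype(float))
            for ch, stack in enumerate(stacks):
                r = _spots.log_filter(stack[0], config.log_sigma)
                cs = _spots.detect_spots(r, config.n_spots_per_cell,
                                         min_separation=2.0, mask=mask,
                                         channel=ch)
                fits = [_spots.fit_gaussian(
                    stack[0], c, window=config.fit_window, sigma0=sigma0,
                    sigma_bounds=(sigma0, config.fit_window / 2))
                    for c in cs]
                dist = (float(np.linalg.norm(
                    np.array(fits[0].center) - np.array(fits[1].center)))
                    if len(fits) == 2 else np.nan)
                for sid, f in enumerate(fits):
                    spot_rows.append({
                        "cell_id": cid, "channel": ch, "spot_id": sid,
                        "frame": 0, "x": f.center[0], "y": f.center[1],
                        "x_um": f.center[0] * config.pixel_size,
                        "y_um": f.center[1] * config.pixel_size,
                        "amplitude": f.amplitude, "offset": f.offset,
                        "sigma_x": f.sigma_x, "sigma_y": f.sigma_y,
                        "theta": f.theta, "residual_rms": f.residual_rms,
                        "interspot_distance_px": dist,
                        "cost": np.nan, "loss_frame": "",
                        "method": "gaussfit",
                    })
    else:
        cells_ok = [(cid, geo) for cid, _st, geo, status in geometries
                    if status == "ok"]
        rods = [geo.outer_rod for _cid, geo in cells_ok]
        per_cell = _track.track_two_spots(
            stacks, rods, weights, log_sigma=config.log_sigma,
            max_displacement=config.max_displacement,
            fit_window=config.fit_window, loss_k=config.loss_k,
            n_spots=config.n_spots_per_cell)
        for (cid, geo), ct in zip(cells_ok, per_cell):
            tracks_out.append((cid, ct))
            if ct.skipped:
                log.info("cell %d tracking skipped: %s", cid, ct.flag)
                continue
            for ch, tracks in ct.tracks.items():
                # per-frame inter-spot distance from the two tracks
                dist_by_frame = {}
                if len(tracks) == 2:
                    n = min(len(tracks[0].vertices), len(tracks[1].vertices))
                    for i in range(n):
                        d = float(np.linalg.norm(tracks[0].positions[i]
                                                 - tracks[1].positions[i]))
                        dist_by_frame[int(tracks[0].frames[i])] = d
                for tr in tracks:
                    g_cum = 0.0
                    for i, v in enumerate(tr.vertices):
                        spot_rows.append({
                            "cell_id": cid, "channel": ch,
                            "spot_id": tr.spot_id, "frame": v.frame,
                            "x": v.position[0], "y": v.position[1],
                            "x_um": v.position[0] * config.pixel_size,
                            "y_um": v.position[1] * config.pixel_size,
                            "amplitude": (tr.amplitudes[i]
                                          if tr.amplitudes is not None
                                          else np.nan),
                            "offset": (tr.offsets[i]
                                       if tr.offsets is not None else np.nan),
                            "sigma_x": np.nan, "sigma_y": np.nan,
                            "theta": np.nan, "residual_rms": np.nan,
                            "interspot_distance_px":
                                dist_by_frame.get(v.frame, np.nan),
                            "cost": g_cum, "loss_frame":
                                "" if tr.loss_frame is None
                                else tr.loss_frame,
                            "method": "gaussfit",
                        })
                direction = geo.outer_ellipse.axis
                ch_tracks = ct.tracks.get(ch, [])
                if ch_tracks:
                    kymographs.append(_kymo.kymo_cell_frame(
                        ch_tracks, geo, direction, cell_id=cid, channel=ch))
                if len(ch_tracks) == 2:
                    kymographs.append(_kymo.kymo_relative(
                        (ch_tracks[0], ch_tracks[1]), cell_id=cid,
                        channel=ch))

    cells_df = pd.DataFrame(cells_rows)
    spots_df = pd.DataFrame(spot_rows)
    table = _io.ResultsTable(cells=cells_df, spots=spots_df)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_results(table, out)
        for k in kymographs:
            _io.write_kymograph(
                out / f"kymo_cell{k.cell_id}_ch{k.channel}_{k.kind}.tif", k)

    return {
        "table": table,
        "cells": geometries,
        "tracks": tracks_out,
        "kymographs": kymographs,
        "dynamic": dynamic,
    }
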