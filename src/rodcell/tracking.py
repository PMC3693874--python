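"""Globally optimal spot tracking by dynamic programming.

Per-frame spot candidates form an acyclic weighted graph: vertices are
candidates, edges connect candidates in *consecutive* frames whose distance
is within the per-frame motion bound, and the source is the frame-1
detection.  With G(x) the cost of the best path from the source to vertex x,

    G(x) = 0                          if x is the source
    G(x) = min_j { G(j) + C(j, x) }   over predecessors j of x

and the track is the path to the cheapest last-frame vertex (Bellman
optimality: every sub-path of the optimum is optimal).  The edge cost is a
weighted sum of bounded terms — intensity, intensity variation, migration
distance, directional persistence — plus a heavy penalty for leaving the
segmented cell.  Because the persistence term looks one step back, the DP
state is the (vertex, predecessor) pair, an exact reformulation.

A fading spot's loss-of-fluorescence frame F_t0 is found by fitting a step
function to the fitted amplitude series and reporting the last frame whose
amplitude stays above a noise-dependent threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spots as _spots
from .rodscule import estimate_noise_std

OUTSIDE_PENALTY = 1.0  # f_out value (scaled by lambda_outside_cell)


@dataclass(frozen=True)
class Vertex:
    frame: int
    index: int                     # index within its frame's candidate list
    position: tuple[float, ...]    # (x, y[, z]) px
    intensity: float


@dataclass(frozen=True)
class CostWeights:
    """Non-negative weights λ_q of the edge-cost terms."""

    intensity: float = 1.0
    intensity_variation: float = 0.5
    distance: float = 0.5
    direction: float = 0.25
    outside_cell: float = 10.0

    def __post_init__(self):
        vals = (self.intensity, self.intensity_variation, self.distance,
                self.direction, self.outside_cell)
        if any(v < 0 for v in vals):
            raise ValueError("weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one weight must be positive")


@dataclass
class TrackGraph:
    frames: list                 # list of list[Vertex]
    max_displacement: float
    source_index: int = 0
    intensity_scale: float = 1.0

    @property
    def n_vertices(self) -> int:
        return sum(len(f) for f in self.frames)

    @property
    def source(self) -> Vertex:
        return self.frames[0][self.source_index]

    def successors(self, v: Vertex) -> list:
        t = v.frame + 1
        if t >= len(self.frames):
            return []
        p = np.asarray(v.position)
        return [u for u in self.frames[t]
                if np.linalg.norm(np.asarray(u.position) - p)
                <= self.max_displacement]


@dataclass
class Track:
    vertices: list
    cost: float
    truncated: bool = False
    amplitudes: np.ndarray | None = None
    offsets: np.ndarray | None = None
    loss_frame: int | None = None
    loss_flag: str = ""
    channel: int = 0
    spot_id: int = 0

    @property
    def frames(self) -> np.ndarray:
        return np.array([v.frame for v in self.vertices])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.position for v in self.vertices], dtype=float)

    @property
    def index_path(self) -> tuple:
        return tuple(v.index for v in self.vertices)


def build_graph(candidates_per_frame, max_displacement: float,
                source_index: int = 0, robust_max_pct: float = 99.5
                ) -> TrackGraph:
    """Assemble the tracking graph from per-frame candidate lists.

    Candidates may be ``SpotCandidate``s or ``(position, intensity)`` pairs.
    Edges exist only between consecutive frames within ``max_displacement``
    px; candidate intensities are later normalized by the sequence's robust
    maximum (the ``robust_max_pct`` percentile) so the intensity cost terms
    stay in [0, 1].
    """
    frames = []
    for t, cands in enumerate(candidates_per_frame):
        verts = []
        for i, c in enumerate(cands):
            if hasattr(c, "position"):
                pos, inten = tuple(c.position), float(c.log_response)
            else:
                pos, inten = tuple(np.atleast_1d(c[0])), float(c[1])
            verts.append(Vertex(frame=t, index=i, position=pos,
                                intensity=inten))
        frames.append(verts)
    if not frames or not frames[0]:
        raise ValueError("the first frame must contain at least one "
                         "candidate (the source)")
    if not (0 <= source_index < len(frames[0])):
        raise ValueError("source_index outside the first frame's candidates")
    intens = [v.intensity for f in frames for v in f]
    scale = float(np.percentile(intens, robust_max_pct))
    if scale <= 0:
        scale = max(max(intens), 1e-12)
    return TrackGraph(frames=frames, max_displacement=max_displacement,
                      source_index=source_index, intensity_scale=scale)


def _norm_intensity(v: Vertex, scale: float) -> float:
    return float(np.clip(v.intensity / scale, 0.0, 1.0))


def edge_cost(v_i: Vertex, v_j: Vertex, weights: CostWeights,
              cell_contains=None, *, prev: Vertex | None = None,
              max_displacement: float = 1.0,
              intensity_scale: float = 1.0) -> float:
    """Cost C(i, j) of stepping from candidate i to candidate j.

    C = λ_int (1 − Â_j) + λ_var |Â_j − Â_i| + λ_dist d(i,j)/d_max
        + λ_dir (1 − cos φ)/2 + λ_out [j outside cell]

    where Â is the intensity normalized to the sequence's robust maximum and
    φ the turning angle relative to the previous step (0 for the first step
    or after a zero-length step).  All terms lie in [0, 1]; the outside-cell
    indicator carries a deliberately heavy weight.
    """
    ai = _norm_intensity(v_i, intensity_scale)
    aj = _norm_intensity(v_j, intensity_scale)
    pi = np.asarray(v_i.position, float)
    pj = np.asarray(v_j.position, float)
    step = pj - pi
    d = float(np.linalg.norm(step))
    f_dir = 0.0
    if prev is not None:
        prev_step = pi - np.asarray(prev.position, float)
        np_prev = float(np.linalg.norm(prev_step))
        if np_prev > 0 and d > 0:
            cosphi = float(prev_step @ step) / (np_prev * d)
            f_dir = (1.0 - np.clip(cosphi, -1.0, 1.0)) / 2.0
    f_out = 0.0
    if cell_contains is not None and not cell_contains(pj):
        f_out = OUTSIDE_PENALTY
    return (weights.intensity * (1.0 - aj)
            + weights.intensity_variation * abs(aj - ai)
            + weights.distance * d / max_displacement
            + weights.direction * f_dir
            + weights.outside_cell * f_out)


def _cost_kwargs(graph: TrackGraph) -> dict:
    return dict(max_displacement=graph.max_displacement,
                intensity_scale=graph.intensity_scale)


def dp_optimal_path(graph: TrackGraph, weights: CostWeights,
                    cell_contains=None) -> Track:
    """Globally optimal source-to-last-frame path by forward recursion.

    The DP state is the (vertex, predecessor) pair so the directional term is
    exact.  Ties are broken by the lexicographically smallest candidate-index
    sequence, the same rule as :func:`brute_force_path`.  If no last-frame
    vertex is reachable the track is truncated at the furthest reachable
    frame and flagged.
    """
    kw = _cost_kwargs(graph)
    src = graph.source
    # state key: (vertex, predecessor vertex or None) -> (cost, path tuple, vertices)
    states = {(src, None): (0.0, (src.index,), [src])}
    best_by_frame = [min(states.values(), key=lambda s: (s[0], s[1]))]
    for _t in range(1, len(graph.frames)):
        nxt: dict = {}
        for (v, _prev), (cost, path, verts) in states.items():
            prev_v = verts[-2] if len(verts) >= 2 else None
            for u in graph.successors(v):
                c = cost + edge_cost(v, u, weights, cell_contains,
                                     prev=prev_v, **kw)
                key = (u, v)
                cand = (c, path + (u.index,), verts + [u])
                if key not in nxt or (cand[0], cand[1]) < (nxt[key][0],
                                                           nxt[key][1]):
                    nxt[key] = cand
        if not nxt:
            break
        states = nxt
        best_by_frame.append(min(states.values(),
                                 key=lambda s: (s[0], s[1])))
    cost, _path, verts = best_by_frame[-1]
    truncated = len(best_by_frame) < len(graph.frames)
    return Track(vertices=verts, cost=cost, truncated=truncated)


def brute_force_path(graph: TrackGraph, weights: CostWeights,
                     cell_contains=None, max_paths: int = 10 ** 6) -> Track:
    """Exhaustive enumeration oracle for :func:`dp_optimal_path`.

    Enumerates every source-to-last-frame path, computing costs by direct
    accumulation; identical tie-breaking (cost, then index sequence).
    """
    kw = _cost_kwargs(graph)
    # bound the path count first
    counts = {graph.source: 1}
    total_last = 0
    for _t in range(1, len(graph.frames)):
        nxt: dict = {}
        for v, n in counts.items():
            for u in graph.successors(v):
                nxt[u] = nxt.get(u, 0) + n
        if not nxt:
            break
        counts = nxt
        total_last = sum(counts.values())
        if total_last > max_paths:
            raise ValueError("too many paths to enumerate")

    best: tuple | None = None

    def recurse(verts, cost):
        nonlocal best
        v = verts[-1]
        if v.frame == len(graph.frames) - 1:
            key = (cost, tuple(x.index for x in verts))
            if best is None or key < (best[0], best[1]):
                best = (cost, key[1], list(verts))
            return
        prev_v = verts[-2] if len(verts) >= 2 else None
        for u in graph.successors(v):
            c = edge_cost(v, u, weights, cell_contains, prev=prev_v, **kw)
            recurse(verts + [u], cost + c)

    recurse([graph.source], 0.0)
    if best is None:
        # fall back to DP for the truncated case so behavior matches
        return dp_optimal_path(graph, weights, cell_contains)
    return Track(vertices=best[2], cost=best[0])


def detect_loss_frame(amplitudes, *, noise_std: float, background: float = 0.0,
                      k: float = 3.0, frames=None):
    """Frame F_t0 where a fading spot was last distinguishable from noise.

    A two-level step function is fitted to the amplitude series (least
    squares over all change points, equivalently maximal correlation with a
    step); the reported frame is the last one before the fitted drop whose
    amplitude stays at or above ``background + k * noise_std``.  Returns
    ``(frame or None, flag)``; a series that never crosses the threshold
    yields ``None``.
    """
    a = np.asarray(amplitudes, float)
    n = a.size
    if frames is None:
        frames = np.arange(n)
    frames = np.asarray(frames)
    if n < 3:
        return None, "too_short"
    threshold = background + k * noise_std
    vis = a >= threshold
    if vis.all():
        return None, "never_crosses"
    if not vis.any():
        return None, "never_visible"
    best_c, best_sse = 1, np.inf
    for c in range(1, n):
        hi, lo = a[:c], a[c:]
        sse = float(np.sum((hi - hi.mean()) ** 2) + np.sum((lo - lo.mean()) ** 2))
        if sse < best_sse and hi.mean() > lo.mean():
            best_sse, best_c = sse, c
    idx = np.nonzero(vis[:best_c])[0]
    if idx.size == 0:
        idx = np.nonzero(vis)[0]
    return int(frames[idx[-1]]), "ok"


# ---------------------------------------------------------------------------
# dense-grid tracking for very low PSNR
# ---------------------------------------------------------------------------

def dp_dense(responses: np.ndarray, positions: np.ndarray, source: int,
             weights: CostWeights, reach: float,
             intensity_scale: float | None = None):
    """Vectorized DP over a shared dense vertex grid (one vertex per pixel).

    ``responses`` is (T, V) filter responses at the V grid ``positions``.
    Requires ``weights.direction == 0`` so the DP state is a single vertex
    (no predecessor augmentation) and each frame transition is one matrix
    operation.  Returns ``(path indices, total cost)``.
    """
    if weights.direction != 0:
        raise ValueError("dp_dense requires weights.direction == 0; use "
                         "dp_optimal_path for directional persistence")
    T, V = responses.shape
    if intensity_scale is None:
        intensity_scale = float(np.percentile(responses, 99.9))
    scale = max(intensity_scale, 1e-12)
    ahat = np.clip(responses / scale, 0.0, 1.0)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    dist_cost = np.where(d <= reach,
                         weights.distance * d / max(reach, 1e-12), np.inf)
    G = np.full(V, np.inf)
    G[source] = 0.0
    backptr = np.empty((T - 1, V), dtype=np.int32)
    for t in range(1, T):
        tot = (G[:, None] + dist_cost
               + weights.intensity * (1.0 - ahat[t])[None, :]
               + weights.intensity_variation
               * np.abs(ahat[t][None, :] - ahat[t - 1][:, None]))
        bp = np.argmin(tot, axis=0)
        G = tot[bp, np.arange(V)]
        backptr[t - 1] = bp
    end = int(np.argmin(G))
    path = [end]
    for t in range(T - 2, -1, -1):
        path.append(int(backptr[t][path[-1]]))
    return path[::-1], float(G[end])


def track_spot_dense(frames: np.ndarray, region_mask: np.ndarray, start,
                     *, spot_sigma: float, weights: CostWeights | None = None,
                     max_displacement: float = 4.0, grid_margin: float = 1.0,
                     median_subtract: bool = True, refine: bool = True,
                     fit_window: int = 9) -> np.ndarray:
    """Track one spot through a noisy sequence on a dense pixel grid.

    Designed for the very-low-PSNR regime, where sparse detection misses the
    spot in many frames and breaks a candidate chain.  Every in-region pixel
    is a DP vertex whose intensity is the LoG response at ``spot_sigma``;
    the response of static structures (cell body, membrane ring) is removed
    by subtracting the temporal median per pixel, so only moving or fading
    structures keep signal.  Edges reach ``max_displacement + grid_margin``
    px (the margin absorbs pixel quantization of the true motion bound).
    No directional-persistence term is used: the motion model is an
    undirected bounded walk, and a vertex-state DP stays tractable on the
    dense grid.  When ``refine`` is set, each path position is replaced by
    the PSF-fit center when the fit converges within 2.5 px.

    Returns the tracked positions, shape (T, 2).
    """
    frames = np.asarray(frames, float)
    if weights is None:
        weights = CostWeights(intensity=1.0, intensity_variation=0.5,
                              distance=1.0, direction=0.0, outside_cell=10.0)
    T = frames.shape[0]
    filt = np.stack([_spots.log_filter(f, spot_sigma) for f in frames])
    if median_subtract:
        filt = filt - np.median(filt, axis=0)
    ys, xs = np.nonzero(np.asarray(region_mask, bool))
    positions = np.stack([xs, ys], axis=1).astype(float)
    responses = filt[:, ys, xs]
    source = int(np.argmin(np.linalg.norm(positions - np.asarray(start, float),
                                          axis=1)))
    path, _cost = dp_dense(responses, positions, source, weights,
                           reach=max_displacement + grid_margin)
    pos = positions[path]
    if refine:
        out = []
        for t, p in enumerate(pos):
            try:
                f = _spots.fit_gaussian(frames[t], tuple(p),
                                        window=fit_window, sigma0=spot_sigma)
            except ValueError:
                out.append(p)
                continue
            c = np.asarray(f.center)
            ok = f.converged and np.linalg.norm(c - p) <= 2.5
            out.append(c if ok else p)
        pos = np.asarray(out)
    return pos


@dataclass
class CellTracks:
    cell_index: int
    tracks: dict = field(default_factory=dict)  # channel -> list[Track]
    pairing: list = field(default_factory=list)  # (ref_spot_id, other_spot_id)
    skipped: bool = False
    flag: str = ""


def _fit_track_amplitudes(track: Track, frames_stack: np.ndarray,
                          fit_window: int, sigma0: float):
    # the spot width is known from the optics/filter scale: bound sigma
    # below by it so fits on pure noise cannot fake narrow bright spots
    bounds = (sigma0, fit_window / 2)
    amps, offs = [], []
    for v in track.vertices:
        try:
            f = _spots.fit_gaussian(frames_stack[v.frame], v.position,
                                    window=fit_window, sigma0=sigma0,
                                    sigma_bounds=bounds)
            amps.append(f.amplitude)
            offs.append(f.offset)
        except ValueError:
            amps.append(np.nan)
            offs.append(np.nan)
    track.amplitudes = np.asarray(amps)
    track.offsets = np.asarray(offs)


def track_two_spots(channel_stacks, cells, weights: CostWeights = CostWeights(),
                    *, log_sigma: float = 1.0, n_candidates: int = 12,
                    max_displacement: float = 5.0, fit_window: int = 9,
                    reference_channel: int = 0, loss_k: float = 3.0,
                    n_spots: int = 2) -> list:
    """Track up to ``n_spots`` structures per cell in each channel.

    ``channel_stacks`` is a sequence of (T, H, W) arrays (one per channel);
    ``cells`` a sequence of regions exposing ``contains(point)`` (outer
    rods).  For every cell, candidates are detected per frame inside the
    cell, one DP track is built per frame-1 detection of each channel, the
    non-reference channels' tracks are associated with the reference tracks
    by mean per-frame distance, and fitted amplitudes plus the loss frame
    F_t0 are attached to every track.  Cells with fewer than ``n_spots``
    frame-1 detections in the reference channel are skipped with a flag.
    """
    channel_stacks = [np.asarray(s, float) for s in channel_stacks]
    T = channel_stacks[0].shape[0]
    # LoG responses once per channel/frame
    logs = [np.stack([_spots.log_filter(st[t], log_sigma) for t in range(T)])
            for st in channel_stacks]
    results = []
    for ci, cell in enumerate(cells):
        contains = cell.contains if hasattr(cell, "contains") else cell
        h, w = channel_stacks[0].shape[1:]
        ys, xs = np.mgrid[0:h, 0:w]
        mask = np.asarray(contains(np.stack([xs, ys], -1).astype(float)),
                          bool)
        res = CellTracks(cell_index=ci)
        per_channel_tracks: dict = {}
        for ch, lg in enumerate(logs):
            # bright-spot convention: keep positive responses only, with a
            # relative floor that discards numerical dust on flat regions
            floor = 1e-6 * float(np.abs(lg).max())
            cands = [_spots.detect_spots(lg[t], n_candidates,
                                         min_separation=2.0, mask=mask,
                                         threshold=floor, frame=t,
                                         channel=ch)
                     for t in range(T)]
            if ch == reference_channel and len(cands[0]) < n_spots:
                res.skipped = True
                res.flag = (f"only {len(cands[0])} frame-1 candidates in "
                            f"reference channel (need {n_spots})")
                break
            if not cands[0]:
                per_channel_tracks[ch] = []
                continue
            tracks = []
            noise = estimate_noise_std(channel_stacks[ch][0])
            for sid in range(min(n_spots, len(cands[0]))):
                graph = build_graph(cands, max_displacement,
                                    source_index=sid)
                tr = dp_optimal_path(graph, weights,
                                     cell_contains=lambda p: bool(
                                         contains(np.asarray(p))))
                tr.channel = ch
                tr.spot_id = sid
                _fit_track_amplitudes(tr, channel_stacks[ch], fit_window,
                                      sigma0=log_sigma)
                amps = np.nan_to_num(tr.amplitudes, nan=0.0)
                frames_idx = tr.frames
                if tr.truncated:
                    # a spot that vanished leaves nothing to track: treat
                    # the untracked tail as zero amplitude for loss fitting
                    pad = T - len(amps)
                    amps = np.concatenate([amps, np.zeros(pad)])
                    frames_idx = np.arange(T)
                tr.loss_frame, tr.loss_flag = detect_loss_frame(
                    amps, noise_std=noise, k=loss_k, frames=frames_idx)
                tracks.append(tr)
            per_channel_tracks[ch] = tracks
        if res.skipped:
            results.append(res)
            continue
        res.tracks = per_channel_tracks
        ref_tracks = per_channel_tracks.get(reference_channel, [])
        for ch, tracks in per_channel_tracks.items():
            if ch == reference_channel or not tracks or not ref_tracks:
                continue
            # associate by mean per-frame distance (best assignment)
            res.pairing = _associate(ref_tracks, tracks)
            # loss detection in a signal channel measures the amplitude at
            # the *reference* track's positions: once a spot fades, its own
            # track latches onto residual structure, but the reference
            # protein still marks where the structure actually is
            noise = estimate_noise_std(channel_stacks[ch][0])
            for ref_sid, sid in res.pairing:
                ref_tr = ref_tracks[ref_sid]
                tr = tracks[sid]
                probe = Track(vertices=ref_tr.vertices, cost=0.0)
                _fit_track_amplitudes(probe, channel_stacks[ch], fit_window,
                                      sigma0=log_sigma)
                amps = np.nan_to_num(probe.amplitudes, nan=0.0)
                tr.loss_frame, tr.loss_flag = detect_loss_frame(
                    amps, noise_std=noise, k=loss_k, frames=ref_tr.frames)
        results.append(res)
    return results


def _associate(ref_tracks, other_tracks):
    """Match tracks across channels by minimal total mean distance."""
    from itertools import permutations

    n = min(len(ref_tracks), len(other_tracks))

    def mean_dist(a: Track, b: Track) -> float:
        ta = min(len(a.vertices), len(b.vertices))
        return float(np.mean(np.linalg.norm(
            a.positions[:ta] - b.positions[:ta], axis=1)))

    best, best_cost = None, np.inf
    for perm in permutations(range(len(other_tracks)), n):
        cost = sum(mean_dist(ref_tracks[i], other_tracks[j])
                   for i, j in zip(range(n), perm))
        if cost < best_cost:
            best_cost = cost
            best = [(ref_tracks[i].spot_id, other_tracks[j].spot_id)
                    for i, j in zip(range(n), perm)]
    return best or []
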