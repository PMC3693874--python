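"""Kymographs: time-vs-position renderings of tracked spot motion.

Two kinds are produced.  The *cell-frame* kymograph plots each spot's signed
position along the cell's center line (origin at the barycenter, off-axis
displacement discarded by orthogonal projection), one row per frame, with the
fitted amplitude as the rendered value — it shows migration relative to the
cell.  The *relative* kymograph places the two spots of a pair symmetrically
about the midline at ±d/2, where d is their euclidean separation; positions
are symmetric by construction so brightness differences (asymmetry of the two
structures) stand out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .rodscule import RodGeometry


@dataclass
class KymographMatrix:
    values: np.ndarray        # (n_frames, n_columns), raw (unsmeared)
    column_origin: int        # column index of axial coordinate 0
    kind: str                 # "cell_frame" | "relative"
    cell_id: int = 0
    channel: int = 0

    def rendered(self, smear_sigma: float = 1.0) -> np.ndarray:
        """Display version with a 1-px Gaussian smear along columns."""
        return ndi.gaussian_filter1d(self.values, smear_sigma, axis=1)

    def column_coordinates(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) - self.column_origin


def project_on_axis(point, cell: RodGeometry, direction=None):
    """Signed axial coordinate of a point in the cell's frame.

    Orthogonal projection onto the axis through the barycenter M along the
    rod orientation; ``direction`` (a unit vector, fixed at frame 1) sets the
    sign and defaults to the orientation vector.  Returns ``(s, inside)``
    where ``inside`` is False when the point lies outside the outer rod (it
    is still projected, only flagged).
    """
    p = np.asarray(point, float)
    if direction is None:
        direction = cell.outer_ellipse.axis
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    s = float((p - cell.barycenter) @ direction)
    inside = bool(cell.outer_rod.contains(p))
    return s, inside


def _amp(track, i: int) -> float:
    if track.amplitudes is not None and np.isfinite(track.amplitudes[i]):
        a = float(track.amplitudes[i])
    else:
        a = float(track.vertices[i].intensity)
    if track.loss_frame is not None and track.frames[i] > track.loss_frame:
        return 0.0
    return a


def kymo_cell_frame(tracks, cell: RodGeometry, direction=None,
                    cell_id: int = 0, channel: int = 0) -> KymographMatrix:
    """Cell-frame kymograph of one or more tracks in a cell.

    Columns span the outer rod tip-to-tip; each spot is rendered at the
    rounded column of its axial coordinate with its fitted amplitude.
    """
    if not tracks:
        raise ValueError("need at least one track")
    half = int(np.ceil(cell.outer_ellipse.semi_major)) + 1
    n_cols = 2 * half + 1
    n_rows = int(max(len(t.vertices) for t in tracks))
    mat = np.zeros((n_rows, n_cols))
    for tr in tracks:
        for i, v in enumerate(tr.vertices):
            s, _ = project_on_axis(v.position, cell, direction)
            col = int(round(s)) + half
            if 0 <= col < n_cols:
                mat[i, col] = max(mat[i, col], _amp(tr, i))
    return KymographMatrix(values=mat, column_origin=half, kind="cell_frame",
                           cell_id=cell_id, channel=channel)


def kymo_relative(track_pair, cell_id: int = 0,
                  channel: int = 0) -> KymographMatrix:
    """Relative kymograph of a spot pair: positions at ±separation/2.

    Past a track's loss frame its side is rendered with amplitude 0, so the
    fading of one structure remains visible while the geometry stays
    symmetric about the midline.
    """
    t1, t2 = track_pair
    n = min(len(t1.vertices), len(t2.vertices))
    if n == 0:
        raise ValueError("tracks share no frames")
    seps = np.linalg.norm(t1.positions[:n] - t2.positions[:n], axis=1)
    half = int(np.ceil(seps.max() / 2.0)) + 2
    n_cols = 2 * half + 1
    mat = np.zeros((n, n_cols))
    for i in range(n):
        d2 = seps[i] / 2.0
        for tr, sgn in ((t1, -1.0), (t2, +1.0)):
            col = int(round(sgn * d2)) + half
            if 0 <= col < n_cols:
                mat[i, col] = max(mat[i, col], _amp(tr, i))
    return KymographMatrix(values=mat, column_origin=half, kind="relative",
                           cell_id=cell_id, channel=channel)
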