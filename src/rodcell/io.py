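"""File I/O and configuration: TIFF stacks in, tab-delimited tables out."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end pipeline, serializable as key=value text.

    Physical quantities are in micrometers (``pixel_size`` per px); all other
    lengths are pixels.
    """

    pixel_size: float = 0.1             # um / px
    diffraction_limit: float = 0.25     # um
    log_sigma: float = 1.0              # px, LoG scale ~ spot size
    n_spots_per_cell: int = 2
    n_cells: int = 1
    fit_window: int = 9
    max_displacement: float = 5.0       # px / frame
    lambda_intensity: float = 1.0
    lambda_intensity_variation: float = 0.5
    lambda_distance: float = 0.5
    lambda_direction: float = 0.25
    lambda_outside_cell: float = 10.0
    loss_k: float = 3.0
    default_width: float = 14.0         # px, rod initialization
    init_margin: float = 6.0            # px beyond each spot
    grad_tol: float = 1e-4
    max_iter: int = 500
    max_pair_distance: float = 80.0     # px, spot pairing for initialization
    seed: int = 0
    output_dir: str = "rodcell_out"

    def __post_init__(self):
        for name in ("pixel_size", "diffraction_limit", "log_sigma",
                     "max_displacement", "default_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_file(self, path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            cur = getattr(defaults, key)
            kwargs[key] = type(cur)(val.strip())
        return cls(**kwargs)


def read_stack(path, axes: str | None = None):
    """Read a grayscale 8/16-bit TIFF stack.

    Returns ``(array, axes)``; axes are taken from the TIFF metadata unless
    declared, with 2D data mapped to "YX" and plain multi-page stacks to
    "TYX".  Color (RGB/samples) images are rejected.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        meta_axes = series.axes
    if "S" in meta_axes or data.ndim >= 3 and data.shape[-1] in (3, 4) and \
            meta_axes.endswith("S"):
        raise ValueError("unsupported axis 'S': color (RGB) input is not "
                         "grayscale")
    if axes is None:
        axes = meta_axes
        if data.ndim == 3 and axes in ("QYX", "IYX"):
            axes = "TYX"
    if len(axes) != data.ndim:
        raise ValueError(f"declared axes {axes!r} do not match data with "
                         f"{data.ndim} dimensions")
    for ax in axes:
        if ax not in "TZCYX":
            raise ValueError(f"unsupported axis {ax!r}")
    return data, axes


def write_stack(path, data: np.ndarray, *, bit_depth: int = 8) -> None:
    """Write an image or stack as 8/16-bit grayscale TIFF (rounded,
    clipped)."""
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.clip(np.round(np.asarray(data, float)), 0,
                  2 ** bit_depth - 1).astype(dtype)
    tifffile.imwrite(str(path), arr)


def write_kymograph(path, kymo) -> None:
    """Save a kymograph as 32-bit float TIFF (path) and a .txt matrix."""
    tifffile.imwrite(str(path), kymo.rendered().astype(np.float32))
    np.savetxt(str(Path(path).with_suffix(".txt")), kymo.values,
               delimiter="\t", fmt="%.6g")


@dataclass
class ResultsTable:
    """Per-cell and per-spot result tables of one pipeline run."""

    cells: pd.DataFrame
    spots: pd.DataFrame


def write_results(table: ResultsTable, directory) -> dict:
    """Write the result tables as tab-delimited text with headers.

    Values use a decimal point and 6 significant digits; positions are given
    both in px and (when scaled by the caller) in um columns already present.
    Returns the paths written.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("cells", table.cells), ("spots", table.spots)):
        p = d / f"{name}.txt"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p
    return paths


def read_results(directory) -> ResultsTable:
    d = Path(directory)
    return ResultsTable(cells=pd.read_csv(d / "cells.txt", sep="\t"),
                        spots=pd.read_csv(d / "spots.txt", sep="\t"))


def write_ground_truth(path, truth) -> None:
    """Tab-delimited ground-truth sidecar for a phantom scene."""
    lines = ["kind\tid\tframe\tx\ty\tamplitude\tsigma\tlength\twidth\tangle"]
    for i, cs in enumerate(truth.get("cell_specs", [])):
        lines.append(f"cell\t{i}\t0\t{cs.center[0]:.4f}\t{cs.center[1]:.4f}"
                     f"\t\t\t{cs.length:.4f}\t{cs.width:.4f}"
                     f"\t{cs.orientation:.6f}")
    for i, (pos, amp, sig) in enumerate(truth.get("spots", [])):
        lines.append(f"spot\t{i}\t0\t{pos[0]:.4f}\t{pos[1]:.4f}\t{amp:.4f}"
                     f"\t{sig:.4f}\t\t\t")
    Path(path).write_text("\n".join(lines) + "\n")
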