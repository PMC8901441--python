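"""Image-stack container and TIFF I/O.

All pixel data are kept as counts (photon or camera counts). Stacks are
stored in memory as ``float64`` arrays of shape ``(frames, rows, cols)``
and written to disk as 16-bit multi-page TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """A fluorescence image stack with acquisition metadata.

    Parameters
    ----------
    data:
        Pixel array, shape ``(frames, rows, cols)``. A 2-D array is
        promoted to a single-frame stack.
    pixel_size_nm:
        Lateral pixel size in nanometres (default 100, typical for an
        EM-CCD TIRF setup at 100x magnification).
    frame_interval:
        Time between frames. Units are carried by convention (ms for
        bleaching movies, min for live-cell time series).
    channel:
        Free-text channel label.
    z_interval_nm:
        Axial plane spacing when the frames axis is a z-stack.
    """

    data: np.ndarray
    pixel_size_nm: float = 100.0
    frame_interval: float | None = None
    channel: str = ""
    z_interval_nm: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[np.newaxis, ...]
        if arr.ndim != 3:
            raise ValueError(f"stack must be 2-D or 3-D, got ndim={arr.ndim}")
        if arr.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if np.any(arr < 0):
            raise ValueError("stack intensities must be non-negative")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_stack(
    path: str | Path,
    pixel_size_nm: float = 100.0,
    channel: int | None = None,
    **metadata,
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Colour (RGB/RGBA) TIFFs are rejected unless ``channel`` selects one
    colour plane; the analysis operates on single-channel count data.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"could not read TIFF stack {path!s}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        # trailing colour axis (RGB/RGBA)
        if channel is None:
            raise ValueError(
                f"{path!s} is a colour image; pass channel=<index> to select one plane"
            )
        arr = arr[..., channel]
    return ImageStack(arr, pixel_size_nm=pixel_size_nm, **metadata)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as 16-bit multi-page TIFF (values clipped/rounded)."""
    path = Path(path)
    data = np.clip(np.rint(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path
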