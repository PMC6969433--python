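"""Image-stack container and TIFF I/O.

A :class:`FrameStack` is the raw observable of a single-molecule TIRFM
experiment: a time series of wide-field camera frames, with the pixel pitch
and frame interval needed to convert between pixels/frames and nm/seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["FrameStack", "read_stack", "write_stack"]

#: EMCCD pixel pitch in the object plane, nm per pixel.
DEFAULT_PIXEL_NM = 220.0
#: Camera integration time, seconds per frame.
DEFAULT_FRAME_INTERVAL_S = 1.0


@dataclass
class FrameStack:
    """A movie: ``(n_frames, height, width)`` non-negative intensities.

    Parameters
    ----------
    data
        3D array of intensities; finite and >= 0.
    pixel_nm
        Physical size of one camera pixel in the object plane (nm).
    frame_interval_s
        Time between consecutive frames (s).
    """

    data: np.ndarray
    pixel_nm: float = DEFAULT_PIXEL_NM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    n_clipped_emitters: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (t, y, x), got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one frame")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("stack intensities must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(height, width)``."""
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


def write_stack(path, stack: FrameStack) -> None:
    """Write a stack as a multi-frame 16-bit TIFF (values clipped to uint16)."""
    data = np.clip(np.round(stack.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "pixel_nm": stack.pixel_nm,
            "frame_interval_s": stack.frame_interval_s,
        },
    )


def read_stack(
    path,
    pixel_nm: float = DEFAULT_PIXEL_NM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> FrameStack:
    """Read a multi-frame TIFF into a :class:`FrameStack`.

    Pixel pitch and frame interval are taken from the arguments; TIFF
    metadata written by :func:`write_stack` overrides them when present.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    pixel_nm = float(meta.get("pixel_nm", pixel_nm))
    frame_interval_s = float(meta.get("frame_interval_s", frame_interval_s))
    return FrameStack(
        data.astype(np.float64), pixel_nm=pixel_nm, frame_interval_s=frame_interval_s
    )
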