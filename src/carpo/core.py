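"""Shared containers and the bone-class labelling scheme.

Label maps use ``0`` for background and the integer codes below for the
eight segmented structures of the wrist (distal forearm, proximal and
distal carpal rows).  All image arrays are ``(H, W)`` row-major with the
origin at the top-left corner; pixel ``(r, c)`` has its center at
``x = c, y = r`` in pixel units and ``(c * spacing, r * spacing)`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Bone class codes, in the conventional reading order of the wrist.
RADIUS = 1
ULNA = 2
SCAPHOID = 3
LUNATE = 4
TRIQUETRUM = 5
HAMATE = 6
CAPITATE = 7
TRAPEZIUM_TRAPEZOID = 8

CLASS_NAMES = {
    0: "background",
    RADIUS: "distal radius",
    ULNA: "distal ulna",
    SCAPHOID: "scaphoid",
    LUNATE: "lunate",
    TRIQUETRUM: "triquetrum",
    HAMATE: "hamate",
    CAPITATE: "capitate",
    TRAPEZIUM_TRAPEZOID: "trapezium and trapezoid",
}

FOREGROUND_CLASSES = tuple(range(1, 9))
N_CLASSES = 8  # foreground bone classes
FOREARM_CLASSES = (RADIUS, ULNA)
PROXIMAL_ROW = (SCAPHOID, LUNATE, TRIQUETRUM)
DISTAL_ROW = (HAMATE, CAPITATE, TRAPEZIUM_TRAPEZOID)


@dataclass
class ImageSequence:
    """Ordered stack of 2D intensity frames with acquisition geometry.

    Parameters
    ----------
    frames : ndarray, shape (n, H, W)
        Grayscale intensities, one 2D frame per time point.
    pixel_spacing_mm : float
        In-plane isotropic pixel size in millimetres per pixel.
    frame_interval_ms : float
        Time between consecutive frames in milliseconds.
    """

    frames: np.ndarray
    pixel_spacing_mm: float
    frame_interval_ms: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.pixel_spacing_mm <= 0 or self.frame_interval_ms <= 0:
            raise ValueError("pixel spacing and frame interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        """Timestamp of each frame in ms (first frame at t = 0)."""
        return np.arange(len(self)) * float(self.frame_interval_ms)


def validate_label_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is an integer label map with values in 0..8."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2D")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must have an integer dtype")
    if mask.min() < 0 or mask.max() > N_CLASSES:
        raise ValueError("label values must lie in {0,...,8}")
    return mask
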