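"""Reading and writing of image sequences, masks, annotations and configs.

Supported sequence formats: multi-page TIFF, NIfTI (2D+t volumes, via
nibabel), and directories of single-frame DICOM files (via pydicom).
Label-mask sequences round-trip through integer-typed TIFF/NIfTI.
Polygon annotations are JSON objects ``{class_id: [[x, y], ...]}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import ImageSequence
from .preprocess import PolygonAnnotation

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_mask_sequence",
    "write_mask_sequence",
    "read_annotation",
    "write_annotation",
]


def _read_tiff(path: Path) -> np.ndarray:
    import tifffile
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        return data.T[None]
    if data.ndim == 3:  # (x, y, t) -> (t, y, x)
        return data.transpose(2, 1, 0)
    raise ValueError(f"unsupported NIfTI dimensionality {data.ndim}")


def _read_dicom_dir(path: Path) -> tuple[np.ndarray, float | None, float | None]:
    import pydicom
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    frames, spacing, interval = [], None, None
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    for ds in datasets:
        frames.append(ds.pixel_array.astype(np.float32))
        if spacing is None and hasattr(ds, "PixelSpacing"):
            spacing = float(ds.PixelSpacing[0])
        if interval is None and hasattr(ds, "FrameTime"):
            interval = float(ds.FrameTime)
    return np.stack(frames), spacing, interval


def read_sequence(path: str | Path, pixel_spacing_mm: float | None = None,
                  frame_interval_ms: float | None = None) -> ImageSequence:
    """Load a 2D+t sequence from TIFF, NIfTI, or a DICOM directory.

    Geometry metadata absent from the file (TIFF has none) must be
    supplied via the keyword arguments; values in the file are used as
    defaults otherwise.
    """
    path = Path(path)
    spacing_file = interval_file = None
    if path.is_dir():
        frames, spacing_file, interval_file = _read_dicom_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        frames = _read_tiff(path)
    elif path.suffix.lower() in (".nii", ".gz"):
        frames = _read_nifti(path)
    else:
        raise ValueError(f"unrecognized sequence format: {path}")
    spacing = pixel_spacing_mm or spacing_file
    interval = frame_interval_ms or interval_file
    if spacing is None or interval is None:
        raise ValueError("pixel_spacing_mm and frame_interval_ms are required "
                         "when the file carries no geometry metadata")
    return ImageSequence(np.asarray(frames, dtype=np.float32), spacing, interval)


def write_sequence(path: str | Path, seq: ImageSequence) -> None:
    """Write frames as multi-page TIFF (.tif) or NIfTI (.nii)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, seq.frames.astype(np.float32),
                         photometric="minisblack")
    elif path.suffix.lower() == ".nii":
        import nibabel as nib
        affine = np.diag([seq.pixel_spacing_mm, seq.pixel_spacing_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(seq.frames.transpose(2, 1, 0), affine), str(path))
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


def write_mask_sequence(path: str | Path, masks: np.ndarray,
                        pixel_spacing_mm: float = 1.0) -> None:
    path = Path(path)
    masks = np.asarray(masks, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, masks, photometric="minisblack")
    elif path.suffix.lower() == ".nii":
        import nibabel as nib
        affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(masks.transpose(2, 1, 0), affine), str(path))
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")


def read_mask_sequence(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = _read_tiff(path)
    else:
        arr = _read_nifti(path)
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.rint(arr).astype(np.uint8)
    return arr.astype(np.uint8)


def read_annotation(path: str | Path) -> PolygonAnnotation:
    data = json.loads(Path(path).read_text())
    return PolygonAnnotation({int(k): np.asarray(v, dtype=float)
                              for k, v in data.items()})


def write_annotation(path: str | Path, ann: PolygonAnnotation) -> None:
    Path(path).write_text(json.dumps(
        {str(k): np.asarray(v).tolist() for k, v in ann.polygons.items()}))
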