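"""Image input/output: 8-bit grayscale PNG/TIFF, plus an optional DICOM
adapter that window-levels a CT slice to 8 bits."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .exceptions import InvalidParameterError

__all__ = ["load_gray_image", "save_gray_image", "dicom_to_gray"]


def dicom_to_gray(path, window_center: float = -600.0,
                  window_width: float = 1500.0) -> np.ndarray:
    """Read a DICOM slice and window-level it to an 8-bit grayscale array.

    Defaults correspond to a standard lung window (center -600 HU, width
    1500 HU).  Requires ``pydicom``.
    """
    try:
        import pydicom
    except ImportError as e:  # pragma: no cover
        raise InvalidParameterError("DICOM support requires pydicom") from e
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    lo = window_center - window_width / 2.0
    scaled = np.clip((hu - lo) / window_width, 0.0, 1.0)
    return np.rint(scaled * 255).astype(np.uint8)


def load_gray_image(path, window_center: float = -600.0,
                    window_width: float = 1500.0) -> np.ndarray:
    """Load an image as 8-bit grayscale (PNG/TIFF; .dcm via the adapter)."""
    p = Path(path)
    if not p.exists():
        raise IOError(f"cannot read image: no such file {p}")
    if p.suffix.lower() in (".dcm", ".dicom"):
        return dicom_to_gray(p, window_center, window_width)
    arr = iio.imread(p)
    if arr.ndim == 3:  # collapse RGB(A) via luminance
        arr = np.rint(arr[..., :3].astype(float) @ [0.299, 0.587, 0.114])
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255)
    return arr.astype(np.uint8)


def save_gray_image(path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        if arr.max() <= 1:  # binary mask convenience
            arr = (arr * 255).astype(np.uint8)
        else:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)
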