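"""Reading, writing and labeling of nucleus segmentation masks.

Masks are plain 2-D ``numpy`` arrays.  A *binary mask* contains only {0, 1}
(foreground = nucleus pixels); an *instance mask* contains non-negative
integers where 0 is background and each value ``1..n`` identifies one
nucleus.  Binary segmentation output is turned into instances with
8-connected component labeling, mirroring the classical
connected-components step applied to a binary network output.
"""

from __future__ import annotations

import os
from typing import Literal

import numpy as np
from scipy import ndimage

#: Physical pixel size of the slide scans this workflow was designed for.
DEFAULT_UM_PER_PIXEL: float = 0.25

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def validate_binary_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is a valid 2-D {0,1} array and return it as uint8."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"binary mask must be 2-D and non-empty, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("binary mask must contain only 0 and 1")
    return arr.astype(np.uint8, copy=False)


def validate_instance_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is 2-D with contiguous labels {0..n}; return int32."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"instance mask must be 2-D and non-empty, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.mod(arr, 1) == 0):
            raise ValueError("instance mask must hold integer labels")
    arr = arr.astype(np.int32, copy=False)
    if arr.min() < 0:
        raise ValueError("instance mask labels must be non-negative")
    labels = np.unique(arr)
    labels = labels[labels > 0]
    if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
        raise ValueError("instance mask labels must be contiguous 1..n")
    return arr


def n_objects(mask: np.ndarray) -> int:
    """Number of distinct nonzero labels in an instance mask."""
    return int(np.asarray(mask).max())


def relabel_sequential(mask: np.ndarray) -> np.ndarray:
    """Map the nonzero values of ``mask`` onto contiguous labels 1..n.

    Original label order (ascending value) is preserved, so e.g. labels
    {0, 3, 9} become {0, 1, 2}.
    """
    arr = np.asarray(mask)
    labels = np.unique(arr)
    labels = labels[labels > 0]
    lut = np.zeros(int(arr.max()) + 1 if arr.size else 1, dtype=np.int32)
    lut[labels.astype(np.int64)] = np.arange(1, labels.size + 1, dtype=np.int32)
    return lut[arr.astype(np.int64)]


def _collapse_channels(arr: np.ndarray, path: str) -> np.ndarray:
    """Reduce an HxWxC raster to a single channel if channels are identical."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop a fully-opaque alpha channel
            alpha = arr[..., 3]
            if np.all(alpha == alpha.flat[0]):
                arr = arr[..., :3]
        if arr.shape[2] == 1:
            return arr[..., 0]
        if all(np.array_equal(arr[..., 0], arr[..., c]) for c in range(1, arr.shape[2])):
            return arr[..., 0]
        raise ValueError(f"{path}: multi-channel image with differing channels is not a mask")
    raise ValueError(f"{path}: expected a 2-D raster, got shape {arr.shape}")


def read_mask(path: str | os.PathLike, mode: Literal["binary", "instance"]) -> np.ndarray:
    """Read a mask raster from PNG/TIFF.

    Parameters
    ----------
    path:
        Single-channel (or channel-constant) 8/16-bit raster.
    mode:
        ``"binary"`` maps every nonzero pixel to 1; ``"instance"``
        relabels nonzero values onto contiguous ``1..n``.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    arr = _collapse_channels(arr, str(path))
    if mode == "binary":
        return (arr != 0).astype(np.uint8)
    if mode == "instance":
        return relabel_sequential(arr)
    raise ValueError(f"unknown mode {mode!r}; expected 'binary' or 'instance'")


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a mask losslessly as single-channel PNG or TIFF.

    8-bit output when the largest label fits in a byte, 16-bit otherwise.
    """
    import imageio.v3 as iio

    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    top = int(arr.max()) if arr.size else 0
    if top > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored losslessly")
    dtype = np.uint8 if top <= np.iinfo(np.uint8).max else np.uint16
    iio.imwrite(path, arr.astype(dtype))


def label_connected_components(mask: np.ndarray) -> np.ndarray:
    """Label maximal 8-connected foreground regions of a binary mask.

    Labels are assigned ``1..n`` in raster-scan order of each component's
    first pixel, which makes the output deterministic across runs.
    """
    binary = validate_binary_mask(mask)
    labeled, _ = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    return labeled.astype(np.int32)
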