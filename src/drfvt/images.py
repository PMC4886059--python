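"""Silhouette image loading and preprocessing.

Images enter the pipeline as binary masks (foreground = the shape).  PNG
and PGM files are read through Pillow; any pixel above a grey-level
threshold is foreground, with an ``invert`` flag for dark-on-light
sketches.  Freehand strokes are optionally consolidated into a filled
region (morphological closing followed by hole filling) so the boundary
tracer sees one closed silhouette even when the drawing has small gaps.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["load_silhouette", "binarize", "fill_strokes", "save_silhouette"]


def binarize(pixels: np.ndarray, threshold: int = 127,
             invert: bool = False) -> np.ndarray:
    """Threshold a grey-level array to a boolean foreground mask."""
    arr = np.asarray(pixels)
    mask = arr > threshold
    return ~mask if invert else mask


def load_silhouette(path, threshold: int = 127,
                    invert: bool = False) -> np.ndarray:
    """Read a PNG or PGM image as a boolean foreground mask."""
    with Image.open(path) as im:
        grey = np.asarray(im.convert("L"))
    return binarize(grey, threshold=threshold, invert=invert)


def save_silhouette(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG/PGM (foreground = 255)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def fill_strokes(mask: np.ndarray, closing_radius: int = 1,
                 fill_holes: bool = True) -> np.ndarray:
    """Convert an outline drawing into a filled silhouette.

    Morphological closing with a square footprint of half-width
    ``closing_radius`` bridges gaps up to ``2 * closing_radius`` pixels
    in a stroke (a square, unlike a cross/disk footprint, also bridges
    gaps in axis-aligned strokes); hole filling then floods the
    interior.  A mask that is already a filled region passes through
    unchanged (up to the closing of pixel-scale concavities).
    ``closing_radius=0`` skips the closing step.
    """
    mask = np.asarray(mask, dtype=bool)
    if closing_radius > 0:
        size = 2 * closing_radius + 1
        mask = ndimage.binary_closing(mask, structure=np.ones((size, size),
                                                              dtype=bool))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask
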