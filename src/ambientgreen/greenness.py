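"""Green chromatic coordinate ("greenness index") computation.

The index of a pixel is G / (R + G + B): the share of the green channel in
the total 8-bit intensity. An image's greenness is the arithmetic mean of
this ratio over all pixels with a positive channel sum; pure black pixels
(R = G = B = 0) have an undefined ratio and are excluded from the mean (the
exclusion count is reported). Channels are used exactly as decoded — 8-bit
sRGB values with no gamma linearization, white-balance or other correction.

Two implementation notes that matter for correctness:

* the ratio is taken per pixel and then averaged — NOT the ratio of the
  channel means. The two differ on any image whose brightness covaries with
  hue, and only the per-pixel form tracks vegetation color faithfully.
* grayscale inputs are expanded to R = G = B (index exactly 1/3); an alpha
  channel, if present, is dropped before computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "EXCLUDED",
    "GreennessObservation",
    "pixel_greenness",
    "image_greenness",
    "corpus_greenness",
    "load_image_rgb",
]

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`pixel_greenness` for an all-zero pixel.
EXCLUDED = None


@dataclass(frozen=True)
class GreennessObservation:
    """Greenness of one image, labelled for aggregation."""

    record_id: str
    park: str
    year: int
    month: int  # 1..12
    greenness: float
    n_pixels_used: int
    n_pixels_excluded: int


def pixel_greenness(pixel: Sequence[int]) -> float | None:
    """Greenness of a single (R, G, B) pixel.

    Returns ``G / (R + G + B)``, or :data:`EXCLUDED` (``None``) when the
    channel sum is zero, where the ratio is undefined.
    """
    r, g, b = (int(c) for c in pixel)
    for c in (r, g, b):
        if not 0 <= c <= 255:
            raise ValueError(f"channel value {c} outside [0, 255]")
    s = r + g + b
    if s == 0:
        return EXCLUDED
    return g / s


def image_greenness(pixels: np.ndarray) -> tuple[float, int, int]:
    """Mean per-pixel greenness of an RGB pixel array.

    Parameters
    ----------
    pixels
        Array of shape ``(..., 3)`` holding R, G, B in the last axis
        (any integer or float dtype; values are treated as given).

    Returns
    -------
    (greenness, n_used, n_excluded)
        Mean of ``G/(R+G+B)`` over pixels with positive channel sum, the
        number of pixels used, and the number excluded (zero channel sum).

    Raises
    ------
    ValueError
        If no pixel has a positive channel sum ("no valid pixels").
    """
    arr = np.asarray(pixels)
    if arr.ndim < 1 or arr.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) RGB array, got shape {arr.shape}")
    flat = arr.reshape(-1, 3).astype(np.float64)
    total = flat.sum(axis=1)
    valid = total > 0
    n_used = int(valid.sum())
    n_excluded = flat.shape[0] - n_used
    if n_used == 0:
        raise ValueError("no valid pixels: image is entirely black")
    ratios = flat[valid, 1] / total[valid]
    return float(ratios.mean()), n_used, n_excluded


def load_image_rgb(path: str | Path) -> np.ndarray:
    """Decode an image file to an ``(H, W, 3)`` uint8 RGB array.

    Grayscale images are expanded to R = G = B; alpha channels are dropped.
    Pillow's ``convert("RGB")`` implements both conventions exactly.
    """
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def corpus_greenness(
    records: Iterable,
    image_root: str | Path | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Compute the greenness index for every decodable record of a corpus.

    Parameters
    ----------
    records
        Iterable of manifest records (anything with ``record_id``, ``park``,
        ``timestamp`` and ``filepath`` attributes, e.g.
        :class:`ambientgreen.corpus.ImageRecord`).
    image_root
        Directory that relative ``filepath`` entries are resolved against.

    Returns
    -------
    (observations, errors)
        ``observations`` is a DataFrame with one row per decodable record
        (columns ``record_id, park, year, month, greenness, n_pixels_used,
        n_pixels_excluded``); ``errors`` lists ``(record_id, reason)`` for
        records that could not be decoded.

    Raises
    ------
    ValueError
        If no record at all could be decoded.
    """
    root = Path(image_root) if image_root is not None else None
    rows: list[GreennessObservation] = []
    errors: list[tuple[str, str]] = []
    for rec in records:
        path = Path(rec.filepath)
        if root is not None and not path.is_absolute():
            path = root / path
        try:
            arr = load_image_rgb(path)
            value, n_used, n_excl = image_greenness(arr)
        except (OSError, ValueError) as exc:
            logger.debug("skipping %s: %s", rec.record_id, exc)
            errors.append((rec.record_id, str(exc)))
            continue
        ts = rec.timestamp
        rows.append(
            GreennessObservation(
                record_id=rec.record_id,
                park=rec.park,
                year=ts.year,
                month=ts.month,
                greenness=value,
                n_pixels_used=n_used,
                n_pixels_excluded=n_excl,
            )
        )
    if not rows:
        raise ValueError("no decodable records in corpus")
    df = pd.DataFrame([vars(o) for o in rows])
    return df, errors
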