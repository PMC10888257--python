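"""Bead-array image pipeline: registration, segmentation, mask propagation,
and per-bead intensity extraction.

Conventions
-----------
* All coordinates are 0-based ``(row, col) = (y, x)``; TIFF origin is the
  top-left pixel.
* A shift ``(dy, dx)`` maps the reference round into the moving round:
  ``translate(reference, dy, dx) ~= moving``.
* Rounds are named ``scan1`` (first probing) and ``dyeswitch`` (second
  probing with fluorophores swapped between alleles); channels are
  ``brightfield``, ``ch1``, ``ch2``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table

logger = logging.getLogger(__name__)

ROUNDS = ("scan1", "dyeswitch")
CHANNELS = ("brightfield", "ch1", "ch2")

#: fixed page order used when a BeadImageSet is written to multi-page TIFF
PAGE_ORDER = tuple((r, c) for r in ROUNDS for c in CHANNELS)

INTENSITY_COLUMNS = ("ch1_scan1", "ch2_scan1", "ch1_dyeswitch", "ch2_dyeswitch")
BEAD_TABLE_COLUMNS = ("bead_id", "y", "x", "area") + INTENSITY_COLUMNS


@dataclass
class BeadImageSet:
    """Two probing rounds x three channels of one bead-array field."""

    images: dict[tuple[str, str], np.ndarray]
    pixel_size: float | None = None  # micrometres per pixel, optional

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"all images must share one shape, got {shapes}")
        for key in PAGE_ORDER:
            if key not in self.images:
                raise ValueError(f"missing image for (round, channel) = {key}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.images[key]

    def save_tiff(self, path) -> None:
        """Write the six planes as multi-page TIFF in :data:`PAGE_ORDER`."""
        meta = json.dumps({"pages": [list(k) for k in PAGE_ORDER],
                           "pixel_size": self.pixel_size})
        with tifffile.TiffWriter(path) as tif:
            for i, key in enumerate(PAGE_ORDER):
                tif.write(self.images[key].astype(np.float32),
                          description=meta if i == 0 else None)

    @classmethod
    def load_tiff(cls, path) -> "BeadImageSet":
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
            desc = tif.pages[0].description
        order = PAGE_ORDER
        pixel_size = None
        if desc:
            try:
                meta = json.loads(desc)
                order = tuple(tuple(k) for k in meta["pages"])
                pixel_size = meta.get("pixel_size")
            except (json.JSONDecodeError, KeyError):
                pass
        if len(pages) != len(order):
            raise ValueError(
                f"expected {len(order)} TIFF pages, found {len(pages)}")
        return cls(dict(zip(order, pages)), pixel_size=pixel_size)


@dataclass
class RegistrationResult:
    """Integer-pixel translation between two rounds.

    ``accepted`` is False when the estimated shift exceeds ``max_shift``
    (such image pairs are discarded upstream rather than force-aligned).
    """

    dy: int
    dx: int
    peak_correlation: float
    accepted: bool
    max_shift: int = 500

    @property
    def shift(self) -> tuple[int, int]:
        return (self.dy, self.dx)


def translate(image: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Translate by whole pixels, filling vacated area with ``fill``."""
    out = np.full_like(image, fill)
    h, w = image.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = image[ys_src, xs_src]
    return out


def _overlap_ncc(reference: np.ndarray, moving: np.ndarray, dy: int, dx: int,
                 min_overlap: int = 16) -> float:
    """Normalized correlation of the overlapping region at a candidate shift."""
    h, w = reference.shape
    ref = reference[max(dy, 0) - dy if dy < 0 else 0:, :]
    # slice overlap explicitly: reference index r maps to moving index r + dy
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    if (r1 - r0) < min_overlap or (c1 - c0) < min_overlap:
        return -np.inf
    a = reference[r0:r1, c0:c1].ravel()
    b = moving[r0 + dy:r1 + dy, c0 + dx:c1 + dx].ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -np.inf
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))


def register_rounds(reference: np.ndarray, moving: np.ndarray,
                    max_shift: int = 500) -> RegistrationResult:
    """Estimate the integer translation between two brightfield images.

    The translation maximising the normalized cross-correlation is found via
    FFT cross-correlation; the circular wrap-around ambiguity is resolved by
    re-scoring the candidate shifts on the actual (non-periodic) overlap.
    Pairs needing more than ``max_shift`` pixels of correction are flagged
    ``accepted=False`` and should be discarded.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError("images must have the same shape")
    if reference.std() == 0 or moving.std() == 0:
        raise ValueError("constant image: normalized correlation undefined")

    h, w = reference.shape
    a = (reference - reference.mean()) / reference.std()
    b = (moving - moving.mean()) / moving.std()
    corr = np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b)).real / a.size
    ky, kx = np.unravel_index(np.argmax(corr), corr.shape)

    best = (-np.inf, 0, 0)
    for dy in (ky, ky - h):
        for dx in (kx, kx - w):
            score = _overlap_ncc(reference, moving, dy, dx)
            if score > best[0]:
                best = (score, dy, dx)
    peak, dy, dx = best
    if not math.isfinite(peak):  # no usable overlap at any candidate
        peak, dy, dx = float(corr[ky, kx]), int(ky), int(kx)
    accepted = max(abs(dy), abs(dx)) <= max_shift
    return RegistrationResult(dy=int(dy), dx=int(dx),
                              peak_correlation=float(peak),
                              accepted=accepted, max_shift=max_shift)


def _atrous_smooth(image: np.ndarray, level: int) -> np.ndarray:
    """B3-spline 'a trous' smoothing at the given dyadic scale."""
    kernel = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    out = image
    for j in range(level):
        step = 2 ** j
        k = np.zeros(4 * step + 1)
        k[::step] = kernel
        out = ndimage.convolve1d(out, k, axis=0, mode="reflect")
        out = ndimage.convolve1d(out, k, axis=1, mode="reflect")
    return out


def _detail_noise_gain(level: int) -> float:
    """Std-dev gain of the detail filter (identity - smooth) on white noise.

    Computed exactly from the impulse response of the cumulative B3-spline
    smoothing at the given level; cached per level.
    """
    if level not in _GAIN_CACHE:
        n = 4 * (2 ** level)  # comfortably covers the kernel support
        delta = np.zeros((2 * n + 1, 2 * n + 1))
        delta[n, n] = 1.0
        filt = delta - _atrous_smooth(delta, level)
        _GAIN_CACHE[level] = float(np.sqrt((filt ** 2).sum()))
    return _GAIN_CACHE[level]


_GAIN_CACHE: dict[int, float] = {}


def segment_beads(brightfield: np.ndarray,
                  min_area: float | None = None,
                  max_area: float | None = None,
                  bead_radius: float | None = None,
                  method: str = "wavelet",
                  levels: int = 3,
                  threshold_k: float = 5.0) -> np.ndarray:
    """Segment beads in a brightfield image into a labelled mask.

    ``method="wavelet"`` (default) subtracts the coarse stationary-wavelet
    (à-trous B3 spline) background and thresholds the detail image at
    ``threshold_k`` noise standard deviations. The noise level is estimated
    from the first-level detail coefficients (robust MAD, rescaled by the
    exact white-noise gain of each detail filter) so it is not inflated by
    the beads themselves even on densely covered fields. ``method="otsu"``
    is a plain global-threshold fallback. Connected components outside
    ``[min_area, max_area]`` are removed. When a ``bead_radius`` is given
    and the area bounds are not, they default to disks of 0.5x and 1.5x
    that radius.
    """
    img = np.asarray(brightfield, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("brightfield image contains non-finite values")
    if min_area is None:
        min_area = math.pi * (0.5 * bead_radius) ** 2 if bead_radius else 1.0
    if max_area is None:
        max_area = math.pi * (1.5 * bead_radius) ** 2 if bead_radius else np.inf

    if method == "wavelet":
        detail = img - _atrous_smooth(img, levels)
        d1 = img - _atrous_smooth(img, 1)
        noise_sd = 1.4826 * np.median(np.abs(d1)) / _detail_noise_gain(1)
        binary = detail > threshold_k * noise_sd * _detail_noise_gain(levels)
        if not binary.any():
            return np.zeros(img.shape, dtype=np.int32)
    elif method == "otsu":
        if img.min() == img.max():
            return np.zeros(img.shape, dtype=np.int32)
        binary = img > threshold_otsu(img)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    if n == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero((areas >= min_area) & (areas <= max_area)) + 1
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    return relabel[labels]


def propagate_mask(mask: np.ndarray, registration: RegistrationResult,
                   other_mask: np.ndarray, overlap_min: float = 0.5
                   ) -> tuple[np.ndarray, pd.Series]:
    """Translate a label mask onto the other round and match beads.

    Returns the shifted label image and a boolean Series (indexed by bead
    label) that is True where the translated bead footprint overlaps the
    other round's foreground by at least ``overlap_min`` of its area.
    """
    if not registration.accepted:
        raise ValueError("registration was not accepted; discard this pair")
    shifted = translate(mask, registration.dy, registration.dx, fill=0)
    labels = np.arange(1, mask.max() + 1)
    if labels.size == 0:
        return shifted, pd.Series(dtype=bool)
    areas = np.bincount(mask.ravel(), minlength=mask.max() + 1)[1:]
    fg = other_mask > 0
    overlap = np.bincount(shifted[fg].ravel(), minlength=mask.max() + 1)[1:]
    matched = pd.Series(overlap / np.maximum(areas, 1) >= overlap_min,
                        index=labels, name="matched")
    return shifted, matched


def extract_bead_table(image_set: BeadImageSet, mask: np.ndarray,
                       registration: RegistrationResult,
                       matched: pd.Series | None = None) -> pd.DataFrame:
    """Extract per-bead mean intensities for every channel and round.

    The mask is defined on the ``scan1`` round; dye-switch channel images are
    translated back into the reference frame by the registered shift before
    averaging over each bead footprint. If ``matched`` is given, unmatched
    beads are dropped.
    """
    if not registration.accepted:
        raise ValueError("registration was not accepted; discard this pair")
    stack = np.stack([
        image_set[("scan1", "ch1")],
        image_set[("scan1", "ch2")],
        translate(image_set[("dyeswitch", "ch1")], -registration.dy,
                  -registration.dx),
        translate(image_set[("dyeswitch", "ch2")], -registration.dy,
                  -registration.dx),
    ], axis=-1)
    props = regionprops_table(mask, intensity_image=stack,
                              properties=("label", "centroid", "area",
                                          "intensity_mean"))
    table = pd.DataFrame({
        "bead_id": props["label"],
        "y": props["centroid-0"],
        "x": props["centroid-1"],
        "area": props["area"],
        "ch1_scan1": props["intensity_mean-0"],
        "ch2_scan1": props["intensity_mean-1"],
        "ch1_dyeswitch": props["intensity_mean-2"],
        "ch2_dyeswitch": props["intensity_mean-3"],
    })
    if matched is not None:
        keep = matched.reindex(table["bead_id"]).fillna(False).to_numpy(bool)
        table = table.loc[keep].reset_index(drop=True)
    if table.empty:
        warnings.warn("no matched beads: returning empty bead table",
                      stacklevel=2)
    return table
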