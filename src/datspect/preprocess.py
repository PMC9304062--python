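"""Standardized striatal image preparation.

The chain converts a transaxial count volume into the 70x70 normalized
striatal image that quantitation and learning consume:

1. pick the striatal slice with maximal counts and sum the three slices
   around it;
2. trim the background, keep the largest brain-shaped component, rescale its
   bounding box to 100x120 pixels, and crop a 70x70 window centred on the
   striatal-uptake centroid;
3. normalize either to maximum count 1.0 or to a fixed non-striatal
   background mean of 0.15, the latter using a group-level striatal mask
   obtained by thresholding the cohort-average image at a 30% cutoff.

Horizontal-flip augmentation (used to double the training set and teach the
classifiers side-invariance) also lives here.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .types import GroupStriatalMask, SpectVolume, StandardImage

__all__ = [
    "select_summed_slice",
    "trim_and_center",
    "normalize_max",
    "normalize_background",
    "build_group_striatal_mask",
    "augment_flip",
    "preprocess_volume",
    "BACKGROUND_TARGET",
    "FRAME_SHAPE",
]

BACKGROUND_TARGET = 0.15
FRAME_SHAPE = (70, 70)
_BRAIN_SHAPE = (120, 100)   # (rows, cols) of the rescaled brain box


def select_summed_slice(volume: SpectVolume,
                        striatal_frac: float = 0.6) -> tuple[np.ndarray, int]:
    """Sum the three slices around the striatal count maximum.

    The striatal region is bootstrapped as the set of pixels at or above
    ``striatal_frac`` of the volume maximum; the chosen index maximizes the
    per-slice sum over that set (lowest index on ties) and is clamped so the
    three-slice window stays in range.
    """
    counts = volume.counts
    if counts.shape[0] < 3:
        raise ValueError("need at least 3 slices to form a summed image")
    vmax = counts.max()
    if vmax <= 0:
        raise ValueError("volume contains no counts")
    hot = counts >= striatal_frac * vmax
    per_slice = np.where(hot, counts, 0.0).sum(axis=(1, 2))
    i = int(np.argmax(per_slice))
    i = min(max(i, 1), counts.shape[0] - 2)
    summed = counts[i - 1] + counts[i] + counts[i + 1]
    return summed, i


def _brain_mask_2d(image: np.ndarray, brain_frac: float) -> np.ndarray:
    mask = image >= brain_frac * image.max()
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty brain mask: no pixels above the brain threshold")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def trim_and_center(summed: np.ndarray, brain_frac: float = 0.10,
                    striatal_frac: float = 0.5,
                    crop: int = 70) -> tuple[np.ndarray, dict]:
    """Trim the brain, rescale to 100x120 and crop 70x70 around the striatum.

    The brain region is the largest connected component above ``brain_frac``
    of the image maximum, holes filled; pixels outside it are zeroed.  Its
    bounding box is rescaled (bilinear) to 100 columns x 120 rows, and a
    ``crop`` x ``crop`` window is taken around the intensity-weighted
    centroid of pixels at or above ``striatal_frac`` of the rescaled maximum
    (the striatal uptake plus, at low contrast, the bright brain core — in
    both cases centrally located).  Windows touching the border are
    zero-padded.

    Returns the cropped frame and a provenance dict with the centroid and
    scale factors.
    """
    summed = np.asarray(summed, dtype=float)
    if summed.max() <= 0:
        raise ValueError("summed image contains no counts")
    brain = _brain_mask_2d(summed, brain_frac)
    img = np.where(brain, summed, 0.0)
    rows = np.flatnonzero(brain.any(axis=1))
    cols = np.flatnonzero(brain.any(axis=0))
    sub = img[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    scaled = resize(sub, _BRAIN_SHAPE, order=1, preserve_range=True,
                    anti_aliasing=False)
    hot = scaled >= striatal_frac * scaled.max()
    w = np.where(hot, scaled, 0.0)
    r_c, c_c = ndimage.center_of_mass(w)
    # quantize before rounding so that a mirrored image (centroid jittered by
    # summation order at the 1e-10 level) maps to the mirrored crop exactly
    r0 = int(np.floor(np.round(r_c, 6) + 0.5)) - crop // 2
    c0 = int(np.floor(np.round(c_c, 6) + 0.5)) - crop // 2
    frame = np.zeros((crop, crop), dtype=float)
    rs, re = max(r0, 0), min(r0 + crop, scaled.shape[0])
    cs, ce = max(c0, 0), min(c0 + crop, scaled.shape[1])
    frame[rs - r0: re - r0, cs - c0: ce - c0] = scaled[rs:re, cs:ce]
    prov = {
        "centroid": (float(r_c), float(c_c)),
        "crop_origin": (r0, c0),
        "scale": (
            _BRAIN_SHAPE[0] / sub.shape[0],
            _BRAIN_SHAPE[1] / sub.shape[1],
        ),
    }
    return frame, prov


def normalize_max(frame: np.ndarray, provenance: dict | None = None) -> StandardImage:
    """Rescale linearly so the maximum pixel equals 1.0."""
    frame = np.asarray(frame, dtype=float)
    m = frame.max()
    if m <= 0:
        raise ValueError("cannot max-normalize an all-zero frame")
    return StandardImage(frame / m, "max", dict(provenance or {}))


def normalize_background(frame: np.ndarray, striatal_mask: GroupStriatalMask,
                         target: float = BACKGROUND_TARGET,
                         dilation: int = 1,
                         provenance: dict | None = None) -> StandardImage:
    """Rescale linearly so the non-striatal brain mean equals ``target``.

    The background region is the in-brain area (non-zero pixels) minus the
    group striatal mask dilated by ``dilation`` pixels, which guards against
    partial-volume bleed from the striatal rim.
    """
    frame = np.asarray(frame, dtype=float)
    striatal = striatal_mask.mask
    if striatal.shape != frame.shape:
        raise ValueError("mask shape does not match frame shape")
    if dilation > 0:
        striatal = ndimage.binary_dilation(striatal, iterations=dilation)
    region = (frame > 0) & ~striatal
    if not region.any():
        raise ValueError("background region is empty")
    mean = frame[region].mean()
    if mean <= 0:
        raise ValueError("background region has non-positive mean count")
    return StandardImage(frame * (target / mean), "background", dict(provenance or {}))


def build_group_striatal_mask(images: Sequence[StandardImage | np.ndarray],
                              cutoff: float = 0.30,
                              mode: str = "robust") -> GroupStriatalMask:
    """Threshold the group-average image to delineate the striatal region.

    ``mode="absolute"`` applies the cutoff to the average image's maximum
    (mask = pixels >= cutoff x max).  ``mode="robust"`` (default) references
    the cutoff to the in-brain intensity range, thresholding at
    ``median + cutoff x (max - median)`` where the median is taken over
    non-zero pixels: because the non-striatal brain occupies the bulk of the
    frame, the median estimates the background plateau, making the mask
    insensitive to how high that plateau sits relative to the striatal peak
    (it rises toward the absolute rule as the plateau falls).
    """
    arrs = [im.pixels if isinstance(im, StandardImage) else np.asarray(im, float)
            for im in images]
    if len(arrs) < 2:
        raise ValueError("need at least 2 images to build a group mask")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("images must share one shape")
    avg = np.mean(arrs, axis=0)
    amax = avg.max()
    if mode == "absolute":
        thr = cutoff * amax
    elif mode == "robust":
        inside = avg[avg > 0]
        med = float(np.median(inside))
        thr = med + cutoff * (amax - med)
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    mask = avg >= thr
    if not mask.any():
        raise ValueError(
            f"group mask empty at cutoff {cutoff}: average image range "
            f"[{avg.min():.3g}, {amax:.3g}]"
        )
    return GroupStriatalMask(mask=mask, cutoff=cutoff, n_subjects=len(arrs))


def augment_flip(images: Sequence[StandardImage],
                 labels: Sequence | None = None):
    """Append horizontally mirrored copies, doubling the set.

    Feature labels are side-agnostic (asymmetry does not name a side), so
    flipped copies carry their original labels unchanged.
    """
    flipped = [im.flipped() if isinstance(im, StandardImage)
               else np.asarray(im)[:, ::-1].copy() for im in images]
    out_images = list(images) + flipped
    if labels is None:
        return out_images
    return out_images, list(labels) + list(labels)


def preprocess_volume(volume: SpectVolume, subject_id: str = "subj",
                      striatal_frac_select: float = 0.6,
                      brain_frac: float = 0.10,
                      striatal_frac_center: float = 0.5) -> tuple[np.ndarray, dict]:
    """Volume -> un-normalized 70x70 frame plus provenance."""
    summed, idx = select_summed_slice(volume, striatal_frac_select)
    frame, prov = trim_and_center(summed, brain_frac, striatal_frac_center)
    prov.update({"subject_id": subject_id, "selected_slice": idx})
    return frame, prov
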