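"""Shared data containers for the DAT-SPECT analysis pipeline.

The containers deliberately mirror the stages of the analysis: a raw
count-valued SPECT volume, the standardized 70x70 striatal image that all
quantitation and learning operates on, the group-level striatal mask used
for background normalization, and the per-subject feature labels that the
phantom generator controls and the classifiers try to recover.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = [
    "SpectVolume",
    "StandardImage",
    "GroupStriatalMask",
    "FeatureLabelSet",
    "SubjectRecord",
]


@dataclass
class SpectVolume:
    """Ordered stack of transaxial count images.

    Parameters
    ----------
    counts
        3-D non-negative array indexed ``(slice, row, column)``, slices
        ordered inferior to superior.
    pixel_spacing
        In-plane pixel size in millimetres.
    slice_thickness
        Slice spacing in millimetres.
    """

    counts: np.ndarray
    pixel_spacing: float = 3.3
    slice_thickness: float = 3.3

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-D (slice, row, column) array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.counts.shape[0]


@dataclass
class StandardImage:
    """Standardized, normalized 70x70 striatal image.

    ``normalization`` records how the pixel scale was fixed: ``"max"``
    (maximum pixel rescaled to 1.0) or ``"background"`` (mean count over the
    non-striatal brain region rescaled to 0.15).  ``provenance`` carries the
    source subject id and the index of the selected summed slice.
    """

    pixels: np.ndarray
    normalization: str
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be non-negative")
        if self.normalization not in ("max", "background", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def flipped(self) -> "StandardImage":
        """Horizontally mirrored copy (left/right swap)."""
        prov = dict(self.provenance)
        prov["flipped"] = not prov.get("flipped", False)
        return StandardImage(self.pixels[:, ::-1].copy(), self.normalization, prov)


@dataclass
class GroupStriatalMask:
    """Boolean striatal mask derived from a group-average image."""

    mask: np.ndarray
    cutoff: float
    n_subjects: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("group striatal mask is empty")


@dataclass(frozen=True)
class FeatureLabelSet:
    """Binary visual features of a striatal image.

    ``low``: overall uptake reduced (vs. the normal high level);
    ``asymmetric``: left/right uptake differs; ``dot``: putamen uptake lost
    relative to the caudate, turning the comma outline into a dot;
    ``abnormal``: overall impression.  Under the default generative rule the
    overall impression is abnormal whenever any single feature is present.
    """

    low: bool = False
    asymmetric: bool = False
    dot: bool = False
    abnormal: bool = False

    @classmethod
    def from_features(cls, low: bool, asymmetric: bool, dot: bool) -> "FeatureLabelSet":
        return cls(low=low, asymmetric=asymmetric, dot=dot,
                   abnormal=bool(low or asymmetric or dot))

    def as_dict(self) -> dict[str, bool]:
        return {"low": self.low, "asymmetric": self.asymmetric,
                "dot": self.dot, "abnormal": self.abnormal}

    FEATURES = ("low", "asymmetric", "dot", "abnormal")


@dataclass
class SubjectRecord:
    """One synthetic subject: image volume plus ground truth."""

    subject_id: str
    age: float
    labels: FeatureLabelSet
    diagnosis: bool          # True = PS/PD/DLB-like (nigrostriatal degeneration)
    volume: SpectVolume
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.age < 130):
            raise ValueError(f"implausible age {self.age}")


def _replace(obj, **kw):
    return replace(obj, **kw)
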