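"""Synthetic striatal SPECT phantom generator.

Real dopamine-transporter images are not redistributable, so the pipeline is
exercised on parametric phantoms: a uniform elliptical "brain" background
with two comma-shaped striata (caudate disc + angled putamen ellipse), blurred
by a Gaussian point-spread function and degraded with Poisson counting noise.
Four binary attributes control the image class:

* ``low``        — striatal:background contrast drops from the normal high
                   level to a reduced one;
* ``asymmetric`` — uptake on one (the "worse") side is multiplied by an
                   asymmetry factor < 1;
* ``dot``        — putamen uptake is attenuated relative to the caudate,
                   turning the comma outline into a dot;
* ``abnormal``   — overall impression; by default the OR of the other three.

Each subject also carries an age and a binary diagnosis (nigrostriatal
degeneration: PS/PD/DLB-like vs. not) drawn from a logistic rule in the
features and age, so that diagnosis models have a known ground truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import FeatureLabelSet, SpectVolume, SubjectRecord

__all__ = [
    "PhantomParams",
    "DiagnosisRule",
    "DEFAULT_PARAMS",
    "DEFAULT_RULE",
    "TRAINING_MIX",
    "TEST_MIX",
    "make_striatum_template",
    "striatum_masks",
    "generate_subject",
    "generate_label_table",
    "generate_cohort",
    "cohort_manifest",
    "write_dicom_series",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and statistics of the striatal phantom.

    All lengths are in pixels of the native acquisition grid.  The striata
    are mirror-symmetric about the vertical midline: per side a caudate disc
    sits anterior-medially and a rotated putamen ellipse posterior-laterally,
    with a small gap that the point-spread function blurs into a connected
    comma.
    """

    image_size: tuple[int, int] = (128, 128)
    n_slices: int = 21
    brain_axes: tuple[float, float] = (48.0, 40.0)   # semi-axes (row, col)
    caudate_radius: float = 5.0
    putamen_axes: tuple[float, float] = (8.5, 4.5)   # semi-major, semi-minor
    putamen_angle: float = 25.0                      # deg from the row axis
    striatum_offset: float = 10.0                    # caudate centre from midline
    putamen_lateral_shift: float = 7.0               # putamen beyond caudate
    caudate_row_offset: float = -9.0                 # anterior of brain centre
    putamen_row_offset: float = 2.0
    background_level: float = 30.0                   # mean counts / pixel
    uptake_contrast_high: float = 5.0
    uptake_contrast_low: float = 2.0
    asymmetry_factor: float = 0.6
    putamen_attenuation: float = 0.5
    psf_sigma: float = 2.5
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        nr, nc = self.image_size
        if self.uptake_contrast_high <= 1 or self.uptake_contrast_low <= 1:
            raise ValueError("uptake contrasts must exceed 1 (striatum above background)")
        if not (0 < self.asymmetry_factor <= 1):
            raise ValueError("asymmetry_factor must be in (0, 1]")
        if not (0 < self.putamen_attenuation <= 1):
            raise ValueError("putamen_attenuation must be in (0, 1]")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be non-negative")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.n_slices < 5:
            raise ValueError("need at least 5 slices for the axial profile")
        # geometric extents must stay inside the brain ellipse
        lat = self.striatum_offset + self.putamen_lateral_shift + max(self.putamen_axes)
        if lat >= self.brain_axes[1]:
            raise ValueError("striatal geometry extends outside the brain laterally")
        post = max(abs(self.caudate_row_offset) + self.caudate_radius,
                   abs(self.putamen_row_offset) + max(self.putamen_axes))
        if post >= self.brain_axes[0]:
            raise ValueError("striatal geometry extends outside the brain axially")
        if self.brain_axes[0] >= nr / 2 or self.brain_axes[1] >= nc / 2:
            raise ValueError("brain ellipse must fit inside the image")

    @property
    def centre(self) -> tuple[float, float]:
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)


DEFAULT_PARAMS = PhantomParams()


def _disc_mask(shape: tuple[int, int], centre: tuple[float, float], radius: float,
               grow: float = 0.0) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= (radius + grow) ** 2


def _ellipse_mask(shape: tuple[int, int], centre: tuple[float, float],
                  axes: tuple[float, float], angle_deg: float,
                  grow: float = 0.0) -> np.ndarray:
    a, b = axes[0] + grow, axes[1] + grow
    th = np.deg2rad(angle_deg)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr, dc = rr - centre[0], cc - centre[1]
    u = dr * np.cos(th) + dc * np.sin(th)
    v = -dr * np.sin(th) + dc * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def striatum_masks(params: PhantomParams, side: str,
                   grow: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint boolean masks ``(caudate, putamen)`` for one side.

    ``side`` is "left" or "right" in image coordinates (left = lower column
    indices).  ``grow`` dilates (positive) or erodes (negative) both regions
    by that many pixels; used to vary the footprint across axial slices.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    s = -1.0 if side == "left" else 1.0
    r0, c0 = params.centre
    cau_c = (r0 + params.caudate_row_offset, c0 + s * params.striatum_offset)
    put_c = (r0 + params.putamen_row_offset,
             c0 + s * (params.striatum_offset + params.putamen_lateral_shift))
    shape = params.image_size
    caudate = _disc_mask(shape, cau_c, params.caudate_radius, grow)
    putamen = _ellipse_mask(shape, put_c, params.putamen_axes,
                            s * params.putamen_angle, grow)
    putamen &= ~caudate
    return caudate, putamen


def make_striatum_template(params: PhantomParams, side: str,
                           grow: float = 0.0) -> np.ndarray:
    """Relative-intensity map of one striatum.

    Caudate pixels carry intensity 1, putamen pixels carry
    ``params.putamen_attenuation`` — a comma outline at attenuation 1 and a
    dot-like one below it.  Multiply by contrast x background to obtain
    expected counts.
    """
    caudate, putamen = striatum_masks(params, side, grow)
    out = np.zeros(params.image_size, dtype=float)
    out[caudate] = 1.0
    out[putamen] = params.putamen_attenuation
    return out


# Footprint change (pixels of dilation) by axial offset from the striatal
# equator: the footprint is largest on the central slice so that slice
# selection has a unique argmax, while the three central slices all carry
# full uptake inside the base footprint.
_AXIAL_GROW = {-2: -1.5, -1: 0.0, 0: 1.0, 1: 0.0, 2: -1.5}


def _brain_mask(params: PhantomParams, z: int) -> np.ndarray:
    z0 = params.n_slices // 2
    half = params.n_slices / 2.0 + 2.0
    scale = float(np.sqrt(max(1.0 - ((z - z0) / half) ** 2, 0.05)))
    return _ellipse_mask(params.image_size, params.centre,
                         (params.brain_axes[0] * scale, params.brain_axes[1] * scale), 0.0)


def expected_volume(params: PhantomParams, labels: FeatureLabelSet,
                    worse_side: str = "right") -> np.ndarray:
    """Noise-free expectation counts before the PSF blur."""
    contrast = params.uptake_contrast_low if labels.low else params.uptake_contrast_high
    eff = dataclasses.replace(
        params,
        putamen_attenuation=params.putamen_attenuation if labels.dot else 1.0,
    )
    z0 = params.n_slices // 2
    vol = np.zeros((params.n_slices, *params.image_size), dtype=float)
    for z in range(params.n_slices):
        sl = np.where(_brain_mask(params, z), params.background_level, 0.0)
        dz = z - z0
        if dz in _AXIAL_GROW:
            for side in ("left", "right"):
                side_contrast = contrast
                if labels.asymmetric and side == worse_side:
                    side_contrast = contrast * params.asymmetry_factor
                tmpl = make_striatum_template(eff, side, grow=_AXIAL_GROW[dz])
                hot = tmpl > 0
                # the template value scales the SPECIFIC (above-background)
                # uptake, so an attenuated putamen keeps att x the caudate's
                # specific binding: value = bg * (1 + (contrast-1) * t)
                sl[hot] = params.background_level * (
                    1.0 + (side_contrast - 1.0) * tmpl[hot])
        vol[z] = sl
    return vol


def generate_subject(params: PhantomParams, labels: FeatureLabelSet, age: float,
                     seed: int, subject_id: str = "subj",
                     worse_side: str = "right",
                     diagnosis: bool | None = None) -> SubjectRecord:
    """Generate one phantom subject with known ground truth.

    The Poisson noise is applied to the PSF-blurred expectation; with
    ``noise_scale == 0`` the blurred expectation is returned unchanged
    (noise-free phantom).  ``worse_side`` names the side carrying the reduced
    uptake for asymmetric subjects.
    """
    lam = expected_volume(params, labels, worse_side)
    if params.psf_sigma > 0:
        for z in range(lam.shape[0]):
            lam[z] = ndimage.gaussian_filter(lam[z], params.psf_sigma)
    if params.noise_scale > 0:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam * params.noise_scale).astype(float)
    else:
        counts = lam
    vol = SpectVolume(counts)
    if diagnosis is None:
        diagnosis = bool(labels.abnormal)
    return SubjectRecord(subject_id=subject_id, age=float(age), labels=labels,
                         diagnosis=diagnosis, volume=vol, seed=int(seed))


@dataclass(frozen=True)
class DiagnosisRule:
    """Logistic rule linking features and age to P(PS/PD/DLB).

    ``p = 1 / (1 + exp(-(b0 + b_age*age + b_low*low + b_asym*asym + b_dot*dot)))``
    """

    b0: float = -8.0
    b_age: float = 0.1
    b_low: float = 2.0
    b_asym: float = 1.0
    b_dot: float = 2.0

    def probability(self, low, asymmetric, dot, age):
        lin = (self.b0 + self.b_age * np.asarray(age, dtype=float)
               + self.b_low * np.asarray(low, dtype=float)
               + self.b_asym * np.asarray(asymmetric, dtype=float)
               + self.b_dot * np.asarray(dot, dtype=float))
        return 1.0 / (1.0 + np.exp(-lin))


DEFAULT_RULE = DiagnosisRule()

# Proportions of the eight (low, asymmetric, dot) combinations.  The
# training-like mix reproduces the marginal feature frequencies of a memory
# clinic / movement-disorder referral stream where ~79% of scans are read as
# abnormal; the test-like mix is a less enriched stream (~57% abnormal).
TRAINING_MIX: dict[tuple[bool, bool, bool], float] = {
    (False, False, False): 0.21,
    (True, True, True): 0.45,
    (True, True, False): 0.13,
    (True, False, True): 0.17,
    (True, False, False): 0.02,
    (False, True, True): 0.01,
    (False, True, False): 0.005,
    (False, False, True): 0.005,
}
TEST_MIX: dict[tuple[bool, bool, bool], float] = {
    (False, False, False): 0.43,
    (True, True, True): 0.25,
    (True, True, False): 0.06,
    (True, False, True): 0.12,
    (True, False, False): 0.03,
    (False, True, True): 0.05,
    (False, True, False): 0.01,
    (False, False, True): 0.05,
}

AGE_TRAINING = (75.0, 8.0)
AGE_TEST = (67.0, 15.0)
AGE_RANGE = (40.0, 95.0)


def generate_label_table(n: int,
                         class_mix: Mapping[tuple[bool, bool, bool], float] = TRAINING_MIX,
                         age_model: tuple[float, float] = AGE_TRAINING,
                         diagnosis_rule: DiagnosisRule = DEFAULT_RULE,
                         seed: int = 0) -> pd.DataFrame:
    """Sample feature labels, ages and diagnoses without rendering images.

    Used both by :func:`generate_cohort` and directly wherever only the
    statistical ground truth is needed (e.g. logistic-recovery checks).
    """
    combos = list(class_mix.keys())
    probs = np.asarray([class_mix[c] for c in combos], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("class_mix proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(combos), size=n, p=probs)
    low = np.array([combos[i][0] for i in idx])
    asym = np.array([combos[i][1] for i in idx])
    dot = np.array([combos[i][2] for i in idx])
    age = np.clip(rng.normal(age_model[0], age_model[1], size=n), *AGE_RANGE)
    p_dx = diagnosis_rule.probability(low, asym, dot, age)
    dx = rng.random(n) < p_dx
    worse = np.where(rng.random(n) < 0.5, "left", "right")
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return pd.DataFrame({
        "low": low, "asymmetric": asym, "dot": dot,
        "abnormal": low | asym | dot,
        "age": age, "diagnosis": dx, "worse_side": worse, "seed": seeds,
    })


def generate_cohort(n: int,
                    class_mix: Mapping[tuple[bool, bool, bool], float] = TRAINING_MIX,
                    age_model: tuple[float, float] = AGE_TRAINING,
                    diagnosis_rule: DiagnosisRule = DEFAULT_RULE,
                    seed: int = 0,
                    params: PhantomParams = DEFAULT_PARAMS,
                    prefix: str = "S") -> list[SubjectRecord]:
    """Generate a reproducible cohort of phantom subjects."""
    if n < 8:
        raise ValueError("cohort must contain at least 8 subjects to populate folds")
    table = generate_label_table(n, class_mix, age_model, diagnosis_rule, seed)
    records = []
    for i, row in table.iterrows():
        labels = FeatureLabelSet.from_features(
            bool(row["low"]), bool(row["asymmetric"]), bool(row["dot"]))
        rec = generate_subject(params, labels, float(row["age"]), int(row["seed"]),
                               subject_id=f"{prefix}{i:04d}",
                               worse_side=str(row["worse_side"]),
                               diagnosis=bool(row["diagnosis"]))
        records.append(rec)
    return records


def cohort_manifest(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {"subject_id": r.subject_id, "age": r.age, **r.labels.as_dict(),
             "diagnosis": r.diagnosis, "seed": r.seed}
        rows.append(d)
    return pd.DataFrame(rows)


def write_dicom_series(volume: SpectVolume, outdir: str | Path,
                       subject_id: str = "subj") -> list[Path]:
    """Write a volume as one monochrome count-valued DICOM file per slice."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid(entropy_srcs=[subject_id])
    paths = []
    counts = np.rint(volume.counts).astype(np.uint16)
    for z in range(volume.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[subject_id, str(z)])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "NM"
        ds.PatientID = subject_id
        ds.PatientName = subject_id
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = generate_uid(entropy_srcs=[subject_id, "study"])
        ds.InstanceNumber = z + 1
        ds.SliceLocation = z * volume.slice_thickness
        ds.PixelSpacing = [volume.pixel_spacing, volume.pixel_spacing]
        ds.SliceThickness = volume.slice_thickness
        ds.Rows, ds.Columns = counts.shape[1:]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = counts[z].tobytes()
        p = outdir / f"{subject_id}_{z:03d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def read_dicom_series(indir: str | Path) -> SpectVolume:
    """Read a directory of single-slice DICOM files back into a volume."""
    import pydicom

    files = sorted(Path(indir).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {indir}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda d: int(d.InstanceNumber))
    counts = np.stack([d.pixel_array.astype(float) for d in slices])
    spacing = float(slices[0].PixelSpacing[0])
    thickness = float(getattr(slices[0], "SliceThickness", spacing))
    return SpectVolume(counts, pixel_spacing=spacing, slice_thickness=thickness)
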