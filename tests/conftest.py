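"""Shared fixtures: small deterministic phantoms and cohorts.

Everything is generated at test time; session scope keeps the heavier
cohorts to a single construction.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from datspect import phantom, preprocess
from datspect.types import FeatureLabelSet


@pytest.fixture(scope="session")
def default_params():
    return phantom.DEFAULT_PARAMS


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, blur-free phantom parameters (exact-arithmetic oracle)."""
    return dataclasses.replace(phantom.DEFAULT_PARAMS, psf_sigma=0.0, noise_scale=0.0)


@pytest.fixture(scope="session")
def normal_clean_subject(clean_params):
    return phantom.generate_subject(clean_params, FeatureLabelSet(), age=70, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """60 default-noise subjects used across preprocessing/ROI tests."""
    return phantom.generate_cohort(60, seed=11)


@pytest.fixture(scope="session")
def small_cohort_images(small_cohort):
    """Preprocessed frames for the small cohort plus the group mask."""
    prep = [preprocess.preprocess_volume(r.volume, r.subject_id) for r in small_cohort]
    maxn = [preprocess.normalize_max(f, p) for f, p in prep]
    mask = preprocess.build_group_striatal_mask(preprocess.augment_flip(maxn))
    bgn = [preprocess.normalize_background(f, mask, provenance=p) for f, p in prep]
    return {"frames": prep, "max": maxn, "background": bgn, "mask": mask}
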