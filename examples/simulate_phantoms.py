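"""Generate a few striatal phantoms and inspect their ground truth.

Each subject is a 21-slice count volume containing two comma-shaped striata
on a uniform brain background, with its visual-feature labels (low uptake,
asymmetry, dot-like shape), age and diagnosis drawn from the default
generative model.  A DICOM series is written for the first subject.
"""
import tempfile
from pathlib import Path

from datspect import phantom

cohort = phantom.generate_cohort(10, seed=7)
print(phantom.cohort_manifest(cohort).to_string(index=False))

outdir = Path(tempfile.mkdtemp()) / cohort[0].subject_id
paths = phantom.write_dicom_series(cohort[0].volume, outdir, cohort[0].subject_id)
print(f"\nwrote {len(paths)} DICOM slices for {cohort[0].subject_id} to {outdir}")
print("volume shape:", cohort[0].volume.counts.shape,
      "total counts:", int(cohort[0].volume.counts.sum()))
# The manifest column 'abnormal' is the OR of the three features; 'diagnosis'
# is the PS/PD/DLB-like label drawn from the logistic rule in features + age.
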