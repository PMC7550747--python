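import numpy as np
import pytest

from casemap.io_formats import VolumeImage
from casemap.normative import NormativeCohort

ASEG_TEXT = """\
# Title Segmentation Statistics
# Measure BrainSeg, BrainSegVol, Brain Segmentation Volume, 1161205.000000, mm^3
# Measure VentricleChoroidVol, VentricleChoroidVol, Volume of ventricles and choroid plexus, 12755.000000, mm^3
# Measure TotalGray, TotalGrayVol, Total gray matter volume, 650424.000000, mm^3
# Measure CerebralWhiteMatter, CerebralWhiteMatterVol, Total cerebral white matter volume, 450327.000000, mm^3
# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, 1534363.000000, mm^3
# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean normStdDev normMin normMax normRange
  1  10  3520  3512.0  Left-Caudate   75.2  8.1  40.0  105.0  65.0
  2  11  4980  4975.5  Left-Putamen   81.0  7.3  44.0  108.0  64.0
  3  49  3610  3604.3  Right-Caudate  74.9  8.4  39.0  104.0  65.0
"""

APARC_TEXT = """\
# Table of FreeSurfer cortical parcellation anatomical statistics
# hemi lh
# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv GausCurv FoldInd CurvInd
precentral  12000  8210  13050  2.51  0.45  0.12  0.02  90  8.0
postcentral 10000  6900  10100  2.05  0.40  0.10  0.02  70  6.5
insula       5000  3100   6800  3.02  0.55  0.15  0.04  40  4.0
"""


@pytest.fixture
def aseg_file(tmp_path):
    path = tmp_path / "aseg.stats"
    path.write_text(ASEG_TEXT)
    return path


@pytest.fixture
def aparc_file(tmp_path):
    path = tmp_path / "lh.aparc.stats"
    path.write_text(APARC_TEXT)
    return path


@pytest.fixture
def small_cohort():
    """Hand-checkable cohort: values {10, 12, 14} -> mean 12, sd 2, n 3."""
    return NormativeCohort(
        biomarker_key=("Left-Caudate", "volume_mm3"),
        values=[10.0, 12.0, 14.0],
        control_ids=["c1", "c2", "c3"],
        age_window=(35.0, 55.0),
    )


def make_image(data, voxel_size=(2.0, 2.0, 2.0)):
    return VolumeImage(data=np.asarray(data, dtype=float), affine=np.diag([*voxel_size, 1.0]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
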