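"""Published reference statistics of the public sEV TEM benchmark.

The public benchmark this tool targets consists of three annotated
datasets of negatively stained sEV TEM images.  The constants below are
the published annotation counts and the detection counts (true/false
positives) reported for the FRU-Net models (FRU1-FRU3, named after the
dataset each was tested on) and the TEM ExosomeAnalyzer baseline (EA);
they are the inputs for consistency arithmetic such as the false-positive
ratio FP / (FP + TP) and are *not* recomputed by this package.
"""

from __future__ import annotations

__all__ = ["DATASET_SEV_COUNTS", "DETECTION_COUNTS", "fp_ratio"]

#: Annotated vesicles per benchmark dataset.
DATASET_SEV_COUNTS = {"dataset1": 65, "dataset2": 346, "dataset3": 688}

#: Published (TP, FP) detection counts per model and test dataset.
DETECTION_COUNTS = {
    "FRU1": {"TP": 47, "FP": 4},
    "FRU2": {"TP": 241, "FP": 254},
    "FRU3": {"TP": 578, "FP": 159},
    "EA1": {"TP": 45, "FP": 3},
    "EA2": {"TP": 167, "FP": 90},
    "EA3": {"TP": 149, "FP": 335},
}


def fp_ratio(tp: int, fp: int) -> float:
    """False-positive ratio FP / (FP + TP); 0 when there are no detections."""
    total = tp + fp
    return fp / total if total else 0.0
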