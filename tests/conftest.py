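from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from neoecg.cycle import build_cycle_matrix, extract_representative
from neoecg.preprocess import extract_segments, filter_segment, normalize
from neoecg.qrs import detect_r_peaks, locate_qrs_points, quality_gate
from neoecg.synth import CohortConfig, synthesize_record


@pytest.fixture(scope="session")
def clean_cohort_config() -> CohortConfig:
    """Noise-free default cohort, 21 s records (event mid-record)."""
    return CohortConfig(noise=None, duration_s=21.0)


@pytest.fixture(scope="session")
def clean_record(clean_cohort_config):
    """One clean normal-group record with its ground truth and event table."""
    return synthesize_record(clean_cohort_config, "normal", 11)


@pytest.fixture(scope="session")
def processed(clean_record):
    """The clean record taken through filter -> detect -> gate -> cycle."""
    rec, truth, events = clean_record
    seg = extract_segments(rec, events, sides=("following",))[0]
    norm = normalize(filter_segment(seg))
    ann = quality_gate(locate_qrs_points(norm, detect_r_peaks(norm)), norm)
    assert ann.verdict == "accepted"
    rep = extract_representative(build_cycle_matrix(norm, ann))
    rep = replace(rep, offset=norm.offset, scale=norm.scale)
    return {"segment": norm, "annotation": ann, "cycle": rep, "truth": truth}
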