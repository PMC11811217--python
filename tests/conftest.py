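import pytest

from cardiocausal.cohort import (
    CohortSpec,
    hypertension_feature_dag,
    simulate_feature_sem,
    simulate_waveform_cohort,
)
from cardiocausal.waveforms import detect_fiducials, detect_r_peaks, preprocess


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(
        n_subjects=8,
        prevalence=0.5,
        segments_per_subject=(3, 3),
        segment_duration_s=(15.0, 15.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_waveform_cohort(small_spec)


@pytest.fixture(scope="session")
def one_segment(small_cohort):
    """Preprocessed channels, R peaks and fiducials of one clean segment."""
    rec = small_cohort[0]
    seg = preprocess(rec)[0]
    r_times = detect_r_peaks(seg.ecg, seg.fs)
    fids = detect_fiducials(seg.ppg, seg.dppg, seg.sdppg, r_times, seg.fs)
    return rec, seg, r_times, fids


@pytest.fixture(scope="session")
def planted_frame():
    """Feature-level planted cohort (n=400) with its ground-truth DAG."""
    dag = hypertension_feature_dag()
    df, _ = simulate_feature_sem(dag, 400, seed=7)
    return df, dag
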