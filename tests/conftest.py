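"""Shared fixtures: small simulated cohorts and quiet single-scenario
signals, generated once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

from afpulse.config import ProcessingConfig, RunConfig, SimConfig

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")
from afpulse.pipeline import run_pipeline
from afpulse.synth import PatientProfile, render_ppg, simulate_af_rr


@pytest.fixture(scope="session")
def proc_config() -> ProcessingConfig:
    return ProcessingConfig()


def quiet_profile(
    rr_mean: float = 0.8,
    rr_sd: float = 0.184,
    duration_h: float = 1.0,
    start_hour: float = 12.0,
) -> PatientProfile:
    """Artefact-free profile: no motion, no dropouts, no CHF."""
    return PatientProfile(
        patient_id="QUIET",
        chf_flag=False,
        day_rr_params=(rr_mean, rr_sd),
        night_rr_params=(rr_mean, rr_sd),
        motion_schedule=np.zeros((0, 3)),
        dropout_minutes=np.array([], dtype=int),
        ecg_bad_minutes=np.array([], dtype=int),
        start_s=start_hour * 3600.0,
        duration_h=duration_h,
    )


@pytest.fixture(scope="session")
def clean_af_signal():
    """One clean hour of AF at ~75 bpm: (rhythm, ppg array, sim config)."""
    cfg = SimConfig(n_patients=1, duration_h=1.0, dropout_fraction=0.0, seed=5)
    prof = quiet_profile(rr_mean=0.8, duration_h=1.0)
    rhythm = simulate_af_rr(prof, 1.0, seed=7)
    ppg = render_ppg(rhythm, prof, cfg, seed=2)
    return rhythm, ppg, cfg


@pytest.fixture(scope="session")
def cohort_bundle():
    """Full-pipeline bundle: 3 patients x 24 h under default (motion-
    degraded, dropout-injected) study conditions; no correction models."""
    cfg = RunConfig(sim=SimConfig(n_patients=3, duration_h=24.0, seed=202), run_models=())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)
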