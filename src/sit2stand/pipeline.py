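"""End-to-end trial processing: two sensor streams in, three-segment
kinematics, labeled episodes and evaluation reports out.

Stages: per-segment EKF estimation -> tier-1 stationary/transition
segmentation -> tier-2 transition naming and stationary resolution ->
sigmoid thigh reconstruction -> (when a reference is supplied) NRMSE,
Bland–Altman and label-accuracy scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ekf import EkfConfig, InertialStream, SegmentKinematics, estimate_segment_kinematics, make_default_config
from .errors import Sit2StandError
from .metrics import AgreementReport, TimingSummary, agreement_report, transition_timings
from .segmentation import Episode, segment_trial
from .thigh_reconstruction import DEFAULT_W, reconstruct_thigh
from .transition_classify import (
    classification_accuracy,
    classify_episodes,
    derive_reference_labels,
    episodes_to_sample_labels,
)


@dataclass
class TrialBundle:
    """One trial's inputs: the two streams plus optional reference
    kinematics and identifying metadata."""

    shank: InertialStream
    back: InertialStream
    reference: dict[str, SegmentKinematics] | None = None
    participant: str = ""
    group: str = ""


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one trial."""

    kinematics: dict[str, SegmentKinematics]     # "S", "B", "T"
    episodes: list[Episode]
    sample_labels: np.ndarray
    threshold: float
    timings: TimingSummary
    reports: dict[str, AgreementReport] = field(default_factory=dict)
    accuracy_pct: float | None = None


def run_pipeline(
    bundle: TrialBundle,
    ekf_config: EkfConfig | None = None,
    w: float = DEFAULT_W,
    seed: int = 0,
    feature_window: int = 5,
) -> PipelineResult:
    """Process one trial end to end.

    Degenerate trials (no detectable transitions) raise
    :class:`~sit2stand.errors.DegenerateDataError` from the segmentation
    stage; callers that consider a motionless trial valid should catch it.
    """
    dt = bundle.shank.dt
    cfg = ekf_config if ekf_config is not None else make_default_config(dt)
    shank = estimate_segment_kinematics(bundle.shank, cfg)
    back = estimate_segment_kinematics(bundle.back, cfg)

    episodes_raw, threshold = _staged("segmentation", segment_trial, shank, back,
                                      window=feature_window)
    episodes = _staged("transition_classify", classify_episodes, episodes_raw,
                       shank, back, seed=seed)

    n = len(shank)
    thigh = _staged("thigh_reconstruction", reconstruct_thigh, episodes, n, dt, w=w)
    kinematics = {"S": shank, "B": back, "T": thigh}
    sample_labels = episodes_to_sample_labels(episodes, n)
    result = PipelineResult(
        kinematics=kinematics,
        episodes=episodes,
        sample_labels=sample_labels,
        threshold=threshold,
        timings=transition_timings(episodes, dt),
    )

    if bundle.reference:
        for seg, ref in bundle.reference.items():
            if seg in kinematics and len(ref) == n:
                result.reports[seg] = agreement_report(kinematics[seg], ref)
        if "T" in bundle.reference and len(bundle.reference["T"]) == n:
            ref_labels = derive_reference_labels(bundle.reference["T"])
            result.accuracy_pct = classification_accuracy(sample_labels, ref_labels)
    return result


def _staged(stage: str, fn, *args, **kwargs):
    """Run a stage, tagging any pipeline error with the stage name."""
    try:
        return fn(*args, **kwargs)
    except Sit2StandError as exc:
        exc.args = (f"[{stage}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
        raise
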