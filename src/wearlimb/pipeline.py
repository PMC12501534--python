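"""End-to-end validation pipeline: wearable vs reference joint angles.

Mirrors the laboratory validation workflow: the 18 Hz wearable angle
trace is linearly upsampled to the reference rate (100 Hz), synchronized
by cross-correlation, movement cycles are segmented on the reference
waveform (minima flanking each repetition's flexion maximum) and the same
boundaries are applied to both systems, then per-cycle CMC, RMSE, RRMSE
and Bland–Altman blocks on the cycle extrema are computed.
"""

from __future__ import annotations

import numpy as np

from .agreement import AgreementReport, compare_cycles, resample_linear, synchronize
from .cycles import SegmentParams, segment_by_flexion, time_normalize
from .datatypes import JointAngleSeries, ReferenceSeries

__all__ = ["validate_against_reference"]


def validate_against_reference(
    wearable: JointAngleSeries,
    reference: ReferenceSeries,
    channel: str = "flexion",
    target_hz: float = 100.0,
    max_lag_s: float = 1.0,
    seg_params: SegmentParams | None = None,
    n_points: int = 80,
) -> AgreementReport:
    """Full agreement analysis of one wearable channel against a reference
    joint-angle series.

    Returns an :class:`AgreementReport` with per-cycle statistics; raises
    if segmentation finds no complete cycle.
    """
    values = wearable.flexion if channel == "flexion" else wearable.abduction
    if values is None:
        raise ValueError(f"wearable series has no {channel!r} channel")

    _, ref_u = resample_linear(reference.timestamps, reference.values, target_hz)
    _, wear_u = resample_linear(wearable.timestamps, values, target_hz)

    lag_s, ref_al, wear_al = synchronize(ref_u, wear_u, target_hz, max_lag_s)

    t_al = np.arange(len(ref_al)) / target_hz
    ref_series = JointAngleSeries(timestamps=t_al, flexion=ref_al, joint=wearable.joint)
    cycleset = segment_by_flexion(ref_series, seg_params or SegmentParams())
    if cycleset.n_cycles == 0:
        raise ValueError("no complete movement cycles found in the reference series")

    ref_cycles = np.vstack(
        [time_normalize(ref_al[a : b + 1], n_points) for a, b in cycleset.slices]
    )
    wear_cycles = np.vstack(
        [time_normalize(wear_al[a : b + 1], n_points) for a, b in cycleset.slices]
    )
    return compare_cycles(ref_cycles, wear_cycles, sync_lag_s=lag_s)
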