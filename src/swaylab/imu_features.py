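"""Per-channel median summaries of IMU trunk-kinematics trials.

Each 3000-sample waveform is reduced to its sample median (even-length
convention: mean of the two central order statistics), giving nine scalars
per trial: acc_x/y/z (deg/s^2), gyro_x/y/z (deg/s), roll/pitch/yaw (deg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import IMU_CHANNELS, IMUTrial, ValidationError


@dataclass(frozen=True)
class IMUSummary:
    acc_x: float
    acc_y: float
    acc_z: float
    gyro_x: float
    gyro_y: float
    gyro_z: float
    roll: float
    pitch: float
    yaw: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in IMU_CHANNELS}


def channel_median(series) -> float:
    """Sample median of one waveform."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("channel_median of an empty series")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite sample in channel series")
    return float(np.median(x))


def imu_medians(trial: IMUTrial) -> IMUSummary:
    """Median of each of the nine channels, labels preserved."""
    return IMUSummary(**{name: channel_median(trial.channels[name]) for name in IMU_CHANNELS})
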