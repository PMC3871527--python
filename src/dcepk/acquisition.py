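"""Acquisition parameters for the dual-echo dynamic / Look-Locker / DWI protocol.

The defaults describe a 7 T small-animal protocol: a dual-echo spoiled
gradient-echo (2GE) dynamic series of 150 frames at 4 s intervals with a
contrast bolus pushed at the 15th frame, bracketed by Look-Locker
inversion-recovery scans for T1 mapping, plus a two-b-value diffusion pair.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class AcquisitionSpec(BaseModel):
    """Timing, flip angles and contrast-agent constants of one study.

    All times are seconds unless the field name says otherwise; the dose is
    mmol per kg body weight and the relaxivity ``r1`` is in s^-1 mM^-1.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_frames: int = Field(150, ge=20)
    frame_interval_s: float = Field(4.0, gt=0)
    bolus_frame: int = Field(15, ge=2, description="1-based frame of the bolus push")
    te1_s: float = Field(0.002, gt=0)
    te2_s: float = Field(0.004, gt=0)
    tr_s: float = Field(0.060, gt=0)
    flip_angle_deg: float = Field(25.0, gt=0, lt=90)
    # Look-Locker readout
    ll_n_echoes: int = Field(24, ge=4)
    ll_tr_s: float = Field(2.0, gt=0)
    ll_flip_angle_deg: float = Field(12.0, gt=0, lt=90)
    # Diffusion pair
    b_values_s_mm2: tuple[float, float] = (0.0, 1217.0)
    # Contrast agent
    dose_mmol_kg: float = Field(0.25, gt=0)
    r1_relaxivity: float = Field(3.8, gt=0, description="s^-1 mM^-1 at 7 T")
    hematocrit: float = Field(0.45, gt=0, lt=1)

    @model_validator(mode="after")
    def _check_times(self) -> "AcquisitionSpec":
        if not (self.te1_s < self.te2_s < self.tr_s):
            raise ValueError("echo/repetition times must satisfy TE1 < TE2 < TR")
        if self.b_values_s_mm2[0] == self.b_values_s_mm2[1]:
            raise ValueError("b-values must be distinct")
        if self.bolus_frame >= self.n_frames:
            raise ValueError("bolus frame must fall inside the dynamic series")
        return self

    @property
    def time_grid_s(self) -> np.ndarray:
        """Frame mid-times, first frame at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    @property
    def bolus_time_s(self) -> float:
        return (self.bolus_frame - 1) * self.frame_interval_s

    @property
    def inversion_times_s(self) -> np.ndarray:
        """Look-Locker sampling times after inversion (uniform echo train)."""
        tau = self.ll_tr_s / self.ll_n_echoes
        return tau * (np.arange(self.ll_n_echoes) + 0.5)

    @property
    def flip_angle_rad(self) -> float:
        return float(np.deg2rad(self.flip_angle_deg))

    # -- JSON sidecar -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionSpec":
        return cls.model_validate(json.loads(Path(path).read_text()))
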