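"""Apparent diffusion coefficient from a two-b-value acquisition.

With only two b-values the ADC has the closed form
``ADC = ln(S(b0)/S(b1)) / (b1 - b0)`` per voxel; it is invariant to any
common scaling of the two signals. Used for tumor localization context, not
for the kinetic analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ADCMap", "compute_adc"]


@dataclass
class ADCMap:
    adc_mm2_s: np.ndarray
    valid: np.ndarray  # bool; False where a signal was nonpositive
    clipped: np.ndarray  # bool; True where a negative estimate was clipped to 0


def compute_adc(s_b0: np.ndarray, s_b1: np.ndarray, b0: float, b1: float) -> ADCMap:
    """Two-point ADC map (mm^2/s).

    Voxels with nonpositive signal at either b-value are invalid; negative
    estimates (noise at low attenuation) are clipped to zero and annotated.
    """
    if b1 <= b0 or b0 < 0:
        raise ValueError("b-values must satisfy b1 > b0 >= 0")
    s0 = np.asarray(s_b0, dtype=float)
    s1 = np.asarray(s_b1, dtype=float)
    valid = (s0 > 0) & (s1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(s0 / s1) / (b1 - b0)
    adc = np.where(valid, adc, np.nan)
    clipped = valid & (adc < 0)
    adc = np.where(clipped, 0.0, adc)
    return ADCMap(adc_mm2_s=adc, valid=valid, clipped=clipped)
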