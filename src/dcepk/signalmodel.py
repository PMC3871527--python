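"""Spoiled gradient-echo and Look-Locker signal equations.

Shared between the synthetic-data generator (forward direction) and the
relaxometry / concentration modules (inverse direction).
"""

from __future__ import annotations

import numpy as np


def spgr_signal(m0: np.ndarray | float, r1: np.ndarray | float, flip_rad: float, tr_s: float) -> np.ndarray:
    """Steady-state spoiled gradient-echo signal at TE = 0.

    S = M0 sin(a) (1 - E) / (1 - cos(a) E),  E = exp(-TR * R1).
    """
    e = np.exp(-tr_s * np.asarray(r1, dtype=float))
    return np.asarray(m0) * np.sin(flip_rad) * (1.0 - e) / (1.0 - np.cos(flip_rad) * e)


def spgr_invert(signal: np.ndarray, m0: np.ndarray | float, flip_rad: float, tr_s: float) -> np.ndarray:
    """Invert the spoiled gradient-echo equation for R1.

    The equation is monotone increasing in R1, with supremum M0 sin(a); the
    inversion is closed form. Out-of-domain samples (signal at or above the
    supremum, or nonpositive) come back as NaN for the caller to flag.
    """
    y = np.asarray(signal, dtype=float) / np.asarray(m0, dtype=float)
    sin_a, cos_a = np.sin(flip_rad), np.cos(flip_rad)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = (sin_a - y) / (sin_a - y * cos_a)
        r1 = np.where((e > 0.0) & (e < 1.0), -np.log(np.clip(e, 1e-300, None)) / tr_s, np.nan)
    r1 = np.where(y <= 0.0, np.nan, r1)
    return r1


def spgr_dsignal_dr1(m0: np.ndarray | float, r1: np.ndarray | float, flip_rad: float, tr_s: float) -> np.ndarray:
    """Derivative of the spoiled gradient-echo signal with respect to R1.

    Used by the linearized small-dR1 concentration shortcut.
    """
    e = np.exp(-tr_s * np.asarray(r1, dtype=float))
    cos_a = np.cos(flip_rad)
    return np.asarray(m0) * np.sin(flip_rad) * (1.0 - cos_a) * tr_s * e / (1.0 - cos_a * e) ** 2


def look_locker_apparent(t1_s: np.ndarray | float, flip_rad: float, tau_s: float) -> np.ndarray:
    """Apparent (readout-shortened) relaxation time T1* of a Look-Locker train.

    1/T1* = 1/T1 - ln(cos a)/tau for a small-flip readout every ``tau`` seconds.
    """
    t1 = np.asarray(t1_s, dtype=float)
    return 1.0 / (1.0 / t1 - np.log(np.cos(flip_rad)) / tau_s)


def look_locker_series(
    m0: np.ndarray | float,
    t1_s: np.ndarray | float,
    inversion_times_s: np.ndarray,
    flip_rad: float,
    tau_s: float,
) -> np.ndarray:
    """Magnitude inversion-recovery train |A - B exp(-TI/T1*)|.

    With perfect inversion the driven-equilibrium amplitude is
    A = M0 T1*/T1 and B = M0 + A, so the standard correction
    T1 = T1* (B/A - 1) is exact for this forward model. Output shape is
    ``np.shape(m0) + (len(TI),)``.
    """
    t1 = np.atleast_1d(np.asarray(t1_s, dtype=float))
    m0 = np.broadcast_to(np.asarray(m0, dtype=float), t1.shape)
    t1_star = look_locker_apparent(t1, flip_rad, tau_s)
    a = m0 * t1_star / t1
    b = m0 + a
    ti = np.asarray(inversion_times_s, dtype=float)
    s = a[..., None] - b[..., None] * np.exp(-ti / t1_star[..., None])
    return np.abs(s)
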