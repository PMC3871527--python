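"""Dual-echo signal to contrast-agent concentration.

The dynamic series is acquired at two echo times so that susceptibility
(T2*) weighting can be removed frame by frame: the log-ratio of the echoes
gives R2*(t) and an extrapolation to TE = 0 gives the purely T1-weighted
amplitude S0(t). With the pre-contrast T1 known from the Look-Locker scan,
the spoiled gradient-echo equation is inverted per frame for R1(t) and the
concentration follows from the linear relaxivity relation
``Ct = (R1(t) - R1pre) / r1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionSpec
from .relaxometry import T1Map
from .signalmodel import spgr_dsignal_dr1, spgr_invert, spgr_signal

__all__ = ["ConcentrationSeries", "dual_echo_split", "signal_to_concentration"]


@dataclass
class ConcentrationSeries:
    """Per-voxel tissue concentration Ct(t) in mM plus R2* diagnostics."""

    ct_mM: np.ndarray          # (n_vox, n_frames)
    r2star_per_s: np.ndarray   # (n_vox, n_frames)
    baseline_frames: tuple[int, int]  # [start, stop) 0-based frame window
    valid: np.ndarray          # (n_vox,) bool


def dual_echo_split(
    s1: np.ndarray,
    s2: np.ndarray,
    te1_s: float,
    te2_s: float,
    noise_sd: float | None = None,
    systematic_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a dual-echo pair into TE = 0 amplitude and R2*.

    R2* = ln(S1/S2)/(TE2 - TE1) and S0 = S1 exp(TE1 R2*). A second echo
    slightly above the first is an ordinary noise excursion; the implied
    (small, negative) R2* is kept as-is, because truncating the noise at
    R2* = 0 would bias the extrapolated amplitude in a signal-level-dependent
    way and forge spurious enhancement. When ``noise_sd`` is given, samples
    where S2 exceeds S1 by more than 4 sqrt(2) noise SDs are beyond noise
    tolerance and are clamped to R2* = 0 with a warning. If more than
    ``systematic_fraction`` of all samples are inverted the echo assignment
    is systematically wrong and the split is refused.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if te2_s <= te1_s:
        raise ValueError("TE2 must exceed TE1")
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("dual-echo split requires positive signals")
    inverted = s2 > s1
    frac = float(inverted.mean())
    if frac > systematic_fraction:
        raise ValueError(
            f"second echo exceeds first on {frac:.0%} of samples; "
            "echo assignment looks systematically wrong"
        )
    with np.errstate(divide="ignore"):
        r2star = np.log(s1 / s2) / (te2_s - te1_s)
    if noise_sd is not None:
        beyond = s2 > s1 + 4.0 * np.sqrt(2.0) * noise_sd
        if np.any(beyond):
            warnings.warn(
                f"R2* clamped to 0 on {float(beyond.mean()):.2%} of samples "
                "(second echo above first beyond noise tolerance)",
                RuntimeWarning,
                stacklevel=2,
            )
            r2star = np.where(beyond, 0.0, r2star)
    s0 = s1 * np.exp(te1_s * r2star)
    return s0, r2star


def signal_to_concentration(
    s0_series: np.ndarray,
    t1_pre: T1Map,
    spec: AcquisitionSpec,
    r1_relaxivity: float | None = None,
    baseline_frames: tuple[int, int] | None = None,
    max_flagged_fraction: float = 0.10,
    r2star: np.ndarray | None = None,
    linearize: bool = False,
) -> ConcentrationSeries:
    """Invert TE = 0 dynamic amplitudes into concentration time-courses.

    The voxel scale factor M0 is fixed from the baseline mean and the
    pre-contrast T1, after which each frame is inverted in closed form for
    R1(t). Frames whose signal falls outside the invertible domain are
    flagged and linearly interpolated from neighbouring frames; voxels with
    more than ``max_flagged_fraction`` flagged frames, or without a valid
    pre-contrast T1, are excluded.

    Baseline default: frames 2..(bolus-1) in 1-based counting — frame 1 is
    skipped for steady-state settling.

    ``linearize`` replaces the exact inversion with the first-order
    small-dR1 expansion ``dR1 = dS / (M0 dS/dR1|pre)`` — cheaper and
    adequate at low enhancement, but biased when the signal response
    saturates; the exact inversion is the default.
    """
    s0 = np.atleast_2d(np.asarray(s0_series, dtype=float))
    n_vox, n_frames = s0.shape
    if n_frames != spec.n_frames:
        raise ValueError("dynamic series length does not match the acquisition spec")
    r1 = spec.r1_relaxivity if r1_relaxivity is None else r1_relaxivity
    if baseline_frames is None:
        baseline_frames = (1, spec.bolus_frame - 1)  # 0-based [1, bolus-1)
    b0, b1 = baseline_frames
    if b1 <= b0 or b1 > spec.bolus_frame - 1:
        raise ValueError("baseline window must be non-empty and entirely pre-bolus")

    t1v = np.asarray(t1_pre.t1_s, dtype=float).reshape(n_vox)
    valid = np.asarray(t1_pre.converged, dtype=bool).reshape(n_vox) & (t1v > 0)
    r1_pre = np.where(valid, 1.0 / np.where(valid, t1v, 1.0), np.nan)

    alpha, tr = spec.flip_angle_rad, spec.tr_s
    base_mean = s0[:, b0:b1].mean(axis=1)
    f_pre = spgr_signal(1.0, r1_pre, alpha, tr)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = base_mean / f_pre

    if linearize:
        slope = m0 * spgr_dsignal_dr1(1.0, r1_pre, alpha, tr)
        with np.errstate(divide="ignore", invalid="ignore"):
            r1_t = r1_pre[:, None] + (s0 - base_mean[:, None]) / slope[:, None]
    else:
        r1_t = spgr_invert(s0, m0[:, None], alpha, tr)
    flagged = ~np.isfinite(r1_t)
    frac_flagged = flagged.mean(axis=1)
    valid &= frac_flagged <= max_flagged_fraction

    # interpolate flagged frames from valid neighbours, per voxel
    if np.any(flagged & valid[:, None]):
        idx = np.arange(n_frames)
        for v in np.nonzero(valid & flagged.any(axis=1))[0]:
            good = ~flagged[v]
            r1_t[v, flagged[v]] = np.interp(idx[flagged[v]], idx[good], r1_t[v, good])

    ct = (r1_t - r1_pre[:, None]) / r1
    ct = np.where(valid[:, None], ct, np.nan)
    if r2star is None:
        r2star = np.zeros_like(ct)
    return ConcentrationSeries(
        ct_mM=ct,
        r2star_per_s=np.atleast_2d(r2star),
        baseline_frames=baseline_frames,
        valid=valid,
    )
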