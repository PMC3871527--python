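"""Nested transvascular kinetic models and per-voxel fitting.

Three nested models describe the tissue concentration time-course Ct(t)
driven by the plasma curve Cp(t):

* Model 1 — intravascular only:       Ct = vp Cp
* Model 2 — influx without backflux:  Ct = vp Cp + Ktrans int_0^t Cp dtau
* Model 3 — influx with backflux:     Ct = vp Cp + Ktrans int_0^t Cp(tau) exp(-kep (t - tau)) dtau

vp is the fractional plasma volume, Ktrans (min^-1) the forward volume
transfer constant, kep (min^-1) the backflux rate, and ve = Ktrans/kep the
fractional interstitial volume. Model 2 is the Patlak limit of Model 3
(kep -> 0); Model 1 is the Ktrans = 0 limit of Model 2, so least-squares
residuals are nested: SSE1 >= SSE2 >= SSE3.

Orders 1-2 are linear least-squares problems. Order 3 is separable: for
fixed kep the remaining parameters are linear, so the fit profiles the
linear pair over a bracketed scalar search in kep (coarse grid plus
golden-section refinement), with nonnegativity enforced by comparing the
boundary-constrained candidates of the 2x2 problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .aif import PlasmaCurve, detect_bolus_arrival

__all__ = [
    "PKVoxelResult",
    "PKFitMaps",
    "forward_model",
    "fit_model",
    "fit_voxels",
    "exp_conv",
]

_KEP_MAX_DEFAULT = 10.0  # min^-1; generous upper bound for tumor backflux


# ---------------------------------------------------------------------------
# numerical kernels
# ---------------------------------------------------------------------------

def exp_conv(cp: np.ndarray, t_min: np.ndarray, kep: np.ndarray | float) -> np.ndarray:
    """Causal convolution int_0^t Cp(tau) exp(-kep (t - tau)) dtau.

    Exact for a piecewise-linear Cp; reduces to the cumulative trapezoid at
    kep = 0 (series branch), which keeps the Model 3 -> Model 2 limit exact
    to rounding. ``kep`` may be a scalar or an array of per-voxel rates; the
    result has shape ``np.shape(kep) + cp.shape``.
    """
    cp = np.asarray(cp, dtype=float)
    t = np.asarray(t_min, dtype=float)
    k = np.atleast_1d(np.asarray(kep, dtype=float))
    n = cp.size
    out = np.zeros(k.shape + (n,), dtype=float)
    acc = np.zeros(k.shape, dtype=float)
    dts = np.diff(t)
    uniform = bool(np.all(np.abs(dts - dts[0]) <= 1e-12 * dts[0])) if n > 1 else True

    def _weights(dt: float):
        kdt = k * dt
        e = np.exp(-kdt)
        small = kdt < 1e-6
        ksafe = np.where(k == 0, 1.0, k)
        j0 = np.where(small, dt * (1.0 - kdt / 2.0), (1.0 - e) / ksafe)
        j1 = np.where(
            small,
            dt / 2.0 * (1.0 - kdt / 3.0),
            (1.0 - e) / ksafe - (1.0 - e * (1.0 + kdt)) / ksafe**2 / dt,
        )
        return e, j0 - j1, j1

    if uniform and n > 1:
        e, w_prev, w_cur = _weights(float(dts[0]))
        for i in range(1, n):
            acc = acc * e + cp[i - 1] * w_prev + cp[i] * w_cur
            out[..., i] = acc
    else:
        for i in range(1, n):
            e, w_prev, w_cur = _weights(float(t[i] - t[i - 1]))
            acc = acc * e + cp[i - 1] * w_prev + cp[i] * w_cur
            out[..., i] = acc
    if np.isscalar(kep) or np.asarray(kep).ndim == 0:
        return out[0]
    return out


def _windowed_aif(aif: PlasmaCurve, arrival_idx: int | None = None):
    """Time grid (min), Cp and start index with integrals anchored at bolus arrival.

    Cp before the detected arrival is treated as zero so that the kinetic
    integrals start at the arrival sample rather than accumulating baseline
    noise or the half-interval of the step.
    """
    if arrival_idx is None:
        try:
            arrival_idx = detect_bolus_arrival(aif.cp_mM)
        except ValueError:
            # flat curve (e.g. Cp identically zero): no origin to anchor;
            # keep the whole grid, downstream flags unfittable voxels
            arrival_idx = 0
    t_min = aif.time_s / 60.0
    cp = aif.cp_mM.copy()
    cp[:arrival_idx] = 0.0
    return t_min[arrival_idx:] , cp[arrival_idx:], arrival_idx


# ---------------------------------------------------------------------------
# forward evaluation
# ---------------------------------------------------------------------------

def forward_model(
    order: int,
    aif: PlasmaCurve,
    vp: float = 0.0,
    ktrans: float = 0.0,
    kep: float = 0.0,
    arrival_idx: int | None = None,
) -> np.ndarray:
    """Evaluate one nested model on the AIF grid.

    Returns Ct (mM) on the full acquisition grid (zero before bolus
    arrival). Causality holds by construction; the kinetic integrals use the
    same quadrature as the fitting routines, so noiseless synthesis followed
    by fitting recovers the generating parameters.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"model order must be 1, 2 or 3, got {order!r}")
    if vp < 0 or ktrans < 0:
        raise ValueError("vp and Ktrans must be nonnegative")
    if order == 3 and kep <= 0:
        raise ValueError("order 3 requires kep > 0")
    t_sub, cp_sub, i0 = _windowed_aif(aif, arrival_idx)
    ct_sub = vp * cp_sub
    if order == 2:
        ct_sub = ct_sub + ktrans * cumulative_trapezoid(cp_sub, t_sub, initial=0.0)
    elif order == 3:
        ct_sub = ct_sub + ktrans * exp_conv(cp_sub, t_sub, kep)
    ct = np.zeros_like(aif.cp_mM)
    ct[i0:] = ct_sub
    return ct


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _ls2(a11, a12, a22, b1, b2, yy):
    """Unconstrained least squares for two regressors, vectorized closed form.

    Returns (beta1, beta2, sse, ok) from the Gram/cross products; ``ok`` is
    False where the regressors are numerically collinear.
    """
    det = a11 * a22 - a12 * a12
    scale = np.maximum(a11 * a22, 1e-300)
    ok = det > 1e-12 * scale
    safe_det = np.where(ok, det, 1.0)
    u1 = (a22 * b1 - a12 * b2) / safe_det
    u2 = (a11 * b2 - a12 * b1) / safe_det
    sse = yy - u1 * b1 - u2 * b2
    return u1, u2, np.maximum(sse, 0.0), ok


def _nnls2(a11, a12, a22, b1, b2, yy):
    """Nonnegative least squares for two regressors, vectorized closed form.

    Solves min ||y - b1*x1 - b2*x2||^2 s.t. beta >= 0 by comparing the
    unconstrained stationary point with the two boundary solutions. Inputs
    are the Gram/cross products; returns (beta1, beta2, sse).
    """
    u1, u2, sse_u, ok = _ls2(a11, a12, a22, b1, b2, yy)
    # boundary candidates
    c1 = np.maximum(b1 / np.maximum(a11, 1e-300), 0.0)  # beta2 = 0
    sse_c1 = yy - 2 * c1 * b1 + c1 * c1 * a11
    c2 = np.maximum(b2 / np.maximum(a22, 1e-300), 0.0)  # beta1 = 0
    sse_c2 = yy - 2 * c2 * b2 + c2 * c2 * a22
    interior = ok & (u1 >= 0) & (u2 >= 0)
    use_c1 = ~interior & (sse_c1 <= sse_c2)
    beta1 = np.where(interior, u1, np.where(use_c1, c1, 0.0))
    beta2 = np.where(interior, u2, np.where(use_c1, 0.0, c2))
    sse = np.where(interior, sse_u, np.where(use_c1, sse_c1, sse_c2))
    return beta1, beta2, np.maximum(sse, 0.0)


@dataclass
class PKVoxelResult:
    """Per-voxel nested-model fit: parameters per order plus residuals.

    ``ve = Ktrans/kep`` is emitted as an identity of the order-3 parameters.
    ``selected_order`` is filled by the model-selection stage.
    """

    vp1: float
    sse1: float
    vp2: float
    ktrans2: float
    sse2: float
    vp3: float
    ktrans3: float
    kep3: float
    sse3: float
    n_fit: int
    fittable: bool = True
    cov2: np.ndarray | None = None
    cov3: np.ndarray | None = None
    selected_order: int | None = None

    @property
    def ve3(self) -> float:
        return self.ktrans3 / self.kep3 if self.kep3 > 0 else np.nan


@dataclass
class PKFitMaps:
    """Vectorized fit results over a set of voxels (flat arrays)."""

    vp1: np.ndarray
    sse1: np.ndarray
    vp2: np.ndarray
    ktrans2: np.ndarray
    sse2: np.ndarray
    vp3: np.ndarray
    ktrans3: np.ndarray
    kep3: np.ndarray
    sse3: np.ndarray
    n_fit: int
    fittable: np.ndarray

    @property
    def ve3(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.kep3 > 0, self.ktrans3 / self.kep3, np.nan)

    def __len__(self) -> int:
        return self.vp1.size


def fit_voxels(
    ct: np.ndarray,
    aif: PlasmaCurve,
    weights: np.ndarray | None = None,
    kep_max: float = _KEP_MAX_DEFAULT,
    n_kep_coarse: int = 40,
    n_golden: int = 40,
    min_post_frames: int = 10,
) -> PKFitMaps:
    """Fit all three nested models to every row of ``ct``.

    ``ct`` has shape (n_voxels, n_frames) on the AIF grid. Only post-arrival
    frames enter the least squares (the models are identically zero before
    arrival). Optional per-frame weights implement inverse-variance
    weighting; default is unweighted.
    """
    ct = np.atleast_2d(np.asarray(ct, dtype=float))
    if ct.shape[1] != len(aif):
        raise ValueError("concentration grid and AIF grid are misaligned")
    t_sub, cp, i0 = _windowed_aif(aif)
    n = t_sub.size
    if n < min_post_frames:
        raise ValueError(f"need at least {min_post_frames} post-bolus frames, have {n}")
    y = ct[:, i0:]
    cp_raw = cp  # convolution kernels act on the unweighted plasma curve
    icp = cumulative_trapezoid(cp_raw, t_sub, initial=0.0)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float)[i0:])
        y = y * w
        cp = cp_raw * w
        icp = icp * w
    else:
        w = None

    yy = np.einsum("ij,ij->i", y, y)
    a11 = float(cp @ cp)
    b1 = y @ cp
    fittable = a11 > 0

    # Recorded SSEs are those of the unconstrained nested least-squares fits
    # (classical nested-F theory); reported parameters are projected to the
    # physical domain (nonnegative, via the boundary-comparing 2x2 solver).
    # The constraint only binds on voxels whose signal is noise-dominated.

    # order 1: single regressor {Cp}
    vp1_u = b1 / max(a11, 1e-300)
    sse1 = np.maximum(yy - vp1_u * b1, 0.0)
    vp1 = np.maximum(vp1_u, 0.0)

    # order 2: regressors {Cp, int Cp}
    a22 = float(icp @ icp)
    a12 = float(cp @ icp)
    b2 = y @ icp
    _, _, sse2, _ = _ls2(a11, a12, a22, b1, b2, yy)
    sse2 = np.minimum(sse2, sse1)  # nesting, exact in theory, enforced vs rounding
    vp2, kt2, _ = _nnls2(a11, a12, a22, b1, b2, yy)

    # order 3: profile the linear pair over kep
    kep_grid = np.concatenate([[0.0], np.geomspace(1e-3, kep_max, n_kep_coarse - 1)])
    sse_grid = np.empty((kep_grid.size, y.shape[0]))
    for j, k in enumerate(kep_grid):
        conv = icp if k == 0.0 else exp_conv(cp_raw, t_sub, k)
        if w is not None and k != 0.0:
            conv = conv * w
        _, _, sse_grid[j], _ = _ls2(a11, float(cp @ conv), float(conv @ conv), b1, y @ conv, yy)
    best = np.argmin(sse_grid, axis=0)
    lo = kep_grid[np.maximum(best - 1, 0)]
    hi = kep_grid[np.minimum(best + 1, kep_grid.size - 1)]

    def sse_at(k_arr: np.ndarray) -> np.ndarray:
        conv = exp_conv(cp_raw, t_sub, k_arr)  # (n_vox, n)
        if w is not None:
            conv = conv * w
        a12v = conv @ cp
        a22v = np.einsum("ij,ij->i", conv, conv)
        b2v = np.einsum("ij,ij->i", y, conv)
        _, _, s, _ = _ls2(a11, a12v, a22v, b1, b2v, yy)
        return s

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(n_golden):
        d = hi - lo
        x1 = hi - invphi * d
        x2 = lo + invphi * d
        f1 = sse_at(x1)
        f2 = sse_at(x2)
        take_left = f1 < f2
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
    kep3 = 0.5 * (lo + hi)
    conv = exp_conv(cp_raw, t_sub, kep3)
    if w is not None:
        conv = conv * w
    a12v = conv @ cp
    a22v = np.einsum("ij,ij->i", conv, conv)
    b2v = np.einsum("ij,ij->i", y, conv)
    _, _, sse3, _ = _ls2(a11, a12v, a22v, b1, b2v, yy)
    vp3, kt3, _ = _nnls2(a11, a12v, a22v, b1, b2v, yy)
    # fall back to the Patlak solution where the refined point did not beat it
    worse = sse3 > sse2
    kep3 = np.where(worse, 0.0, kep3)
    vp3 = np.where(worse, vp2, vp3)
    kt3 = np.where(worse, kt2, kt3)
    sse3 = np.minimum(sse3, sse2)

    fit = PKFitMaps(
        vp1=vp1, sse1=sse1,
        vp2=vp2, ktrans2=kt2, sse2=sse2,
        vp3=vp3, ktrans3=kt3, kep3=kep3, sse3=sse3,
        n_fit=n,
        fittable=np.broadcast_to(np.asarray(fittable), vp1.shape).copy(),
    )
    return fit


def _cov2(a11, a12, a22, sse, n):
    """Covariance of a 2-regressor linear fit, sigma^2 (X'X)^-1."""
    det = a11 * a22 - a12 * a12
    if det <= 0 or n <= 2:
        return None
    s2 = sse / (n - 2)
    return s2 / det * np.array([[a22, -a12], [-a12, a11]])


def fit_model(
    order: int,
    ct: np.ndarray,
    aif: PlasmaCurve,
    weights: np.ndarray | None = None,
    **kwargs,
) -> PKVoxelResult:
    """Single-voxel convenience wrapper around :func:`fit_voxels`.

    Fits all three orders (they share the expensive pieces) and returns the
    scalar result; ``order`` controls which covariance is populated.
    """
    maps = fit_voxels(np.atleast_2d(ct), aif, weights=weights, **kwargs)
    t_sub, cp, i0 = _windowed_aif(aif)
    icp = cumulative_trapezoid(cp, t_sub, initial=0.0)
    a11 = float(cp @ cp)
    cov2 = _cov2(a11, float(cp @ icp), float(icp @ icp), float(maps.sse2[0]), maps.n_fit)
    conv = exp_conv(cp, t_sub, float(maps.kep3[0]))
    cov3 = _cov2(a11, float(cp @ conv), float(conv @ conv), float(maps.sse3[0]), maps.n_fit)
    return PKVoxelResult(
        vp1=float(maps.vp1[0]), sse1=float(maps.sse1[0]),
        vp2=float(maps.vp2[0]), ktrans2=float(maps.ktrans2[0]), sse2=float(maps.sse2[0]),
        vp3=float(maps.vp3[0]), ktrans3=float(maps.ktrans3[0]),
        kep3=float(maps.kep3[0]), sse3=float(maps.sse3[0]),
        n_fit=maps.n_fit, fittable=bool(maps.fittable[0]),
        cov2=cov2, cov3=cov3,
    )
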