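"""Look-Locker T1 mapping.

Fits the three-parameter magnitude inversion-recovery model
``|S(TI)| = |A - B exp(-TI/T1*)|`` per voxel and applies the standard
readout correction ``T1 = T1* (B/A - 1)``. Magnitude data lose the sign of
the inverted magnetization, so polarity is restored by a sign-flip search
around the signal minimum before fitting.

The fit is separable: for fixed T1* the model is linear in (A, B), so each
voxel reduces to a one-dimensional minimization over T1*, solved with a
coarse bracket plus golden-section refinement, vectorized over voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["T1Map", "fit_look_locker"]

_T1STAR_LO = 0.02  # s
_T1STAR_HI = 10.0  # s


@dataclass
class T1Map:
    """Per-voxel corrected T1 (s), apparent T1* (s) and fit diagnostics."""

    t1_s: np.ndarray
    t1_star_s: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray  # bool per voxel

    def __len__(self) -> int:
        return self.t1_s.size


def _separable_sse(s: np.ndarray, ti: np.ndarray, t1_star: np.ndarray):
    """Profile (A, B) out of the IR model for per-voxel T1*.

    ``s`` is the polarity-restored signal (n_vox, n_ti); ``t1_star`` is
    (n_vox,). Returns (sse, a, b) from the exact 2x2 normal equations with
    regressors {1, -exp(-TI/T1*)}.
    """
    e = np.exp(-ti[None, :] / t1_star[:, None])
    n = float(ti.size)
    se = e.sum(axis=1)
    see = np.einsum("ij,ij->i", e, e)
    sy = s.sum(axis=1)
    sye = np.einsum("ij,ij->i", s, e)
    syy = np.einsum("ij,ij->i", s, s)
    det = n * see - se * se
    det = np.where(det <= 0, np.nan, det)
    a = (see * sy - se * sye) / det
    b = (n * sye - se * sy) / det * -1.0  # model is A - B e
    sse = syy - 2 * a * sy + 2 * b * sye + a * a * n - 2 * a * b * se + b * b * see
    return np.maximum(sse, 0.0), a, b


def _fit_polarity(s_signed: np.ndarray, ti: np.ndarray, n_golden: int = 45):
    """Golden-section minimization of the separable SSE over T1*."""
    n_vox = s_signed.shape[0]
    # coarse bracket
    grid = np.geomspace(_T1STAR_LO, _T1STAR_HI, 24)
    sse_g = np.empty((grid.size, n_vox))
    for j, t1s in enumerate(grid):
        sse_g[j], _, _ = _separable_sse(s_signed, ti, np.full(n_vox, t1s))
    best = np.nanargmin(sse_g, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid.size - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(n_golden):
        d = hi - lo
        x1 = hi - invphi * d
        x2 = lo + invphi * d
        f1, _, _ = _separable_sse(s_signed, ti, x1)
        f2, _, _ = _separable_sse(s_signed, ti, x2)
        left = f1 < f2
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
    t1_star = 0.5 * (lo + hi)
    sse, a, b = _separable_sse(s_signed, ti, t1_star)
    return t1_star, sse, a, b


def fit_look_locker(
    series: np.ndarray,
    inversion_times_s: np.ndarray,
    n_golden: int = 45,
) -> T1Map:
    """Fit the Look-Locker model to every voxel of a magnitude series.

    ``series`` has shape (n_voxels, n_ti); ``inversion_times_s`` must hold at
    least 4 distinct values (three parameters plus one residual degree of
    freedom). Voxels that cannot be fit (all-zero series, degenerate
    amplitudes with B <= A, or non-finite input) are flagged rather than
    raising. Estimates do not depend on the ordering of the (TI, S) pairs.
    """
    s = np.atleast_2d(np.asarray(series, dtype=float))
    ti = np.asarray(inversion_times_s, dtype=float)
    if np.unique(ti).size < 4:
        raise ValueError("need at least 4 distinct inversion times")
    if s.shape[1] != ti.size:
        raise ValueError("series and inversion-time axes are misaligned")
    order = np.argsort(ti, kind="stable")
    ti = ti[order]
    s = np.abs(s[:, order])

    n_vox = s.shape[0]
    finite = np.all(np.isfinite(s), axis=1)
    nonzero = s.max(axis=1) > 0
    usable = finite & nonzero

    imin = np.argmin(np.where(usable[:, None], s, np.inf), axis=1)
    best = {"sse": np.full(n_vox, np.inf), "t1s": np.zeros(n_vox),
            "a": np.zeros(n_vox), "b": np.zeros(n_vox),
            "k": np.zeros(n_vox, dtype=int)}
    # the true zero crossing lies just before or just after the minimum sample
    for extra in (0, 1):
        k = np.clip(imin + extra, 0, ti.size)
        signs = np.where(np.arange(ti.size)[None, :] < k[:, None], -1.0, 1.0)
        t1s, sse, a, b = _fit_polarity(s * signs, ti, n_golden=n_golden)
        better = sse < best["sse"]
        for key, val in (("sse", sse), ("t1s", t1s), ("a", a), ("b", b), ("k", k)):
            best[key] = np.where(better, val, best[key])

    # Gauss-Newton polish: the golden section localizes T1* only to about
    # sqrt(machine eps); a few full-model Newton steps (with an SSE-decrease
    # safeguard, so the residual is non-increasing) reach the floor.
    signs = np.where(np.arange(ti.size)[None, :] < best["k"][:, None], -1.0, 1.0)
    s_signed = s * signs
    a, b, t1_star, sse = best["a"], best["b"], best["t1s"], best["sse"]
    for _ in range(4):
        with np.errstate(all="ignore"):
            e = np.exp(-ti[None, :] / t1_star[:, None])
            model = a[:, None] - b[:, None] * e
            r = s_signed - model
            j_t = -b[:, None] * e * ti[None, :] / (t1_star**2)[:, None]
            jac = np.stack([np.ones_like(e), -e, j_t], axis=2)  # (n, m, 3)
            jtj = np.einsum("nmi,nmj->nij", jac, jac)
            jtr = np.einsum("nmi,nm->ni", jac, r)
            # tiny Levenberg ridge keeps degenerate (e.g. all-zero) voxels solvable
            ridge = 1e-12 * np.maximum(jtj[:, [0, 1, 2], [0, 1, 2]].max(axis=1), 1.0)
            jtj[:, [0, 1, 2], [0, 1, 2]] += ridge[:, None]
            delta = np.linalg.solve(jtj, jtr[:, :, None])[:, :, 0]
            a_n = a + delta[:, 0]
            b_n = b + delta[:, 1]
            t_n = np.clip(t1_star + delta[:, 2], _T1STAR_LO / 10, _T1STAR_HI * 10)
            e_n = np.exp(-ti[None, :] / t_n[:, None])
            sse_n = np.einsum("nm,nm->n", s_signed - (a_n[:, None] - b_n[:, None] * e_n),
                              s_signed - (a_n[:, None] - b_n[:, None] * e_n))
            accept = np.isfinite(sse_n) & (sse_n < sse)
            a = np.where(accept, a_n, a)
            b = np.where(accept, b_n, b)
            t1_star = np.where(accept, t_n, t1_star)
            sse = np.where(accept, sse_n, sse)
    best["sse"] = sse
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b / a
        t1 = t1_star * (ratio - 1.0)
    signal_norm = np.sqrt(np.einsum("ij,ij->i", s, s))
    converged = (
        usable
        & np.isfinite(t1)
        & (a > 0)
        & (ratio > 1.0 + 1e-9)
        & (t1 > 0)
    )
    t1 = np.where(converged, t1, np.nan)
    t1_star = np.where(usable, t1_star, np.nan)
    resid = np.sqrt(best["sse"]) / np.maximum(signal_norm, 1e-300)
    return T1Map(t1_s=t1, t1_star_s=t1_star, residual_norm=resid, converged=converged)
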