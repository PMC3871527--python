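"""Per-voxel model-order assignment by sequential nested F-tests.

Starting from the intravascular model, each added parameter is kept only if
it reduces the residual sum of squares more than chance would predict:

    F = ((SSE_a - SSE_b) / (p_b - p_a)) / (SSE_b / (n - p_b))

with p1 = 1, p2 = 2, p3 = 3 and n the number of post-arrival frames used in
fitting. Selection proceeds 1 -> 2 -> 3 and stops at the first
non-significant step, so a voxel is called order 3 only when both steps are
significant. Voxels whose baseline SNR is below threshold are order 0
(background) and never fitted. The order-3 mask is what feeds every
downstream test-retest statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pk_models import PKFitMaps

__all__ = ["ModelOrderMap", "select_models", "select_model", "make_masked_maps"]

# perfect fits at both orders: treat as "no improvement" (parsimony)
_REL_EPS = 1e-12


@dataclass
class ModelOrderMap:
    """Selected model order per voxel with the F statistics behind it."""

    order: np.ndarray  # int, in {0,1,2,3}
    f12: np.ndarray
    f23: np.ndarray
    p12: np.ndarray
    p23: np.ndarray
    alpha: float

    def __len__(self) -> int:
        return self.order.size


def _nested_f(sse_a: np.ndarray, sse_b: np.ndarray, df_extra: int, df_resid: np.ndarray | int):
    """F statistic and p-value of one nesting step, safe at zero residuals."""
    sse_a = np.asarray(sse_a, dtype=float)
    sse_b = np.asarray(sse_b, dtype=float)
    diff = np.maximum(sse_a - sse_b, 0.0)
    scale = np.maximum(sse_a, 1e-300)
    both_perfect = (sse_b <= _REL_EPS * scale) & (diff <= _REL_EPS * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (diff / df_extra) / (sse_b / df_resid)
    # a perfect larger model with real improvement is infinitely significant
    f = np.where((sse_b == 0) & (diff > 0), np.inf, f)
    f = np.where(both_perfect, 0.0, f)
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isfinite(f), f, 0.0), df_extra, df_resid))
    p = np.where(both_perfect, 1.0, p)
    return f, p


def select_models(
    fit: PKFitMaps,
    alpha: float = 0.05,
    background: np.ndarray | None = None,
) -> ModelOrderMap:
    """Assign an order to every voxel of a vectorized fit.

    ``background`` marks voxels to force to order 0 (e.g. sub-threshold
    baseline SNR); unfittable voxels are also order 0. Raising ``alpha``
    never shrinks the order-3 set for fixed data.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    n = fit.n_fit
    if n <= 4:
        raise ValueError("too few frames for nested F-tests")
    f12, p12 = _nested_f(fit.sse1, fit.sse2, 1, n - 2)
    f23, p23 = _nested_f(fit.sse2, fit.sse3, 1, n - 3)
    # acceptance at p <= alpha: under the boundary null (kep pinned at 0)
    # the 2->3 step can yield p = 1 exactly, and the alpha = 1 limit must
    # still promote every fittable voxel
    order = np.ones(len(fit), dtype=int)
    step2 = p12 <= alpha
    order[step2] = 2
    order[step2 & (p23 <= alpha)] = 3
    excluded = ~fit.fittable
    if background is not None:
        excluded |= np.asarray(background, dtype=bool)
    order[excluded] = 0
    return ModelOrderMap(order=order, f12=f12, f23=f23, p12=p12, p23=p23, alpha=alpha)


def select_model(fit, alpha: float = 0.05, background: bool = False) -> int:
    """Single-voxel convenience wrapper; returns the selected order."""
    from .pk_models import PKVoxelResult

    if isinstance(fit, PKVoxelResult):
        maps = PKFitMaps(
            vp1=np.array([fit.vp1]), sse1=np.array([fit.sse1]),
            vp2=np.array([fit.vp2]), ktrans2=np.array([fit.ktrans2]), sse2=np.array([fit.sse2]),
            vp3=np.array([fit.vp3]), ktrans3=np.array([fit.ktrans3]),
            kep3=np.array([fit.kep3]), sse3=np.array([fit.sse3]),
            n_fit=fit.n_fit, fittable=np.array([fit.fittable]),
        )
    else:
        maps = fit
    sel = select_models(maps, alpha=alpha, background=np.array([background]))
    return int(sel.order[0])


class NoModel3VoxelsError(ValueError):
    """Raised when a summary is requested over an empty order-3 mask."""


def make_masked_maps(fit: PKFitMaps, order_map: ModelOrderMap) -> dict[str, np.ndarray]:
    """Final parameter maps masked by the selected order.

    vp is reported wherever a vascular signal exists (order >= 1), Ktrans
    wherever leakage was significant (order >= 2) and ve only on order-3
    voxels, where the backflux rate is identifiable. The order-3 boolean
    mask is exported alongside.
    """
    order = order_map.order
    if order.shape != fit.vp1.shape:
        raise ValueError("order map and fit maps are misaligned")
    o = order
    vp = np.where(o >= 3, fit.vp3, np.where(o == 2, fit.vp2, np.where(o == 1, fit.vp1, np.nan)))
    ktrans = np.where(o >= 3, fit.ktrans3, np.where(o == 2, fit.ktrans2, np.nan))
    kep = np.where(o >= 3, fit.kep3, np.nan)
    ve = np.where(o >= 3, fit.ve3, np.nan)
    mask3 = o == 3
    return {"vp": vp, "ktrans": ktrans, "kep": kep, "ve": ve, "model3_mask": mask3, "order": o}
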