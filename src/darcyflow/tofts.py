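"""Extended Tofts compartmental model: forward solution and fitting.

The model describes the tissue saturation curve as leakage from plasma
into the extravascular-extracellular space (EES) plus a direct plasma
contribution:

    s(t) = Ktrans * int_0^t s_AIF(u) exp(-(Ktrans/ve) (t-u)) du + fpv * s_AIF(t)

with Ktrans [1/s] the forward volume transfer constant, ve the EES
volume fraction, and fpv the fractional plasma volume. fpv is left
unconstrained in the fit: negative fitted values are a known behaviour
of this model on real data and must not be clipped away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import AIFCurve, DynamicImage, Image3D, LabelMap
from .errors import ArgumentError, DegenerateInputError


@dataclass
class ToftsParams:
    ktrans: float           # 1/s, >= 0
    ve: float               # (0, 1]
    fpv: float              # unbounded
    residual: float = 0.0   # RMS of the fit residual
    converged: bool = True


@dataclass
class ToftsParamMaps:
    ktrans: Image3D
    ve: Image3D
    fpv: Image3D
    residual: Image3D
    valid: np.ndarray


DEFAULT_INIT = ToftsParams(ktrans=0.005, ve=0.3, fpv=0.05)
# fallback starting points used when the first fit leaves a large residual
_MULTISTART = [(0.001, 0.1, 0.0), (0.02, 0.5, 0.2), (0.05, 0.8, -0.05)]

_TRAPZ_CACHE: dict[bytes, np.ndarray] = {}


def _cumulative_trapezoid_weights(t: np.ndarray) -> np.ndarray:
    """Lower-triangular W with row i holding trapezoid weights for int_0^{t_i}."""
    key = t.tobytes()
    w = _TRAPZ_CACHE.get(key)
    if w is None:
        n = len(t)
        dt = np.diff(t)
        c = np.concatenate([[dt[0] / 2], (dt[:-1] + dt[1:]) / 2])  # interior weights
        diag = np.concatenate([[0.0], dt / 2])                      # right-endpoint weight
        I, J = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        w = np.where(J < I, np.take(c, np.minimum(J, n - 2)), 0.0)
        w[np.arange(n), np.arange(n)] = diag
        if len(_TRAPZ_CACHE) > 16:
            _TRAPZ_CACHE.clear()
        _TRAPZ_CACHE[key] = w
    return w


def extended_tofts_forward(ktrans: float, ve: float, fpv: float,
                           aif: AIFCurve, times=None) -> np.ndarray:
    """Forward model curve on the sampled grid (causal trapezoid convolution)."""
    if ktrans < 0:
        raise ArgumentError(f"ktrans must be nonnegative, got {ktrans}")
    if ktrans > 0 and ve <= 0:
        raise ArgumentError(f"ve must be positive when ktrans > 0, got {ve}")
    t = np.asarray(aif.times if times is None else times, dtype=float)
    s = aif.sample(t)
    out = fpv * s
    if ktrans > 0:
        kep = ktrans / ve
        # trapezoid over u <= t_i of s(u) * exp(-kep (t_i - u))
        lag = np.maximum(t[:, None] - t[None, :], 0.0)
        E = np.exp(-kep * lag)
        w = _cumulative_trapezoid_weights(t)
        out = out + ktrans * (w * E * s[None, :]).sum(axis=1)
    return out


def fit_extended_tofts(curve: np.ndarray, aif: AIFCurve, times=None,
                       init: ToftsParams = DEFAULT_INIT,
                       residual_threshold: float = 0.1) -> ToftsParams:
    """Nonlinear least-squares fit of (Ktrans, ve, fpv) to one curve.

    Ktrans and ve are bounded for identifiability; fpv is free. The fit
    is deterministic given ``init``; when the relative residual exceeds
    ``residual_threshold`` a fixed set of alternative starts is tried
    and the best minimiser kept.
    """
    curve = np.asarray(curve, dtype=float)
    t = np.asarray(aif.times if times is None else times, dtype=float)
    if len(curve) < 4:
        raise DegenerateInputError("fit needs at least 4 samples")
    scale = float(np.max(np.abs(curve)))
    if scale == 0.0:
        return ToftsParams(0.0, init.ve, 0.0, residual=0.0, converged=True)

    def resid(x):
        return extended_tofts_forward(x[0], x[1], x[2], aif, t) - curve

    # Ktrans capped at 5/min, the physiologic ceiling used by DCE fitting
    # tools; beyond it the convolution term degenerates into a rescaled
    # AIF and trades off against fpv.
    lb = [0.0, 1e-6, -np.inf]
    ub = [5.0 / 60.0, 1.0, np.inf]

    def run(x0):
        x0 = np.clip(x0, lb, [ub[0], 1.0, np.finfo(float).max])
        return least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)

    sol = run([init.ktrans, init.ve, init.fpv])
    rms = np.sqrt(2 * sol.cost / len(curve))
    if rms / scale > residual_threshold:
        for x0 in _MULTISTART:
            alt = run(x0)
            if alt.cost < sol.cost:
                sol = alt
        rms = np.sqrt(2 * sol.cost / len(curve))
    return ToftsParams(
        ktrans=float(sol.x[0]), ve=float(sol.x[1]), fpv=float(sol.x[2]),
        residual=float(rms), converged=bool(sol.success),
    )


def tofts_map(sat: DynamicImage, aif: AIFCurve, mask: LabelMap | np.ndarray,
              labels=("parenchyma", "tumor"), init: ToftsParams = DEFAULT_INIT) -> ToftsParamMaps:
    """Voxelwise extended Tofts fit within a mask.

    Voxels are fit independently, so the maps are invariant to voxel
    ordering; per-voxel failures are flagged in the validity mask.
    """
    m = mask.mask(*labels) if isinstance(mask, LabelMap) else np.asarray(mask, bool)
    if not m.any():
        raise DegenerateInputError("Tofts mask is empty")
    shape = sat.shape[:3]
    kt = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    fpv = np.full(shape, np.nan)
    res = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    idx = np.argwhere(m)
    for i, j, k in idx:
        try:
            p = fit_extended_tofts(sat.values[i, j, k], aif, sat.times, init=init)
        except Exception:
            continue
        kt[i, j, k], ve[i, j, k], fpv[i, j, k], res[i, j, k] = p.ktrans, p.ve, p.fpv, p.residual
        valid[i, j, k] = p.converged
    g = (sat.spacing, sat.origin)
    return ToftsParamMaps(
        Image3D(kt, *g), Image3D(ve, *g), Image3D(fpv, *g), Image3D(res, *g), valid
    )
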