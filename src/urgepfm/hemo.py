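"""Haemodynamic forward model shared by simulation, deconvolution and the GLM.

The pipeline assumes a linear time-invariant coupling between the
activity-inducing signal and the measured BOLD signal: the percent signal
change at echo time ``TE`` is ``-TE * (h * dR2*)(t)``, where ``h`` is the
canonical double-gamma haemodynamic response function (HRF) and ``dR2*`` is
the change in the transverse relaxation rate (s^-1).  Negative ``dR2*``
therefore produces a positive BOLD deflection whose amplitude scales
linearly with echo time.

This module provides the canonical HRF, the causal convolution operator, the
stacked multi-echo design used by the deconvolution, and percent-signal-change
conversion with Legendre-polynomial detrending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.linalg import toeplitz
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFModel",
    "ConvolutionOperator",
    "MultiEchoDesign",
    "PercentChangeSeries",
    "canonical_hrf",
    "build_convolution_operator",
    "multiecho_design",
    "percent_signal_change",
    "legendre_basis",
    "detrend_legendre",
]


@dataclass(frozen=True)
class HRFModel:
    """Canonical HRF sampled on the acquisition grid.

    ``kernel[i]`` is the response at ``i * tr_ms / 1000`` seconds after a unit
    impulse.  With the default ``normalise='sum'`` the kernel has unit DC gain,
    so a sustained unit input converges to a sustained unit output.
    """

    kernel: np.ndarray
    tr_ms: float
    params: dict = field(default_factory=dict)

    @property
    def tr_s(self) -> float:
        return self.tr_ms / 1000.0


@dataclass(frozen=True)
class ConvolutionOperator:
    """Lower-triangular Toeplitz matrix implementing causal HRF convolution."""

    matrix: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def __matmul__(self, other):
        return self.matrix @ other


@dataclass(frozen=True)
class MultiEchoDesign:
    """Vertical stack of per-echo blocks ``-TE_k[s] * H``.

    Solving least squares on stacked percent-change data returns the
    activity-inducing ``dR2*`` train in s^-1.
    """

    matrix: np.ndarray
    tes_ms: tuple
    n_timepoints: int

    @property
    def n_echoes(self) -> int:
        return len(self.tes_ms)

    def echo_block(self, k: int) -> np.ndarray:
        T = self.n_timepoints
        return self.matrix[k * T : (k + 1) * T, :]


@dataclass(frozen=True)
class PercentChangeSeries:
    """Per-voxel timeseries in percent-change units (zero temporal mean)."""

    values: np.ndarray  # (..., T)
    detrend_order: int


# Canonical double-gamma parameters (response delay 6 s, undershoot delay
# 16 s, unit dispersions, response:undershoot ratio 6, 32 s support).
_CANONICAL = dict(
    response_delay_s=6.0,
    undershoot_delay_s=16.0,
    response_dispersion_s=1.0,
    undershoot_dispersion_s=1.0,
    ratio=6.0,
    length_s=32.0,
)


def double_gamma(t: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds)."""
    p = dict(_CANONICAL, **(params or {}))
    a1 = p["response_delay_s"] / p["response_dispersion_s"]
    a2 = p["undershoot_delay_s"] / p["undershoot_dispersion_s"]
    peak = gamma_dist.pdf(t, a1, scale=p["response_dispersion_s"])
    under = gamma_dist.pdf(t, a2, scale=p["undershoot_dispersion_s"])
    return peak - under / p["ratio"]


def canonical_hrf(
    tr_ms: float,
    length_s: float = 32.0,
    normalise: str = "sum",
    params: dict | None = None,
) -> HRFModel:
    """Canonical double-gamma HRF sampled at the repetition time.

    Parameters
    ----------
    tr_ms:
        Repetition time in milliseconds (must be positive).
    length_s:
        Kernel support in seconds; the canonical kernel is effectively zero
        beyond ~32 s.
    normalise:
        ``'sum'`` (default) scales the kernel to unit sum so that sustained
        inputs pass with unit gain — the convention of the standard canonical
        HRF implementation; ``'peak'`` scales to unit maximum; ``'none'``
        leaves the raw gamma-density difference.
    """
    if tr_ms <= 0:
        raise ValueError(f"TR must be positive, got {tr_ms} ms")
    if length_s < 20:
        raise ValueError("kernel length below 20 s truncates the undershoot")
    p = dict(_CANONICAL, **(params or {}), length_s=length_s)
    tr_s = tr_ms / 1000.0
    t = np.arange(0.0, length_s + 0.5 * tr_s, tr_s)
    kernel = double_gamma(t, p)
    if normalise == "sum":
        kernel = kernel / kernel.sum()
    elif normalise == "peak":
        kernel = kernel / kernel.max()
    elif normalise != "none":
        raise ValueError(f"unknown normalisation {normalise!r}")
    return HRFModel(kernel=kernel, tr_ms=float(tr_ms), params=dict(p, normalise=normalise))


def build_convolution_operator(hrf: HRFModel | np.ndarray, n_timepoints: int) -> ConvolutionOperator:
    """T x T lower-triangular Toeplitz operator for causal convolution.

    Column ``j`` is the HRF kernel placed at onset ``j`` and truncated at the
    end of the run, so ``H @ s`` is the discrete convolution of ``s`` with the
    kernel restricted to the run.
    """
    if n_timepoints <= 0:
        raise ValueError(f"need at least one timepoint, got {n_timepoints}")
    kernel = hrf.kernel if isinstance(hrf, HRFModel) else np.asarray(hrf, float)
    col = np.zeros(n_timepoints)
    m = min(len(kernel), n_timepoints)
    col[:m] = kernel[:m]
    return ConvolutionOperator(matrix=toeplitz(col, np.zeros(n_timepoints)))


def multiecho_design(hconv: ConvolutionOperator, tes_ms) -> MultiEchoDesign:
    """Stack per-echo blocks ``-TE_k[s] * H`` into the (E*T) x T design.

    TEs are supplied in milliseconds and converted to seconds inside the
    design so that the estimated coefficients carry units of s^-1; values
    below 1 are rejected as a probable ms/s unit mix-up.
    """
    tes = np.asarray(tes_ms, float)
    if tes.size < 2:
        raise ValueError("multi-echo design needs at least 2 echoes")
    if np.any(np.diff(tes) <= 0):
        raise ValueError(f"TEs must be strictly increasing, got {tes.tolist()}")
    if np.any(tes < 1.0):
        raise ValueError(
            f"TEs look like seconds ({tes.tolist()}); pass milliseconds"
        )
    H = hconv.matrix
    blocks = [-(te / 1000.0) * H for te in tes]
    return MultiEchoDesign(
        matrix=np.vstack(blocks),
        tes_ms=tuple(tes.tolist()),
        n_timepoints=H.shape[0],
    )


def legendre_basis(n_timepoints: int, order: int) -> np.ndarray:
    """Legendre polynomials P_0..P_order evaluated on [-1, 1] (T x (order+1))."""
    x = np.linspace(-1.0, 1.0, n_timepoints)
    return np.stack(
        [legendre.legval(x, np.eye(order + 1)[j]) for j in range(order + 1)], axis=1
    )


def detrend_legendre(values: np.ndarray, order: int) -> np.ndarray:
    """Remove the least-squares Legendre fit of given order along the last axis."""
    T = values.shape[-1]
    B = legendre_basis(T, order)
    flat = values.reshape(-1, T)
    coef, *_ = np.linalg.lstsq(B, flat.T, rcond=None)
    return (flat - (B @ coef).T).reshape(values.shape)


def percent_signal_change(
    series: np.ndarray,
    detrend_order: int = 4,
    mask: np.ndarray | None = None,
) -> PercentChangeSeries:
    """Convert raw signal to percent change around the voxel mean.

    Per voxel: remove a Legendre polynomial trend of ``detrend_order``, divide
    by the temporal mean of the *raw* series, scale by 100.  Works on any
    array whose last axis is time (a 4D volume or a voxel-by-time matrix).
    ``mask`` restricts the computation; voxels outside it are returned as
    zeros.  A zero-mean voxel inside the mask is an error (the voxel index is
    named) rather than a silent NaN.
    """
    series = np.asarray(series, float)
    T = series.shape[-1]
    flat = series.reshape(-1, T)
    if mask is not None:
        mflat = np.asarray(mask, bool).reshape(-1)
        if mflat.shape[0] != flat.shape[0]:
            raise ValueError("mask shape does not match series grid")
    else:
        mflat = np.ones(flat.shape[0], bool)
    out = np.zeros_like(flat)
    sub = flat[mflat]
    means = sub.mean(axis=1)
    bad = np.flatnonzero(np.abs(means) < 1e-12)
    if bad.size:
        vox = np.flatnonzero(mflat)[bad[0]]
        idx = np.unravel_index(vox, series.shape[:-1])
        raise ValueError(f"voxel {tuple(int(i) for i in idx)} has zero temporal mean inside mask")
    detr = detrend_legendre(sub, detrend_order)
    out[mflat] = 100.0 * detr / means[:, None]
    return PercentChangeSeries(values=out.reshape(series.shape), detrend_order=detrend_order)
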