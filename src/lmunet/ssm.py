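"""Selective state-space (Mamba) core.

A selective SSM evaluates, strictly left to right over a token sequence,

    h_t = exp(dt_t * A) * h_{t-1} + dt_t * B_t * u_t
    y_t = C_t . h_t + D * u_t

where the step size ``dt``, input projection ``B`` and read-out ``C`` are
functions of the current token (the "selective" mechanism), ``A <= 0`` is a
per-(channel, state) decay and ``D`` a per-channel skip.  The recurrence is
linear in the sequence length.

Discretisation uses the Euler-simplified zero-order hold
``Abar = exp(dt*A)``, ``Bbar = dt*B``.  The scan is evaluated by jitted
sequential kernels (:func:`selective_scan`); an intentionally slow dense
oracle that unrolls the recurrence into an L x L lower-triangular operator
(:func:`selective_scan_dense`) is provided for verification.

:class:`MambaBlock` wraps the scan in the standard block: input projection
to a (stream, gate) pair, depthwise causal convolution + SiLU on the
stream, token-dependent dt/B/C projections, scan, gating, output
projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import Tensor, mac_counter, as_tensor

try:  # jitted kernels; pure-numpy fallback keeps the package importable
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "SSMConfig",
    "discretize",
    "selective_scan",
    "selective_scan_dense",
    "MambaBlock",
    "scan_stats",
]

#: running tally of recurrence steps executed, for cost-scaling assertions
scan_stats = {"steps": 0, "calls": 0}


@dataclass(frozen=True)
class SSMConfig:
    """Hyper-parameters of a single Mamba block.

    model_dim
        token feature width d.
    state_dim
        latent state size N per channel (default 16).
    dt_min, dt_max
        bounds of the initial discretisation step; the step-projection bias
        is initialised so softplus(bias) is log-uniform in [dt_min, dt_max].
    conv_width
        depthwise causal convolution kernel length.
    expand
        inner-width multiplier (d_inner = expand * model_dim).
    """

    model_dim: int
    state_dim: int = 16
    dt_min: float = 0.001
    dt_max: float = 0.1
    conv_width: int = 3
    expand: int = 2

    def __post_init__(self):
        if self.model_dim < 1 or self.state_dim < 1 or self.conv_width < 1 or self.expand < 1:
            raise ValueError("all SSM dimensions must be >= 1")
        if not (0 < self.dt_min < self.dt_max):
            raise ValueError("require 0 < dt_min < dt_max")

    @property
    def inner_dim(self):
        return self.expand * self.model_dim

    @property
    def dt_rank(self):
        return max(1, math.ceil(self.model_dim / 16))


# ---------------------------------------------------------------------------
# discretisation


def discretize(delta, A, B):
    """Euler-simplified zero-order-hold discretisation.

    Returns ``Abar = exp(delta * A)`` and ``Bbar = delta * B`` with numpy
    broadcasting; ``delta`` must be nonnegative.  Raises on non-finite
    inputs.
    """
    delta, A, B = (np.asarray(v, dtype=np.float64) for v in (delta, A, B))
    for name, v in (("delta", delta), ("A", A), ("B", B)):
        if not np.all(np.isfinite(v)):
            raise ValueError(f"discretize: non-finite values in {name}")
    if np.any(delta < 0):
        raise ValueError("discretize: delta must be nonnegative")
    return np.exp(delta * A), delta * B


# ---------------------------------------------------------------------------
# jitted kernels


@njit(cache=False, fastmath=True)
def _scan_fwd_kernel(u, delta, Abar, B, C, D, hs, y):  # pragma: no cover - jitted
    nb, L, nd = u.shape
    ns = Abar.shape[3]
    for b in range(nb):
        h = np.zeros((nd, ns), u.dtype)
        for t in range(L):
            for d in range(nd):
                dt = delta[b, t, d]
                ut = u[b, t, d]
                acc = 0.0
                for n in range(ns):
                    h[d, n] = Abar[b, t, d, n] * h[d, n] + dt * B[b, t, n] * ut
                    acc += C[b, t, n] * h[d, n]
                hs[b, t, d] = h[d]
                y[b, t, d] = acc + D[d] * ut


@njit(cache=False, fastmath=True)
def _scan_bwd_kernel(u, delta, A, Abar, B, C, D, hs, gy,
                     gu, gdelta, gA, gB, gC, gD):  # pragma: no cover - jitted
    nb, L, nd = u.shape
    ns = A.shape[1]
    for b in range(nb):
        gh = np.zeros((nd, ns), u.dtype)
        for t in range(L - 1, -1, -1):
            for d in range(nd):
                dt = delta[b, t, d]
                ut = u[b, t, d]
                gyv = gy[b, t, d]
                gD[d] += gyv * ut
                gu_acc = D[d] * gyv
                gd_acc = 0.0
                for n in range(ns):
                    htn = hs[b, t, d, n]
                    gC[b, t, n] += gyv * htn
                    ghn = gh[d, n] + gyv * C[b, t, n]
                    ab = Abar[b, t, d, n]
                    hprev = hs[b, t - 1, d, n] if t > 0 else 0.0
                    gab = ghn * hprev
                    gA[d, n] += gab * dt * ab
                    gd_acc += gab * A[d, n] * ab
                    gd_acc += ghn * B[b, t, n] * ut
                    gB[b, t, n] += ghn * dt * ut
                    gu_acc += ghn * dt * B[b, t, n]
                    gh[d, n] = ghn * ab
                gu[b, t, d] = gu_acc
                gdelta[b, t, d] = gd_acc


def _scan_fwd_numpy(u, delta, A, B, C, D, hs, y):
    nb, L, nd = u.shape
    ns = A.shape[1]
    h = np.zeros((nb, nd, ns), u.dtype)
    for t in range(L):
        ab = np.exp(delta[:, t, :, None] * A[None])
        h = ab * h + delta[:, t, :, None] * B[:, t, None, :] * u[:, t, :, None]
        hs[:, t] = h
        y[:, t] = (h * C[:, t, None, :]).sum(axis=2) + D[None] * u[:, t]


# ---------------------------------------------------------------------------
# scan as an autograd primitive


def selective_scan(u, delta, A, B, C, D):
    """Run the selective scan over (batch, length, dim) token streams.

    Parameters
    ----------
    u, delta : (B, L, D) tensors; ``delta`` must already be positive.
    A : (D, N) state-transition tensor (typically negative).
    B, C : (B, L, N) token-dependent input/read-out projections.
    D : (D,) skip connection.
    """
    u, delta, A, B, C, D = (as_tensor(v) for v in (u, delta, A, B, C, D))
    nb, L, nd = u.shape
    ns = A.shape[1]
    for name, v, want in (("delta", delta, (nb, L, nd)),
                          ("B", B, (nb, L, ns)),
                          ("C", C, (nb, L, ns))):
        if v.shape != want:
            raise ValueError(
                f"selective_scan: stream '{name}' has shape {v.shape}, expected {want}")
    if A.shape != (nd, ns):
        raise ValueError(f"selective_scan: A has shape {A.shape}, expected {(nd, ns)}")
    if D.shape != (nd,):
        raise ValueError(f"selective_scan: D has shape {D.shape}, expected {(nd,)}")

    dtype = u.dtype
    args = [np.ascontiguousarray(v.data, dtype=dtype) for v in (u, delta, A, B, C, D)]
    # discretised transition, vectorised outside the sequential kernel
    abar = np.exp(args[1][..., None] * args[2][None, None])
    hs = np.empty((nb, L, nd, ns), dtype=dtype)
    y = np.empty((nb, L, nd), dtype=dtype)
    if _HAVE_NUMBA:
        _scan_fwd_kernel(args[0], args[1], abar, args[3], args[4], args[5], hs, y)
    else:
        _scan_fwd_numpy(*args, hs, y)

    scan_stats["steps"] += L
    scan_stats["calls"] += 1
    mac_counter.add(nb * L * (4 * nd * ns + nd))

    prev = (u, delta, A, B, C, D)

    def bw(g):
        g = np.ascontiguousarray(g, dtype=dtype)
        gu = np.zeros_like(args[0])
        gdelta = np.zeros_like(args[1])
        gA = np.zeros_like(args[2])
        gB = np.zeros_like(args[3])
        gC = np.zeros_like(args[4])
        gD = np.zeros_like(args[5])
        if _HAVE_NUMBA:
            _scan_bwd_kernel(args[0], args[1], args[2], abar, args[3], args[4],
                             args[5], hs, g, gu, gdelta, gA, gB, gC, gD)
        else:
            _scan_bwd_numpy_ref(*args, hs, g, gu, gdelta, gA, gB, gC, gD)
        for t, gt in zip(prev, (gu, gdelta, gA, gB, gC, gD)):
            if t.requires_grad:
                t._accum(gt)

    return Tensor._make(y, prev, bw)


def _scan_bwd_numpy_ref(u, delta, A, B, C, D, hs, gy, gu, gdelta, gA, gB, gC, gD):
    """Pure-numpy transcription of the backward kernel (fallback path)."""
    nb, L, nd = u.shape
    ns = A.shape[1]
    gh = np.zeros((nb, nd, ns), u.dtype)
    for t in range(L - 1, -1, -1):
        gD += (gy[:, t] * u[:, t]).sum(axis=0)
        gC[:, t] += (gy[:, t, :, None] * hs[:, t]).sum(axis=1)
        gh = gh + gy[:, t, :, None] * C[:, t, None, :]
        ab = np.exp(delta[:, t, :, None] * A[None])
        hprev = hs[:, t - 1] if t > 0 else np.zeros_like(hs[:, 0])
        gab = gh * hprev
        gA += (gab * delta[:, t, :, None] * ab).sum(axis=0)
        gdelta[:, t] = (gab * A[None] * ab).sum(axis=2) \
            + (gh * B[:, t, None, :]).sum(axis=2) * u[:, t]
        gB[:, t] += (gh * delta[:, t, :, None] * u[:, t, :, None]).sum(axis=1)
        gu[:, t] = D[None] * gy[:, t] + (gh * delta[:, t, :, None] * B[:, t, None, :]).sum(axis=2)
        gh = gh * ab


# ---------------------------------------------------------------------------
# dense unrolled oracle


def selective_scan_dense(u, delta, A, B, C, D):
    """Dense O(L^2) oracle for the scan, for verification only.

    Materialises, for every (batch, channel), the L x L lower-triangular
    causal operator implied by the recurrence and applies it directly:

        y_t = sum_{s<=t} C_t . (prod_{r=s+1..t} Abar_r) Bbar_s u_s + D u_t
    """
    u, delta, A, B, C, D = (np.asarray(v, dtype=np.float64) for v in (u, delta, A, B, C, D))
    nb, L, nd = u.shape
    Abar, Bbar = discretize(delta[..., None], A[None, None], B[:, :, None, :])
    Bu = Bbar * u[..., None]  # (nb, L, nd, ns)
    y = np.zeros((nb, L, nd))
    for b in range(nb):
        for s in range(L):
            p = Bu[b, s].copy()  # contribution of token s propagated forward
            y[b, s] += (C[b, s][None, :] * p).sum(axis=1)
            for t in range(s + 1, L):
                p = Abar[b, t] * p
                y[b, t] += (C[b, t][None, :] * p).sum(axis=1)
    y += D[None, None, :] * u
    return y


def hidden_state_bound(delta, A, B, u):
    """Geometric-series bound on |h_t| for decaying dynamics (A <= 0).

    With ``a = max |Abar| < 1`` and ``m = max |Bbar * u|`` the recurrence
    from a zero state satisfies |h_t| <= m * (1 - a^t) / (1 - a) <= m / (1 - a).
    """
    Abar, Bbar = discretize(np.asarray(delta)[..., None], np.asarray(A)[None, None],
                            np.asarray(B)[:, :, None, :])
    a = float(np.max(np.abs(Abar)))
    if a >= 1.0:
        raise ValueError("bound requires strictly decaying dynamics (|Abar| < 1)")
    m = float(np.max(np.abs(Bbar * np.asarray(u)[..., None])))
    return m / (1.0 - a)


# ---------------------------------------------------------------------------
# the Mamba block


class MambaBlock(nn.Module):
    """Gated selective-SSM block over token sequences (B, L, d).

    Pipeline: input projection to a (stream, gate) pair of width
    ``expand*d`` -> depthwise causal convolution + SiLU on the stream ->
    token-dependent dt/B/C projections -> selective scan -> multiply by
    SiLU(gate) -> output projection back to d.  Strictly causal.
    """

    def __init__(self, cfg: SSMConfig, rng):
        super().__init__()
        self.cfg = cfg
        d, di, ns, r = cfg.model_dim, cfg.inner_dim, cfg.state_dim, cfg.dt_rank
        self.in_proj = nn.Linear(d, 2 * di, rng, bias=False)
        self.conv = nn.CausalDepthwiseConv1d(di, cfg.conv_width, rng)
        self.x_proj = nn.Linear(di, r + 2 * ns, rng, bias=False)
        self.dt_proj = nn.Linear(r, di, rng)
        # dt bias: softplus(bias) log-uniform in [dt_min, dt_max]
        dt = np.exp(rng.uniform(math.log(cfg.dt_min), math.log(cfg.dt_max), size=di))
        self.dt_proj.bias.data = (dt + np.log(-np.expm1(-dt))).astype(np.float32)
        # S4D-real initialisation: A = -(n+1) per state, shared across channels
        self.A_log = nn.Parameter(np.tile(np.log(np.arange(1, ns + 1, dtype=np.float32)), (di, 1)))
        self.D = nn.Parameter(np.ones(di, np.float32))
        self.out_proj = nn.Linear(di, d, rng, bias=False)

    def forward(self, seq: Tensor) -> Tensor:
        if seq.shape[-1] != self.cfg.model_dim:
            raise ValueError(
                f"MambaBlock: token dim {seq.shape[-1]} != model_dim {self.cfg.model_dim}")
        di, ns, r = self.cfg.inner_dim, self.cfg.state_dim, self.cfg.dt_rank
        xz = self.in_proj(seq)
        x, z = xz[:, :, :di], xz[:, :, di:]
        x = self.conv(x.transpose(0, 2, 1)).transpose(0, 2, 1).silu()
        dbc = self.x_proj(x)
        delta = self.dt_proj(dbc[:, :, :r]).softplus()
        Bp = dbc[:, :, r:r + ns]
        Cp = dbc[:, :, r + ns:]
        A = -self.A_log.exp()
        y = selective_scan(x, delta, A, Bp, Cp, self.D)
        y = y * z.silu()
        return self.out_proj(y)
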