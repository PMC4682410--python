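"""One-dimensional dual-tree complex wavelet transform.

Two parallel critically-sampled orthonormal filter banks ("tree a" and
"tree b") whose outputs are combined as real/imaginary parts of complex
coefficients.  Tree b lags tree a by one input sample at level 1 and uses
the time-reversed q-shift low-pass at deeper levels, giving the
approximate half-sample delay difference that makes coefficient
magnitudes nearly shift invariant.

The transform is periodized; callers that need boundary safety should
reflect-pad before analysis (see :func:`reflect_pad`).
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

import numpy as np

__all__ = [
    "DtcwtPyramid",
    "daubechies_lowpass",
    "dtcwt_forward",
    "dtcwt_inverse",
    "qshift_lowpass",
    "reflect_pad",
]

# 14-tap q-shift orthonormal low-pass (tree a); group delay ~ 6.25 samples.
# Tree b uses the time reverse (group delay ~ 6.75).
_QSHIFT_14 = np.array(
    [
        0.00325314,
        -0.00388321,
        0.03466035,
        -0.03887280,
        -0.11720389,
        0.27529538,
        0.75614564,
        0.56881042,
        0.01186609,
        -0.10671180,
        0.02382538,
        0.01702522,
        -0.00543948,
        -0.00455690,
    ]
)


def qshift_lowpass() -> np.ndarray:
    """Return the 14-tap q-shift analysis low-pass filter (tree a)."""
    return _QSHIFT_14.copy()


@lru_cache(maxsize=None)
def _daubechies_cached(n_vanishing: int) -> tuple[float, ...]:
    K = n_vanishing
    if K < 1:
        raise ValueError("need at least one vanishing moment")
    # Maxflat halfband construction: P(y) = sum_k C(K-1+k, k) y^k, then
    # spectral factorization keeping roots inside the unit circle.
    k = np.arange(K)
    from math import comb

    P = np.array([comb(K - 1 + j, j) for j in range(K)], dtype=float)
    # Q(z) with Q(e^{iw}) = P(sin^2(w/2)); substitute y = (2 - z - 1/z)/4.
    y_poly = np.array([-0.25, 0.5, -0.25])  # -(z - 1)^2 / (4 z), coeffs in z
    q = np.zeros(2 * K - 1)
    q[K - 1] = P[0]
    ypow = np.array([1.0])
    for j in range(1, K):
        ypow = np.convolve(ypow, y_poly[::-1])  # symmetric Laurent poly
        centred = np.zeros(2 * K - 1)
        lo = K - 1 - j
        centred[lo : lo + 2 * j + 1] = ypow
        q += P[j] * centred
    roots = np.roots(q)
    inside = roots[np.abs(roots) < 1.0 - 1e-12]
    # pair conjugates deterministically
    inside = inside[np.argsort([abs(r) for r in inside], kind="stable")]
    f = np.array([1.0])
    for r in inside:
        f = np.convolve(f, np.array([1.0, -r]))
    f = np.real_if_close(f, tol=1e6)
    h = np.convolve(np.real(f), np.poly(-np.ones(K)))
    h = h * np.sqrt(2.0) / h.sum()
    return tuple(float(v) for v in h)


def daubechies_lowpass(n_vanishing: int) -> np.ndarray:
    """Orthonormal Daubechies low-pass filter with ``n_vanishing`` moments.

    Designed by spectral factorization of the maxflat halfband polynomial;
    length is ``2 * n_vanishing`` and the result satisfies the CQF
    orthonormality conditions to machine precision.
    """
    return np.asarray(_daubechies_cached(n_vanishing))


def _cqf_highpass(h0: np.ndarray) -> np.ndarray:
    n = np.arange(h0.size)
    return ((-1.0) ** n) * h0[::-1]


def _analysis(x: np.ndarray, h: np.ndarray, phase: int) -> np.ndarray:
    """Periodized correlate-and-decimate: y[k] = sum_n h[n] x[(2k+phase+n) % N]."""
    N = x.size
    idx = (2 * np.arange(N // 2)[:, None] + phase + np.arange(h.size)[None, :]) % N
    return x[idx] @ h


def _synthesis(lo: np.ndarray, h: np.ndarray, N: int, phase: int) -> np.ndarray:
    """Adjoint of :func:`_analysis` (periodized)."""
    up = np.zeros(N)
    out = np.zeros(N)
    up[::2] = lo
    for n, hv in enumerate(h):
        out += hv * np.roll(up, n + phase)
    return out


class DtcwtPyramid(NamedTuple):
    """Analysis result: complex detail coefficients plus the two real
    low-pass residues (tree a, tree b)."""

    highpasses: tuple[np.ndarray, ...]
    lowpass_a: np.ndarray
    lowpass_b: np.ndarray
    length: int


def max_levels(n: int, first_filter_len: int = 14) -> int:
    """Largest usable decomposition depth for a length-``n`` signal."""
    lev = 0
    while n % 2 == 0 and n // 2 >= first_filter_len:
        n //= 2
        lev += 1
    return lev


def dtcwt_forward(x: np.ndarray, nlevels: int, level1_moments: int = 7) -> DtcwtPyramid:
    """Forward 1-D DT-CWT of ``x`` (length divisible by 2**nlevels)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if nlevels < 1:
        raise ValueError("nlevels must be >= 1")
    if x.size % (2**nlevels) != 0:
        raise ValueError("signal length must be divisible by 2**nlevels")

    h0_1 = daubechies_lowpass(level1_moments)
    h1_1 = _cqf_highpass(h0_1)
    h0a = _QSHIFT_14
    h0b = h0a[::-1].copy()
    h1a = _cqf_highpass(h0a)
    h1b = _cqf_highpass(h0b)

    highs: list[np.ndarray] = []
    lo_a = _analysis(x, h0_1, 0)
    hi_a = _analysis(x, h1_1, 0)
    lo_b = _analysis(x, h0_1, 1)
    hi_b = _analysis(x, h1_1, 1)
    highs.append(hi_a + 1j * hi_b)
    for _ in range(1, nlevels):
        hi_a = _analysis(lo_a, h1a, 0)
        hi_b = _analysis(lo_b, h1b, 0)
        lo_a = _analysis(lo_a, h0a, 0)
        lo_b = _analysis(lo_b, h0b, 0)
        highs.append(hi_a + 1j * hi_b)
    return DtcwtPyramid(tuple(highs), lo_a, lo_b, x.size)


def dtcwt_inverse(pyr: DtcwtPyramid, level1_moments: int = 7) -> np.ndarray:
    """Invert :func:`dtcwt_forward`; exact to machine precision."""
    h0_1 = daubechies_lowpass(level1_moments)
    h1_1 = _cqf_highpass(h0_1)
    h0a = _QSHIFT_14
    h0b = h0a[::-1].copy()
    h1a = _cqf_highpass(h0a)
    h1b = _cqf_highpass(h0b)

    lo_a, lo_b = pyr.lowpass_a, pyr.lowpass_b
    for lev in range(len(pyr.highpasses) - 1, 0, -1):
        hi = pyr.highpasses[lev]
        N = 2 * lo_a.size
        lo_a = _synthesis(lo_a, h0a, N, 0) + _synthesis(hi.real, h1a, N, 0)
        lo_b = _synthesis(lo_b, h0b, N, 0) + _synthesis(hi.imag, h1b, N, 0)
    hi = pyr.highpasses[0]
    N = pyr.length
    xa = _synthesis(lo_a, h0_1, N, 0) + _synthesis(hi.real, h1_1, N, 0)
    xb = _synthesis(lo_b, h0_1, N, 1) + _synthesis(hi.imag, h1_1, N, 1)
    return 0.5 * (xa + xb)


def reflect_pad(x: np.ndarray, nlevels: int, margin: int = 32) -> tuple[np.ndarray, int]:
    """Reflect-pad ``x`` so its length is a multiple of ``2**nlevels``.

    Returns the padded signal and the left-pad length.  The pad absorbs the
    wrap-around of the periodized transform.
    """
    x = np.asarray(x, dtype=float)
    block = 2**nlevels
    target = x.size + 2 * margin
    target = ((target + block - 1) // block) * block
    total_pad = target - x.size
    left = total_pad // 2
    right = total_pad - left
    if max(left, right) >= x.size:
        reps = int(np.ceil(max(left, right) / max(x.size - 1, 1))) + 1
        tiles = [x]
        for i in range(reps):
            tiles.insert(0, tiles[0][::-1])
            tiles.append(tiles[-1][::-1])
        big = np.concatenate(tiles)
        mid = reps * x.size
        return big[mid - left : mid + x.size + right], left
    return np.pad(x, (left, right), mode="reflect"), left
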