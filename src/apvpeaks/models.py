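"""Peak shape models and per-peak derived quantities.

The primary model is a piecewise pseudo-Voigt ("mAPV"): each side of the
summit is an independent linear mixture of a Lorentzian and a Gaussian
sharing the half-width-at-half-maximum ``sigma`` of that side.  The
classical Gaussian, Lorentzian and Bi-Gaussian shapes are exposed both as
stand-alone functions and as parameter corners of the main model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SQRT_PI_LN2 = float(np.sqrt(np.pi / np.log(2.0)))
_LN2 = float(np.log(2.0))

__all__ = [
    "PeakParams",
    "mapv_eval",
    "gaussian_eval",
    "lorentz_eval",
    "bigaussian_eval",
    "peak_area",
    "asymmetry",
]


@dataclass(frozen=True)
class PeakParams:
    """Six-parameter description of a single asymmetric pseudo-Voigt peak.

    Attributes
    ----------
    H : float
        Peak height (intensity units), attained at ``m = alpha``.
    alpha : float
        Summit location (m/z units).
    sigma1, sigma2 : float
        Half width at half maximum of the left / right half.
    beta1, beta2 : float
        Lorentzian fraction of the left / right half, in ``[0, 1]``.
    """

    H: float
    alpha: float
    sigma1: float
    sigma2: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        if not (self.H > 0):
            raise ValueError(f"H must be positive, got {self.H}")
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("sigma1 and sigma2 must be positive")
        for name in ("beta1", "beta2"):
            b = getattr(self, name)
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {b}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.H, self.alpha, self.sigma1, self.sigma2, self.beta1, self.beta2]
        )

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "PeakParams":
        H, alpha, s1, s2, b1, b2 = (float(v) for v in np.asarray(theta))
        return cls(H, alpha, s1, s2, b1, b2)


def _half_profile(z2: np.ndarray, beta: float) -> np.ndarray:
    """Mixture value for squared scaled offset ``z2 = ((m - alpha)/sigma)^2``."""
    return beta / (1.0 + z2) + (1.0 - beta) * np.exp(-_LN2 * z2)


def mapv_eval(m, theta: PeakParams):
    """Evaluate the piecewise asymmetric pseudo-Voigt peak at ``m``.

    Left of the summit the profile is ``H * [b1 L + (1-b1) G]`` with scale
    ``sigma1``; at and right of the summit the same with ``sigma2``/``b2``.
    Both the Lorentzian L and the Gaussian G equal 1 at the summit and 1/2
    at one sigma, so the model is continuous with value ``H`` at ``alpha``
    and sigma is the HWHM of its side for every mixing fraction.
    """
    m = np.asarray(m, dtype=float)
    scalar = m.ndim == 0
    m = np.atleast_1d(m)
    left = m < theta.alpha
    out = np.empty_like(m)
    z2 = ((m[left] - theta.alpha) / theta.sigma1) ** 2
    out[left] = theta.H * _half_profile(z2, theta.beta1)
    z2 = ((m[~left] - theta.alpha) / theta.sigma2) ** 2
    out[~left] = theta.H * _half_profile(z2, theta.beta2)
    return float(out[0]) if scalar else out


def gaussian_eval(m, H: float, alpha: float, sigma: float):
    """Gaussian peak with HWHM parameterization: H * 2^(-((m-alpha)/sigma)^2)."""
    if H <= 0 or sigma <= 0:
        raise ValueError("H and sigma must be positive")
    m = np.asarray(m, dtype=float)
    return H * np.exp(-_LN2 * ((m - alpha) / sigma) ** 2)


def lorentz_eval(m, H: float, alpha: float, sigma: float):
    """Lorentzian peak: H / (1 + ((m-alpha)/sigma)^2)."""
    if H <= 0 or sigma <= 0:
        raise ValueError("H and sigma must be positive")
    m = np.asarray(m, dtype=float)
    return H / (1.0 + ((m - alpha) / sigma) ** 2)


def bigaussian_eval(m, H: float, alpha: float, sigma1: float, sigma2: float):
    """Piecewise Gaussian with independent left/right HWHM."""
    if H <= 0 or sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("H and sigmas must be positive")
    m = np.asarray(m, dtype=float)
    sigma = np.where(m < alpha, sigma1, sigma2)
    return H * np.exp(-_LN2 * ((m - alpha) / sigma) ** 2)


def peak_area(theta: PeakParams) -> float:
    """Analytic area under the peak over the whole real line.

    Each half contributes ``sigma * (beta * pi/2 + (1-beta) * sqrt(pi/ln 2)/2)``
    times ``H`` (half-Lorentzian and half-Gaussian integrals in the HWHM
    parameterization).
    """

    def half(sigma: float, beta: float) -> float:
        return sigma * (beta * np.pi / 2.0 + (1.0 - beta) * 0.5 * _SQRT_PI_LN2)

    return theta.H * (half(theta.sigma1, theta.beta1) + half(theta.sigma2, theta.beta2))


def asymmetry(theta: PeakParams) -> float:
    """Width ratio max(sigma1, sigma2) / min(sigma1, sigma2), always >= 1."""
    lo, hi = sorted((theta.sigma1, theta.sigma2))
    return hi / lo


def mapv_eval_batch(m: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Evaluate many parameter vectors on one grid.

    Parameters
    ----------
    m : (p,) array of m/z values.
    thetas : (n, 6) array, columns (H, alpha, sigma1, sigma2, beta1, beta2).

    Returns
    -------
    (n, p) array of model intensities.
    """
    m = np.asarray(m, dtype=float)[None, :]
    H = thetas[:, 0:1]
    alpha = thetas[:, 1:2]
    left = m < alpha
    sigma = np.where(left, thetas[:, 2:3], thetas[:, 3:4])
    beta = np.where(left, thetas[:, 4:5], thetas[:, 5:6])
    z2 = ((m - alpha) / sigma) ** 2
    return H * (beta / (1.0 + z2) + (1.0 - beta) * np.exp(-_LN2 * z2))
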