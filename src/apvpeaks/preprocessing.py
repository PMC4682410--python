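"""Spectrum smoothing and baseline correction.

Smoothing: the intensity trace is cut into a few equal sections (noise in
MALDI spectra shrinks towards high m/z, so each section gets its own
noise scale), each section is taken through a dual-tree complex wavelet
transform, complex detail magnitudes are soft-thresholded at a per-level
threshold chosen by minimizing Stein's unbiased risk estimate, and the
section is transformed back.

Baseline: a monotone local-minimum curve — it follows the spectrum while
the spectrum decreases and stays flat while it increases — subtracted
with negative residuals clipped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._dtcwt import dtcwt_forward, dtcwt_inverse, max_levels, reflect_pad
from .io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SureInputs",
    "WaveletShrinkageConfig",
    "correct_baseline",
    "estimate_baseline",
    "estimate_noise_sigma",
    "preprocess",
    "select_sure_threshold",
    "smooth_spectrum",
    "sure_risk",
]


@dataclass(frozen=True)
class WaveletShrinkageConfig:
    """Knobs of the wavelet shrinkage step.

    ``n_levels=None`` picks ``floor(log2(section length)) - 3`` clamped to
    [3, 8] per section.
    """

    n_segments: int = 4
    n_levels: int | None = None
    level1_moments: int = 7
    threshold_rule: str = "soft"
    sigma_estimator: str = "mad_finest_level"

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.n_levels is not None and self.n_levels < 1:
            raise ValueError("n_levels must be >= 1 when explicit")
        if self.threshold_rule != "soft":
            raise ValueError("only soft thresholding is implemented")


@dataclass(frozen=True)
class SureInputs:
    """Coefficient magnitudes and noise scale feeding the risk estimate."""

    x: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.x.ndim != 1 or self.x.size < 1:
            raise ValueError("x must be a non-empty 1-D vector")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")

    @property
    def d(self) -> int:
        return int(self.x.size)


def estimate_noise_sigma(coeffs: np.ndarray) -> float:
    """MAD noise-scale estimate: median(|c - median(c)|) / 0.6745."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size < 1:
        raise ValueError("empty coefficient vector")
    return float(np.median(np.abs(coeffs - np.median(coeffs))) / 0.6745)


def sure_risk(t: float, inputs: SureInputs) -> float:
    """Unbiased risk estimate of the soft-threshold estimator at threshold t.

    Closed form: ``d σ² + Σ min(xᵢ², t²) − 2 σ² #{i : |xᵢ| ≤ t}``.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    x = inputs.x
    s2 = inputs.sigma**2
    return float(
        inputs.d * s2
        + np.minimum(x**2, t**2).sum()
        - 2.0 * s2 * np.count_nonzero(np.abs(x) <= t)
    )


def select_sure_threshold(inputs: SureInputs) -> float:
    """Threshold minimizing the SURE risk.

    The risk is piecewise smooth with breakpoints at the coefficient
    magnitudes, so the minimum is attained on ``{0} ∪ {|xᵢ|}``; ties are
    broken toward the smaller threshold.
    """
    a = np.sort(np.abs(inputs.x))
    d = a.size
    s2 = inputs.sigma**2
    cand = np.concatenate([[0.0], a])
    csum = np.concatenate([[0.0], np.cumsum(a**2)])
    n_below = np.searchsorted(a, cand, side="right")
    # Σ min(xᵢ², t²) = Σ_{|x|≤t} x² + t²·#{|x|>t}, with ties folded in by the sort
    risks = d * s2 + csum[n_below] + (d - n_below) * cand**2 - 2.0 * s2 * n_below
    j = int(np.argmin(risks))
    return float(cand[j])


def _soft_threshold_complex(c: np.ndarray, t: float) -> np.ndarray:
    mag = np.abs(c)
    shrunk = np.maximum(mag - t, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mag > 0, shrunk / np.where(mag > 0, mag, 1.0), 0.0)
    return c * scale


def _smooth_section(y: np.ndarray, cfg: WaveletShrinkageConfig) -> np.ndarray:
    n_levels = cfg.n_levels
    if n_levels is None:
        n_levels = int(np.clip(int(np.floor(np.log2(max(y.size, 2)))) - 3, 3, 8))
    padded, left = reflect_pad(y, 1, margin=64)
    n_levels = max(min(n_levels, max_levels(padded.size)), 1)
    padded, left = reflect_pad(y, n_levels, margin=64)
    pyr = dtcwt_forward(padded, n_levels, level1_moments=cfg.level1_moments)
    sigma = estimate_noise_sigma(np.abs(pyr.highpasses[0]))
    if sigma > 0:
        new_highs = []
        for level_coeffs in pyr.highpasses:
            inputs = SureInputs(np.abs(level_coeffs), sigma)
            t = select_sure_threshold(inputs)
            new_highs.append(_soft_threshold_complex(level_coeffs, t))
        pyr = pyr._replace(highpasses=tuple(new_highs))
    out = dtcwt_inverse(pyr, level1_moments=cfg.level1_moments)
    return out[left : left + y.size]


def smooth_spectrum(s: Spectrum, cfg: WaveletShrinkageConfig | None = None) -> Spectrum:
    """Segmented DT-CWT shrinkage of the intensity trace; m/z untouched."""
    cfg = cfg or WaveletShrinkageConfig()
    n = len(s)
    if n < 2 * cfg.n_segments:
        raise ValueError(
            f"spectrum of {n} points too short for {cfg.n_segments} segments"
        )
    seg_len = n // cfg.n_segments
    out = np.empty(n)
    for k in range(cfg.n_segments):
        lo = k * seg_len
        hi = n if k == cfg.n_segments - 1 else (k + 1) * seg_len
        out[lo:hi] = _smooth_section(s.intensity[lo:hi], cfg)
    return s.with_intensity(out, stage="smoothed")


def estimate_baseline(s: Spectrum) -> np.ndarray:
    """Monotone local-minimum baseline: running minimum of the intensity."""
    return np.minimum.accumulate(s.intensity)


def correct_baseline(s: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract a baseline vector, clipping negative residuals to zero."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != s.intensity.shape:
        raise ValueError("baseline length mismatch")
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return s.with_intensity(corrected, stage="baseline_corrected")


def preprocess(
    s: Spectrum,
    cfg: WaveletShrinkageConfig | None = None,
    baseline_enabled: bool = True,
) -> Spectrum:
    """Full preprocessing chain: smooth, then estimate and remove baseline."""
    smoothed = smooth_spectrum(s, cfg)
    if not baseline_enabled:
        return smoothed
    return correct_baseline(smoothed, estimate_baseline(smoothed))
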