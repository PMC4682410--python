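"""Peak picking: valley segmentation, per-component model fitting and
recursive decomposition of broad or highly asymmetric components.

The detection loop mirrors the overall algorithm: cut the preprocessed
spectrum into components at local minima, fit the asymmetric pseudo-Voigt
model to each component with the swarm optimizer, drop low-area fits, and
re-split components whose fitted width or asymmetry suggests several
overlapping peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .hpso import HpsoConfig, optimize
from .io import PeakTable, Spectrum
from .models import PeakParams, asymmetry, mapv_eval_batch, peak_area

logger = logging.getLogger(__name__)

__all__ = [
    "Component",
    "DetectorConfig",
    "FittedPeak",
    "component_fit_bounds",
    "detect_peaks",
    "find_valleys",
    "fit_component",
    "split_at_valleys",
]


class EmptyComponentError(ValueError):
    """Component has no usable signal (all zero or too few points)."""


@dataclass(frozen=True)
class Component:
    """A contiguous slice of the spectrum between two valleys."""

    start: int  # inclusive
    stop: int  # exclusive
    mz: np.ndarray
    intensity: np.ndarray
    depth: int = 0

    def __len__(self) -> int:
        return int(self.stop - self.start)


@dataclass(frozen=True)
class FittedPeak:
    theta: PeakParams
    area: float
    mu: float
    sse: float
    start_mz: float
    end_mz: float


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds steering elimination and recursive splitting.

    ``area_threshold`` and ``width_threshold`` default to data-driven
    values chosen at detection time (see :func:`detect_peaks`): the area
    cut scales with the residual noise level and the width cut with the
    spanned m/z range.
    """

    area_threshold: float | None = None
    width_threshold: float | None = None
    asymmetry_threshold: float = 2.0
    max_depth: int = 3
    min_points: int = 5
    valley_tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.asymmetry_threshold <= 1:
            raise ValueError("asymmetry_threshold must exceed 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


def find_valleys(intensity: np.ndarray, tolerance: float = 0.0) -> list[int]:
    """Interior local minima of an intensity vector.

    Plateau minima (runs of equal values lower than both neighbours)
    collapse to their midpoint index.  With a positive ``tolerance``,
    adjacent valleys separated by a barrier lower than ``tolerance`` above
    the deeper valley are merged (the deeper one is kept).
    """
    y = np.asarray(intensity, dtype=float)
    n = y.size
    if n < 3:
        return []
    valleys: list[int] = []
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and y[j + 1] == y[i]:
            j += 1
        # run y[i..j] of equal values; a valley if both flanks are >= the run
        if y[i - 1] >= y[i] and j + 1 <= n - 1 and y[j + 1] >= y[j]:
            mid = (i + j) // 2
            if 0 < mid < n - 1:
                valleys.append(mid)
        i = j + 1
    if tolerance > 0 and len(valleys) > 1:
        merged = [valleys[0]]
        for v in valleys[1:]:
            prev = merged[-1]
            barrier = float(np.max(y[prev : v + 1]))
            if barrier - max(y[prev], y[v]) < tolerance:
                merged[-1] = v if y[v] < y[prev] else prev
            else:
                merged.append(v)
        valleys = merged
    return valleys


def split_at_valleys(
    mz: np.ndarray,
    intensity: np.ndarray,
    tolerance: float = 0.0,
    offset: int = 0,
    depth: int = 0,
) -> list[Component]:
    """Cut a trace into components at its valleys.

    Each valley index is the shared closed boundary of the two adjacent
    components, so fitted peaks can meet exactly at the valley.
    """
    valleys = find_valleys(intensity, tolerance)
    edges = [0, *valleys, len(intensity) - 1]
    comps = []
    for a, b in zip(edges[:-1], edges[1:]):
        comps.append(
            Component(
                start=offset + a,
                stop=offset + b + 1,
                mz=mz[a : b + 1],
                intensity=intensity[a : b + 1],
                depth=depth,
            )
        )
    return comps


def component_fit_bounds(c: Component) -> tuple[tuple[float, float], ...]:
    """Data-driven box constraints for fitting one component."""
    m_lo, m_hi = float(c.mz[0]), float(c.mz[-1])
    span = max(m_hi - m_lo, 1e-12)
    dx = float(np.median(np.diff(c.mz))) if len(c) > 1 else span
    peak = float(np.max(c.intensity))
    return (
        (0.5 * peak, 2.0 * peak),  # H
        (m_lo, m_hi),  # alpha
        (dx, span),  # sigma1
        (dx, span),  # sigma2
        (0.0, 1.0),  # beta1
        (0.0, 1.0),  # beta2
    )


def fit_component(
    c: Component,
    hpso_cfg: HpsoConfig | None = None,
    rng: np.random.Generator | None = None,
    min_points: int = 5,
) -> FittedPeak:
    """Fit the asymmetric pseudo-Voigt model to one component by HPSO."""
    if len(c) < min_points:
        raise EmptyComponentError(f"insufficient points ({len(c)} < {min_points})")
    if not np.any(c.intensity > 0):
        raise EmptyComponentError("component has no positive intensity")
    bounds = component_fit_bounds(c)
    if hpso_cfg is None:
        hpso_cfg = HpsoConfig(bounds=bounds)
    else:
        hpso_cfg = replace(hpso_cfg, bounds=bounds)
    y = c.intensity

    def objective(thetas: np.ndarray) -> np.ndarray:
        resid = mapv_eval_batch(c.mz, np.atleast_2d(thetas)) - y[None, :]
        return np.einsum("ij,ij->i", resid, resid)

    theta_vec, sse = optimize(objective, hpso_cfg, rng=rng)
    theta = PeakParams.from_array(theta_vec)
    return FittedPeak(
        theta=theta,
        area=peak_area(theta),
        mu=asymmetry(theta),
        sse=sse,
        start_mz=float(c.mz[0]),
        end_mz=float(c.mz[-1]),
    )


def residual_noise_sigma(s: Spectrum) -> float:
    """Residual noise scale from first differences of the corrected trace."""
    d = np.diff(s.intensity)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745) / np.sqrt(2.0)


def _default_area_threshold(s: Spectrum, factor: float = 50.0) -> float:
    # roughly the area of a 5-sigma-high, 10-sample-wide noise bump
    dx = float(np.median(np.diff(s.mz)))
    return factor * residual_noise_sigma(s) * dx


def detect_peaks(
    s: Spectrum,
    cfg: DetectorConfig | None = None,
    hpso_cfg: HpsoConfig | None = None,
    seed: int | None = None,
) -> PeakTable:
    """Run the full picking recursion on a preprocessed spectrum."""
    cfg = cfg or DetectorConfig()
    if s.metadata.get("stage") not in ("baseline_corrected", "smoothed"):
        logger.warning("spectrum does not look preprocessed (stage=%r)",
                       s.metadata.get("stage"))
    area_thr = cfg.area_threshold
    if area_thr is None:
        area_thr = _default_area_threshold(s)
    width_thr = cfg.width_threshold
    if width_thr is None:
        width_thr = 0.1 * float(s.mz[-1] - s.mz[0])
    valley_tol = cfg.valley_tolerance
    if valley_tol is None:
        valley_tol = 8.0 * residual_noise_sigma(s)
    rng = np.random.default_rng(seed)

    queue = split_at_valleys(s.mz, s.intensity, valley_tol)
    accepted: list[FittedPeak] = []
    while queue:
        comp = queue.pop(0)
        if len(comp) < cfg.min_points or not np.any(comp.intensity > 0):
            continue
        try:
            fp = fit_component(comp, hpso_cfg, rng=rng, min_points=cfg.min_points)
        except EmptyComponentError:
            continue
        if fp.area < area_thr:
            continue
        width = fp.theta.sigma1 + fp.theta.sigma2  # FWHM of the fitted shape
        interior = find_valleys(comp.intensity, valley_tol)
        splittable = (
            comp.depth < cfg.max_depth
            and len(interior) > 0
            and (width > width_thr or fp.mu > cfg.asymmetry_threshold)
        )
        if splittable:
            queue.extend(
                split_at_valleys(
                    comp.mz,
                    comp.intensity,
                    valley_tol,
                    offset=comp.start,
                    depth=comp.depth + 1,
                )
            )
            continue
        if not (fp.start_mz <= fp.theta.alpha <= fp.end_mz):
            logger.warning("fitted summit %.4f outside component [%f, %f]; dropped",
                           fp.theta.alpha, fp.start_mz, fp.end_mz)
            continue
        accepted.append(fp)

    rows = [
        {
            "summit_mz": fp.theta.alpha,
            "height": fp.theta.H,
            "sigma1": fp.theta.sigma1,
            "sigma2": fp.theta.sigma2,
            "beta1": fp.theta.beta1,
            "beta2": fp.theta.beta2,
            "area": fp.area,
            "asymmetry": fp.mu,
            "start_mz": fp.start_mz,
            "end_mz": fp.end_mz,
            "sse": fp.sse,
        }
        for fp in accepted
    ]
    if not rows:
        return PeakTable.empty()
    return PeakTable.from_rows(rows)
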