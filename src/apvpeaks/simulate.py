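"""Synthetic spectrum generation.

Two families: (i) two-component asymmetric pseudo-Voigt mixtures on a
grid of asymmetry/overlap/noise levels, used for the model-comparison
study; (ii) many-peak MALDI-like spectra with an exponentially decaying
baseline and noise whose scale shrinks along the m/z axis, used to
exercise the full pipeline end to end.

All generators are pure functions of their design (seed included).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .io import PeakTable, Spectrum
from .models import PeakParams, asymmetry, mapv_eval, peak_area

__all__ = [
    "DEFAULT_GRID_LEVELS",
    "MultiPeakDesign",
    "TwoPeakDesign",
    "dataset1_grid",
    "default_multipeak_design",
    "generate_multipeak_spectrum",
    "generate_two_peak_spectrum",
    "truth_table",
]


@dataclass(frozen=True)
class TwoPeakDesign:
    theta_a: PeakParams
    theta_b: PeakParams
    grid_start: float
    grid_stop: float
    grid_spacing: float
    noise_sd: float
    seed: int
    mu_level: float | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo = self.theta_a.alpha - 5 * max(self.theta_a.sigma1, self.theta_a.sigma2)
        hi = self.theta_b.alpha + 5 * max(self.theta_b.sigma1, self.theta_b.sigma2)
        if self.grid_start > lo or self.grid_stop < hi:
            raise ValueError("grid must cover both peaks to at least 5 sigma")

    @property
    def mz(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_spacing)) + 1
        return self.grid_start + self.grid_spacing * np.arange(n)


def truth_table(thetas: Sequence[PeakParams], start_mz: float, end_mz: float) -> PeakTable:
    """Exact peak table (analytic areas, zero SSE) for known components."""
    rows = [
        {
            "summit_mz": t.alpha,
            "height": t.H,
            "sigma1": t.sigma1,
            "sigma2": t.sigma2,
            "beta1": t.beta1,
            "beta2": t.beta2,
            "area": peak_area(t),
            "asymmetry": asymmetry(t),
            "start_mz": start_mz,
            "end_mz": end_mz,
            "sse": 0.0,
        }
        for t in thetas
    ]
    return PeakTable.from_rows(rows)


def generate_two_peak_spectrum(design: TwoPeakDesign) -> tuple[Spectrum, PeakTable]:
    """Sum of the two components plus i.i.d. Gaussian noise, clipped at 0."""
    m = design.mz
    clean = mapv_eval(m, design.theta_a) + mapv_eval(m, design.theta_b)
    rng = np.random.default_rng(design.seed)
    noisy = clean + rng.normal(0.0, design.noise_sd, size=m.size) if design.noise_sd else clean
    noisy = np.clip(noisy, 0.0, None)
    spec = Spectrum(m, noisy, metadata={"stage": "raw", "kind": "two_peak"})
    truth = truth_table(
        sorted([design.theta_a, design.theta_b], key=lambda t: t.alpha),
        float(m[0]),
        float(m[-1]),
    )
    return spec, truth


# Emulated study grid: asymmetry rows mu in {1 .. 2}, an overlap axis in
# units of the first component's FWHM, and a relative noise axis.  The
# exact published grid lives in external supplementary material; these
# defaults reproduce its axes at plausible scales and are overridable.
DEFAULT_GRID_LEVELS: dict[str, tuple] = {
    "mu": (1.0, 1.25, 1.5, 1.75, 2.0),
    "sigma1": (1.0,),
    "h1": (100.0,),
    "h2": (80.0,),
    "beta1": (0.1,),
    "beta2": (0.9,),
    "separation": (4.0, 5.0),
    "noise_frac": (0.05,),
    "alpha1": (30.0,),
    "spacing": (0.1,),
}


def _design_from_combo(combo: dict, seed: int) -> TwoPeakDesign:
    mu = float(combo["mu"])
    s1 = float(combo["sigma1"])
    s2 = mu * s1
    fwhm = s1 + s2
    a1 = float(combo["alpha1"])
    a2 = a1 + float(combo["separation"]) * fwhm
    theta_a = PeakParams(
        float(combo["h1"]), a1, s1, s2, float(combo["beta1"]), float(combo["beta2"])
    )
    theta_b = PeakParams(
        float(combo["h2"]), a2, s1, s2, float(combo["beta1"]), float(combo["beta2"])
    )
    hmax = max(theta_a.H, theta_b.H)
    pad = 6.0 * max(s1, s2)
    return TwoPeakDesign(
        theta_a=theta_a,
        theta_b=theta_b,
        grid_start=a1 - pad,
        grid_stop=a2 + pad,
        grid_spacing=float(combo["spacing"]),
        noise_sd=float(combo["noise_frac"]) * hmax,
        seed=seed,
        mu_level=mu,
    )


def dataset1_grid(
    levels: dict[str, Sequence] | None = None,
    reps: int = 10,
    base_seed: int = 0,
) -> Iterator[TwoPeakDesign]:
    """Cartesian product of the level lists, ``reps`` seeded replicates each.

    The iterator is order stable and fully reproducible from
    ``base_seed``; every design at asymmetry level mu has both components
    built with ``sigma2 = mu * sigma1``.
    """
    lv = dict(DEFAULT_GRID_LEVELS)
    if levels:
        lv.update({k: tuple(v) for k, v in levels.items()})
    keys = sorted(lv)
    for idx, values in enumerate(itertools.product(*(lv[k] for k in keys))):
        combo = dict(zip(keys, values))
        for rep in range(reps):
            seed = int(
                np.random.SeedSequence((base_seed, idx, rep)).generate_state(1)[0]
            )
            yield _design_from_combo(combo, seed)


@dataclass(frozen=True)
class MultiPeakDesign:
    truth: tuple[PeakParams, ...]
    grid_start: float
    grid_stop: float
    grid_spacing: float
    baseline_amplitude: float = 0.0
    baseline_decay: float = 0.01
    noise_sd_start: float = 0.0
    noise_sd_end: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        alphas = [t.alpha for t in self.truth]
        if alphas != sorted(alphas):
            raise ValueError("truth peaks must be sorted by summit location")
        if any(a < self.grid_start or a > self.grid_stop for a in alphas):
            raise ValueError("all peaks must lie inside the grid")

    @property
    def mz(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_spacing)) + 1
        return self.grid_start + self.grid_spacing * np.arange(n)


def generate_multipeak_spectrum(design: MultiPeakDesign) -> tuple[Spectrum, PeakTable]:
    """Peaks + decaying baseline + noise of linearly decreasing scale."""
    m = design.mz
    clean = np.zeros_like(m)
    for t in design.truth:
        clean += mapv_eval(m, t)
    baseline = design.baseline_amplitude * np.exp(
        -design.baseline_decay * (m - m[0])
    )
    scale = np.linspace(design.noise_sd_start, design.noise_sd_end, m.size)
    rng = np.random.default_rng(design.seed)
    noise = rng.normal(0.0, 1.0, size=m.size) * scale
    y = np.clip(clean + baseline + noise, 0.0, None)
    spec = Spectrum(m, y, metadata={"stage": "raw", "kind": "multipeak"})
    truth = truth_table(design.truth, float(m[0]), float(m[-1]))
    return spec, truth


def default_multipeak_design(
    n_peaks: int = 30, seed: int = 0, noise_frac: float = 0.015
) -> MultiPeakDesign:
    """A MALDI-like many-peak fixture on m/z 100-1100.

    Peaks widen towards high m/z, heights span a decade, asymmetries reach
    2, and summits keep at least 1.2 combined widths of separation so the
    truth is recoverable in principle.
    """
    rng = np.random.default_rng(seed)
    lo, hi = 150.0, 1050.0
    alphas: list[float] = []
    guard = 0
    while len(alphas) < n_peaks and guard < 10000:
        guard += 1
        a = float(rng.uniform(lo, hi))
        w = 1.0 + 3.0 * (a - lo) / (hi - lo)
        if all(abs(a - b) > 3.5 * w for b in alphas):
            alphas.append(a)
    alphas.sort()
    thetas = []
    for a in alphas:
        base_w = (1.0 + 3.0 * (a - lo) / (hi - lo)) * rng.uniform(0.7, 1.1)
        mu = rng.uniform(1.0, 2.0)
        s1, s2 = base_w, base_w * mu
        if rng.random() < 0.5:
            s1, s2 = s2, s1
        thetas.append(
            PeakParams(
                H=float(rng.uniform(40.0, 400.0)),
                alpha=a,
                sigma1=float(s1),
                sigma2=float(s2),
                beta1=float(rng.uniform(0.0, 1.0)),
                beta2=float(rng.uniform(0.0, 1.0)),
            )
        )
    hmax = max(t.H for t in thetas)
    return MultiPeakDesign(
        truth=tuple(thetas),
        grid_start=100.0,
        grid_stop=1100.0,
        grid_spacing=0.25,
        baseline_amplitude=0.3 * hmax,
        baseline_decay=0.01,
        noise_sd_start=2.0 * noise_frac * hmax,
        noise_sd_end=0.5 * noise_frac * hmax,
        seed=int(np.random.SeedSequence((seed, 1)).generate_state(1)[0]),
    )
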