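"""Hydration-layer statistics: d_pw, population histograms, DGD, fractions.

The coordinate of the whole analysis is d_pw — the minimum-image distance
from each water oxygen to its nearest polymer atom.  Time-averaged
population histograms of d_pw typically show two shells (near 0.28 nm and
0.56 nm for hydrophilic polysaccharides); a double-Gaussian decomposition
(DGD) quantifies them, and fixed cutoffs (0.45 nm / 2.0 nm by default)
partition water into a first adsorbed layer, a second layer and the
remainder.  Layer volume fractions assign each counted water molecule a
fixed molecular volume and close the balance with the polymer fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .curves import WATER_MOLECULAR_VOLUME_NM3
from .geometry import Box, Configuration, minimum_image_displacement

__all__ = [
    "DistanceHistogram",
    "DGDResults",
    "DoubleGaussianModel",
    "LayerPartition",
    "FitError",
    "polymer_water_distances",
    "population_histogram",
    "fit_double_gaussian",
    "assign_layers",
    "layer_volume_fractions",
    "DEFAULT_CUTOFF_12",
    "DEFAULT_CUTOFF_2END",
]

#: First/second layer boundary, nm (the inter-shell valley).
DEFAULT_CUTOFF_12 = 0.45
#: Outer boundary of the second layer, nm.
DEFAULT_CUTOFF_2END = 2.0


class FitError(RuntimeError):
    """Non-convergent fit; carries the best iterate for diagnosis."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def polymer_water_distances(
    config: Configuration, include_hydrogens: bool = True
) -> np.ndarray:
    """d_pw for every water molecule: the minimum-image distance from its
    oxygen to the nearest polymer atom.

    ``include_hydrogens=False`` restricts "polymer atom" to heavy atoms.
    """
    poly = np.flatnonzero(config.polymer_mask)
    if not include_hydrogens:
        poly = poly[[config.elements[i].upper() != "H" for i in poly]]
    if len(poly) == 0:
        raise ValueError("configuration has no polymer atoms")
    wo = config.water_oxygen_indices
    if len(wo) == 0:
        return np.empty(0)
    return _nearest_distances(config.positions[wo], config.positions[poly], config.box)


def _nearest_distances(query: np.ndarray, targets: np.ndarray, box: Box) -> np.ndarray:
    from scipy.spatial import cKDTree

    L = box.lengths_array
    if box.fully_periodic:
        tree = cKDTree(np.mod(targets, L), boxsize=L)
        d, _ = tree.query(np.mod(query, L), k=1)
        return np.asarray(d, dtype=float)
    disp = minimum_image_displacement(query[:, None, :], targets[None, :, :], box)
    return np.linalg.norm(disp, axis=-1).min(axis=1)


@dataclass
class DistanceHistogram:
    """Time-averaged water population per d_pw bin at one moisture content."""

    bin_edges: np.ndarray
    population: np.ndarray
    m: float = float("nan")
    n_frames: int = 1
    n_truncated: float = 0.0  # mean per-frame count beyond the last edge

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        if len(self.bin_edges) != len(self.population) + 1:
            raise ValueError("bin_edges must have one more entry than population")
        if np.any(self.population < 0):
            raise ValueError("population must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        """Mean per-frame water count inside [0, d_max)."""
        return float(self.population.sum())


def population_histogram(
    distances,
    bin_width: float = 0.01,
    d_max: float = 2.0,
    m: float = float("nan"),
) -> DistanceHistogram:
    """Histogram of d_pw, averaged over frames.

    ``distances`` is one frame's array or a sequence of per-frame arrays.
    Bins are half-open [lo, hi) from 0 to d_max; distances beyond d_max
    are excluded and reported via ``n_truncated`` (with a warning when the
    histogram comes out empty).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = _as_frames(distances)
    edges = np.arange(0.0, d_max + 0.5 * bin_width, bin_width)
    pops = np.zeros(len(edges) - 1)
    truncated = 0.0
    for fr in frames:
        fr = np.asarray(fr, dtype=float)
        counts, _ = np.histogram(fr, bins=edges)
        pops += counts
        truncated += float(np.sum(fr >= edges[-1]))
    n_frames = len(frames)
    pops /= n_frames
    truncated /= n_frames
    if truncated > 0 and pops.sum() == 0:
        warnings.warn(
            f"all {truncated:.1f} distances per frame lie beyond d_max={d_max}; "
            "histogram is empty"
        )
    return DistanceHistogram(edges, pops, m=m, n_frames=n_frames, n_truncated=truncated)


def _as_frames(distances) -> list[np.ndarray]:
    if isinstance(distances, np.ndarray) and distances.ndim == 1:
        return [distances]
    seq = list(distances)
    if seq and np.isscalar(seq[0]):
        return [np.asarray(seq, dtype=float)]
    return [np.asarray(f, dtype=float) for f in seq]


# ---------------------------------------------------------------------------
# double-Gaussian decomposition


def _two_gaussians(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - m2) / s2) ** 2
    )


@dataclass
class DGDResults:
    """Double-Gaussian fit of a population histogram.

    Amplitudes are peak heights in counts-per-bin; means/sds in nm; the
    components are ordered by mean.  ``degenerate`` flags a collapsed
    second component (single-shell data).
    """

    amp1: float
    mean1: float
    sd1: float
    amp2: float
    mean2: float
    sd2: float
    rss: float
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.amp1, self.mean1, self.sd1, self.amp2, self.mean2, self.sd2]
        )

    @property
    def degenerate(self) -> bool:
        """True when the data do not support two resolved shells: one
        amplitude vanishes, a width collapses to its bound, or the two
        means coincide within half the wider component's sd."""
        big = max(self.amp1, self.amp2)
        return bool(
            min(self.amp1, self.amp2) < 1e-2 * big
            or self.sd1 <= 1.1e-4
            or self.sd2 <= 1.1e-4
            or (self.mean2 - self.mean1) < 0.5 * max(self.sd1, self.sd2)
        )

    def predict(self, x) -> np.ndarray:
        return _two_gaussians(np.asarray(x, dtype=float), *self.params)

    def summary(self) -> str:
        lines = [
            "Double-Gaussian decomposition",
            "=" * 47,
            f"{'component':<12}{'amp':>10}{'mean (nm)':>12}{'sd (nm)':>10}",
            f"{'shell 1':<12}{self.amp1:>10.3f}{self.mean1:>12.4f}{self.sd1:>10.4f}",
            f"{'shell 2':<12}{self.amp2:>10.3f}{self.mean2:>12.4f}{self.sd2:>10.4f}",
            f"rss: {self.rss:.6g}" + ("   [degenerate 2nd component]" if self.degenerate else ""),
            "=" * 47,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "amp1": self.amp1, "mean1_nm": self.mean1, "sd1_nm": self.sd1,
            "amp2": self.amp2, "mean2_nm": self.mean2, "sd2_nm": self.sd2,
            "rss": self.rss, "degenerate": self.degenerate,
        }


class DoubleGaussianModel:
    """Least-squares two-Gaussian model of a d_pw population histogram."""

    def __init__(self, hist: DistanceHistogram):
        self.hist = hist
        if int(np.sum(hist.population > 0)) < 6:
            raise ValueError("need at least 6 nonzero bins for a two-Gaussian fit")

    def _initial_guesses(self) -> list[np.ndarray]:
        """Candidate starts: smoothed-peak based and quantile based.

        Raw histograms of a few thousand counts carry Poisson spikes that
        can mislead a single peak-based start into a poor local optimum,
        so the fit is multi-started and the best optimum kept.
        """
        x, y = self.hist.bin_centers, self.hist.population
        dx = x[1] - x[0]
        guesses: list[np.ndarray] = []

        win = max(3, int(round(0.05 / dx)) | 1)
        smooth = np.convolve(y, np.ones(win) / win, mode="same")
        peaks, props = find_peaks(
            smooth, height=0.1 * smooth.max(), distance=max(5, int(0.1 / dx))
        )
        if len(peaks) >= 2:
            order = np.argsort(props["peak_heights"])[::-1][:2]
            chosen = np.sort(peaks[order])
            m1, m2 = x[chosen[0]], x[chosen[1]]
            spread = max((m2 - m1) / 4, 2 * dx)
            guesses.append(
                np.array([y[chosen[0]], m1, spread, y[chosen[1]], m2, 2 * spread])
            )
        # quantile start: shell centers near the 30th/80th population quantiles
        cum = np.cumsum(y) / y.sum()
        q30, q80 = x[np.searchsorted(cum, 0.3)], x[np.searchsorted(cum, 0.8)]
        spread = max((q80 - q30) / 3, 2 * dx)
        amp = float(y.max())
        guesses.append(np.array([amp, q30, spread, amp / 3, q80, 2 * spread]))
        # single-shell start: everything under one peak, vestigial second
        k = int(np.argmax(smooth))
        guesses.append(
            np.array([y[k], x[k], 4 * dx, 0.2 * y[k], min(2 * x[k], x[-1]), 8 * dx])
        )
        return guesses

    def fit(self, init: np.ndarray | DGDResults | None = None) -> DGDResults:
        x, y = self.hist.bin_centers, self.hist.population
        if init is None:
            starts = self._initial_guesses()
        elif isinstance(init, DGDResults):
            starts = [init.params]
        else:
            starts = [np.asarray(init, dtype=float)]
        lo = [0.0, x[0], 1e-4, 0.0, x[0], 1e-4]
        hi = [np.inf, x[-1], x[-1], np.inf, x[-1], x[-1]]
        best = None
        last_exc: Exception | None = None
        for p0 in starts:
            p0 = np.clip(p0, lo, hi)
            try:
                popt_i, pcov_i = curve_fit(
                    _two_gaussians, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
            except RuntimeError as exc:
                last_exc = exc
                continue
            rss_i = float(np.sum((y - _two_gaussians(x, *popt_i)) ** 2))
            if best is None or rss_i < best[0]:
                best = (rss_i, popt_i, pcov_i)
        if best is None:
            raise FitError(
                f"double-Gaussian fit did not converge: {last_exc}",
                best=starts[0],
            )
        rss, popt, pcov = best
        a1, m1, s1, a2, m2, s2 = popt
        if m1 > m2:  # report components in ascending-mean order
            a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
            perm = [3, 4, 5, 0, 1, 2]
            pcov = pcov[np.ix_(perm, perm)]
        return DGDResults(a1, m1, s1, a2, m2, s2, rss, cov=pcov)


def fit_double_gaussian(
    hist: DistanceHistogram, init: np.ndarray | DGDResults | None = None
) -> DGDResults:
    """Fit amp1·N(mean1, sd1) + amp2·N(mean2, sd2) to a population histogram."""
    return DoubleGaussianModel(hist).fit(init)


# ---------------------------------------------------------------------------
# layer assignment and volume fractions


@dataclass
class LayerPartition:
    """Time-averaged layer counts plus closing volume fractions."""

    cutoff_12: float
    cutoff_2end: float
    n_w1: float
    n_w2: float
    n_beyond: float
    f_p: float = float("nan")
    f_w1: float = float("nan")
    f_w2: float = float("nan")


def assign_layers(
    distances,
    cutoff_12: float = DEFAULT_CUTOFF_12,
    cutoff_2end: float = DEFAULT_CUTOFF_2END,
) -> LayerPartition:
    """Partition water by d_pw: layer 1 (< cutoff_12), layer 2
    ([cutoff_12, cutoff_2end)) and beyond; counts are frame averages."""
    if not 0 < cutoff_12 < cutoff_2end:
        raise ValueError("need 0 < cutoff_12 < cutoff_2end")
    frames = _as_frames(distances)
    n1 = np.mean([np.sum(f < cutoff_12) for f in frames])
    n2 = np.mean([np.sum((f >= cutoff_12) & (f < cutoff_2end)) for f in frames])
    nb = np.mean([np.sum(f >= cutoff_2end) for f in frames])
    return LayerPartition(cutoff_12, cutoff_2end, float(n1), float(n2), float(nb))


def layer_volume_fractions(
    partition: LayerPartition,
    box_volume: float,
    water_molar_volume: float = WATER_MOLECULAR_VOLUME_NM3,
) -> tuple[float, float, float]:
    """(f_p, f_w1, f_w2) from layer counts: f_wi = n_wi·v_w/V, f_p closes to 1.

    Raises when the implied water volume exceeds the box (unphysical).
    """
    if box_volume <= 0:
        raise ValueError("box volume must be positive")
    f_w1 = partition.n_w1 * water_molar_volume / box_volume
    f_w2 = partition.n_w2 * water_molar_volume / box_volume
    f_p = 1.0 - f_w1 - f_w2
    if f_p < 0:
        raise ValueError(
            f"water volume exceeds the box (f_w1 + f_w2 = {f_w1 + f_w2:.3f} > 1)"
        )
    partition.f_p, partition.f_w1, partition.f_w2 = f_p, f_w1, f_w2
    return f_p, f_w1, f_w2
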