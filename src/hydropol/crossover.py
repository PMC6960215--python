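"""Moisture-induced crossover detection by continuous two-segment fitting.

Property-vs-moisture curves of hydrated hydrophilic polymers often show
two linear regimes — a low-moisture regime where added water binds to the
polymer and a high-moisture regime where it accumulates on previously
adsorbed water — meeting at a breakpoint m*.  :class:`TwoSegmentModel`
fits a continuous piecewise-linear function

    y(m) = b0 + b1 m + b2 (m - m*)_+

by least squares: candidate breakpoints are scanned over the interior
data points (each candidate leaves at least three points strictly on each
side), the best candidate is polished by a bounded continuous search, and
the breakpoint uncertainty comes from seeded residual-bootstrap
resampling.  Whether a crossover is present at all is decided by a
permutation test on the rss improvement of the two-segment fit over a
single straight line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .curves import PropertyCurve

__all__ = ["TwoSegmentModel", "CrossoverResults", "fit_two_segment"]


def _hinge_design(m: np.ndarray, c: float) -> np.ndarray:
    return np.column_stack([np.ones_like(m), m, np.clip(m - c, 0.0, None)])


def _fit_at_breakpoint(m, y, c):
    A = _hinge_design(m, c)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    return coef, rss


def _one_segment(m, y):
    A = np.column_stack([np.ones_like(m), m])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(np.sum((y - A @ coef) ** 2))
    return coef, rss


def _best_breakpoint(m, y, candidates, polish=True):
    """Scan candidates, then polish continuously inside the best bracket.

    The polish is skipped during bootstrap/permutation resampling, where
    candidate-grid resolution is sufficient and refits dominate runtime.
    """
    rss_by_c = [
        _fit_at_breakpoint(m, y, c)[1] for c in candidates
    ]
    k = int(np.argmin(rss_by_c))
    c_best, rss_best = candidates[k], rss_by_c[k]
    lo = candidates[k - 1] if k > 0 else m[0]
    hi = candidates[k + 1] if k < len(candidates) - 1 else m[-1]
    if polish and hi > lo:
        sol = minimize_scalar(
            lambda c: _fit_at_breakpoint(m, y, c)[1],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        # keep the polish only when it strictly improves the fit
        if sol.fun < rss_best * (1 - 1e-12) - 1e-300:
            c_best, rss_best = float(sol.x), float(sol.fun)
    coef, rss = _fit_at_breakpoint(m, y, c_best)
    return c_best, coef, rss


class TwoSegmentModel:
    """Continuous two-segment linear model of a property-vs-moisture curve."""

    def __init__(self, m, y):
        order = np.argsort(np.asarray(m, dtype=float))
        self.m = np.asarray(m, dtype=float)[order]
        self.y = np.asarray(y, dtype=float)[order]
        if len(self.m) < 6:
            raise ValueError("need at least 6 points for a two-segment fit")
        if len(np.unique(self.m)) != len(self.m):
            raise ValueError("duplicate m values are not supported")

    @classmethod
    def from_curve(cls, curve: PropertyCurve) -> "TwoSegmentModel":
        return cls(curve.m_grid, curve.values)

    def _candidates(self, m_min, m_max):
        m = self.m
        lo = m[0] if m_min is None else float(m_min)
        hi = m[-1] if m_max is None else float(m_max)
        if lo >= hi:
            raise ValueError("m_min must be below m_max")
        # interior data points with >= 3 points strictly on each side
        cands = [
            c for i, c in enumerate(m)
            if 3 <= i <= len(m) - 4 and lo <= c <= hi
        ]
        if not cands:
            raise ValueError(
                "no admissible breakpoint: fewer than 3 points on one side of "
                "every candidate in the requested window"
            )
        return np.asarray(cands)

    def fit(
        self,
        m_min: float | None = None,
        m_max: float | None = None,
        *,
        n_bootstrap: int = 200,
        n_permutations: int = 199,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> "CrossoverResults":
        """Fit the breakpoint; bootstrap its CI; permutation-test its reality.

        ``seed`` drives both resampling procedures; identical seeds give
        identical results.
        """
        m, y = self.m, self.y
        cands = self._candidates(m_min, m_max)
        c_best, coef, rss2 = _best_breakpoint(m, y, cands)
        coef1, rss1 = _one_segment(m, y)

        rng = np.random.default_rng(seed)
        fitted = _hinge_design(m, c_best) @ coef
        resid = y - fitted
        boot = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            y_b = fitted + rng.choice(resid, size=len(resid), replace=True)
            boot[b] = _best_breakpoint(m, y_b, cands, polish=False)[0]
        ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))

        # permutation test of the two-segment improvement under the
        # single-line null: permute one-segment residuals.  The observed
        # statistic uses the grid-only (unpolished) fit so it is computed
        # exactly like the permuted ones.
        line = np.column_stack([np.ones_like(m), m]) @ coef1
        resid1 = y - line
        rss2_grid = _best_breakpoint(m, y, cands, polish=False)[2]
        gain_obs = rss1 - rss2_grid
        exceed = 0
        for _ in range(n_permutations):
            y_p = line + rng.permutation(resid1)
            _, _, rss2_p = _best_breakpoint(m, y_p, cands, polish=False)
            _, rss1_p = _one_segment(m, y_p)
            if (rss1_p - rss2_p) >= gain_obs:
                exceed += 1
        p_value = (1 + exceed) / (1 + n_permutations)

        return CrossoverResults(
            model=self,
            m_star=float(c_best),
            intercept_lo=float(coef[0]),
            slope_lo=float(coef[1]),
            slope_hi=float(coef[1] + coef[2]),
            rss=rss2,
            rss_one_segment=rss1,
            ci_m_star=ci,
            p_value=float(p_value),
            crossover_detected=bool(p_value <= alpha),
            bootstrap_breakpoints=boot,
        )


@dataclass
class CrossoverResults:
    """Breakpoint, segment parameters, CI and the crossover verdict."""

    model: TwoSegmentModel
    m_star: float
    intercept_lo: float
    slope_lo: float
    slope_hi: float
    rss: float
    rss_one_segment: float
    ci_m_star: tuple[float, float]
    p_value: float
    crossover_detected: bool
    bootstrap_breakpoints: np.ndarray = field(repr=False, default=None)

    @property
    def intercept_hi(self) -> float:
        """Intercept of the high-moisture segment (continuity at m_star)."""
        return self.intercept_lo + (self.slope_lo - self.slope_hi) * self.m_star

    def predict(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        coef = np.array(
            [self.intercept_lo, self.slope_lo, self.slope_hi - self.slope_lo]
        )
        return _hinge_design(m, self.m_star) @ coef

    def to_dict(self) -> dict:
        return {
            "m_star": self.m_star,
            "ci_m_star": list(self.ci_m_star),
            "slope_lo": self.slope_lo,
            "slope_hi": self.slope_hi,
            "intercept_lo": self.intercept_lo,
            "rss": self.rss,
            "rss_one_segment": self.rss_one_segment,
            "p_value": self.p_value,
            "verdict": "crossover" if self.crossover_detected else "no crossover detected",
        }

    def summary(self) -> str:
        verdict = "crossover" if self.crossover_detected else "no crossover detected"
        return "\n".join([
            "Two-segment crossover fit",
            "=" * 47,
            f"breakpoint m*:   {self.m_star:.4f}  "
            f"(95% CI {self.ci_m_star[0]:.4f} – {self.ci_m_star[1]:.4f})",
            f"slope (low m):   {self.slope_lo:.6g}",
            f"slope (high m):  {self.slope_hi:.6g}",
            f"rss 2-segment:   {self.rss:.6g}",
            f"rss 1-segment:   {self.rss_one_segment:.6g}",
            f"permutation p:   {self.p_value:.4f}  -> {verdict}",
            "=" * 47,
        ])


def fit_two_segment(
    curve,
    m_min: float | None = None,
    m_max: float | None = None,
    *,
    seed: int | None = None,
    **kwargs,
) -> CrossoverResults:
    """Fit the two-regime crossover of a property curve.

    ``curve`` is a :class:`~hydropol.curves.PropertyCurve` or an ``(m, y)``
    pair of arrays.
    """
    if isinstance(curve, PropertyCurve):
        model = TwoSegmentModel.from_curve(curve)
    else:
        m, y = curve
        model = TwoSegmentModel(m, y)
    return model.fit(m_min, m_max, seed=seed, **kwargs)
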