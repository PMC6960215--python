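"""Three-component composite-material models and their inversion.

A hydrated polymer is treated as a composite of three phases — polymer,
first adsorbed water layer, second adsorbed water layer — with volume
fractions (f_p, f_w1, f_w2) that change with moisture content.  A
property X_c of the composite is modelled as either the fraction-weighted
arithmetic mean of the phase properties (mixture rule / parallel model)

    X_c = f_p X_p + f_w1 X_w1 + f_w2 X_w2

or the fraction-weighted harmonic mean (series model)

    1/X_c = f_p/X_p + f_w1/X_w1 + f_w2/X_w2 .

Given a property-vs-moisture curve with attached fractions,
:class:`CompositeModel` recovers the phase properties (X_p, X_w1, X_w2) by
least squares, with standard errors from the local quadratic
approximation.  Elastic moduli conventionally follow the series model,
scalar thermodynamic properties (adsorption heat, heat capacity) the
mixture rule, and the thermal expansion coefficient the parallel model;
``DEFAULT_MODEL_KINDS`` encodes that mapping and callers may override it.

The isotropic-elasticity relation G = 3KE/(9K − E) connects the shear
modulus to bulk and Young's moduli for an isotropic material.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import FractionSchedule, PropertyCurve

__all__ = [
    "CompositeKind",
    "CompositeModel",
    "CompositeResults",
    "IdentifiabilityError",
    "composite_predict",
    "fit_composite",
    "shear_from_isotropy",
    "DEFAULT_MODEL_KINDS",
]


class CompositeKind(str, enum.Enum):
    MIXTURE = "mixture"
    PARALLEL = "parallel"
    SERIES = "series"

    @classmethod
    def coerce(cls, kind) -> "CompositeKind":
        if isinstance(kind, cls):
            return kind
        return cls(str(kind).lower())


#: Conventional model per property: moduli in series, scalar heats by the
#: mixture rule, thermal expansion in parallel.
DEFAULT_MODEL_KINDS: dict[str, CompositeKind] = {
    "K": CompositeKind.SERIES,
    "E": CompositeKind.SERIES,
    "G": CompositeKind.SERIES,
    "Q": CompositeKind.MIXTURE,
    "CP": CompositeKind.MIXTURE,
    "ALPHA": CompositeKind.PARALLEL,
}


class IdentifiabilityError(ValueError):
    """Raised when the fraction design cannot identify all three phases."""


_PARAM_NAMES = ("X_p", "X_w1", "X_w2")


def composite_predict(model_kind, X_p, X_w1, X_w2, f_p, f_w1, f_w2):
    """Composite property from phase properties and volume fractions.

    Vectorised over the fractions.  MIXTURE and PARALLEL are the
    arithmetic mean; SERIES is the harmonic mean and requires strictly
    positive phase properties.
    """
    kind = CompositeKind.coerce(model_kind)
    F = np.column_stack(
        [np.atleast_1d(np.asarray(f, dtype=float)) for f in (f_p, f_w1, f_w2)]
    )
    if np.any(F < -1e-9):
        raise ValueError("volume fractions must be non-negative")
    total = F.sum(axis=1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ValueError("volume fractions must sum to 1 (within 1e-6)")
    X = np.asarray([X_p, X_w1, X_w2], dtype=float)
    if kind is CompositeKind.SERIES:
        if np.any(X <= 0):
            raise ValueError("series model requires strictly positive phase properties")
        out = 1.0 / (F @ (1.0 / X))
    else:
        out = F @ X
    return out if out.size > 1 else float(out[0])


def shear_from_isotropy(K: float, E: float) -> float:
    """Shear modulus of an isotropic material from bulk and Young's moduli,
    G = 3KE/(9K − E).  Requires 9K > E (else the pair is not isotropic)."""
    if 9.0 * K - E <= 0:
        raise ValueError(f"9K - E must be positive for an isotropic solid (K={K}, E={E})")
    return 3.0 * K * E / (9.0 * K - E)


class CompositeModel:
    """Least-squares decomposition of a property curve into phase properties.

    Parameters
    ----------
    endog : array
        Observed composite property at each grid point.
    fractions : (n, 3) array
        Volume fractions (f_p, f_w1, f_w2) per grid point.
    kind : CompositeKind or str
        Mixing law.
    weights : array, optional
        Per-point weights; inverse variances when the curve supplies sd.
    """

    def __init__(self, endog, fractions, kind, weights=None):
        self.endog = np.asarray(endog, dtype=float)
        self.fractions = np.asarray(fractions, dtype=float)
        self.kind = CompositeKind.coerce(kind)
        n = len(self.endog)
        if self.fractions.shape != (n, 3):
            raise ValueError("fractions must be an (n, 3) array aligned with endog")
        if n < 4:
            raise ValueError("need at least 4 grid points to fit 3 phase properties")
        self.weights = (
            np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        )
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        self._check_identifiable()

    @classmethod
    def from_curve(cls, curve: PropertyCurve, kind=None) -> "CompositeModel":
        if curve.fractions is None:
            raise ValueError("curve has no attached fraction schedule")
        if kind is None:
            try:
                kind = DEFAULT_MODEL_KINDS[curve.property]
            except KeyError:
                raise ValueError(
                    f"no default model kind for property {curve.property!r}; "
                    "pass kind explicitly"
                ) from None
        weights = None
        if curve.sd is not None:
            if np.any(curve.sd <= 0):
                raise ValueError("sd column must be strictly positive")
            weights = 1.0 / curve.sd**2
        return cls(curve.values, curve.fractions.fractions, kind, weights=weights)

    def _check_identifiable(self) -> None:
        W = np.sqrt(self.weights)[:, None]
        rank = np.linalg.matrix_rank(self.fractions * W, tol=1e-10)
        if rank < 3:
            # name the parameter dominating the null space
            _, _, vt = np.linalg.svd(self.fractions * W)
            culprit = _PARAM_NAMES[int(np.argmax(np.abs(vt[-1])))]
            raise IdentifiabilityError(
                f"fraction design has rank {rank} < 3: parameter {culprit} is not "
                "identifiable (fractions do not vary independently across the grid)"
            )

    def predict(self, params) -> np.ndarray:
        return np.asarray(
            composite_predict(
                self.kind, *params,
                self.fractions[:, 0], self.fractions[:, 1], self.fractions[:, 2],
            )
        ).reshape(-1)

    def fit(self) -> "CompositeResults":
        y, F, w = self.endog, self.fractions, self.weights
        sw = np.sqrt(w)
        if self.kind is CompositeKind.SERIES:
            params, cov = self._fit_series(y, F, sw)
        else:
            params, cov = self._fit_linear(y, F, sw)
        resid = y - self.predict(params)
        rss = float(np.sum(w * resid**2))
        return CompositeResults(self, params, cov, rss)

    def _fit_linear(self, y, F, sw):
        A = F * sw[:, None]
        b = y * sw
        params, *_ = np.linalg.lstsq(A, b, rcond=None)
        dof = max(len(y) - 3, 1)
        sigma2 = float(np.sum((b - A @ params) ** 2)) / dof
        cov = sigma2 * np.linalg.inv(A.T @ A)
        return params, cov

    def _fit_series(self, y, F, sw):
        """Series fit in the reciprocal parametrisation beta_j = 1/X_j.

        The reciprocal response 1/X_c is linear in beta, which gives a
        closed-form start; the bounded refinement then minimises the
        original-scale residuals over beta, where the likelihood stays
        well conditioned even when a phase contributes little (X -> inf
        is the finite boundary beta -> 0).  Covariances transform back by
        the delta method and are then floored by a seeded residual-
        bootstrap estimate: the reciprocal transform makes the sampling
        distribution of 1/beta skewed at small n, and the linearised
        standard errors alone under-state it.  The reported standard
        error per parameter is the larger of the two (conservative).
        """
        if np.any(y <= 0):
            raise ValueError("series model requires strictly positive observations")
        A = F * sw[:, None]
        b = sw / y
        beta0, *_ = np.linalg.lstsq(A, b, rcond=None)
        beta0 = np.clip(beta0, 1e-10, 1e10)

        def resid(beta):
            return sw * (y - 1.0 / (F @ beta))

        sol = least_squares(
            resid, beta0, bounds=(1e-12, 1e12),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        beta = sol.x
        dof = max(len(y) - 3, 1)
        sigma2 = float(np.sum(sol.fun**2)) / dof
        JtJ = sol.jac.T @ sol.jac
        try:
            cov_beta = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov_beta = sigma2 * np.linalg.pinv(JtJ)
        D = np.diag(-1.0 / beta**2)
        cov = D @ cov_beta @ D
        boot = self._series_bootstrap_se(y, F, sw, beta)
        delta_se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        scale = np.maximum(boot, delta_se) / delta_se
        cov = cov * np.outer(scale, scale)  # inflate, keep correlations
        return 1.0 / beta, cov

    @staticmethod
    def _series_bootstrap_se(y, F, sw, beta, n_boot=200, seed=0):
        """Residual-bootstrap spread of the phase properties, using the
        weighted linear solve in reciprocal space (var(1/y) ~ sigma^2/y^4)
        as a fast surrogate for the full refit."""
        yhat = 1.0 / (F @ beta)
        resid = y - yhat
        rng = np.random.default_rng(seed)
        W = sw**2 * yhat**4
        M = np.linalg.solve(F.T @ (F * W[:, None]), (F * W[:, None]).T)
        Y = np.clip(
            yhat[None, :] + rng.choice(resid, size=(n_boot, len(y)), replace=True),
            1e-9, None,
        )
        betas = (1.0 / Y) @ M.T
        Xs = 1.0 / np.clip(betas, 1e-12, None)
        return Xs.std(axis=0)


@dataclass
class CompositeResults:
    """Fitted phase properties with uncertainties and diagnostics."""

    model: CompositeModel
    params: np.ndarray
    cov_params_: np.ndarray
    rss: float

    @property
    def X_p(self) -> float:
        return float(self.params[0])

    @property
    def X_w1(self) -> float:
        return float(self.params[1])

    @property
    def X_w2(self) -> float:
        return float(self.params[2])

    @property
    def bse(self) -> np.ndarray:
        """Per-parameter standard errors."""
        return np.sqrt(np.clip(np.diag(self.cov_params_), 0, None))

    @property
    def se(self) -> np.ndarray:
        return self.bse

    def cov_params(self) -> np.ndarray:
        return self.cov_params_

    def predict(self, fractions=None) -> np.ndarray:
        if fractions is None:
            return self.model.predict(self.params)
        F = np.asarray(fractions, dtype=float)
        return np.asarray(
            composite_predict(self.model.kind, *self.params, F[:, 0], F[:, 1], F[:, 2])
        ).reshape(-1)

    def to_dict(self) -> dict:
        return {
            "model": self.model.kind.value,
            "X_p": self.X_p,
            "X_w1": self.X_w1,
            "X_w2": self.X_w2,
            "se": [float(s) for s in self.bse],
            "rss": self.rss,
        }

    def summary(self) -> str:
        lines = [
            "Composite decomposition",
            "=" * 47,
            f"model kind:      {self.model.kind.value}",
            f"n points:        {len(self.model.endog)}",
            f"weighted rss:    {self.rss:.6g}",
            "-" * 47,
            f"{'phase':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name, p, s in zip(_PARAM_NAMES, self.params, self.bse):
            lines.append(f"{name:<10}{p:>14.6g}{s:>14.3g}")
        lines.append("=" * 47)
        return "\n".join(lines)


def fit_composite(model_kind, curve: PropertyCurve) -> CompositeResults:
    """Recover (X_p, X_w1, X_w2) from a property curve with fractions."""
    return CompositeModel.from_curve(curve, kind=model_kind).fit()
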