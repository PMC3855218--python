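"""Maximum-likelihood fitting of accuracy curves to cross-validated data.

The observation model: the replicate accuracy of scenario *i* (training-set
size ``N_i``) is normal with mean given by the chosen deterministic equation
at ``N_i`` and variance equal to the scenario's empirical variance over its
replicates.  Replicates and scenarios are treated as independent (a
modelling simplification: folds within a replicate share animals).  The log
likelihood is maximised over Me alone (D1/G1/G2), over (Me, w) jointly
(D2/G3), or over a global (Me, z) with w tied to the marker density through
w = 1 - z/ln(rho) (D2-density, pooling scenario tables of several panels).

The user-facing surface mirrors statsmodels: construct a model object from
the data, call :meth:`fit`, and read estimates, log-likelihood and a
``summary()`` off the returned results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar

from .crossval import CVScenarioTable
from .eqns import AccuracyModelSpec, SpecificationError, accuracy, w_of_density
from .relmat import InputError

__all__ = [
    "log_likelihood",
    "AccuracyCurveModel",
    "AccuracyCurveResults",
    "FitResult",
    "DensityAccuracyModel",
    "DensityRegressionResult",
    "fit_me",
    "fit_me_w",
    "fit_global_density",
    "regress_w_density",
    "extrapolate",
]

ME_BOUNDS = (1.0, 1e6)
W_BOUNDS = (0.01, 1.0)
Z_BOUNDS = (0.0, 10.0)
PLATEAU_TOL = 0.005  # successive w closer than this define the constant region


class DegenerateScenarioError(ValueError):
    """A scenario has zero empirical variance; its likelihood is undefined."""


def _scenario_arrays(table: CVScenarioTable):
    out = []
    for s in table:
        var = s.empirical_variance
        if not var > 0:
            raise DegenerateScenarioError(
                f"scenario k={s.k} has zero empirical variance"
            )
        out.append((float(s.n_train), s.accuracies, var))
    return out


def log_likelihood(table: CVScenarioTable, spec: AccuracyModelSpec) -> float:
    """Normal log-likelihood of a scenario table under an accuracy equation."""
    ll = 0.0
    for n_train, accs, var in _scenario_arrays(table):
        mu = accuracy(spec, n_train)
        ll += float(
            -0.5 * len(accs) * np.log(2.0 * np.pi * var)
            - np.sum((accs - mu) ** 2) / (2.0 * var)
        )
    return ll


@dataclass
class AccuracyCurveResults:
    """Estimates and diagnostics of one accuracy-curve fit."""

    family: str
    me_hat: float
    log_likelihood: float
    converged: bool
    n_scenarios: int
    w_hat: float | None = None
    z_hat: float | None = None
    model: object = field(default=None, repr=False)

    @property
    def llf(self) -> float:
        return self.log_likelihood

    @property
    def params(self) -> dict:
        out = {"me": self.me_hat}
        if self.w_hat is not None:
            out["w"] = self.w_hat
        if self.z_hat is not None:
            out["z"] = self.z_hat
        return out

    def spec(self, n_markers: float | None = None) -> AccuracyModelSpec:
        """Equation spec carrying the fitted parameters."""
        m = self.model
        return AccuracyModelSpec(
            family=self.family,
            me=self.me_hat,
            h2=m.h2,
            w=self.w_hat,
            z=self.z_hat,
            w_plateau=getattr(m, "w_plateau", 1.0),
            n_markers=n_markers if n_markers is not None else getattr(m, "n_markers", None),
            genome_length=getattr(m, "genome_length", 29.0),
        )

    def predict(self, n_train):
        """Expected accuracy at (an array of) training-set sizes."""
        return accuracy(self.spec(), n_train)

    def summary(self) -> str:
        lines = [
            "Accuracy curve fit (maximum likelihood)",
            "=" * 44,
            f"{'family':<22}{self.family:>22}",
            f"{'scenarios':<22}{self.n_scenarios:>22d}",
            f"{'Me (chrom. segments)':<22}{self.me_hat:>22.1f}",
        ]
        if self.w_hat is not None:
            lines.append(f"{'w (max accuracy)':<22}{self.w_hat:>22.3f}")
            lines.append(f"{'% variance captured':<22}{100 * self.w_hat ** 2:>22.1f}")
        if self.z_hat is not None:
            lines.append(f"{'z (density slope)':<22}{self.z_hat:>22.4f}")
        lines.append(f"{'ln(likelihood)':<22}{self.log_likelihood:>22.2f}")
        lines.append(f"{'converged':<22}{str(self.converged):>22}")
        return "\n".join(lines)


FitResult = AccuracyCurveResults


class AccuracyCurveModel:
    """Deterministic accuracy equation fitted to one scenario table.

    Parameters
    ----------
    table
        Cross-validation scenarios (one per k) with replicate accuracies.
    family
        One of D1, G1, G2 (Me fitted) or D2, G3 (Me and w fitted).
    h2
        Reliability of the quasi-phenotype, fixed by the data design.
    n_markers
        Marker count of the panel; required by G1/G2.
    """

    def __init__(self, table, family, h2, n_markers=None, genome_length=29.0):
        if family not in ("D1", "G1", "G2", "D2", "G3"):
            raise SpecificationError(f"unsupported family {family!r}")
        self.table = table
        self.family = family
        self.h2 = float(h2)
        self.n_markers = n_markers
        self.genome_length = float(genome_length)
        self.n_params = 2 if family in ("D2", "G3") else 1
        if len(table) < self.n_params + 1:
            raise InputError(
                f"need at least {self.n_params + 1} scenarios to fit {family}"
            )
        _scenario_arrays(table)  # validate variances up front

    def _spec(self, me, w=None) -> AccuracyModelSpec:
        return AccuracyModelSpec(
            family=self.family,
            me=me,
            h2=self.h2,
            w=w,
            n_markers=self.n_markers,
            genome_length=self.genome_length,
        )

    def loglike(self, params) -> float:
        params = np.atleast_1d(np.asarray(params, dtype=float))
        me = params[0]
        w = params[1] if self.n_params == 2 else None
        return log_likelihood(self.table, self._spec(me, w))

    def fit(self) -> AccuracyCurveResults:
        if self.n_params == 1:
            return self._fit_1d()
        return self._fit_2d()

    def _fit_1d(self) -> AccuracyCurveResults:
        def neg(log_me):
            return -self.loglike([np.exp(log_me)])

        res = minimize_scalar(
            neg,
            bounds=(np.log(ME_BOUNDS[0]), np.log(ME_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-10},
        )
        me = float(np.exp(res.x))
        return AccuracyCurveResults(
            family=self.family,
            me_hat=me,
            log_likelihood=self.loglike([me]),
            converged=bool(res.success),
            n_scenarios=len(self.table),
            model=self,
        )

    def _fit_2d(self, n_starts=5) -> AccuracyCurveResults:
        # coarse grid to seed the quasi-Newton polish: the (Me, w) likelihood
        # surface is a curved ridge and a single start often stalls on it
        log_me_grid = np.linspace(np.log(ME_BOUNDS[0]), np.log(ME_BOUNDS[1]), 40)
        w_grid = np.linspace(W_BOUNDS[0], W_BOUNDS[1], 25)
        scores = np.array(
            [[-self.loglike([np.exp(lm), w]) for w in w_grid] for lm in log_me_grid]
        )
        order = np.dstack(np.unravel_index(np.argsort(scores, axis=None), scores.shape))[0]
        best = None
        for i, j in order[:n_starts]:
            res = minimize(
                lambda p: -self.loglike([np.exp(p[0]), p[1]]),
                x0=[log_me_grid[i], w_grid[j]],
                method="L-BFGS-B",
                bounds=[(np.log(ME_BOUNDS[0]), np.log(ME_BOUNDS[1])), W_BOUNDS],
            )
            if best is None or res.fun < best.fun:
                best = res
        me, w = float(np.exp(best.x[0])), float(best.x[1])
        return AccuracyCurveResults(
            family=self.family,
            me_hat=me,
            w_hat=w,
            log_likelihood=self.loglike([me, w]),
            converged=bool(best.success),
            n_scenarios=len(self.table),
            model=self,
        )


class DensityAccuracyModel:
    """Global (Me, z) fit pooling scenario tables of several marker panels.

    The expected accuracy uses D2 with the density law w = 1 - z/ln(M/L)
    substituted for w, so one parameter pair describes every panel density
    at once.  At least two distinct densities are required, otherwise z is
    not identifiable.
    """

    def __init__(self, tables, h2, genome_length=29.0, w_plateau=1.0):
        tables = [(float(m), t) for m, t in tables]
        if len({m for m, _ in tables}) < 2:
            raise InputError(
                "global density fit needs tables from at least two distinct "
                "marker counts (z is unidentifiable from a single density)"
            )
        for m, t in tables:
            if m / genome_length <= 1:
                raise SpecificationError("marker density M/L must exceed 1")
            _scenario_arrays(t)
        self.tables = tables
        self.h2 = float(h2)
        self.genome_length = float(genome_length)
        self.w_plateau = float(w_plateau)
        self.family = "D2-density"

    def loglike(self, params) -> float:
        me, z = float(params[0]), float(params[1])
        ll = 0.0
        for m, table in self.tables:
            spec = AccuracyModelSpec(
                family="D2-density",
                me=me,
                h2=self.h2,
                z=z,
                w_plateau=self.w_plateau,
                n_markers=m,
                genome_length=self.genome_length,
            )
            ll += log_likelihood(table, spec)
        return ll

    def fit(self, n_starts=5) -> AccuracyCurveResults:
        log_me_grid = np.linspace(np.log(ME_BOUNDS[0]), np.log(ME_BOUNDS[1]), 30)
        z_grid = np.linspace(Z_BOUNDS[0], min(Z_BOUNDS[1], 3.0), 16)
        scores = np.array(
            [[-self.loglike([np.exp(lm), z]) for z in z_grid] for lm in log_me_grid]
        )
        order = np.dstack(np.unravel_index(np.argsort(scores, axis=None), scores.shape))[0]
        best = None
        for i, j in order[:n_starts]:
            res = minimize(
                lambda p: -self.loglike([np.exp(p[0]), p[1]]),
                x0=[log_me_grid[i], z_grid[j]],
                method="L-BFGS-B",
                bounds=[(np.log(ME_BOUNDS[0]), np.log(ME_BOUNDS[1])), Z_BOUNDS],
            )
            if best is None or res.fun < best.fun:
                best = res
        me, z = float(np.exp(best.x[0])), float(best.x[1])
        n_scen = sum(len(t) for _, t in self.tables)
        return AccuracyCurveResults(
            family="D2-density",
            me_hat=me,
            z_hat=z,
            log_likelihood=self.loglike([me, z]),
            converged=bool(best.success),
            n_scenarios=n_scen,
            model=self,
        )


def fit_me(table, family, h2, n_markers=None, genome_length=29.0) -> AccuracyCurveResults:
    """One-dimensional ML fit of Me under D1, G1 or G2."""
    if family not in ("D1", "G1", "G2"):
        raise SpecificationError("fit_me handles families D1, G1 and G2")
    return AccuracyCurveModel(table, family, h2, n_markers, genome_length).fit()


def fit_me_w(table, family, h2) -> AccuracyCurveResults:
    """Joint two-dimensional ML fit of (Me, w) under D2 or G3."""
    if family not in ("D2", "G3"):
        raise SpecificationError("fit_me_w handles families D2 and G3")
    return AccuracyCurveModel(table, family, h2).fit()


def fit_global_density(tables, h2, genome_length=29.0, w_plateau=1.0):
    """Global (Me, z) fit across panels; see :class:`DensityAccuracyModel`."""
    return DensityAccuracyModel(tables, h2, genome_length, w_plateau).fit()


@dataclass
class DensityRegressionResult:
    """OLS of w on the reciprocal log marker density, with optional plateau."""

    intercept: float
    slope: float
    r_squared: float
    points_used: list
    plateau_w: float | None = None
    plateau_points: list = field(default_factory=list)


def regress_w_density(
    points, genome_length: float = 29.0, plateau_detection: bool = False
) -> DensityRegressionResult:
    """Regress fitted w values on x = 1/ln(M/L) across marker counts.

    With ``plateau_detection``, the maximal high-density run of points whose
    successive w differ by less than 0.005 is treated as the constant region:
    it is excluded from the regression and its mean w reported as the
    plateau estimate.
    """
    pts = sorted(((float(m), float(w)) for m, w in points))
    if len({m for m, _ in pts}) != len(pts):
        raise InputError("marker counts must be distinct")
    plateau_pts, plateau_w = [], None
    linear = pts
    if plateau_detection and len(pts) >= 3:
        ws = [w for _, w in pts]
        start = len(pts) - 1
        while start > 0 and abs(ws[start] - ws[start - 1]) < PLATEAU_TOL:
            start -= 1
        if len(pts) - start >= 2:
            plateau_pts = pts[start:]
            plateau_w = float(np.mean([w for _, w in plateau_pts]))
            linear = pts[:start]
    if len(linear) < 3:
        raise InputError("need at least 3 non-plateau points for the regression")
    dens = np.array([m / genome_length for m, _ in linear])
    if np.any(dens <= 1):
        raise SpecificationError("marker density M/L must exceed 1")
    x = 1.0 / np.log(dens)
    if np.ptp(x) == 0:
        raise InputError("identical densities: regression is rank deficient")
    y = np.array([w for _, w in linear])
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    return DensityRegressionResult(
        intercept=float(ols.params[0]),
        slope=float(ols.params[1]),
        r_squared=float(ols.rsquared),
        points_used=[(m / genome_length, w) for m, w in linear],
        plateau_w=plateau_w,
        plateau_points=[(m / genome_length, w) for m, w in plateau_pts],
    )


def extrapolate(subset_table, family, h2, target_n, n_markers=None) -> float:
    """Fit an equation on CV scenarios from a reduced population, then predict
    the accuracy at a (possibly larger) training-set size."""
    if family in ("D2", "G3"):
        res = fit_me_w(subset_table, family, h2)
    else:
        res = fit_me(subset_table, family, h2, n_markers)
    return float(res.predict(float(target_n)))
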