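"""Systematic multi-level k-fold cross-validation of GBLUP accuracy.

For every k in the scheme, individuals are randomly partitioned into k
balanced folds; each fold is predicted from the remaining k-1 folds and the
realised accuracy

    r_hat = corr(GBV, EBV) / r(EBV, TBV)

is averaged over the k folds, yielding one replicate value.  Replicating the
partition (default 50 times) gives, per k, a sample of accuracies whose mean
and empirical variance feed the maximum-likelihood curve fit.  Variance
components are estimated once on the complete data per marker panel and
reused across all folds and replicates — re-estimating them inside folds
would be prohibitively costly and changes results only marginally for the
panel sizes of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import VarianceComponents, gblup_predict
from .relmat import GRM, GenotypeMatrix, InputError, vanraden_grm
from .simdata import QuasiPhenotypes

__all__ = [
    "CVScheme",
    "CVScenario",
    "CVScenarioTable",
    "assign_folds",
    "fold_accuracy",
    "run_cv",
    "normality_check",
]

DEFAULT_K_VALUES = (2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20)


class UndefinedCorrelationError(ValueError):
    """Correlation undefined because one of the vectors is constant."""


@dataclass
class CVScheme:
    """k-fold scenarios to run and how often to replicate each."""

    k_values: tuple = DEFAULT_K_VALUES
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self):
        self.k_values = tuple(int(k) for k in self.k_values)
        if any(k < 2 for k in self.k_values):
            raise InputError("every k must be >= 2")
        if self.n_replicates < 2:
            raise InputError("n_replicates must be >= 2")


@dataclass
class CVScenario:
    """One k-fold scenario: realised training size and replicate accuracies."""

    k: int
    n_train: int
    accuracies: np.ndarray

    def __post_init__(self):
        self.accuracies = np.asarray(self.accuracies, dtype=float)

    @property
    def n_replicates(self) -> int:
        return len(self.accuracies)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def empirical_variance(self) -> float:
        return float(self.accuracies.var(ddof=1))


@dataclass
class CVScenarioTable:
    """Collection of CV scenarios, one per k."""

    scenarios: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.scenarios)

    def __len__(self):
        return len(self.scenarios)

    @property
    def n_train(self) -> np.ndarray:
        return np.array([s.n_train for s in self.scenarios])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"k": s.k, "n_train": s.n_train, "replicate": j + 1, "accuracy": a}
            for s in self.scenarios
            for j, a in enumerate(s.accuracies)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CVScenarioTable":
        scenarios = []
        for (k, n_train), grp in df.groupby(["k", "n_train"], sort=True):
            scenarios.append(
                CVScenario(int(k), int(n_train), grp["accuracy"].to_numpy())
            )
        return cls(scenarios)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [s.k for s in self.scenarios],
                "n_train": [s.n_train for s in self.scenarios],
                "mean_accuracy": [s.mean_accuracy for s in self.scenarios],
                "std_error": [
                    s.accuracies.std(ddof=1) / np.sqrt(s.n_replicates)
                    for s in self.scenarios
                ],
                "empirical_variance": [s.empirical_variance for s in self.scenarios],
            }
        )


def training_size(n: int, k: int) -> int:
    """Mean realised training-set size of balanced k-fold CV, floor(n(k-1)/k)."""
    return (n * (k - 1)) // k


def assign_folds(n: int, k: int, seed=None) -> np.ndarray:
    """Random balanced fold assignment; fold sizes differ by at most one."""
    if k > n:
        raise InputError(f"k={k} exceeds number of individuals n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.repeat(np.arange(k), sizes)
    return folds[rng.permutation(n)]


def fold_accuracy(gbv, ebv, ebv_accuracy: float) -> float:
    """Accuracy r(GBV, TBV) estimated as corr(GBV, EBV) / r(EBV, TBV).

    Quasi-phenotypes are EBVs whose own accuracy dilutes the observable
    correlation; dividing by it recovers the accuracy against the true
    breeding value.  Values above 1 can occur in small samples and are not
    clipped.
    """
    gbv = np.asarray(gbv, float)
    ebv = np.asarray(ebv, float)
    if len(gbv) != len(ebv) or len(gbv) < 3:
        raise InputError("need two equal-length vectors of length >= 3")
    if not 0 < ebv_accuracy <= 1:
        raise InputError("ebv_accuracy must be in (0, 1]")
    if gbv.std() == 0 or ebv.std() == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return float(np.corrcoef(gbv, ebv)[0, 1]) / ebv_accuracy


def run_cv(
    genotypes: GenotypeMatrix | None,
    phenotypes: QuasiPhenotypes,
    scheme: CVScheme,
    vc: VarianceComponents,
    grm: GRM | None = None,
) -> CVScenarioTable:
    """Run every k-fold scenario of the scheme and collect replicate accuracies.

    A precomputed ``grm`` may be supplied to avoid rebuilding it; otherwise
    it is built from ``genotypes`` with observed allele frequencies.
    """
    if grm is None:
        if genotypes is None:
            raise InputError("either genotypes or a precomputed GRM is required")
        grm = vanraden_grm(genotypes)
    n = grm.n_individuals
    if phenotypes.n != n:
        raise InputError("phenotype count must match GRM dimension")
    y = phenotypes.ebv
    acc = phenotypes.ebv_accuracy

    scenarios = []
    for k in scheme.k_values:
        rng = np.random.default_rng(np.random.SeedSequence([scheme.seed, k]))
        reps = np.empty(scheme.n_replicates)
        for rep in range(scheme.n_replicates):
            folds = assign_folds(n, k, rng)
            fold_accs = np.empty(k)
            for f in range(k):
                val = np.nonzero(folds == f)[0]
                train = np.nonzero(folds != f)[0]
                fit = gblup_predict(y[train], grm, train, val, vc)
                fold_accs[f] = fold_accuracy(fit.gbv, y[val], float(acc[val].mean()))
            reps[rep] = fold_accs.mean()
        scenarios.append(CVScenario(k, training_size(n, k), reps))
    return CVScenarioTable(scenarios)


def normality_check(table: CVScenarioTable) -> pd.DataFrame:
    """Shapiro-Wilk p-value per scenario (QC only; never gates the fit)."""
    rows = []
    for s in table:
        if s.n_replicates < 3 or np.ptp(s.accuracies) == 0:
            p = np.nan  # constant or too-short sample: test undefined
        else:
            p = float(stats.shapiro(s.accuracies).pvalue)
        rows.append({"k": s.k, "n_train": s.n_train, "shapiro_p": p})
    return pd.DataFrame(rows)
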