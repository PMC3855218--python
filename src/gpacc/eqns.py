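"""Deterministic equations for the expected accuracy of genomic prediction.

Five equation families predict the average accuracy r(GBV, TBV) from the
training-set size N, the reliability h2 of the quasi-phenotype, the number
of independent chromosome segments Me, and — depending on the family — the
marker count M or the maximum achievable accuracy w:

    D1:  r = sqrt( N h2 / (N h2 + Me) )
    G1:  r = sqrt( b N h2 / (b N h2 + Me) ),        b = M / (M + Me)
    G2:  r = sqrt(b) * sqrt( b N h2 / (b N h2 + Me) )
    D2:  r = w * sqrt( N h2 / (N h2 + Me) )
    G3:  r = w * sqrt( w^2 N h2 / (w^2 N h2 + Me) )

D1 ignores the finiteness of the marker panel and tends to 1 as N grows.
G1/G2 discount through Goddard's factor b.  D2/G3 instead carry an
empirically fitted weight w, interpretable as the accuracy reachable with
an infinite training set: w^2 is the fraction of genetic variance tagged by
the panel.  The D2-density family replaces w with the log-density law

    w(rho) = min( w_plateau, 1 - z / ln(rho) ),     rho = M / L,

with L the genome length in Morgan, so a single (Me, z) pair describes all
panel densities of one population at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AccuracyModelSpec",
    "b_factor",
    "accuracy",
    "required_n",
    "variance_captured",
    "w_of_density",
    "FAMILIES",
]

FAMILIES = ("D1", "G1", "G2", "D2", "G3", "D2-density")


class SpecificationError(ValueError):
    """Equation family given without the parameters it requires."""


@dataclass
class AccuracyModelSpec:
    """A fully parameterised accuracy equation.

    Only the parameters that the chosen family uses need to be supplied:
    ``me`` and ``h2`` always; ``n_markers`` for G1/G2 and the density law;
    ``w`` for D2/G3; ``z``/``w_plateau``/``genome_length`` for D2-density.
    """

    family: str
    me: float
    h2: float
    w: float | None = None
    z: float | None = None
    w_plateau: float = 1.0
    n_markers: float | None = None
    genome_length: float = 29.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SpecificationError(f"unknown equation family {self.family!r}")
        if not self.me > 0:
            raise SpecificationError("me must be positive")
        if not 0 < self.h2 <= 1:
            raise SpecificationError("h2 must be in (0, 1]")
        if self.family in ("G1", "G2") and not (self.n_markers and self.n_markers > 0):
            raise SpecificationError(f"{self.family} requires n_markers")
        if self.family in ("D2", "G3"):
            if self.w is None or not 0 < self.w <= 1:
                raise SpecificationError(f"{self.family} requires w in (0, 1]")
        if self.family == "D2-density":
            if self.z is None or self.z < 0:
                raise SpecificationError("D2-density requires z >= 0")
            if not (self.n_markers and self.n_markers > 0):
                raise SpecificationError("D2-density requires n_markers")
            if not 0 < self.w_plateau <= 1:
                raise SpecificationError("w_plateau must be in (0, 1]")
            if self.genome_length <= 0:
                raise SpecificationError("genome_length must be positive")


def b_factor(n_markers: float, me: float) -> float:
    """Goddard's factor b = M / (M + Me), the theoretical fraction of genetic
    variance explainable by M markers."""
    if n_markers <= 0 or me <= 0:
        raise SpecificationError("n_markers and me must be positive")
    return n_markers / (n_markers + me)


def w_of_density(
    z: float, w_plateau: float, n_markers: float, genome_length: float
) -> float:
    """Maximum achievable accuracy as a function of marker density.

    ``w = 1 - z / ln(rho)`` with ``rho = M / L`` SNPs per Morgan, capped at
    ``w_plateau``; strictly increasing in the density below the plateau.
    """
    rho = n_markers / genome_length
    if rho <= 1:
        raise SpecificationError("marker density M/L must exceed 1 (ln rho > 0)")
    return min(w_plateau, 1.0 - z / np.log(rho))


def _d1_core(n, h2, me):
    nh = np.asarray(n, dtype=float) * h2
    return np.sqrt(nh / (nh + me))


def accuracy(spec: AccuracyModelSpec, n_train) -> float | np.ndarray:
    """Expected accuracy of the chosen family at training-set size ``n_train``.

    Accepts a scalar or an array of sizes; every family is strictly
    increasing in ``n_train`` and ``h2`` and decreasing in ``me``.
    """
    n = np.asarray(n_train, dtype=float)
    if np.any(n <= 0):
        raise SpecificationError("n_train must be positive")
    fam = spec.family
    if fam == "D1":
        out = _d1_core(n, spec.h2, spec.me)
    elif fam in ("G1", "G2"):
        b = b_factor(spec.n_markers, spec.me)
        out = _d1_core(n, b * spec.h2, spec.me)
        if fam == "G2":
            out = np.sqrt(b) * out
    elif fam == "D2":
        out = spec.w * _d1_core(n, spec.h2, spec.me)
    elif fam == "G3":
        out = spec.w * _d1_core(n, spec.w ** 2 * spec.h2, spec.me)
    else:  # D2-density
        w = w_of_density(spec.z, spec.w_plateau, spec.n_markers, spec.genome_length)
        out = w * _d1_core(n, spec.h2, spec.me)
    return float(out) if np.isscalar(n_train) else out


def required_n(spec: AccuracyModelSpec, target_fraction_of_max: float) -> float:
    """Training-set size at which D1/D2 reach a fraction f of their asymptote.

    Inverting r = w * sqrt(N h2 / (N h2 + Me)) at r = f * w gives
    ``N = Me f^2 / ((1 - f^2) h2)``; w cancels, so D1 and D2 coincide.
    """
    f = target_fraction_of_max
    if not 0 < f < 1:
        raise SpecificationError("target fraction must be in (0, 1)")
    if spec.family not in ("D1", "D2"):
        raise SpecificationError("required_n is defined for families D1 and D2")
    return spec.me * f ** 2 / ((1.0 - f ** 2) * spec.h2)


def variance_captured(w: float) -> float:
    """Percent of genetic variance tagged by the panel, 100 * w^2."""
    if not 0 < w <= 1:
        raise SpecificationError("w must be in (0, 1]")
    return 100.0 * w ** 2
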