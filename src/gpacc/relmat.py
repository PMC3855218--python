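"""Genotype containers, marker filtering/thinning and the VanRaden genomic
relationship matrix (GRM).

The GRM used throughout is VanRaden's method 1,

    G = (X - 2P)(X - 2P)' / (2 * sum_j p_j (1 - p_j)),

where ``X`` is the individuals x markers matrix of additive genotype codes
(0/1/2 copies of the reference allele), ``p_j`` the observed allele frequency
of marker ``j`` and ``P`` the row-replicated frequency vector.  Frequencies
are always the observed ones of the full individual set for the marker panel
at hand, and are recomputed after any filtering or thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "allele_frequencies",
    "filter_markers",
    "thin_markers",
    "vanraden_grm",
]


class InputError(ValueError):
    """Invalid or inconsistent user input."""


class DegeneratePanelError(ValueError):
    """Marker panel carries no polymorphism (zero GRM scaling constant)."""


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes for a set of individuals.

    Parameters
    ----------
    values
        Integer matrix, individuals x markers, entries in {0, 1, 2}.
        Missing genotypes are not supported; data are expected to be
        imputed upstream.
    individual_ids, marker_ids
        Identifier lists matching the matrix dimensions.
    """

    values: np.ndarray
    individual_ids: list = field(default=None)
    marker_ids: list = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InputError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i + 1}" for i in range(n)]
        if self.marker_ids is None:
            self.marker_ids = [f"snp{j + 1}" for j in range(m)]
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise InputError("id lists inconsistent with matrix dimensions")
        if np.isnan(self.values.astype(float)).any():
            raise InputError("missing genotypes are not supported")
        uniq = np.unique(self.values)
        if not np.isin(uniq, [0, 1, 2]).all():
            raise InputError("genotypes must be coded 0/1/2")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[:, idx],
            list(self.individual_ids),
            [self.marker_ids[j] for j in idx],
        )

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx, :],
            [self.individual_ids[i] for i in idx],
            list(self.marker_ids),
        )


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling metadata."""

    matrix: np.ndarray
    n_markers_used: int
    scaling_constant: float
    individual_ids: list = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise InputError("GRM must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise InputError("GRM must be symmetric (tolerance 1e-10)")
        if self.scaling_constant <= 0:
            raise DegeneratePanelError("GRM scaling constant must be positive")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i + 1}" for i in range(self.matrix.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Observed allele frequency per marker, ``p_j = sum_i x_ij / (2n)``."""
    if genotypes.n_individuals == 0 or genotypes.n_markers == 0:
        raise InputError("empty genotype matrix")
    return genotypes.values.sum(axis=0) / (2.0 * genotypes.n_individuals)


def filter_markers(genotypes: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Drop markers whose minor allele frequency is below ``maf_min``.

    Retains exactly the markers with ``min(p, 1 - p) >= maf_min``; the
    original marker order is preserved.  May return an empty panel.
    """
    if not 0 <= maf_min <= 0.5:
        raise InputError("maf_min must be in [0, 0.5]")
    p = allele_frequencies(genotypes)
    maf = np.minimum(p, 1.0 - p)
    keep = np.nonzero(maf >= maf_min)[0]
    return genotypes.subset_markers(keep)


def thin_markers(
    genotypes: GenotypeMatrix,
    scheme: str = "random",
    target_count: int | None = None,
    step_exponent: int | None = None,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Reduce marker density, either at random or systematically.

    ``scheme='random'`` draws ``target_count`` markers uniformly without
    replacement (order preserved, deterministic under ``seed``), emulating
    random down-sampling of a SNP chip.  ``scheme='systematic'`` keeps every
    ``2**step_exponent``-th marker starting from the first, the scheme used
    for dense imputed panels.
    """
    m = genotypes.n_markers
    if scheme == "random":
        if target_count is None:
            raise InputError("random thinning requires target_count")
        if target_count > m:
            raise InputError(f"target_count {target_count} exceeds panel size {m}")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(m, size=target_count, replace=False))
        return genotypes.subset_markers(idx)
    if scheme == "systematic":
        if step_exponent is None:
            raise InputError("systematic thinning requires step_exponent")
        if step_exponent < 0:
            raise InputError("step_exponent must be >= 0")
        idx = np.arange(0, m, 2 ** step_exponent)
        return genotypes.subset_markers(idx)
    raise InputError(f"unknown thinning scheme {scheme!r}")


def vanraden_grm(
    genotypes: GenotypeMatrix, frequencies: np.ndarray | None = None
) -> GRM:
    """VanRaden method-1 genomic relationship matrix.

    Frequencies default to the observed ones of ``genotypes``; passing them
    explicitly allows building G for an individual subset with frequencies
    from the complete data set.
    """
    if frequencies is None:
        frequencies = allele_frequencies(genotypes)
    p = np.asarray(frequencies, dtype=float)
    if p.shape != (genotypes.n_markers,):
        raise InputError("frequency vector length must equal marker count")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise DegeneratePanelError(
            "all markers monomorphic: 2*sum p(1-p) = 0, cannot scale GRM"
        )
    z = genotypes.values.astype(float) - 2.0 * p
    g = (z @ z.T) / denom
    g = 0.5 * (g + g.T)  # enforce exact symmetry against BLAS round-off
    return GRM(g, genotypes.n_markers, denom, list(genotypes.individual_ids))
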