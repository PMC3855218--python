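"""Synthetic populations for genomic-prediction accuracy studies.

The generator emulates the statistical structure that the accuracy-modelling
machinery assumes of a progeny-tested dairy cattle population:

* biallelic SNPs with allele frequencies roughly uniform over the permitted
  range (as on commercial chips), organised in mutually independent LD
  blocks with exchangeable positive within-block correlation;
* a true breeding value (TBV) that is the sum of additive QTL effects, of
  which only a fraction ``w^2`` (``tagged_variance_fraction``) sits on loci
  present in the genotyped marker panel — the remainder lives on hidden,
  untyped loci and is therefore invisible to any marker-based predictor;
* an EBV-like quasi-phenotype ``y`` with a prescribed accuracy
  ``r(y, TBV) = ebv_accuracy``, standing in for highly reliable
  progeny-test breeding values.

Within-block LD is generated with a Gaussian copula: each haplotype draws a
shared block-level latent normal plus a marker-specific one, and the allele
indicator thresholds the mixture at the frequency quantile.  Blocks are
independent, which makes marker thinning across blocks meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .relmat import GenotypeMatrix, InputError

__all__ = [
    "PopulationConfig",
    "SyntheticTruth",
    "QuasiPhenotypes",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_population",
]


class ConfigurationError(ValueError):
    """Invalid population configuration."""


@dataclass
class QuasiPhenotypes:
    """EBV-like response values with their own accuracy r(EBV, TBV)."""

    ids: list
    ebv: np.ndarray
    ebv_accuracy: np.ndarray  # per animal; scalar input is broadcast

    def __post_init__(self):
        self.ebv = np.asarray(self.ebv, dtype=float)
        acc = np.asarray(self.ebv_accuracy, dtype=float)
        if acc.ndim == 0:
            acc = np.full(self.ebv.shape, float(acc))
        self.ebv_accuracy = acc
        if len(self.ids) != len(self.ebv) or len(self.ebv) != len(self.ebv_accuracy):
            raise InputError("phenotype fields must have equal length")

    @property
    def n(self) -> int:
        return len(self.ebv)


@dataclass
class PopulationConfig:
    """Study-design parameters of one synthetic population.

    ``tagged_variance_fraction`` is the share of genetic variance carried by
    QTL inside the marker panel, i.e. the squared maximum achievable
    accuracy ``w^2``.  ``ebv_accuracy`` is the accuracy of the
    quasi-phenotype, r(EBV, TBV); its square plays the role of the
    heritability in the deterministic accuracy equations and is exposed as
    ``heritability_quasi``.
    """

    n_individuals: int = 1000
    n_markers: int = 2000
    n_qtl: int = 200
    tagged_variance_fraction: float = 0.766
    ebv_accuracy: float = 0.945
    heritability_quasi: float | None = None
    ld_block_length: int = 10
    ld_correlation: float = 0.99
    maf_floor: float = 0.05
    genome_length_morgan: float = 29.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ConfigurationError("population dimensions must be positive")
        if self.n_qtl < 1:
            raise ConfigurationError("n_qtl must be >= 1")
        if not 0 < self.tagged_variance_fraction <= 1:
            raise ConfigurationError("tagged_variance_fraction must be in (0, 1]")
        if not 0 < self.ebv_accuracy <= 1:
            raise ConfigurationError("ebv_accuracy must be in (0, 1]")
        if self.heritability_quasi is None:
            self.heritability_quasi = self.ebv_accuracy ** 2
        if not 0 < self.heritability_quasi <= 1:
            raise ConfigurationError("heritability_quasi must be in (0, 1]")
        if self.ld_block_length < 1:
            raise ConfigurationError("ld_block_length must be >= 1")
        if not 0 <= self.ld_correlation < 1:
            raise ConfigurationError("ld_correlation must be in [0, 1)")
        if not 0 < self.maf_floor < 0.5:
            raise ConfigurationError("maf_floor must be in (0, 0.5)")
        if self.genome_length_morgan <= 0:
            raise ConfigurationError("genome_length_morgan must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated trait.

    ``qtl_positions`` indexes all QTL on a conceptual extended locus array:
    typed QTL are marker column indices in ``[0, n_markers)``, untyped QTL
    occupy indices ``>= n_markers`` and never appear in the genotype matrix.
    """

    tbv: np.ndarray
    qtl_positions: np.ndarray
    untyped_qtl: np.ndarray
    typed_component: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if not np.isin(self.untyped_qtl, self.qtl_positions).all():
            raise InputError("untyped_qtl must be a subset of qtl_positions")


def _simulate_block_genotypes(rng, n, freqs, rho):
    """0/1/2 genotypes for one LD block via a Gaussian-copula haplotype model."""
    m = len(freqs)
    thresh = norm.ppf(freqs)
    geno = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        shared = rng.standard_normal((n, 1))
        specific = rng.standard_normal((n, m))
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * specific
        geno += (latent < thresh).astype(np.int8)
    return geno


def _draw_genotypes(rng, n, m, config):
    # one latent haplotype frequency per LD block, shared by its markers:
    # a block then behaves as a single chromosome segment, the unit the
    # accuracy equations count
    blocks = []
    for start in range(0, m, config.ld_block_length):
        stop = min(start + config.ld_block_length, m)
        freq = rng.uniform(config.maf_floor, 1.0 - config.maf_floor)
        blocks.append(
            _simulate_block_genotypes(
                rng, n, np.full(stop - start, freq), config.ld_correlation
            )
        )
    return np.concatenate(blocks, axis=1)


def simulate_genotypes(config: PopulationConfig) -> GenotypeMatrix:
    """Simulate the genotyped marker panel (LD-blocked, 0/1/2 coded).

    Deterministic under ``config.seed``; markers within a block are
    positively correlated, blocks are mutually independent.
    """
    rng = np.random.default_rng(config.seed)
    values = _draw_genotypes(rng, config.n_individuals, config.n_markers, config)
    return GenotypeMatrix(values)


def simulate_trait(
    genotypes: GenotypeMatrix, config: PopulationConfig
) -> tuple[SyntheticTruth, QuasiPhenotypes]:
    """Simulate TBV and quasi-phenotypes on top of a simulated panel.

    QTL effects are drawn i.i.d. normal.  The typed genetic component (QTL
    on panel markers) and the untyped component (hidden loci, simulated
    independently of the panel) are rescaled so that their empirical
    variance shares are exactly ``tagged_variance_fraction`` and its
    complement; the TBV is then standardised to unit sample variance.  The
    quasi-phenotype is ``y = r * TBV + sqrt(1 - r^2) * eps`` with
    ``r = ebv_accuracy``, so that corr(y, TBV) converges to ``r``.
    """
    w2 = config.tagged_variance_fraction
    n, m = genotypes.n_individuals, genotypes.n_markers
    # independent stream from the genotype draw, still seed-determined
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    n_untyped = 0 if w2 >= 1.0 else max(1, round(config.n_qtl * (1.0 - w2)))
    n_typed = max(1, config.n_qtl - n_untyped)

    typed_pos = np.sort(rng.choice(m, size=min(n_typed, m), replace=False))
    typed_eff = rng.standard_normal(len(typed_pos))
    typed_part = genotypes.values[:, typed_pos].astype(float) @ typed_eff

    if n_untyped > 0:
        hidden_freqs = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, n_untyped)
        hidden = rng.binomial(2, hidden_freqs, size=(n, n_untyped)).astype(float)
        untyped_eff = rng.standard_normal(n_untyped)
        untyped_part = hidden @ untyped_eff
    else:
        untyped_part = np.zeros(n)

    def _std(v):
        s = v.std(ddof=1)
        if s == 0:
            raise ConfigurationError("degenerate genetic component (zero variance)")
        return (v - v.mean()) / s

    tbv = np.sqrt(w2) * _std(typed_part)
    typed_component = tbv.copy()
    if n_untyped > 0:
        tbv = tbv + np.sqrt(1.0 - w2) * _std(untyped_part)
    tbv_std = _std(tbv)

    r = config.ebv_accuracy
    if r >= 1.0:
        y = tbv_std.copy()
    else:
        y = r * tbv_std + np.sqrt(1.0 - r ** 2) * rng.standard_normal(n)

    untyped_pos = m + np.arange(n_untyped)
    truth = SyntheticTruth(
        tbv=tbv_std,
        qtl_positions=np.concatenate([typed_pos, untyped_pos]),
        untyped_qtl=untyped_pos,
        typed_component=typed_component,
    )
    phenos = QuasiPhenotypes(list(genotypes.individual_ids), y, r)
    return truth, phenos


def simulate_population(
    config: PopulationConfig,
) -> tuple[GenotypeMatrix, SyntheticTruth, QuasiPhenotypes]:
    """Convenience wrapper: genotypes plus trait in one call."""
    genotypes = simulate_genotypes(config)
    truth, phenos = simulate_trait(genotypes, config)
    return genotypes, truth, phenos
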