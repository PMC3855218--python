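"""Shared fixtures.  The expensive synthetic worlds are session-scoped and
shared across test modules; their sizes are the package's reference study
conditions (see docs/methods.md)."""

import numpy as np
import pytest

import gpacc as gp


@pytest.fixture(scope="session")
def big_world():
    """Reference synthetic world: n=2000, M=5000, tagged variance 0.75.

    Returns the population plus a cross-validated scenario table
    (k = 2, 3, 5, 10, 20; 3 replicates) built with variance components
    estimated once on the complete data.
    """
    cfg = gp.PopulationConfig(
        n_individuals=2000,
        n_markers=5000,
        n_qtl=300,
        tagged_variance_fraction=0.75,
        ebv_accuracy=0.95,
        seed=1,
    )
    geno, truth, pheno = gp.simulate_population(cfg)
    grm = gp.vanraden_grm(geno)
    vc = gp.reml_estimate(pheno.ebv, grm)
    scheme = gp.CVScheme(k_values=(2, 3, 5, 10, 20), n_replicates=3, seed=1)
    table = gp.run_cv(None, pheno, scheme, vc, grm=grm)
    return {
        "config": cfg,
        "genotypes": geno,
        "truth": truth,
        "phenotypes": pheno,
        "grm": grm,
        "vc": vc,
        "table": table,
        "h2": cfg.ebv_accuracy ** 2,
    }


@pytest.fixture(scope="session")
def small_world():
    """Cheap population for structural tests: n=300, M=600."""
    cfg = gp.PopulationConfig(
        n_individuals=300,
        n_markers=600,
        n_qtl=100,
        tagged_variance_fraction=0.766,
        ebv_accuracy=0.945,
        seed=42,
    )
    geno, truth, pheno = gp.simulate_population(cfg)
    grm = gp.vanraden_grm(geno)
    vc = gp.reml_estimate(pheno.ebv, grm)
    return {
        "config": cfg,
        "genotypes": geno,
        "truth": truth,
        "phenotypes": pheno,
        "grm": grm,
        "vc": vc,
    }


def make_table(n_train_values, mean_fn, noise=1e-4, n_reps=4, seed=0):
    """Scenario table with means from ``mean_fn`` and tiny replicate spread."""
    rng = np.random.default_rng(seed)
    scenarios = []
    for i, n_train in enumerate(n_train_values):
        mu = mean_fn(n_train)
        accs = mu + noise * rng.standard_normal(n_reps)
        scenarios.append(gp.CVScenario(k=i + 2, n_train=int(n_train), accuracies=accs))
    return gp.CVScenarioTable(scenarios)
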