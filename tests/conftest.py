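"""Shared fixtures: the demo cohort and one full pipeline run.

Everything is generated at test time from the simulator; session scope
keeps the expensive pieces (pipeline run, expression network) to one
computation for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from arnet.pipeline import RunConfig, run_pipeline
from arnet.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def demo_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def demo_genotypes(demo_config):
    return simulate_genotypes(demo_config)


@pytest.fixture(scope="session")
def demo_phenotype(demo_config, demo_genotypes):
    return simulate_phenotype(demo_genotypes, demo_config)


@pytest.fixture(scope="session")
def demo_expression(demo_config, demo_genotypes):
    return simulate_expression(demo_genotypes, demo_config)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One complete pipeline run on the default demo configuration."""
    out = tmp_path_factory.mktemp("demo_run")
    return run_pipeline(RunConfig(), out), out


@pytest.fixture(scope="session")
def randomized_control_nonsig_count(demo_run):
    """Of 20 values-randomized replicates, how many leave the planted disease
    module non-significant (q > 0.05, or not even detected/tested)."""
    from arnet import coexpression as cx
    from arnet import esnp as esnp_mod
    from arnet import integrate

    results, _ = demo_run
    geno = results["genotypes"]
    expr = results["expr"]
    truth = results["truth"]
    meta = results["meta"]
    processed = cx.preprocess_expression(expr, log2=False)
    pairs = esnp_mod.cis_pairs(geno.snp_map, expr.annotated())
    disease_genes = truth.planted_module_labels.index[
        truth.planted_module_labels == truth.disease_module_id
    ]

    nonsig = 0
    for rep in range(20):
        rnd = cx.randomize(processed, "values", seed=1000 + rep)
        beta, _ = cx.pick_soft_threshold(rnd)
        modules = cx.detect_modules(cx.compute_tom(rnd, beta=beta))
        q_disease = 1.0
        if modules.modules:
            called = esnp_mod.call_esnps(esnp_mod.esnp_scan(geno, rnd, pairs))
            enrich = integrate.ar_esnp_module_enrichment(called, meta, modules)
            name = modules.labels.loc[disease_genes].mode()[0]
            hit = enrich[enrich["module"] == name]
            if len(hit):
                q_disease = float(hit["q"].iloc[0])
        nonsig += q_disease > 0.05
    return nonsig


def small_module_assignment(labels: dict[str, str]):
    """Build a ModuleAssignment by hand for unit tests of the integration."""
    from arnet.coexpression import ModuleAssignment

    ser = pd.Series(labels, name="module")
    sizes = ser.value_counts().astype(int)
    return ModuleAssignment(
        labels=ser,
        module_sizes=sizes,
        linkage_matrix=np.empty((0, 4)),
        gene_order=ser.index,
    )
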