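"""Shared fixtures: small seeded simulations reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icmskit import qc
from icmskit.io import SignatureSet
from icmskit.simulate import (
    SimConfig,
    build_gene_universe,
    simulate_sc_cohorts,
)


def signature_from_truth(genes: pd.DataFrame) -> SignatureSet:
    """The planted directional signature, read off the generator truth."""
    classes = {}
    for cls in ("i2", "i3"):
        classes[cls] = {
            "Up": set(genes.index[genes["marker_class"] == f"{cls}_Up"]),
            "Down": set(genes.index[genes["marker_class"] == f"{cls}_Down"]),
        }
    return SignatureSet(classes, provenance="generator truth")


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_cohorts=2,
        patients_per_cohort=4,
        cells_per_sample=400,
        n_genes=1500,
        low_quality_sample_frac=0.15,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_sc_cohorts(small_cfg, 11)


@pytest.fixture(scope="session")
def small_universe(small_cfg):
    return build_gene_universe(small_cfg, 11)


@pytest.fixture(scope="session")
def planted_signature(small_universe):
    return signature_from_truth(small_universe.genes)


@pytest.fixture(scope="session")
def noarm_cfg() -> SimConfig:
    """Planted directional markers are the only malignant expression effects
    (no arm dosage), so marker recovery and false inclusions are well defined."""
    return SimConfig(
        n_cohorts=2,
        patients_per_cohort=5,
        cells_per_sample=400,
        n_genes=1500,
        cnv_arms={"i2": {}, "i3": {}},
    )


@pytest.fixture(scope="session")
def noarm_sim(noarm_cfg):
    return simulate_sc_cohorts(noarm_cfg, 17)


@pytest.fixture(scope="session")
def noarm_universe(noarm_cfg):
    return build_gene_universe(noarm_cfg, 17)


@pytest.fixture(scope="session")
def noarm_epi(noarm_sim):
    adata, truth = noarm_sim
    filtered = qc.filter_empty_droplets(adata)
    keep = (
        (filtered.obs["true_cell_type"] == "epithelial")
        & ~filtered.obs["is_doublet"]
        & ~filtered.obs["is_low_quality"]
    )
    return qc.lognormalize(filtered[keep.to_numpy()].copy())


@pytest.fixture(scope="session")
def epi_lognorm(small_sim):
    """Log-normalized epithelial cells of the small simulation (truth-subset),
    restricted to non-degraded samples and singlets."""
    adata, truth = small_sim
    filtered = qc.filter_empty_droplets(adata)
    good_samples = set(truth.samples.index[~truth.samples["is_degraded"]])
    keep = (
        (filtered.obs["true_cell_type"] == "epithelial")
        & ~filtered.obs["is_doublet"]
        & ~filtered.obs["is_low_quality"]
        & filtered.obs["sample_id"].isin(good_samples)
    )
    return qc.lognormalize(filtered[keep.to_numpy()].copy())
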