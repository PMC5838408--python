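import pandas as pd
import pytest

from evsets.simulate import SimulationConfig, simulate_dataset


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A fast, fully featured simulation configuration for tests."""
    params = dict(
        n_genes=300,
        n_variants_total=30_000,
        planted_rare_genes=5,
        planted_common_genes=5,
        planted_disease_genes=5,
        enrichment_shift=8.0,
        gene_intensity_dispersion=0.5,
        network_mean_degree=8.0,
        population_max_variants=500,
        duplicate_edge_rows=25,
        self_loop_rows=5,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture()
def annotations_factory():
    """Build a gene annotation table from per-gene keyword overrides."""

    def build(genes, **columns):
        base = {
            "gene": list(genes),
            "essential_mgi": False,
            "essential_ogee": False,
            "pli": float("nan"),
            "dn_ds": float("nan"),
            "disease_annotated": False,
            "gwas_associated": False,
        }
        base.update(columns)
        return pd.DataFrame(base)

    return build
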