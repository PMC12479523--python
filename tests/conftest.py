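import numpy as np
import pytest

from pharmacobiome import GeneratorConfig, PlantedEffect, generate_cohort, generate_drug_catalog


def small_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A reduced cohort: quick to generate, still carries every planted
    structure kind (taxon effect, metabolite effect, confounded metabolite,
    one mimicry pair, two drug mechanism classes)."""
    defaults = dict(
        seed=seed,
        n_samples=40,
        n_genes=300,
        n_taxa=12,
        n_metabolites=8,
        n_drugs=6,
        n_drug_classes=2,
        planted_taxon_effects=[
            PlantedEffect("TAXON_001", 12, 1.5, +1),
            PlantedEffect("TAXON_001", 12, 1.5, -1),
            PlantedEffect("TAXON_002", 20, 1.5, +1),
            PlantedEffect("TAXON_002", 20, 1.5, -1),
        ],
        planted_metabolite_effects=[
            PlantedEffect("METAB_000", 12, 1.5, +1, confounded=True),
            PlantedEffect("METAB_000", 12, 1.5, -1, confounded=True),
            PlantedEffect("METAB_001", 12, 1.5, +1),
            PlantedEffect("METAB_001", 12, 1.5, -1),
        ],
        mimicry_pairs=[("TAXON_002", "DRUG_03", 0.5)],
        class_filler_size=15,
        drug_private_size=10,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config()
    expr, taxa, metab, cov, truth = generate_cohort(cfg)
    drugs, meta = generate_drug_catalog(cfg, truth)
    return dict(config=cfg, expression=expr, taxa=taxa, metabolites=metab,
                covariates=cov, truth=truth, drugs=drugs, drug_meta=meta)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
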