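import pandas as pd
import pytest

from gxe.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """30 accessions x 8 seasons, 12 SNPs (3 causal), complete."""
    cfg = SyntheticConfig(
        n_accessions=30, n_seasons=8, n_snps=12, n_causal_snps=3,
        missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0, seed=42,
    )
    phen, geno, meta, truth = generate_dataset(cfg)
    return cfg, phen, geno, meta, truth


@pytest.fixture(scope="session")
def paper_scale_complete():
    """257 accessions x 20 seasons without missingness (n = 5,140 records)."""
    cfg = SyntheticConfig(
        n_accessions=257, n_seasons=20,
        missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0, seed=7,
    )
    phen, geno, meta, truth = generate_dataset(cfg)
    return cfg, phen, geno, meta, truth


def long_phenotypes(wide: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Build a long-format phenotype table from {accession: {season: dhs}}."""
    rows = [
        {"accession_id": a, "season_id": s, "dhs": v}
        for a, seasons in wide.items()
        for s, v in seasons.items()
    ]
    return pd.DataFrame(rows)
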