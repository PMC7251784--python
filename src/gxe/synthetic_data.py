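"""Synthetic multi-season barley heading-date datasets.

Generates the three tables the analysis pipeline consumes — phenotypes,
genotypes, accession metadata — under an explicit additive
genotype-by-environment model, together with a :class:`TruthRecord` of every
sampled parameter so that downstream estimators can be checked for recovery.

Generative model for days to heading from sowing (DHS) of accession *i* in
season *j*::

    DHS_ij = mu + g_i + b_i * E_j + sum_k beta_k * x_ik + eps_ij

where ``E_j`` is a centered season effect (the environmental quality),
``b_i`` is the accession's environmental sensitivity (its Finlay-Wilkinson
slope, Normal(slope_mean, slope_sd^2) truncated at zero — negative
sensitivity to a "later-heading year" is biologically implausible),
``x_ik`` are accession-constant biallelic SNP codes, and
``eps_ij ~ Normal(0, noise_sd^2)``.  The accession-level genetic value
``g_i + sum_k beta_k x_ik`` is centered across accessions, so the grand
mean of the noiseless surface equals ``mu`` exactly.

Accession covariates (vernalization requirement, longitude) are generated
with a configurable correlation to ``b_i`` through a Gaussian copula; the
vernalization score is discretized to an ordinal 0-5 scale and growth habit
is set to winter in the upper half of that scale.

All randomness flows from a single seed through named substreams, so the
same config always yields bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import GenotypeTable

#: Eight flowering-pathway genes of the SNP panel (VRN2 is assayed via the
#: linked SNF2P marker).
PANEL_GENES = ("PPD-H1", "VRN1", "SNF2P", "VRN3", "ELF3", "HvLUX1", "CO1", "HvPHYC")

ORIGIN_REGIONS = {
    "East Asia": ["Japan", "China", "Korea"],
    "Southwest Asia": ["Iran", "Iraq", "Afghanistan"],
    "South Asia": ["India", "Nepal"],
    "Europe": ["Germany", "France", "Sweden", "UK"],
    "North Africa": ["Morocco", "Egypt"],
    "Ethiopia": ["Ethiopia"],
    "Turkey": ["Turkey"],
    "North America": ["USA", "Canada"],
    "South America": ["Peru", "Chile"],
    "Former USSR": ["Russia", "Ukraine"],
}

POPULATION_CLUSTERS = ("1", "2", "3", "4", "5", "6", "7", "Mixed")


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model; defaults mirror a 274-accession,
    20-season field trial of autumn-sown barley at one site."""

    n_accessions: int = 274
    n_seasons: int = 20
    grand_mean: float = 156.0       # days
    accession_effect_sd: float = 8.0  # days
    season_effect_sd: float = 4.5   # days
    slope_mean: float = 1.0
    slope_sd: float = 0.25
    noise_sd: float = 2.0           # days
    n_snps: int = 84
    n_causal_snps: int = 8
    snp_effect_sd: float = 2.5      # days per alternate allele
    snp_effect_fixed: float | None = None  # |beta| fixed, random sign
    covariate_slope_correlation: float = -0.4
    missing_phenotype_fraction: float = 0.0032
    missing_genotype_fraction: float = 0.0011
    seed: int = 0

    def __post_init__(self):
        if self.n_accessions < 2 or self.n_seasons < 2:
            raise ConfigError("need at least 2 accessions and 2 seasons")
        if self.n_causal_snps > self.n_snps:
            raise ConfigError("n_causal_snps cannot exceed n_snps")
        for name in (
            "accession_effect_sd", "season_effect_sd", "slope_sd",
            "noise_sd", "snp_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("missing_phenotype_fraction", "missing_genotype_fraction"):
            f = getattr(self, name)
            if not (0 <= f < 1):
                raise ConfigError(f"{name} must be in [0, 1)")
        if not (-1 <= self.covariate_slope_correlation <= 1):
            raise ConfigError("covariate_slope_correlation must be in [-1, 1]")


@dataclass
class TruthRecord:
    """Every parameter sampled during generation, keyed the same way as the
    emitted tables; the estimand register for recovery tests."""

    grand_mean: float
    season_effects: pd.Series        # season_id -> E_j, centered
    accession_effects: pd.Series     # accession_id -> g_i (post-centering)
    slopes: pd.Series                # accession_id -> b_i
    causal_snps: list[str]
    snp_effects: pd.Series           # causal snp_id -> beta_k
    allele_frequencies: pd.Series    # snp_id -> alternate allele frequency
    config: SyntheticConfig = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "grand_mean": self.grand_mean,
            "season_effects": self.season_effects.to_dict(),
            "accession_effects": self.accession_effects.to_dict(),
            "slopes": self.slopes.to_dict(),
            "causal_snps": list(self.causal_snps),
            "snp_effects": self.snp_effects.to_dict(),
            "allele_frequencies": self.allele_frequencies.to_dict(),
            "config": dataclasses.asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


_STREAMS = (
    "season", "slope", "genotype", "snp_effect", "accession",
    "covariate", "metadata", "noise", "missing_phenotype", "missing_genotype",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {n: np.random.default_rng(c) for n, c in zip(_STREAMS, children)}


def accession_ids(n: int) -> list[str]:
    return [f"SV{i:03d}" for i in range(1, n + 1)]


def season_ids(n: int) -> list[str]:
    return [f"{1997 + j}-{1998 + j}" for j in range(n)]


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GenotypeTable, pd.DataFrame, TruthRecord]:
    """Sample one complete dataset (no missingness; see :func:`inject_missing`).

    Returns
    -------
    (phenotypes, genotypes, metadata, truth)
        Long-format phenotype table, genotype table, metadata table and the
        truth record of all sampled parameters.
    """
    rng = _rngs(config.seed)
    acc = accession_ids(config.n_accessions)
    seas = season_ids(config.n_seasons)

    E = rng["season"].normal(0.0, config.season_effect_sd, config.n_seasons)
    E -= E.mean()

    if config.slope_sd > 0:
        a = (0.0 - config.slope_mean) / config.slope_sd
        b = stats.truncnorm.rvs(
            a, np.inf, loc=config.slope_mean, scale=config.slope_sd,
            size=config.n_accessions, random_state=rng["slope"],
        )
    else:
        b = np.full(config.n_accessions, config.slope_mean)

    maf = rng["genotype"].uniform(0.1, 0.5, config.n_snps)
    X = (rng["genotype"].random((config.n_accessions, config.n_snps)) < maf).astype(
        float
    )
    snp_ids, snp_ann = _snp_panel(config.n_snps)
    causal_idx = np.sort(
        rng["snp_effect"].choice(config.n_snps, config.n_causal_snps, replace=False)
    )
    if config.snp_effect_fixed is not None:
        signs = rng["snp_effect"].choice([-1.0, 1.0], config.n_causal_snps)
        beta = signs * config.snp_effect_fixed
    else:
        beta = rng["snp_effect"].normal(0.0, config.snp_effect_sd, config.n_causal_snps)
    snp_contrib = X[:, causal_idx] @ beta if config.n_causal_snps else np.zeros(
        config.n_accessions
    )

    g_raw = rng["accession"].normal(0.0, config.accession_effect_sd, config.n_accessions)
    # center the total accession-level genetic value so the noiseless grand
    # mean is exactly mu
    g = g_raw - (g_raw + snp_contrib).mean()

    metadata = _generate_metadata(config, acc, b, rng)

    accession_value = g + snp_contrib
    surface = (
        config.grand_mean
        + accession_value[:, None]
        + b[:, None] * E[None, :]
    )
    eps = rng["noise"].normal(0.0, config.noise_sd, surface.shape)
    dhs = surface + eps

    phenotypes = pd.DataFrame(
        {
            "accession_id": np.repeat(acc, config.n_seasons),
            "season_id": np.tile(seas, config.n_accessions),
            "dhs": dhs.ravel(),
        }
    )
    genotypes = GenotypeTable(
        calls=pd.DataFrame(X, index=pd.Index(acc, name="accession_id"), columns=snp_ids),
        snps=snp_ann,
    )
    truth = TruthRecord(
        grand_mean=config.grand_mean,
        season_effects=pd.Series(E, index=seas, name="E"),
        accession_effects=pd.Series(g, index=acc, name="g"),
        slopes=pd.Series(b, index=acc, name="b"),
        causal_snps=[snp_ids[k] for k in causal_idx],
        snp_effects=pd.Series(beta, index=[snp_ids[k] for k in causal_idx], name="beta"),
        allele_frequencies=pd.Series(maf, index=snp_ids, name="maf"),
        config=config,
    )
    return phenotypes, genotypes, metadata, truth


def _snp_panel(n_snps: int) -> tuple[list[str], pd.DataFrame]:
    """SNP ids and gene/position annotation, SNPs dealt round-robin over the
    eight-gene flowering panel with increasing within-gene positions."""
    genes = [PANEL_GENES[k % len(PANEL_GENES)] for k in range(n_snps)]
    counts: dict[str, int] = {}
    ids, rows = [], []
    for gene in genes:
        counts[gene] = counts.get(gene, 0) + 1
        pos = 29_000_000 + 1000 * counts[gene]
        snp_id = f"{gene}_{pos}"
        ids.append(snp_id)
        rows.append((snp_id, gene, pos))
    ann = pd.DataFrame(rows, columns=["snp_id", "gene", "position"]).set_index("snp_id")
    return ids, ann


def _generate_metadata(config, acc, b, rng) -> pd.DataFrame:
    rho = config.covariate_slope_correlation
    sd_b = b.std()
    zb = (b - b.mean()) / sd_b if sd_b > 0 else np.zeros_like(b)
    n = config.n_accessions
    resid = math.sqrt(max(0.0, 1.0 - rho * rho))
    zv = rho * zb + resid * rng["covariate"].normal(size=n)
    zl = rho * zb + resid * rng["covariate"].normal(size=n)
    vern = np.clip(np.floor(stats.norm.cdf(zv) * 6), 0, 5).astype(int)
    longitude = np.clip(60.0 + 35.0 * zl, -20.0, 145.0)

    regions = list(ORIGIN_REGIONS)
    region = rng["metadata"].choice(regions, n)
    country = [
        ORIGIN_REGIONS[r][rng["metadata"].integers(len(ORIGIN_REGIONS[r]))]
        for r in region
    ]
    latitude = rng["metadata"].uniform(5.0, 62.0, n)
    kernel_row = rng["metadata"].choice(["two", "six"], n)
    cluster = rng["metadata"].choice(POPULATION_CLUSTERS, n)
    return pd.DataFrame(
        {
            "accession_id": acc,
            "origin_region": region,
            "country": country,
            "latitude": latitude,
            "longitude": longitude,
            "vernalization": vern,
            "growth_habit": np.where(vern >= 3, "winter", "spring"),
            "kernel_row": kernel_row,
            "population_cluster": cluster,
        }
    )


def inject_missing(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GenotypeTable]:
    """Mask exactly ``floor(f * N)`` cells of each table uniformly at random.

    Phenotype cells are removed as records; genotype cells become NA.  The
    inputs are never modified.  Emulates the attrition from a full collection
    to the phenotype-complete and genotype-complete analysis sets.
    """
    rng = _rngs(config.seed)
    phen = phenotypes.reset_index(drop=True)
    n_mask = int(config.missing_phenotype_fraction * len(phen))
    if n_mask:
        drop = rng["missing_phenotype"].choice(len(phen), n_mask, replace=False)
        phen = phen.drop(index=drop)
    phen = phen.reset_index(drop=True)

    calls = genotypes.calls.copy()
    n_cells = calls.size
    n_mask_g = int(config.missing_genotype_fraction * n_cells)
    if n_mask_g:
        flat = rng["missing_genotype"].choice(n_cells, n_mask_g, replace=False)
        vals = calls.to_numpy(dtype=float, copy=True)
        vals.flat[flat] = np.nan
        calls = pd.DataFrame(vals, index=calls.index, columns=calls.columns)
    return phen, GenotypeTable(calls=calls, snps=genotypes.snps.copy())
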