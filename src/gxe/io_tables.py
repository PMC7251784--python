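"""Tabular I/O and completeness filtering for multi-season trial data.

Three tables drive every analysis in this package:

* the **phenotype table** — long-format records of (accession_id, season_id,
  dhs), where DHS is days to heading from sowing;
* the **accession metadata table** — one row per accession with origin,
  coordinates, vernalization requirement, growth habit and kernel row;
* the **genotype table** — biallelic SNP calls per accession (0 = reference,
  1 = alternate, NA = missing), each SNP annotated by gene and 1-based
  physical position.

Barley is a selfing species, so heterozygous calls are treated as data
errors by default (configurable coercion to missing).

Complete-case filters implement the two analysis sets of a typical
multi-season study: accessions phenotyped in every season, and the subset
of those additionally genotyped at every SNP of interest.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("accession_id", "season_id", "dhs")

METADATA_COLUMNS = (
    "accession_id",
    "origin_region",
    "country",
    "latitude",
    "longitude",
    "vernalization",
    "growth_habit",
    "kernel_row",
)


class FormatError(ValueError):
    """A table violates its format contract (duplicates, bad codes, ...)."""


class NoCompleteCasesError(ValueError):
    """A completeness filter removed every accession."""


@dataclass
class GenotypeTable:
    """Accession x SNP biallelic call matrix plus SNP annotation.

    Attributes
    ----------
    calls
        DataFrame indexed by accession_id, one column per snp_id, values in
        {0.0, 1.0, NaN}.
    snps
        DataFrame indexed by snp_id with columns ``gene`` and ``position``
        (1-based).
    """

    calls: pd.DataFrame
    snps: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.snps is None:
            self.snps = pd.DataFrame(
                {"gene": "unknown", "position": np.arange(1, self.calls.shape[1] + 1)},
                index=self.calls.columns,
            )
        missing_ann = set(self.calls.columns) - set(self.snps.index)
        if missing_ann:
            raise FormatError(f"SNPs without annotation: {sorted(missing_ann)[:5]}")
        vals = self.calls.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-biallelic genotype code {vals[i, j]!r} for accession "
                f"{self.calls.index[i]!r}, SNP {self.calls.columns[j]!r}"
            )

    @property
    def accession_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    def equals(self, other: "GenotypeTable") -> bool:
        a = self.calls.sort_index().sort_index(axis=1)
        b = other.calls.sort_index().sort_index(axis=1)
        return a.equals(b) and self.snps.sort_index().equals(other.snps.sort_index())


# ---------------------------------------------------------------------------
# phenotypes


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format phenotype table and return it with clean dtypes."""
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
    df = df.loc[:, list(PHENOTYPE_COLUMNS)].copy()
    df["accession_id"] = df["accession_id"].astype(str)
    df["season_id"] = df["season_id"].astype(str)
    dup = df.duplicated(subset=["accession_id", "season_id"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise FormatError(
            f"duplicate phenotype record for accession {row['accession_id']!r}, "
            f"season {row['season_id']!r}"
        )
    dhs = pd.to_numeric(df["dhs"], errors="coerce")
    bad = dhs.isna() | ~np.isfinite(dhs) | (dhs <= 0)
    if bad.any():
        rownum = int(np.argmax(bad.to_numpy()))
        raise FormatError(
            f"non-numeric or non-positive dhs value {df['dhs'].iloc[rownum]!r} "
            f"at row {rownum}"
        )
    df["dhs"] = dhs.astype(float)
    return df.reset_index(drop=True)


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV phenotype table (delimiter auto-detected)."""
    sep = sep or _sniff_sep(path)
    return validate_phenotypes(pd.read_csv(path, sep=sep))


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    validate_phenotypes(phenotypes).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path, sep: str | None = None) -> pd.DataFrame:
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    missing = {"accession_id"} - set(df.columns)
    if missing:
        raise FormatError("metadata table missing column: accession_id")
    df["accession_id"] = df["accession_id"].astype(str)
    if df["accession_id"].duplicated().any():
        dup_id = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise FormatError(f"duplicate metadata row for accession {dup_id!r}")
    return df.reset_index(drop=True)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path,
    format: str = "tsv",
    annotation_path=None,
    heterozygote: str = "error",
) -> GenotypeTable:
    """Read a genotype table from TSV or a minimal VCF.

    Parameters
    ----------
    format
        ``"tsv"`` — accession rows, SNP columns, values in {0, 1, NA};
        ``"vcf"`` — VCF 4.2 with biallelic records and haploid-style GT.
    annotation_path
        Optional TSV (snp_id, gene, position) for TSV input; for VCF the
        annotation is taken from CHROM/POS/ID.
    heterozygote
        ``"error"`` (default; inbred material makes hets data errors) or
        ``"missing"`` to coerce diploid heterozygous calls to NA.
    """
    if heterozygote not in ("error", "missing"):
        raise ValueError("heterozygote must be 'error' or 'missing'")
    if format == "tsv":
        return _read_genotypes_tsv(path, annotation_path)
    if format == "vcf":
        return _read_genotypes_vcf(path, heterozygote)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path, annotation_path) -> GenotypeTable:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, na_values=["NA", ""])
    df.index = df.index.astype(str)
    snps = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep=_sniff_sep(annotation_path))
        snps = ann.set_index("snp_id")[["gene", "position"]]
        snps.index = snps.index.astype(str)
    return GenotypeTable(calls=df.astype(float), snps=snps)


def _read_genotypes_vcf(path, heterozygote: str) -> GenotypeTable:
    import pysam

    states: dict[str, list[float]] = {}
    ann_rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise FormatError(
                    f"multi-allelic VCF record at {rec.chrom}:{rec.pos} "
                    f"(ALT={','.join(alts) or '.'})"
                )
            snp_id = rec.id or f"{rec.chrom}_{rec.pos}"
            col = []
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    col.append(np.nan)
                elif all(a == alleles[0] for a in alleles):
                    col.append(float(alleles[0]))
                elif heterozygote == "missing":
                    col.append(np.nan)
                else:
                    raise FormatError(
                        f"heterozygous call for sample {s!r} at {rec.chrom}:{rec.pos}"
                    )
            states[snp_id] = col
            ann_rows.append((snp_id, rec.chrom, rec.pos))
    calls = pd.DataFrame(states, index=pd.Index(samples, name="accession_id"))
    snps = pd.DataFrame(ann_rows, columns=["snp_id", "gene", "position"]).set_index(
        "snp_id"
    )
    return GenotypeTable(calls=calls, snps=snps)


def write_genotypes(genotypes: GenotypeTable, path, annotation_path=None) -> None:
    """Write genotype calls as TSV (0/1/NA) and optionally the annotation."""
    out = genotypes.calls.copy()
    out.index.name = "accession_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")
    if annotation_path is not None:
        ann = genotypes.snps.reset_index()
        ann.columns = ["snp_id", "gene", "position"]
        ann.to_csv(annotation_path, sep="\t", index=False)


def write_vcf(genotypes: GenotypeTable, path) -> None:
    """Write a minimal VCF 4.2 with haploid GT; CHROM carries the gene name."""
    snps = genotypes.snps
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for gene in pd.unique(snps["gene"]):
            fh.write(f"##contig=<ID={gene}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = list(genotypes.calls.index)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        order = snps.sort_values(["gene", "position"]).index
        for snp_id in order:
            gene = snps.loc[snp_id, "gene"]
            pos = int(snps.loc[snp_id, "position"])
            calls = genotypes.calls[snp_id]
            gt = ["." if pd.isna(v) else str(int(v)) for v in calls]
            fh.write(
                f"{gene}\t{pos}\t{snp_id}\tA\tT\t.\t.\t.\tGT\t" + "\t".join(gt) + "\n"
            )


# ---------------------------------------------------------------------------
# completeness filters


def complete_case_filter(
    phenotypes: pd.DataFrame, required_seasons: list[str] | None = None
) -> pd.DataFrame:
    """Retain accessions with a phenotype record for every required season.

    ``required_seasons`` defaults to every season observed in the table.
    Dropped accessions are reported through the module logger.
    """
    phenotypes = validate_phenotypes(phenotypes)
    observed = set(phenotypes["season_id"])
    if required_seasons is None:
        required_seasons = sorted(observed)
    else:
        extra = set(required_seasons) - observed
        if extra:
            raise ValueError(f"required seasons never observed: {sorted(extra)}")
    required = set(required_seasons)
    per_acc = phenotypes.groupby("accession_id")["season_id"].agg(set)
    complete = per_acc.index[[required <= s for s in per_acc]]
    dropped = sorted(set(per_acc.index) - set(complete))
    if dropped:
        logger.info(
            "complete_case_filter: dropped %d of %d accessions: %s",
            len(dropped), len(per_acc), ", ".join(dropped[:10]),
        )
    if len(complete) == 0:
        raise NoCompleteCasesError("no accessions complete for the required seasons")
    out = phenotypes[
        phenotypes["accession_id"].isin(set(complete))
        & phenotypes["season_id"].isin(required)
    ]
    return out.reset_index(drop=True)


def genotype_complete_case(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    snp_subset: list[str] | None = None,
    required_seasons: list[str] | None = None,
) -> list[str]:
    """Accessions complete in both phenotype seasons and the given SNPs."""
    if snp_subset is None:
        snp_subset = genotypes.snp_ids
    else:
        extra = set(snp_subset) - set(genotypes.snp_ids)
        if extra:
            raise ValueError(f"SNPs not in genotype table: {sorted(extra)}")
    pheno_complete = set(
        complete_case_filter(phenotypes, required_seasons)["accession_id"]
    )
    calls = genotypes.calls[list(snp_subset)]
    geno_complete = set(calls.index[calls.notna().all(axis=1)].astype(str))
    out = sorted(pheno_complete & geno_complete)
    if not out:
        raise NoCompleteCasesError(
            "no accessions complete for both phenotypes and genotypes"
        )
    return out
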