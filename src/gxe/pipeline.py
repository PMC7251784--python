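"""End-to-end pipeline: simulate/load -> filter -> decompose -> FW ->
plasticity -> SNP association, with a deterministic run manifest.

One YAML config drives the whole run.  All randomness flows from a single
root seed through named substreams (see :mod:`gxe.synthetic_data`), so
enabling or disabling stages never shifts another stage's draws, and the
same config yields byte-identical outputs.

The manifest records package/library versions, the seed, SHA-256 checksums
of every table read or written, and the accession counts at each
completeness filter — the full -> phenotype-complete -> genotype-complete
audit trail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io_tables, seasonal_plasticity, snp_association, synthetic_data
from . import fw_stability, variance_decomposition
from .io_tables import GenotypeTable
from .synthetic_data import SyntheticConfig

logger = logging.getLogger(__name__)

#: factor sets fitted by the decompose stage, in reporting order
DEFAULT_FACTOR_SETS = [
    ["accession"],
    ["origin"],
    ["population_cluster"],
    ["growth_habit"],
    ["kernel_row"],
    ["season"],
    ["accession", "season"],
    ["origin", "season"],
    ["population_cluster", "season"],
    ["growth_habit", "season"],
    ["kernel_row", "season"],
]

ALL_STAGES = ("decompose", "fw", "plasticity", "snp")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    out: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    phenotype_path: Path | None = None
    metadata_path: Path | None = None
    genotype_path: Path | None = None
    genotype_annotation_path: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    selection_method: str = "backward"
    selection_threshold: float = 0.05
    season_factor: bool = True
    factor_sets: list[list[str]] = field(
        default_factory=lambda: [list(fs) for fs in DEFAULT_FACTOR_SETS]
    )

    def __post_init__(self):
        self.out = Path(self.out)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic is None and self.phenotype_path is None:
            raise ValueError("config needs either a synthetic block or input paths")
        for p in (self.phenotype_path, self.metadata_path, self.genotype_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path, out=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.get("synthetic")
        if syn is not None:
            if seed is not None:
                syn = {**syn, "seed": seed}
            syn = SyntheticConfig(**syn)
        inputs = raw.get("inputs", {}) or {}
        return cls(
            out=Path(out if out is not None else raw.get("out", "gxe_run")),
            seed=seed if seed is not None else int(raw.get("seed", 0)),
            synthetic=syn,
            phenotype_path=inputs.get("phenotypes"),
            metadata_path=inputs.get("metadata"),
            genotype_path=inputs.get("genotypes"),
            genotype_annotation_path=inputs.get("snp_annotation"),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            selection_method=raw.get("selection_method", "backward"),
            selection_threshold=float(raw.get("selection_threshold", 0.05)),
            season_factor=bool(raw.get("season_factor", True)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the manifest (also written to
    ``<out>/manifest.json``).  A stage failure aborts the run with the
    failing stage named; outputs of earlier stages are retained."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "library_versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "stages": list(config.stages),
        "counts": {},
        "outputs": {},
        "checksums": {},
        "timings_s": {},
    }

    def _record(name: str, path: Path):
        manifest["outputs"][name] = str(path)
        manifest["checksums"][path.name] = _sha256(path)

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["timings_s"][name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    _write_manifest(manifest, out)
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name,
                            manifest["timings_s"][name])
                return False

        return _Ctx()

    with _stage("inputs"):
        phen, geno, meta, truth = _obtain_tables(config, out, _record)
        manifest["counts"]["accessions_total"] = int(phen["accession_id"].nunique())
        manifest["counts"]["phenotype_records"] = int(len(phen))

    with _stage("filter"):
        phen_cc = io_tables.complete_case_filter(phen)
        manifest["counts"]["phenotype_complete_accessions"] = int(
            phen_cc["accession_id"].nunique()
        )
        if geno is not None:
            geno_acc = io_tables.genotype_complete_case(phen, geno)
            manifest["counts"]["genotype_complete_accessions"] = len(geno_acc)
        else:
            geno_acc = None

    if "decompose" in config.stages:
        with _stage("decompose"):
            summaries, best = variance_decomposition.compare_models(
                phen_cc, meta, config.factor_sets
            )
            tab = variance_decomposition.summaries_to_frame(summaries)
            path = out / "decomposition.tsv"
            tab.to_csv(path, sep="\t", index=False, float_format="%.10g")
            _record("decomposition", path)
            manifest["best_model"] = {"label": best.label, "adj_r2": best.adj_r2}

    if "fw" in config.stages:
        with _stage("fw"):
            index = fw_stability.compute_environment_index(phen_cc)
            acc_fits = fw_stability.fw_by_accession(phen_cc, index)
            sea_fits = fw_stability.fw_by_season(phen_cc)
            corr = fw_stability.correlate_slopes_with_covariates(acc_fits, meta)
            for name, df in (
                ("fw_accession", fw_stability.fits_to_frame(acc_fits)),
                ("fw_season", fw_stability.fits_to_frame(sea_fits)),
                ("fw_covariate_correlations", corr),
            ):
                path = out / f"{name}.tsv"
                df.to_csv(path, sep="\t", index=False, float_format="%.10g")
                _record(name, path)

    if "plasticity" in config.stages:
        with _stage("plasticity"):
            sim = seasonal_plasticity.pairwise_season_similarity(phen_cc)
            _write_matrix(sim.r_matrix, out / "season_r.tsv")
            _record("season_r", out / "season_r.tsv")
            _write_matrix(sim.mse_matrix, out / "season_mse.tsv")
            _record("season_mse", out / "season_mse.tsv")
            summ = seasonal_plasticity.season_summary(phen_cc)
            summ.to_csv(out / "season_summary.tsv", sep="\t", index=False,
                        float_format="%.10g")
            _record("season_summary", out / "season_summary.tsv")

    if "snp" in config.stages and geno is not None:
        with _stage("snp"):
            _snp_stage(config, phen_cc, geno, geno_acc, out, manifest, _record)

    _write_manifest(manifest, out)
    return manifest


def _snp_stage(config, phen_cc, geno, geno_acc, out, manifest, _record):
    phen_g = phen_cc[phen_cc["accession_id"].isin(set(geno_acc))].reset_index(
        drop=True
    )
    scan = snp_association.single_marker_scan(
        phen_g, geno, season_factor=config.season_factor
    )
    scan_df = snp_association.scan_to_frame(scan)
    path = out / "snp_scan.tsv"
    scan_df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    _record("snp_scan", path)

    sel = snp_association.select_variables(
        phen_g, geno, method=config.selection_method,
        threshold=config.selection_threshold,
        season_factor=config.season_factor,
    )
    sel_path = out / "snp_selection.json"
    with open(sel_path, "w") as fh:
        json.dump(
            {
                "method": sel.method, "threshold": sel.threshold,
                "selected": sel.selected,
                "removed": [[s, None if not np.isfinite(p) else p]
                            for s, p in sel.removed],
                "monomorphic": sel.monomorphic, "aliased": sel.aliased,
            },
            fh, indent=1,
        )
    _record("snp_selection", sel_path)
    manifest["counts"]["snps_selected"] = len(sel.selected)

    reports = {}
    for label, g, subset in (
        ("accession+season", None, None),
        ("snps+season", geno, sel.selected or None),
    ):
        rep = snp_association.fit_prediction_model(
            phen_g, g, design_label=label, snp_subset=subset
        )
        reports[label] = rep
        tag = label.replace("+", "_")
        pdf = pd.DataFrame({"observed": rep.observed, "predicted": rep.predicted})
        ppath = out / f"prediction_{tag}.tsv"
        pdf.to_csv(ppath, sep="\t", index=False, float_format="%.10g")
        _record(f"prediction_{tag}", ppath)
    manifest["prediction"] = {
        label: {"model_r2": rep.model_r2, "obs_pred_slope": rep.obs_pred_slope,
                "obs_pred_intercept": rep.obs_pred_intercept, "n": rep.n}
        for label, rep in reports.items()
    }

    if sel.selected:
        std_tab, r2 = snp_association.standardized_coefficients(
            phen_g, geno, sel.selected
        )
        spath = out / "standardized_coefficients.tsv"
        std_tab.to_csv(spath, sep="\t", index=False, float_format="%.10g")
        _record("standardized_coefficients", spath)
        manifest["multiple_regression_r2"] = float(r2)
        signif = list(std_tab.loc[std_tab["p_value"] < 0.05, "snp_id"])
        refit = snp_association.refit_subset(phen_g, geno, signif)
        manifest["refit"] = {
            "snps": signif, "r2": refit.r2, "f_value": refit.f_value,
            "p_value": refit.p_value, "n": refit.n,
        }


def _obtain_tables(config: RunConfig, out: Path, _record):
    if config.synthetic is not None:
        syn = config.synthetic
        if syn.seed != config.seed:
            syn = dataclasses.replace(syn, seed=config.seed)
        phen_full, geno_full, meta, truth = synthetic_data.generate_dataset(syn)
        phen, geno = synthetic_data.inject_missing(phen_full, geno_full, syn)
        io_tables.write_phenotypes(phen, out / "phenotypes.tsv")
        _record("phenotypes", out / "phenotypes.tsv")
        io_tables.write_metadata(meta, out / "metadata.tsv")
        _record("metadata", out / "metadata.tsv")
        io_tables.write_genotypes(geno, out / "genotypes.tsv",
                                  out / "snp_annotation.tsv")
        _record("genotypes", out / "genotypes.tsv")
        _record("snp_annotation", out / "snp_annotation.tsv")
        truth.to_json(out / "truth.json")
        _record("truth", out / "truth.json")
        return phen, geno, meta, truth
    phen = io_tables.read_phenotypes(config.phenotype_path)
    _record("phenotypes", Path(config.phenotype_path))
    meta = io_tables.read_metadata(config.metadata_path)
    _record("metadata", Path(config.metadata_path))
    geno = None
    if config.genotype_path is not None:
        fmt = "vcf" if str(config.genotype_path).endswith(".vcf") else "tsv"
        geno = io_tables.read_genotypes(
            config.genotype_path, format=fmt,
            annotation_path=config.genotype_annotation_path,
        )
        _record("genotypes", Path(config.genotype_path))
    return phen, geno, meta, None


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
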