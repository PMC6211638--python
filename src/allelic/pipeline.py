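"""End-to-end orchestration: dedup -> counts -> DNA proportions -> per-
replicate ASE -> fixed-effects meta -> FDR -> inflation, plus the binding
branch (region test, per-replicate differential binding, Stouffer, FDR,
overlap enrichment) when binding inputs are present.

Each stage failure aborts with the failing stage named; partial outputs
written before the failure are left in place.  A run manifest records
package version, seed, thresholds and input hashes.
"""

from __future__ import annotations

import dataclasses
import platform
from pathlib import Path
from typing import Optional

from . import __version__
from .ase import run_ase
from .combine import call_significant, fixed_effects, genomic_inflation
from .dast import run_dast
from .enrich import overlap_ase_asb
from .errors import StageError
from .io import file_sha256, qq_plot, qq_table, write_json, write_table
from .molecules import dedup_umi, count_reads, estimate_dna_proportions, filter_testable
from .region import test_regions


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, thresholds and method selectors for one pipeline run."""

    molecules: Optional[str] = None  # molecule TSV (needs dedup)
    rna_counts: Optional[str] = None  # pre-deduplicated count TSV
    dna_counts: Optional[str] = None
    binding_counts: Optional[str] = None
    region_counts: Optional[str] = None
    out_dir: str = "."
    fdr_ase: float = 0.10
    fdr_asb: float = 0.10
    fdr_region: float = 0.01
    lfc_threshold: float = 1.0
    min_rna: int = 5
    min_dna: int = 10
    rho: str | float = "auto"
    dedup: bool = True
    include_dna_variance: bool = True
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> None:
        for name in ("fdr_ase", "fdr_asb", "fdr_region"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise StageError(f"config: {name} must be in (0, 1)")
        if self.molecules is None and self.rna_counts is None:
            raise StageError("config: need either molecules or rna_counts input")
        if self.dna_counts is None:
            raise StageError("config: dna_counts input is required")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    config: PipelineConfig,
    tables: Optional[dict] = None,
) -> dict:
    """Execute the pipeline; returns the result bundle as a dict of tables.

    ``tables`` may supply in-memory DataFrames under the same keys as the
    config paths (molecules, rna_counts, dna_counts, binding_counts,
    region_counts); file paths are read only for keys not supplied.
    Outputs are written as TSV under ``config.out_dir`` along with a
    ``manifest.json``.
    """
    from .io import read_table

    config.validate()
    tables = dict(tables or {})
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    input_hashes = {}

    def load(key, kind=None):
        if key in tables:
            return tables[key]
        path = getattr(config, key)
        if path is None:
            return None
        input_hashes[key] = file_sha256(path)
        return read_table(path, kind=kind)

    # --- expression branch ----------------------------------------------
    @_stage("counts")
    def _counts():
        molecules = load("molecules")
        if molecules is not None:
            return dedup_umi(molecules) if config.dedup else count_reads(molecules)
        return load("rna_counts", kind="counts")

    rna_counts = _counts()

    @_stage("dna_proportions")
    def _dna():
        return estimate_dna_proportions(load("dna_counts"))

    dna = _dna()
    results["dna_proportions"] = dna

    @_stage("filter")
    def _filter():
        return filter_testable(rna_counts, dna, config.min_rna, config.min_dna)

    rna_filtered, filter_summary = _filter()
    results["filter_summary"] = filter_summary

    @_stage("ase")
    def _ase():
        return run_ase(
            rna_filtered,
            dna,
            rho=config.rho,
            include_dna_variance=config.include_dna_variance,
        )

    ase_results, rho_by_rep = _ase()
    results["ase_replicate"] = ase_results

    @_stage("meta")
    def _meta():
        meta = fixed_effects(ase_results.dropna(subset=["beta"]))
        meta, n_sig = call_significant(meta, fdr=config.fdr_ase)
        return meta, n_sig

    meta, n_ase = _meta()
    results["ase_meta"] = meta
    results["n_ase_significant"] = n_ase

    @_stage("inflation")
    def _inflation():
        return genomic_inflation(meta["pvalue"].to_numpy())

    inflation = _inflation()
    results["inflation"] = inflation

    write_table(ase_results, out_dir / "ase_replicate.tsv")
    write_table(meta, out_dir / "ase_meta.tsv")
    if config.make_plots:
        table = qq_table(meta["pvalue"].to_numpy())
        write_table(table, out_dir / "qq_ase.tsv")
        qq_plot(table, out_dir / "qq_ase.png")

    # --- binding branch ---------------------------------------------------
    binding = load("binding_counts")
    if binding is not None:

        @_stage("dast")
        def _dast():
            return run_dast(
                binding,
                rho=config.rho,
                include_dna_variance=config.include_dna_variance,
                fdr=config.fdr_asb,
            )

        asb = _dast()
        results["asb_per_concentration"] = asb["per_concentration"]
        results["asb_overall"] = asb["overall"]
        write_table(asb["per_concentration"], out_dir / "asb_per_concentration.tsv")
        write_table(asb["overall"], out_dir / "asb_overall.tsv")

        @_stage("overlap")
        def _overlap():
            tested_both = sorted(
                set(meta["snp_id"]) & set(asb["overall"]["snp_id"])
            )
            ase_calls = set(meta.loc[meta["significant"], "snp_id"]) & set(tested_both)
            asb_calls = set(
                asb["overall"].loc[asb["overall"]["significant"], "snp_id"]
            ) & set(tested_both)
            if tested_both and (ase_calls or asb_calls):
                res, overlap_n = overlap_ase_asb(ase_calls, asb_calls, tested_both)
                return {"enrichment": res, "overlap_n": overlap_n}
            return None

        overlap = _overlap()
        if overlap is not None:
            results["ase_asb_overlap"] = overlap

    region_counts = load("region_counts", kind="region_counts")
    if region_counts is not None:

        @_stage("region")
        def _region():
            return test_regions(
                region_counts,
                lfc_threshold=config.lfc_threshold,
                fdr=config.fdr_region,
            )

        region_results = _region()
        results["region_results"] = region_results
        write_table(region_results, out_dir / "region_results.tsv")

    manifest = {
        "package": "allelic",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {
            "fdr_ase": config.fdr_ase,
            "fdr_asb": config.fdr_asb,
            "fdr_region": config.fdr_region,
            "lfc_threshold": config.lfc_threshold,
            "min_rna": config.min_rna,
            "min_dna": config.min_dna,
        },
        "dedup": config.dedup,
        "rho_by_replicate": {str(k): v for k, v in rho_by_rep.items()},
        "input_hashes": input_hashes,
        "filter_summary": filter_summary,
        "n_ase_significant": n_ase,
        "lambda_gc": inflation.lambda_gc,
    }
    write_json(manifest, out_dir / "manifest.json")
    results["manifest"] = manifest
    return results
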