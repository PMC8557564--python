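"""Config-driven orchestration of the full analysis.

``run_pipeline`` executes simulate -> differential isoform expression ->
differential exon usage -> differential methylation -> integration
(-> enrichment when gene sets are supplied) in dependency order, writes
every stage's TSV under the output directory, and finishes with a manifest
(JSON) recording the seed, thresholds, input hashes and per-stage row
counts. Identical config + seed produce byte-identical outputs.

Configuration is a flat-ish YAML file; every threshold defaults to the
emulated study's value (nominal p <= 0.01 for the three differential tests,
KS p <= 0.001, expression filter 2 counts in >= 9 replicates, CpG coverage
>= 8, 3-kb promoter window).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import exon_usage, integration, isoform, methylation, nbglm, simulate
from .annotation import flatten_gene, read_gtf, write_gtf

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the study's thresholds."""

    out_dir: str = "results/pipeline"
    # analysis-mode inputs (ignored in simulate mode)
    annotation_path: str | None = None
    isoform_counts_path: str | None = None
    bin_counts_path: str | None = None
    design_rna_path: str | None = None
    cytosine_report_paths: dict[str, str] | None = None
    design_meth_path: str | None = None
    gmt_path: str | None = None
    # thresholds
    alpha_die: float = 0.01
    alpha_deu: float = 0.01
    alpha_dm: float = 0.01
    alpha_ks: float = 0.001
    min_count: int = 2
    min_samples: int = 9
    min_coverage: int = 8
    promoter_window: int = 3000
    # mode flags
    simulate_mode: bool = True
    pooled_ks: bool = True
    merge_strands: bool = False
    coverage_all_samples: bool = False
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )

    def validate(self) -> None:
        for name in ("alpha_die", "alpha_deu", "alpha_dm", "alpha_ks"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise PipelineError(f"{name}={v} outside (0, 1]")
        if self.min_coverage < 1 or self.min_count < 0 or self.min_samples < 1:
            raise PipelineError("invalid filter thresholds")
        if not self.simulate_mode:
            required = {
                "annotation_path": self.annotation_path,
                "isoform_counts_path": self.isoform_counts_path,
                "bin_counts_path": self.bin_counts_path,
                "design_rna_path": self.design_rna_path,
            }
            for key, value in required.items():
                if value is None:
                    raise PipelineError(f"analysis mode requires {key}")
                if not Path(value).exists():
                    raise PipelineError(f"{key}: no such file {value!r}")
        self.simulation.validate()


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {})
    sim_over = overrides.pop("simulation", {})
    sim_raw.update(sim_over)
    known_sim = {f.name for f in fields(simulate.SimulationConfig)}
    bad = set(sim_raw) - known_sim
    if bad:
        raise PipelineError(f"unknown simulation keys: {sorted(bad)}")
    for key in ("transcripts_per_gene", "exons_per_transcript", "exon_length",
                "intron_length", "intergenic_gap"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    raw.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    bad = set(raw) - known
    if bad:
        raise PipelineError(f"unknown config keys: {sorted(bad)}")
    cfg = PipelineConfig(**raw, simulation=simulate.SimulationConfig(**sim_raw))
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written as JSON)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.simulation.seed,
        "thresholds": {
            k: getattr(cfg, k)
            for k in ("alpha_die", "alpha_deu", "alpha_dm", "alpha_ks",
                      "min_count", "min_samples", "min_coverage",
                      "promoter_window")
        },
        "stages": {},
    }
    t_all = time.time()

    def stage(name: str, rows_in: int, rows_out: int, t0: float,
              outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "rows_in": rows_in,
            "rows_out": rows_out,
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    # ---- stage 1: inputs (simulate or load) -------------------------------
    t0 = time.time()
    if cfg.simulate_mode:
        genes = simulate.generate_annotation(cfg.simulation)
        iso_df, bin_df, design_rna, truth = simulate.generate_counts(
            cfg.simulation, genes
        )
        meth_data, design_meth = simulate.generate_methylome(
            cfg.simulation, genes, truth
        )
        gtf_path = out / "annotation.gtf"
        write_gtf(genes, str(gtf_path))
        _write(iso_df, out / "isoform_counts.tsv", index=True)
        _write(bin_df, out / "bin_counts.tsv")
        _write(design_rna, out / "design_rna.tsv")
        _write(design_meth, out / "design_meth.tsv")
        for key, df in truth.to_frames().items():
            _write(df, out / f"truth_{key}.tsv")
        stage("simulate", cfg.simulation.n_genes, len(iso_df), t0,
              [gtf_path, out / "isoform_counts.tsv", out / "bin_counts.tsv",
               out / "truth_die.tsv", out / "truth_deu.tsv", out / "truth_dm.tsv"])
    else:
        genes = read_gtf(cfg.annotation_path)
        iso_df = pd.read_csv(cfg.isoform_counts_path, sep="\t", index_col=0)
        bin_df = pd.read_csv(cfg.bin_counts_path, sep="\t")
        design_rna = pd.read_csv(cfg.design_rna_path, sep="\t")
        if cfg.cytosine_report_paths and cfg.design_meth_path:
            design_meth = pd.read_csv(cfg.design_meth_path, sep="\t")
            cond = dict(zip(design_meth["sample_id"], design_meth["condition"]))
            meth_data = methylation.read_cytosine_report(
                cfg.cytosine_report_paths, cond
            )
        else:
            meth_data, design_meth = None, None
        stage("load", len(iso_df), len(bin_df), t0, [])

    flat = {gid: flatten_gene(g, cfg.promoter_window) for gid, g in genes.items()}
    design = nbglm.DesignInfo.from_frame(design_rna)

    # ---- stage 2: differential isoform expression -------------------------
    t0 = time.time()
    iso_kept = isoform.filter_expressed(iso_df, cfg.min_count, cfg.min_samples)
    die_results = isoform.test_isoforms(iso_kept, design, cfg.alpha_die)
    die_df = isoform.results_frame(die_results, adjust=True)
    _write(die_df, out / "die_results.tsv")
    stage("die", len(iso_df), len(die_df), t0, [out / "die_results.tsv"])

    # ---- stage 3: differential exon usage ---------------------------------
    t0 = time.time()
    bins_kept = exon_usage.filter_genes(bin_df, cfg.min_count, cfg.min_samples)
    deu_results = exon_usage.test_exon_usage(bins_kept, design, cfg.alpha_deu)
    deu_df = exon_usage.results_frame(deu_results)
    _write(deu_df, out / "deu_results.tsv")
    n_sig_exons, n_sig_genes = exon_usage.summarize_deu(deu_results)
    manifest["deu_summary"] = {
        "n_significant_exons": n_sig_exons,
        "n_genes_with_significant_exon": n_sig_genes,
    }
    stage("deu", len(bin_df), len(deu_df), t0, [out / "deu_results.tsv"])

    # ---- stage 4: differential methylation --------------------------------
    dm_df = None
    if meth_data is not None:
        t0 = time.time()
        if cfg.merge_strands:
            meth_data = methylation.merge_strands(meth_data)
        filtered = methylation.filter_cytosines(
            meth_data, cfg.min_coverage,
            require_all_samples=cfg.coverage_all_samples,
        )
        dm_df = methylation.test_dm(filtered, cfg.alpha_dm)
        _write(dm_df, out / "dm_results.tsv")
        stage("dm", len(meth_data.sites), len(dm_df), t0,
              [out / "dm_results.tsv"])

    # ---- stage 5: integration ---------------------------------------------
    report = None
    if dm_df is not None and len(dm_df):
        t0 = time.time()
        report = integration.run_integration(
            deu_results, die_results, dm_df, genes, flat,
            alpha_ks=cfg.alpha_ks, pooled=cfg.pooled_ks,
        )
        _write(report.comparisons_frame(), out / "ks_comparisons.tsv")
        _write(report.region_levels, out / "region_levels.tsv")
        _write(integration.annotate_dm(dm_df, flat), out / "dm_annotated.tsv")
        per_tx, per_feat = integration.cpg_count_tables(dm_df, genes, flat)
        _write(per_tx, out / "cpg_counts_per_transcript.tsv")
        _write(per_feat, out / "cpg_counts_per_feature.tsv")
        manifest["integration"] = {
            "n_deu_genes": report.n_deu_genes,
            "n_deu_genes_with_meth": report.n_deu_genes_with_meth,
            "n_die_genes": report.n_die_genes,
            "n_die_genes_with_meth": report.n_die_genes_with_meth,
        }
        stage("integrate", len(dm_df), len(report.region_levels), t0,
              [out / "ks_comparisons.tsv", out / "region_levels.tsv"])

    # ---- stage 6: enrichment (optional) -----------------------------------
    if cfg.gmt_path:
        t0 = time.time()
        sets = enr.read_gmt(cfg.gmt_path)
        bg = set(iso_kept["gene_id"]) if "gene_id" in iso_kept.columns else set()
        sig = {r.gene_id for r in die_results if r.significant}
        die_enr = enr.fisher_enrichment(sig & bg, bg, sets)
        _write(enr.results_frame(die_enr), out / "enrichment_die.tsv")
        bg_deu = {r.gene_id for r in deu_results}
        sig_deu = {r.gene_id for r in deu_results if r.significant}
        deu_enr = enr.fisher_enrichment(sig_deu, bg_deu, sets)
        _write(enr.results_frame(deu_enr), out / "enrichment_deu.tsv")
        stage("enrich", len(sets), len(die_enr) + len(deu_enr), t0,
              [out / "enrichment_die.tsv", out / "enrichment_deu.tsv"])

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
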