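"""End-to-end orchestration: simulate -> pair -> expr -> dynamics ->
chromatin -> compare -> windows.

`run_all` drives the file-based pipeline (each stage reads the previous
stage's outputs from the run directory, so any stage can be re-run or
skipped); `analyze_dataset` is the in-memory fast path used for repeated
simulation studies, where the RBH pairing step may be bypassed in favour of
the planted truth dyads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin as chrom_mod
from . import compare as compare_mod
from . import dynamics as dyn_mod
from . import expression as expr_mod
from . import pairing as pair_mod
from . import windows as win_mod
from .io import (
    ExpressionMatrix,
    FormatError,
    logger,
    read_bed,
    read_bedgraph,
    read_depth_table,
    read_gff3,
    read_hits_table,
    read_sra_regions,
    read_tpm_matrix,
    write_results,
)
from .simulate import SimConfig, SimDataset, simulate_all, write_dataset

ALL_STAGES = ["simulate", "pair", "expr", "dynamics", "chromatin", "compare", "windows"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs: paths, thresholds, seed."""

    outdir: str = "homeobias_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    # pairing
    min_target_coverage: float = 0.90
    min_identity: float = 90.0
    max_evalue: float = 1e-5
    # expression
    min_cumulative_tpm: float = 10.0
    # chromatin
    flank: int = 2000
    peak_window: int = 500
    # comparison
    alpha: float = 0.05
    # windows
    da_window_bp: int = 50_000_000
    cen_window_bp: int = 1_000_000
    fold_threshold: float = 1.5
    sim: SimConfig = None

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            merged = {**dataclasses.asdict(cfg.sim), **sim_raw}
            merged["dominance_mixture"] = tuple(merged["dominance_mixture"])
            cfg.sim = SimConfig(**merged)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# in-memory analysis (simulation studies)
# ---------------------------------------------------------------------------


def metric_tables(
    data: SimDataset,
    dyads: pd.DataFrame,
    flank: int = 2000,
    peak_window: int = 500,
    min_cumulative: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-gene and per-dyad metric tables the comparisons use.

    The gene universe is the dyad members.  Genes are labelled by their own
    midpoint (a gene is rearranged iff it lies inside an SRA region), dyads
    by the either-member rule; a dyad member outside every region therefore
    stays in the gene-level control even when its partner is rearranged,
    which keeps the two gene-level groups disjoint in dyad membership only
    at the dyad level, not the gene level.  Gene-level expression status is
    the cumulative-TPM retention filter.
    """
    genes = data.truth.genes
    gene_labels = pair_mod.assign_genes_to_regions(genes, data.truth.sra_regions)
    dyads = dyads.copy()
    if "dyad_id" not in dyads:
        dyads["dyad_id"] = dyads["m_gene"] + "|" + dyads["u_gene"]
    dyads_lab = pair_mod.assign_dyads_to_regions(dyads, gene_labels)

    dyad_metrics = expr_mod.dyad_global_table(data.expression, dyads_lab)
    chrom_genes = chrom_mod.gene_chromatin_table(
        data.tracks, data.peaks, genes, flank=flank, peak_window=peak_window
    )
    dyad_chrom = chrom_mod.dyad_chromatin_table(chrom_genes, dyads_lab)
    dyad_metrics["hphb"] = dyad_chrom["hphb"]

    gm = dyad_member_genes(dyads, gene_labels)
    gt = expr_mod.global_tpm(data.expression)
    retained = data.expression.retained(min_cumulative)
    member = gm["gene_id"]
    gm["global_tpm"] = gt.reindex(member).to_numpy()
    gm["expressed"] = retained.reindex(member).to_numpy()
    cg = chrom_genes.set_index("gene_id")
    gm["summit_fe"] = cg["summit_fe"].reindex(member).to_numpy()
    gm["peak"] = cg["peak"].reindex(member).to_numpy()
    return gm, dyad_metrics


def dyad_member_genes(dyads: pd.DataFrame, gene_labels: pd.DataFrame) -> pd.DataFrame:
    """Gene-level frame of dyad members with midpoint-based region labels."""
    member = pd.Index(np.concatenate([dyads["m_gene"], dyads["u_gene"]]))
    return (
        pd.DataFrame({"gene_id": member})
        .merge(gene_labels, on="gene_id", how="left")
        .fillna({"label": "non_rearranged"})
    )


def analyze_dataset(
    data: SimDataset,
    use_truth_dyads: bool = True,
    alpha: float = 0.05,
    per_region: bool = False,
):
    """Global (and optionally per-region) comparison on a simulated dataset."""
    if use_truth_dyads:
        dyads = data.truth.dyads[["dyad_id", "m_gene", "u_gene"]]
    else:
        rbh = pair_mod.iterative_rbh(data.hits_mu, data.hits_um)
        dyads = rbh.dyads
    gm, dm = metric_tables(data, dyads)
    out = {"gene_metrics": gm, "dyad_metrics": dm}
    out["global"] = compare_mod.compare_global(gm, dm, alpha=alpha)
    if per_region:
        out["per_region"] = compare_mod.compare_per_region(gm, dm, alpha=alpha)
    return out


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FormatError(f"stage {stage}: missing input {path}")
    return path


def run_all(config: RunConfig) -> dict:
    """Run the requested stages in dependency order; returns the path map.

    Deterministic given the seed: two runs with the same config produce
    byte-identical result tables.  A manifest records the seed, the full
    parameter set and its hash.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: list[str] = []

    def done(stage):
        stage_log.append(stage)
        logger.info("stage %s done (%.1fs elapsed)", stage, time.time() - t0)

    if "simulate" in config.stages:
        data = simulate_all(config.sim)
        write_dataset(data, out)
        done("simulate")

    if "pair" in config.stages:
        hits_mu = read_hits_table(_require(out / "hits_mu.tsv", "pair"))
        hits_um = read_hits_table(_require(out / "hits_um.tsv", "pair"))
        rbh = pair_mod.iterative_rbh(
            hits_mu,
            hits_um,
            config.min_target_coverage,
            config.min_identity,
            config.max_evalue,
        )
        dyads = rbh.dyads.sort_values(["m_gene", "u_gene"]).reset_index(drop=True)
        write_results(out / "dyads.tsv", dyads)
        write_results(
            out / "unpaired.tsv",
            pd.DataFrame(
                {
                    "gene_id": sorted(rbh.unique_m) + sorted(rbh.unique_u),
                    "subgenome": ["M"] * len(rbh.unique_m) + ["U"] * len(rbh.unique_u),
                }
            ),
        )
        done("pair")

    genes = None
    if {"expr", "chromatin", "compare"} & set(config.stages):
        genes = read_gff3(_require(out / "genes.gff3", "expr"))
        regions = read_sra_regions(_require(out / "sra.bed", "expr"))
        labels = pair_mod.assign_genes_to_regions(genes, regions)
        write_results(out / "gene_labels.tsv", labels)

    if "expr" in config.stages:
        matrix = read_tpm_matrix(_require(out / "tpm.tsv", "expr"))
        dyads = pd.read_csv(_require(out / "dyads.tsv", "expr"), sep="\t")
        dyads["dyad_id"] = dyads["m_gene"] + "|" + dyads["u_gene"]
        write_results(out / "expr_bias.tsv", expr_mod.dyad_expression_table(matrix, dyads))
        write_results(
            out / "dyad_global.tsv", expr_mod.dyad_global_table(matrix, dyads)
        )
        write_results(
            out / "cv.tsv",
            expr_mod.cv_classify(
                matrix, expr_mod.filter_expressed(matrix, config.min_cumulative_tpm)
            ).reset_index(),
        )
        done("expr")

    if "dynamics" in config.stages:
        matrix = read_tpm_matrix(_require(out / "tpm.tsv", "dynamics"))
        dyads = pd.read_csv(_require(out / "dyads.tsv", "dynamics"), sep="\t")
        dyads["dyad_id"] = dyads["m_gene"] + "|" + dyads["u_gene"]
        cmds = dyn_mod.cmd_table(matrix, dyads)
        write_results(out / "dynamics.tsv", dyn_mod.classify_dynamics(cmds))
        done("dynamics")

    if "chromatin" in config.stages:
        tracks = {
            "M": read_bedgraph(_require(out / "h3k4me3_M.bedgraph", "chromatin")),
            "U": read_bedgraph(_require(out / "h3k4me3_U.bedgraph", "chromatin")),
        }
        peaks = read_bed(_require(out / "peaks.bed", "chromatin"))
        gene_frame = _genes_frame(genes)
        gtab = chrom_mod.gene_chromatin_table(
            tracks, peaks, gene_frame, flank=config.flank, peak_window=config.peak_window
        )
        dyads = pd.read_csv(_require(out / "dyads.tsv", "chromatin"), sep="\t")
        dyads["dyad_id"] = dyads["m_gene"] + "|" + dyads["u_gene"]
        write_results(out / "chromatin_genes.tsv", gtab)
        write_results(out / "chromatin_dyads.tsv", chrom_mod.dyad_chromatin_table(gtab, dyads))
        done("chromatin")

    if "compare" in config.stages:
        matrix = read_tpm_matrix(_require(out / "tpm.tsv", "compare"))
        dyads = pd.read_csv(_require(out / "dyads.tsv", "compare"), sep="\t")
        dyads["dyad_id"] = dyads["m_gene"] + "|" + dyads["u_gene"]
        labels = pd.read_csv(out / "gene_labels.tsv", sep="\t")
        dyads_lab = pair_mod.assign_dyads_to_regions(dyads, labels)
        dm = expr_mod.dyad_global_table(matrix, dyads_lab)
        ctab = pd.read_csv(_require(out / "chromatin_dyads.tsv", "compare"), sep="\t")
        dm["hphb"] = ctab["hphb"].to_numpy()
        gtab = pd.read_csv(_require(out / "chromatin_genes.tsv", "compare"), sep="\t")
        gm = dyad_member_genes(dyads, labels)
        member = gm["gene_id"]
        gm["global_tpm"] = expr_mod.global_tpm(matrix).reindex(member).to_numpy()
        gm["expressed"] = matrix.retained(config.min_cumulative_tpm).reindex(member).to_numpy()
        cg = gtab.set_index("gene_id")
        gm["summit_fe"] = cg["summit_fe"].reindex(member).to_numpy()
        gm["peak"] = cg["peak"].reindex(member).to_numpy()
        write_results(out / "table1.tsv", compare_mod.compare_global(gm, dm, alpha=config.alpha))
        write_results(
            out / "fig3.tsv", compare_mod.compare_per_region(gm, dm, alpha=config.alpha)
        )
        done("compare")

    if "windows" in config.stages:
        rows = []
        for p in sorted(out.glob("da_line_*.tsv")):
            depth = read_depth_table(p)
            cov = win_mod.normalize_to_median(
                win_mod.window_means(depth, config.da_window_bp)
            )
            rows.append(
                (p.stem.replace("da_line_", "DA_"), win_mod.assign_addition_line(cov, config.fold_threshold))
            )
        write_results(
            out / "da_assignments.tsv",
            pd.DataFrame(rows, columns=["line_id", "assigned_chrom"]),
        )
        cen = win_mod.centromere_midpoints(
            read_depth_table(_require(out / "cenh3.tsv", "windows")),
            window_bp=config.cen_window_bp,
        )
        cen_rows = [
            (c.chrom, mid, h, c.n_peaks)
            for c in cen.values()
            for mid, h in zip(c.midpoints, c.peak_heights)
        ]
        write_results(
            out / "centromeres.tsv",
            pd.DataFrame(cen_rows, columns=["chrom", "midpoint_bp", "height", "n_peaks"]),
        )
        done("windows")

    cfg_dict = _jsonable(config.to_dict())
    cfg_dict.pop("outdir", None)  # identical analyses hash alike anywhere
    manifest = {
        "seed": config.seed,
        "stages": stage_log,
        "config": cfg_dict,
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"outdir": out, "stages": stage_log}


def _genes_frame(genes: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (g.gene_id, g.subgenome, g.chrom, g.start, g.end, g.strand, g.cds_start)
            for g in genes.values()
        ],
        columns=["gene_id", "subgenome", "chrom", "start", "end", "strand", "cds_start"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
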