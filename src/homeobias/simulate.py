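"""Synthetic allotetraploid dataset generator.

Emulates a two-subgenome (M/U) tetraploid with seven chromosome pairs:
planted homoeolog dyads placed collinearly, genome-unique genes, paralog
decoy alignment hits, a balanced / M-dominant / U-dominant expression
mixture across seven tissues, silenced homoeologs, structurally rearranged
(SRA) blocks created by relocating runs of U-genome genes to another U
chromosome (optionally with expression perturbations), H3K4me3 plateaus and
peaks at expressed genes, disomic-addition-line coverage profiles, and
single- or double-peaked CENH3 coverage (the double peak on chromosome 5M).

Every stage draws from an independent substream of one global seed, so
regenerating one layer does not perturb the others.  All outputs are
deterministic given the seed, and a truth table records what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    SRARegionSet,
    logger,
    write_bed,
    write_bedgraph,
    write_gff3,
    write_hits_table,
    write_results,
    write_sra_regions,
    write_tpm_matrix,
)

#: the seven sampled tissues
TISSUES = [
    "seedling_leaf",
    "seedling_root",
    "flag_leaf",
    "leaf_sheath",
    "whole_spike",
    "preanthesis_spike",
    "stem",
]

CHROM_NUMBERS = range(1, 8)

# substream indices, one per generation stage
_STAGE_GENOME = 0
_STAGE_HITS = 1
_STAGE_EXPRESSION = 2
_STAGE_CHROMATIN = 3
_STAGE_COVERAGE = 4


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Defaults describe a null genome: SRA blocks exist (so region labels are
    defined) but carry no expression perturbation.  Perturbations are
    switched on via ``sra_tpm_factor`` / ``sra_extra_silencing``.
    """

    n_dyads: int = 2000
    n_unique_per_genome: int = 200
    n_tissues: int = 7
    # expression mixture: (balanced, M-dominant, U-dominant)
    dominance_mixture: tuple = (0.78, 0.12, 0.10)
    silencing_prob: float = 0.08
    tpm_log_mean: float = 2.0
    tpm_log_sd: float = 1.2
    tissue_effect_sd: float = 0.4
    #: per-gene per-tissue lognormal sd of the homoeolog ratio wobble;
    #: 0 makes within-dyad ratios identical in every tissue
    ratio_noise_sd: float = 0.25
    #: Beta concentration of the M:U split around its class target;
    #: None plants the exact target ratios (0.5, dominant_mean, 1-dominant_mean)
    split_concentration: float | None = 60.0
    dominant_mean: float = 0.95
    # SRA geometry and perturbation
    sra_fraction: float = 0.15
    n_sra_blocks: int = 13
    sra_tpm_factor: float = 1.0
    sra_extra_silencing: float = 0.0
    # alignment-hit noise
    identity_sd: float = 1.5
    decoy_rate: float = 0.1
    dropout_rate: float = 0.01
    # chromatin
    peak_prob: float = 0.9
    fe_scale: float = 1.0
    # coverage layers
    chrom_length_bp: int = 350_000_000
    depth_bin_bp: int = 1_000_000
    da_baseline_depth: float = 1.0
    da_added_fold: float = 2.0
    da_noise_sd: float = 0.1
    cenh3_background: float = 1.0
    cenh3_peak_height: float = 6.0
    cenh3_peak_sd_bins: float = 2.0
    cenh3_double_peak_sep_bins: int = 8
    cenh3_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not math.isclose(sum(self.dominance_mixture), 1.0, abs_tol=1e-9):
            raise ValueError("dominance_mixture must sum to 1")
        for p in (
            *self.dominance_mixture,
            self.silencing_prob,
            self.sra_fraction,
            self.sra_extra_silencing,
            self.decoy_rate,
            self.dropout_rate,
            self.peak_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


@dataclass
class TruthTable:
    """What was planted: per-gene, per-dyad and per-track ground truth."""

    genes: pd.DataFrame  # gene_id, subgenome, chrom, start, end, strand, cds_start, dyad_id, is_sra
    dyads: pd.DataFrame  # dyad_id, m_gene, u_gene, dominance_class, is_sra
    sra_regions: SRARegionSet
    centromeres: pd.DataFrame = None  # chrom, midpoint_bp (one row per true peak)
    da_lines: pd.DataFrame = None  # line_id, added_chrom
    tissues: list = field(default_factory=lambda: list(TISSUES))

    def gene_models(self) -> dict[str, GeneModel]:
        out = {}
        for row in self.genes.itertuples():
            out[row.gene_id] = GeneModel(
                gene_id=row.gene_id,
                subgenome=row.subgenome,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                cds_start=int(row.cds_start),
            )
        return out


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig) -> TruthTable:
    """Lay out genes on 7 M- and 7 U-chromosomes with collinear dyad partners.

    SRA blocks are contiguous runs of U-genome dyad genes relocated to the
    distal end of a different U chromosome; the intervals they land in form
    the SRA region set, so only the relocated copies fall inside SRA regions.
    """
    rng = config.rng(_STAGE_GENOME)
    n = config.n_dyads
    per_chrom = [n // 7 + (1 if k < n % 7 else 0) for k in range(7)]
    uniq_per_chrom = [
        config.n_unique_per_genome // 7 + (1 if k < config.n_unique_per_genome % 7 else 0)
        for k in range(7)
    ]

    # which dyads are rearranged: contiguous runs of U genes per block
    n_sra = int(round(config.sra_fraction * n))
    if config.sra_fraction > 0 and n_sra < 1:
        logger.warning("sra_fraction too small for %d dyads; zero SRA genes", n)
    n_blocks = min(config.n_sra_blocks, n_sra) if n_sra else 0

    lengths = rng.integers(1000, 5001, size=n + 2 * config.n_unique_per_genome)
    strands = rng.choice(["+", "-"], size=n + 2 * config.n_unique_per_genome)

    # dyad index -> (chrom number 1..7, slot on that chromosome)
    dyad_chrom = np.repeat(np.arange(1, 8), per_chrom)
    slot_in_chrom = np.concatenate([np.arange(c) for c in per_chrom])

    # pick SRA blocks: block j sits on source chromosome (j mod 7)+1 and is
    # relocated to the next U chromosome
    sra_flag = np.zeros(n, dtype=bool)
    block_of_dyad = np.full(n, -1)
    if n_blocks:
        per_block = [n_sra // n_blocks + (1 if j < n_sra % n_blocks else 0) for j in range(n_blocks)]
        for j in range(n_blocks):
            src = j % 7 + 1
            members = np.flatnonzero((dyad_chrom == src) & ~sra_flag & (block_of_dyad < 0))
            # a contiguous run in the middle of the chromosome
            if len(members) < per_block[j]:
                take = members
            else:
                lo = (j // 7 + 1) * len(members) // (n_blocks // 7 + 2)
                take = members[lo : lo + per_block[j]]
            sra_flag[take] = True
            block_of_dyad[take] = j

    # gene placement: residents occupy the proximal 75% of the chromosome,
    # relocated SRA blocks the distal 20%
    resident_span = int(config.chrom_length_bp * 0.75)
    sra_span_start = int(config.chrom_length_bp * 0.80)

    gene_rows = []

    def place(chrom_n, subg, slots, ids, dyad_ids, lens, strs, offset=0, spacing=None):
        chrom = f"{chrom_n}{subg}"
        if spacing is None:
            spacing = resident_span // max(len(slots) + 1, 1)
        for k, (gid, did, L, s) in enumerate(zip(ids, dyad_ids, lens, strs)):
            start = offset + (k + 1) * spacing
            end = start + int(L)
            cds_start = start if s == "+" else end - 1
            gene_rows.append((gid, subg, chrom, start, end, s, cds_start, did, False))

    # M genes: all collinear residents (dyad genes then unique genes)
    for c in CHROM_NUMBERS:
        d_idx = np.flatnonzero(dyad_chrom == c)
        ids = [f"{c}MG{k + 1:05d}" for k in range(len(d_idx))]
        dyad_ids = [f"dyad{di + 1:05d}" for di in d_idx]
        place(c, "M", d_idx, ids, dyad_ids, lengths[d_idx], strands[d_idx])

    # U genes: residents (non-SRA) collinear, SRA members relocated
    u_strands = rng.choice(["+", "-"], size=n)
    for c in CHROM_NUMBERS:
        d_idx = np.flatnonzero((dyad_chrom == c) & ~sra_flag)
        ids = [f"{c}UG{k + 1:05d}" for k in range(len(d_idx))]
        dyad_ids = [f"dyad{di + 1:05d}" for di in d_idx]
        place(c, "U", d_idx, ids, dyad_ids, lengths[d_idx], u_strands[d_idx])

    # relocated SRA blocks and the region intervals they occupy
    regions = SRARegionSet()
    sra_gene_rows = []
    for j in range(n_blocks):
        members = np.flatnonzero(block_of_dyad == j)
        if len(members) == 0:
            continue
        src_n = j % 7 + 1
        dest = f"{src_n % 7 + 1}U"  # relocate to the next U chromosome
        spacing = 20_000
        # stack blocks from the same destination one after another
        prior = sum(1 for r in sra_gene_rows if r[2] == dest)
        base = sra_span_start + prior * spacing + j * 1_000_000
        start0 = None
        for k, di in enumerate(members):
            gid = f"sra{j + 1:02d}G{k + 1:04d}U"
            s = base + k * spacing
            e = s + int(lengths[di])
            strand = u_strands[di]
            cds = s if strand == "+" else e - 1
            sra_gene_rows.append(
                (gid, "U", dest, s, e, strand, cds, f"dyad{di + 1:05d}", True)
            )
            if start0 is None:
                start0 = s
            end0 = e
        regions.add(GenomicInterval(dest, start0 - 5000, end0 + 5000), f"SRA{j + 1:02d}")
    gene_rows.extend(sra_gene_rows)

    # genome-unique genes, appended after residents on each chromosome
    li = n
    for subg in ("M", "U"):
        for c in CHROM_NUMBERS:
            cnt = uniq_per_chrom[c - 1]
            ids = [f"{c}{subg}UQ{k + 1:04d}" for k in range(cnt)]
            lens = lengths[li : li + cnt]
            strs = strands[li : li + cnt]
            chrom = f"{c}{subg}"
            spacing = 30_000
            base = int(config.chrom_length_bp * 0.76)
            for k, (gid, L, s) in enumerate(zip(ids, lens, strs)):
                start = base + k * spacing
                end = start + int(L)
                cds = start if s == "+" else end - 1
                gene_rows.append((gid, subg, chrom, start, end, s, cds, None, False))
            li += cnt

    genes = pd.DataFrame(
        gene_rows,
        columns=[
            "gene_id",
            "subgenome",
            "chrom",
            "start",
            "end",
            "strand",
            "cds_start",
            "dyad_id",
            "is_sra",
        ],
    )

    mg = genes[(genes.subgenome == "M") & genes.dyad_id.notna()].set_index("dyad_id")
    ug = genes[(genes.subgenome == "U") & genes.dyad_id.notna()].set_index("dyad_id")
    dyad_ids = [f"dyad{i + 1:05d}" for i in range(n)]
    dyads = pd.DataFrame(
        {
            "dyad_id": dyad_ids,
            "m_gene": mg.loc[dyad_ids, "gene_id"].to_numpy(),
            "u_gene": ug.loc[dyad_ids, "gene_id"].to_numpy(),
            "is_sra": sra_flag,
        }
    )
    return TruthTable(genes=genes, dyads=dyads, sra_regions=regions)


# ---------------------------------------------------------------------------
# alignment hits
# ---------------------------------------------------------------------------


def _hit_row(q, s, ident, qlen, slen, aln, bit, e):
    mism = int(round(aln * (1 - ident / 100)))
    return (q, s, round(ident, 2), aln, mism, 0, 1, aln, 1, aln, e, round(bit, 1), qlen, slen)


def simulate_hits(truth: TruthTable, config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reciprocal alignment hits for every dyad plus paralog decoys.

    True hits: identity ~ N(98, identity_sd) truncated to [90, 100], target
    coverage >= 0.9, e-value <= 1e-20, and a bit score that always exceeds
    any decoy for the same query.  Decoys hit a random non-partner gene of
    the other subgenome.  A fraction ``dropout_rate`` of dyads loses its true
    hit in one (randomly chosen) direction, breaking reciprocity.
    """
    rng = config.rng(_STAGE_HITS)
    genes = truth.genes.set_index("gene_id")
    dyads = truth.dyads
    n = len(dyads)

    gene_len = (genes.end - genes.start).to_dict()
    m_ids = genes[genes.subgenome == "M"].index.to_numpy()
    u_ids = genes[genes.subgenome == "U"].index.to_numpy()

    ident = np.clip(rng.normal(98.0, config.identity_sd, size=(n, 2)), 90.0, 100.0)
    cov = rng.uniform(0.92, 1.0, size=(n, 2))
    drop = rng.random(n) < config.dropout_rate
    drop_dir = rng.integers(0, 2, size=n)  # 0: drop M->U, 1: drop U->M

    rows_mu, rows_um = [], []
    true_bit_mu, true_bit_um = {}, {}
    for i, (m, u) in enumerate(zip(dyads.m_gene, dyads.u_gene)):
        lm, lu = gene_len[m], gene_len[u]
        aln_mu = max(1, int(round(cov[i, 0] * lu)))
        aln_um = max(1, int(round(cov[i, 1] * lm)))
        true_bit_mu[m] = 2.0 * aln_mu
        true_bit_um[u] = 2.0 * aln_um
        if not (drop[i] and drop_dir[i] == 0):
            rows_mu.append(_hit_row(m, u, ident[i, 0], lm, lu, aln_mu, 2.0 * aln_mu, 1e-50))
        if not (drop[i] and drop_dir[i] == 1):
            rows_um.append(_hit_row(u, m, ident[i, 1], lu, lm, aln_um, 2.0 * aln_um, 1e-50))

    # decoys: any gene may hit a random non-partner of the other subgenome,
    # always with a strictly lower bit score than a true hit would have
    partner_of = dict(zip(dyads.m_gene, dyads.u_gene)) | dict(zip(dyads.u_gene, dyads.m_gene))
    for qset, sset, sink, true_bit in (
        (m_ids, u_ids, rows_mu, true_bit_mu),
        (u_ids, m_ids, rows_um, true_bit_um),
    ):
        hit_mask = rng.random(len(qset)) < config.decoy_rate
        targets = rng.choice(sset, size=len(qset))
        d_ident = rng.uniform(90.0, 97.0, size=len(qset))
        d_cov = rng.uniform(0.90, 1.0, size=len(qset))
        d_frac = rng.uniform(0.70, 0.95, size=len(qset))
        for qi in np.flatnonzero(hit_mask):
            q, s = qset[qi], targets[qi]
            if s == partner_of.get(q):
                continue
            slen = gene_len[s]
            aln = max(1, int(round(d_cov[qi] * slen)))
            # strictly below the query's true-hit bit score
            bit = true_bit.get(q, 2.0 * aln) * d_frac[qi]
            sink.append(_hit_row(q, s, d_ident[qi], gene_len[q], slen, aln, bit, 1e-10))

    from .io import HITS_COLUMNS

    return (
        pd.DataFrame(rows_mu, columns=HITS_COLUMNS),
        pd.DataFrame(rows_um, columns=HITS_COLUMNS),
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(truth: TruthTable, config: SimConfig) -> ExpressionMatrix:
    """TPM matrix for all genes over the seven tissues.

    Per dyad: a lognormal base abundance, a dominance class drawn from the
    mixture setting the M:U split (Beta-jittered around 0.5 / dominant_mean /
    1-dominant_mean), a shared per-tissue multiplier and a per-gene ratio
    wobble.  Silenced copies are zeroed.  Rearranged dyads are perturbed
    symmetrically: both copies scaled by ``sra_tpm_factor`` and silenced with
    extra probability ``sra_extra_silencing`` per copy — absolute expression
    shifts, relative (within-dyad) bias does not.

    Adds true dominance/silencing columns to the truth table in place.
    """
    rng = config.rng(_STAGE_EXPRESSION)
    n = len(truth.dyads)
    tissues = truth.tissues[: config.n_tissues]
    nt = len(tissues)

    base = rng.lognormal(config.tpm_log_mean, config.tpm_log_sd, size=n)
    classes = rng.choice(3, size=n, p=list(config.dominance_mixture))
    target = np.where(
        classes == 0, 0.5, np.where(classes == 1, config.dominant_mean, 1 - config.dominant_mean)
    )
    if config.split_concentration is None:
        p = target
    else:
        k = config.split_concentration
        p = rng.beta(target * k, (1 - target) * k)

    tissue_mult = rng.lognormal(0.0, config.tissue_effect_sd, size=(n, nt))
    wobble_m = rng.lognormal(0.0, config.ratio_noise_sd, size=(n, nt)) if config.ratio_noise_sd else 1.0
    wobble_u = rng.lognormal(0.0, config.ratio_noise_sd, size=(n, nt)) if config.ratio_noise_sd else 1.0

    tpm_m = 2 * base[:, None] * p[:, None] * tissue_mult * wobble_m
    tpm_u = 2 * base[:, None] * (1 - p[:, None]) * tissue_mult * wobble_u

    silenced_m = rng.random(n) < config.silencing_prob
    silenced_u = rng.random(n) < config.silencing_prob

    sra = truth.dyads.is_sra.to_numpy()
    if config.sra_tpm_factor != 1.0:
        tpm_m[sra] *= config.sra_tpm_factor
        tpm_u[sra] *= config.sra_tpm_factor
    if config.sra_extra_silencing > 0:
        silenced_m |= sra & (rng.random(n) < config.sra_extra_silencing)
        silenced_u |= sra & (rng.random(n) < config.sra_extra_silencing)

    tpm_m[silenced_m] = 0.0
    tpm_u[silenced_u] = 0.0

    # genome-unique genes: own abundance and tissue effects
    uniq = truth.genes[truth.genes.dyad_id.isna()]
    nu = len(uniq)
    u_base = rng.lognormal(config.tpm_log_mean, config.tpm_log_sd, size=nu)
    u_mult = rng.lognormal(0.0, config.tissue_effect_sd, size=(nu, nt))
    u_sil = rng.random(nu) < config.silencing_prob
    u_tpm = u_base[:, None] * u_mult
    u_tpm[u_sil] = 0.0

    frame = pd.DataFrame(
        np.vstack([tpm_m, tpm_u, u_tpm]),
        index=pd.Index(
            list(truth.dyads.m_gene) + list(truth.dyads.u_gene) + list(uniq.gene_id),
            name="gene_id",
        ),
        columns=tissues,
    )
    # align to annotation order
    frame = frame.loc[truth.genes.gene_id]

    class_names = np.array(["balanced", "M_dominant", "U_dominant"])
    truth.dyads["true_dominance"] = class_names[classes]
    truth.dyads["true_silenced_m"] = silenced_m
    truth.dyads["true_silenced_u"] = silenced_u
    sil = dict(zip(truth.dyads.m_gene, silenced_m))
    sil |= dict(zip(truth.dyads.u_gene, silenced_u))
    sil |= dict(zip(uniq.gene_id, u_sil))
    truth.genes["true_silenced"] = truth.genes.gene_id.map(sil)
    return ExpressionMatrix(frame)


# ---------------------------------------------------------------------------
# chromatin
# ---------------------------------------------------------------------------


def simulate_chromatin(
    truth: TruthTable, config: SimConfig, expression: ExpressionMatrix
) -> tuple[dict[str, SignalTrack], PeakSet]:
    """H3K4me3 fold-enrichment tracks (one per subgenome) and peak intervals.

    Background FE is 1 everywhere; each expressed gene gets a plateau of
    height log1p(global TPM) * fe_scale on top of the background over its
    body, and — with probability ``peak_prob`` — a peak interval within
    500 bp of its coding start.  Silenced genes stay at background.
    """
    from .expression import global_tpm

    rng = config.rng(_STAGE_CHROMATIN)
    gt = global_tpm(expression)
    genes = truth.genes.sort_values(["chrom", "start"]).reset_index(drop=True)

    gvals = gt.reindex(genes.gene_id).fillna(0.0).to_numpy()
    genes["height"] = config.fe_scale * np.log1p(gvals)
    expressed = gvals >= ExpressionMatrix.EXPRESSED_TPM
    genes["has_peak"] = expressed & (rng.random(len(genes)) < config.peak_prob)

    track_rows = {"M": [], "U": []}
    peak_rows = []
    for chrom, sub in genes.groupby("chrom", sort=True):
        subg = sub.subgenome.iloc[0]
        pos = 0
        for row in sub.itertuples():
            if row.start > pos:
                track_rows[subg].append((chrom, pos, row.start, 1.0))
            track_rows[subg].append((chrom, row.start, row.end, 1.0 + row.height))
            pos = row.end
            if row.has_peak:
                peak_rows.append((chrom, max(0, row.cds_start - 100), row.cds_start + 300))
        track_rows[subg].append((chrom, pos, config.chrom_length_bp, 1.0))

    tracks = {
        s: SignalTrack(pd.DataFrame(track_rows[s], columns=["chrom", "start", "end", "value"]))
        for s in ("M", "U")
    }
    peaks = PeakSet(pd.DataFrame(peak_rows, columns=["chrom", "start", "end"]))
    truth.genes["true_peak"] = truth.genes.gene_id.map(
        dict(zip(genes.gene_id, genes.has_peak))
    )
    return tracks, peaks


# ---------------------------------------------------------------------------
# window coverage
# ---------------------------------------------------------------------------


def simulate_window_coverage(
    truth: TruthTable, config: SimConfig
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Disomic-addition-line depth tables and a CENH3 ChIP depth table.

    Thirteen DA lines (every chromosome except 6U, for which no line exists)
    each show ``da_added_fold`` x baseline depth on their added chromosome.
    The CENH3 track has one Gaussian bump per chromosome, except chromosome
    5M which carries two closely spaced bumps.
    """
    rng = config.rng(_STAGE_COVERAGE)
    chroms = [f"{c}{s}" for s in ("M", "U") for c in CHROM_NUMBERS]
    n_bins = config.chrom_length_bp // config.depth_bin_bp
    pos = np.arange(n_bins) * config.depth_bin_bp

    da_chroms = [c for c in chroms if c != "6U"]
    da_tables: dict[str, pd.DataFrame] = {}
    for added in da_chroms:
        rows = []
        for chrom in chroms:
            depth = config.da_baseline_depth * (
                config.da_added_fold if chrom == added else 1.0
            ) + rng.normal(0.0, config.da_noise_sd, size=n_bins)
            rows.append(pd.DataFrame({"chrom": chrom, "pos_bin": pos, "depth": np.clip(depth, 0, None)}))
        da_tables[f"DA_{added}"] = pd.concat(rows, ignore_index=True)

    cen_rows = []
    cen_truth = []
    centers = rng.integers(int(0.3 * n_bins), int(0.7 * n_bins), size=len(chroms))
    for chrom, c0 in zip(chroms, centers):
        x = np.arange(n_bins, dtype=float)
        prof = np.full(n_bins, config.cenh3_background)
        if chrom == "5M":
            half = config.cenh3_double_peak_sep_bins // 2
            peak_bins = [c0 - half, c0 + half]
        else:
            peak_bins = [c0]
        for pb in peak_bins:
            prof += config.cenh3_peak_height * np.exp(
                -0.5 * ((x - pb) / config.cenh3_peak_sd_bins) ** 2
            )
            cen_truth.append(
                (chrom, int(pb * config.depth_bin_bp + config.depth_bin_bp // 2))
            )
        prof += rng.normal(0.0, config.cenh3_noise_sd, size=n_bins)
        cen_rows.append(
            pd.DataFrame({"chrom": chrom, "pos_bin": pos, "depth": np.clip(prof, 0, None)})
        )

    truth.da_lines = pd.DataFrame(
        {"line_id": list(da_tables), "added_chrom": da_chroms}
    )
    truth.centromeres = pd.DataFrame(cen_truth, columns=["chrom", "midpoint_bp"])
    return da_tables, pd.concat(cen_rows, ignore_index=True)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class SimDataset:
    config: SimConfig
    truth: TruthTable
    hits_mu: pd.DataFrame
    hits_um: pd.DataFrame
    expression: ExpressionMatrix
    tracks: dict
    peaks: PeakSet
    da_tables: dict
    cenh3: pd.DataFrame


def simulate_all(config: SimConfig) -> SimDataset:
    """Run every generation stage in order and bundle the results."""
    truth = simulate_genome(config)
    hits_mu, hits_um = simulate_hits(truth, config)
    expression = simulate_expression(truth, config)
    tracks, peaks = simulate_chromatin(truth, config, expression)
    da_tables, cenh3 = simulate_window_coverage(truth, config)
    return SimDataset(
        config=config,
        truth=truth,
        hits_mu=hits_mu,
        hits_um=hits_um,
        expression=expression,
        tracks=tracks,
        peaks=peaks,
        da_tables=da_tables,
        cenh3=cenh3,
    )


def write_dataset(data: SimDataset, outdir) -> dict[str, Path]:
    """Write every layer of the dataset to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.gff3",
        "sra": outdir / "sra.bed",
        "hits_mu": outdir / "hits_mu.tsv",
        "hits_um": outdir / "hits_um.tsv",
        "tpm": outdir / "tpm.tsv",
        "track_m": outdir / "h3k4me3_M.bedgraph",
        "track_u": outdir / "h3k4me3_U.bedgraph",
        "peaks": outdir / "peaks.bed",
        "cenh3": outdir / "cenh3.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_dyads": outdir / "truth_dyads.tsv",
    }
    write_gff3(paths["genes"], data.truth.gene_models().values())
    write_sra_regions(paths["sra"], data.truth.sra_regions)
    write_hits_table(paths["hits_mu"], data.hits_mu)
    write_hits_table(paths["hits_um"], data.hits_um)
    write_tpm_matrix(paths["tpm"], data.expression)
    write_bedgraph(paths["track_m"], data.tracks["M"])
    write_bedgraph(paths["track_u"], data.tracks["U"])
    write_bed(paths["peaks"], data.peaks)
    data.cenh3.to_csv(paths["cenh3"], sep="\t", header=False, index=False, float_format="%.4f")
    for line_id, table in data.da_tables.items():
        p = outdir / f"da_line_{line_id[3:]}.tsv"
        table.to_csv(p, sep="\t", header=False, index=False, float_format="%.4f")
        paths[line_id] = p
    write_results(paths["truth_genes"], data.truth.genes)
    write_results(paths["truth_dyads"], data.truth.dyads)
    return paths
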