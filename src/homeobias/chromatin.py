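"""H3K4me3 signal per gene and homoeolog chromatin bias.

The per-gene signal is the area under the fold-enrichment (FE) step function
over the gene body plus 2 kb flanks.  The H3K4me3 Peak Homoeologous Bias of
a dyad is

    HPHB = log2((Area_M + 1e-6) / (Area_U + 1e-6)),

positive when the M-genome copy carries the stronger mark.  Peak presence is
called when any reproducible peak interval overlaps a +/-500 bp window
around the gene's coding start.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GeneModel, PeakSet, SignalTrack

DEFAULT_FLANK = 2000
HPHB_PSEUDOCOUNT = 1e-6


def gene_profile(
    track: SignalTrack,
    gene: GeneModel,
    flank: int = DEFAULT_FLANK,
    body_bins: int = 100,
    flank_bin: int = 20,
    chrom_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned FE profile over upstream flank, gene body and downstream flank.

    The body is rescaled to ``body_bins`` bins (one bin per bp for genes
    shorter than ``body_bins``); flanks use fixed ``flank_bin``-bp bins.
    Each bin holds the length-weighted mean FE over its span; the returned
    weights are the bp covered per bin (reduced where a flank is truncated
    at a chromosome end).  The profile reads in transcription order:
    upstream of a '-' gene is to its right, and the body runs end-to-start.
    """
    if chrom_length is not None and (gene.end > chrom_length or gene.start < 0):
        raise ValueError(f"{gene.gene_id} extends beyond its chromosome")
    n_flank = flank // flank_bin
    nb = min(body_bins, gene.end - gene.start)

    up_edges = gene.start - flank + np.arange(n_flank + 1) * flank_bin
    body_edges = np.linspace(gene.start, gene.end, nb + 1)
    down_edges = gene.end + np.arange(n_flank + 1) * flank_bin
    edges = np.concatenate([up_edges, body_edges[1:-1], down_edges])

    clipped = np.clip(edges, 0, chrom_length if chrom_length is not None else None)
    lo, hi = clipped[:-1], clipped[1:]
    weights = (hi - lo).astype(float)
    areas = track.integrate_many(gene.chrom, lo, hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(weights > 0, areas / weights, 0.0)
    if gene.strand == "-":
        values = values[::-1].copy()
        weights = weights[::-1].copy()
    return values, weights


def fe_area(track: SignalTrack, gene: GeneModel, flank: int = DEFAULT_FLANK) -> float:
    """Area under the FE curve over [start - flank, end + flank), FE*bp."""
    return track.integrate(gene.chrom, max(0, gene.start - flank), gene.end + flank)


def hphb(area_m, area_u, c: float = HPHB_PSEUDOCOUNT):
    """H3K4me3 Peak Homoeologous Bias: log2((Area_M + c) / (Area_U + c)).

    The constant keeps the ratio defined when signal is absent from one or
    both copies.  Antisymmetric: hphb(a, b) == -hphb(b, a).
    """
    m = np.asarray(area_m, dtype=float)
    u = np.asarray(area_u, dtype=float)
    out = np.log2((m + c) / (u + c))
    return out.item() if out.ndim == 0 else out


def peak_presence(
    peaks: PeakSet, gene: GeneModel, window: int = 500, mode: str = "symmetric"
) -> bool:
    """True iff a peak overlaps the window around the coding start.

    ``symmetric``: [cds_start - window, cds_start + window).  ``downstream``:
    the window extends only in transcription direction (H3K4me3 mass sits
    mostly downstream of initiation sites).
    """
    c = gene.cds_start
    if mode == "symmetric":
        lo, hi = c - window, c + window
    elif mode == "downstream":
        lo, hi = (c, c + window) if gene.strand == "+" else (c - window + 1, c + 1)
    else:
        raise ValueError("mode must be 'symmetric' or 'downstream'")
    return peaks.overlaps(gene.chrom, lo, hi)


def gene_chromatin_table(
    tracks: dict[str, SignalTrack],
    peaks: PeakSet,
    genes: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    peak_window: int = 500,
) -> pd.DataFrame:
    """Per-gene FE area, summit FE and peak presence, vectorised.

    ``tracks`` maps subgenome -> SignalTrack; ``genes`` needs gene_id,
    subgenome, chrom, start, end, cds_start columns.  The summit is the
    maximum FE value over the flanked gene window.
    """
    out = []
    for (subg, chrom), sub in genes.groupby(["subgenome", "chrom"], sort=True):
        track = tracks[subg]
        starts = np.clip(sub["start"].to_numpy() - flank, 0, None)
        ends = sub["end"].to_numpy() + flank
        area = track.integrate_many(chrom, starts, ends)
        summit = track.max_over_many(chrom, starts, ends)
        cds = sub["cds_start"].to_numpy()
        has_peak = [
            peaks.overlaps(chrom, c - peak_window, c + peak_window) for c in cds
        ]
        out.append(
            pd.DataFrame(
                {
                    "gene_id": sub["gene_id"].to_numpy(),
                    "fe_area": area,
                    "summit_fe": summit,
                    "peak": has_peak,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def dyad_chromatin_table(
    gene_table: pd.DataFrame, dyads: pd.DataFrame, c: float = HPHB_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-dyad areas, HPHB and peak flags from the per-gene table."""
    g = gene_table.set_index("gene_id")
    am = g["fe_area"].reindex(dyads["m_gene"]).to_numpy()
    au = g["fe_area"].reindex(dyads["u_gene"]).to_numpy()
    out = dyads.copy().reset_index(drop=True)
    out["area_m"] = am
    out["area_u"] = au
    out["hphb"] = hphb(am, au, c)
    out["peak_m"] = g["peak"].reindex(dyads["m_gene"]).to_numpy()
    out["peak_u"] = g["peak"].reindex(dyads["u_gene"]).to_numpy()
    return out
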