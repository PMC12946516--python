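"""Homoeolog dyad identification by iterative reciprocal best hits.

The pairing cycle: filter hits (target coverage >= 90%, identity >= 90%,
e-value <= 1e-5), take each query's best hit by bit score, keep mutual best
pairs, remove all hits involving paired genes, and repeat until a round
yields no new pairs.  Iterating rescues pairs masked in early rounds by a
stronger competing match.

Also prepares structural-rearrangement (SRA) labels: merging nearby
collinear blocks into regions and assigning genes/dyads to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomicInterval, SRARegionSet, logger


@dataclass
class RBHResult:
    dyads: pd.DataFrame  # m_gene, u_gene, round
    unique_m: set
    unique_u: set
    n_rounds: int


def filter_hits(
    hits: pd.DataFrame,
    min_target_coverage: float = 0.90,
    min_identity: float = 90.0,
    max_evalue: float = 1e-5,
) -> pd.DataFrame:
    """Keep hits meeting the coverage/identity/e-value thresholds (inclusive).

    Target coverage is the aligned fraction of the subject gene,
    aln_length / subject_length, evaluated per hit without HSP chaining.
    """
    if (hits["subject_length"] <= 0).any():
        raise ValueError("subject_length must be positive for coverage filtering")
    keep = (
        (hits["aln_length"] / hits["subject_length"] >= min_target_coverage)
        & (hits["pct_identity"] >= min_identity)
        & (hits["e_value"] <= max_evalue)
    )
    return hits[keep]


#: deterministic best-hit ordering: bit score desc, then e-value asc,
#: then identity desc, then subject_id asc
_BEST_ORDER = dict(
    by=["bit_score", "e_value", "pct_identity", "subject_id"],
    ascending=[False, True, False, True],
)


def best_hits(hits: pd.DataFrame) -> pd.Series:
    """Map each query to its single best subject.

    Ties on bit score break by lower e-value, then higher identity, then
    lexicographically smallest subject id.
    """
    if hits.empty:
        return pd.Series(dtype=object)
    ordered = hits.sort_values(**_BEST_ORDER, kind="stable")
    return ordered.groupby("query_id", sort=False)["subject_id"].first()


def reciprocal_best(best_mu: pd.Series, best_um: pd.Series) -> list[tuple[str, str]]:
    """Pairs (m, u) that are each other's top match in both directions."""
    um = best_um.to_dict()
    return [(m, u) for m, u in best_mu.items() if um.get(u) == m]


def iterative_rbh(
    hits_mu: pd.DataFrame,
    hits_um: pd.DataFrame,
    min_target_coverage: float = 0.90,
    min_identity: float = 90.0,
    max_evalue: float = 1e-5,
) -> RBHResult:
    """Run the reciprocal-best-hit cycle to exhaustion.

    Returns the dyads tagged with the round they were found in, the genes
    never paired in either genome, and the number of rounds run (the final,
    empty round included).  Deterministic: ties follow `best_hits`.
    """
    mu = filter_hits(hits_mu, min_target_coverage, min_identity, max_evalue)
    um = filter_hits(hits_um, min_target_coverage, min_identity, max_evalue)

    all_m = set(hits_mu["query_id"]) | set(hits_um["subject_id"])
    all_u = set(hits_um["query_id"]) | set(hits_mu["subject_id"])

    found = []
    n_rounds = 0
    while True:
        n_rounds += 1
        pairs = reciprocal_best(best_hits(mu), best_hits(um))
        if not pairs:
            break
        for m, u in pairs:
            found.append((m, u, n_rounds))
        paired = {g for p in pairs for g in p}
        mu = mu[~mu["query_id"].isin(paired) & ~mu["subject_id"].isin(paired)]
        um = um[~um["query_id"].isin(paired) & ~um["subject_id"].isin(paired)]

    dyads = pd.DataFrame(found, columns=["m_gene", "u_gene", "round"])
    paired_m, paired_u = set(dyads["m_gene"]), set(dyads["u_gene"])
    return RBHResult(
        dyads=dyads,
        unique_m=all_m - paired_m,
        unique_u=all_u - paired_u,
        n_rounds=n_rounds,
    )


def merge_collinear_blocks(blocks, max_gap_bp: int = 10_000_000) -> SRARegionSet:
    """Union blocks on the same chromosome separated by at most ``max_gap_bp``.

    ``blocks`` is an iterable of GenomicInterval (or (chrom, start, end)
    tuples).  Output regions are sorted and non-overlapping.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be non-negative")
    ivs = [
        b if isinstance(b, GenomicInterval) else GenomicInterval(*b) for b in blocks
    ]
    out = SRARegionSet()
    n = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        merged: list[list[int]] = []
        for iv in sorted(by_chrom[chrom], key=lambda i: i.start):
            if merged and iv.start - merged[-1][1] <= max_gap_bp:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        for s, e in merged:
            n += 1
            out.add(GenomicInterval(chrom, s, e), f"SRA{n:02d}")
    return out


def assign_genes_to_regions(genes, sra_regions: SRARegionSet) -> pd.DataFrame:
    """Label each gene by the SRA region containing its midpoint.

    ``genes`` is a mapping gene_id -> GeneModel or a DataFrame with gene_id,
    chrom, start, end columns.  Returns gene_id, region_id (None outside any
    region) and the rearranged/non_rearranged label.  A gene on a chromosome
    absent from the region set is non_rearranged.
    """
    if isinstance(genes, pd.DataFrame):
        rows = [
            (r.gene_id, r.chrom, (r.start + r.end) / 2) for r in genes.itertuples()
        ]
    else:
        rows = [(g.gene_id, g.chrom, g.midpoint) for g in dict(genes).values()]
    out = []
    for gid, chrom, mid in rows:
        rid = sra_regions.region_of(chrom, mid)
        out.append((gid, rid, "rearranged" if rid is not None else "non_rearranged"))
    return pd.DataFrame(out, columns=["gene_id", "region_id", "label"])


def assign_dyads_to_regions(
    dyads: pd.DataFrame, gene_labels: pd.DataFrame
) -> pd.DataFrame:
    """A dyad is rearranged iff either member is; carries the member's region."""
    lab = gene_labels.set_index("gene_id")
    m = lab.reindex(dyads["m_gene"]).reset_index(drop=True)
    u = lab.reindex(dyads["u_gene"]).reset_index(drop=True)
    region = u["region_id"].where(u["region_id"].notna(), m["region_id"])
    rearranged = (m["label"] == "rearranged") | (u["label"] == "rearranged")
    out = dyads.copy().reset_index(drop=True)
    out["region_id"] = region
    out["label"] = np.where(rearranged, "rearranged", "non_rearranged")
    return out
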