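"""Rearranged-vs-control comparisons of expression and chromatin metrics.

Seven metrics are compared between genes/dyads inside structurally
rearranged (SRA) regions and the non-rearranged control: HEB, HPHB and
dominance-category bias (DCB) at the dyad level; TPM, H3K4me3 summit FE,
proportion of expressed genes and H3K4me3 peak status at the gene level.
Continuous metrics use the Kruskal-Wallis rank test (the global table) or
the two-sided Mann-Whitney rank-sum test (per-region); categorical metrics
use a chi-square contingency test.  P-values are Benjamini-Hochberg
adjusted: across the seven metrics for the global table, across regions
within each metric for the per-region analysis.

Note on naming: the per-region comparison is between two independent gene
sets, so the unpaired rank-sum (Mann-Whitney) test is used; a signed-rank
test would require a pairing that does not exist here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import logger

ALPHA_STAR = 0.05
ALPHA_DOUBLE_STAR = 0.01

CONTINUOUS_DYAD_METRICS = ["HEB", "HPHB"]
CONTINUOUS_GENE_METRICS = ["TPM", "H3K4me3_summit"]
CATEGORICAL_METRICS = ["prop_expressed", "DCB", "H3K4me3_status"]
ALL_METRICS = (
    CONTINUOUS_DYAD_METRICS + CONTINUOUS_GENE_METRICS + CATEGORICAL_METRICS
)


class StatisticsError(RuntimeError):
    """A statistical precondition was not met."""


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    Degenerate input (all values identical across groups) gives H=0, p=1.
    """
    if len(groups) == 1 and len(groups[0]) and np.ndim(groups[0][0]) > 0:
        groups = tuple(groups[0])  # called with a list of groups
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatisticsError("kruskal_wallis needs >= 2 non-empty groups")
    try:
        h, p = stats.kruskal(*groups)
    except ValueError:
        return 0.0, 1.0  # all numbers identical
    return float(h), float(p)


def rank_sum(group_a, group_b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank-sum test.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    observations and there are no ties; otherwise the normal approximation
    with tie correction and no continuity correction, which makes the
    two-group Kruskal-Wallis decision and the rank-sum decision coincide.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatisticsError("rank_sum needs non-empty groups")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(a) <= exact_max_n and len(b) <= exact_max_n and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def proportion_test(*args) -> tuple[float, float]:
    """Chi-square test of independence without continuity correction.

    Call as ``proportion_test(k1, n1, k2, n2)`` for a 2x2 comparison of two
    proportions, or pass a 2xk contingency table (counts per category in
    each group) directly.  Expected cells below 1 produce a warning but the
    p-value is still returned; a degenerate table (zero row/column) gives
    (0, 1).
    """
    if len(args) == 4:
        k1, n1, k2, n2 = args
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    elif len(args) == 1:
        table = np.asarray(args[0], dtype=float)
    else:
        raise TypeError("pass (k1, n1, k2, n2) or a contingency table")
    if (table < 0).any():
        raise ValueError("negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        logger.warning("chi-square expected cell below 1; p-value unreliable")
    return float(chi2), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# metric extraction
# ---------------------------------------------------------------------------


def _stars(p: float) -> str:
    if p <= ALPHA_DOUBLE_STAR:
        return "**"
    if p <= ALPHA_STAR:
        return "*"
    return "ns"


def _direction(a, b) -> str:
    """Sign of the rearranged-minus-control median difference."""
    if len(a) == 0 or len(b) == 0:
        return "none"
    d = np.nanmedian(b) - np.nanmedian(a)
    return "up" if d > 0 else ("down" if d < 0 else "none")


def _metric_values(metric, gene_metrics, dyad_metrics, mask_gene, mask_dyad):
    """(control_values, rearranged_values) or contingency counts for a metric."""
    if metric == "HEB":
        v = dyad_metrics["heb"]
        return v[~mask_dyad].dropna().to_numpy(), v[mask_dyad].dropna().to_numpy()
    if metric == "HPHB":
        v = dyad_metrics["hphb"]
        return v[~mask_dyad].dropna().to_numpy(), v[mask_dyad].dropna().to_numpy()
    if metric == "TPM":
        v = gene_metrics["global_tpm"]
        return v[~mask_gene].dropna().to_numpy(), v[mask_gene].dropna().to_numpy()
    if metric == "H3K4me3_summit":
        v = gene_metrics["summit_fe"]
        return v[~mask_gene].dropna().to_numpy(), v[mask_gene].dropna().to_numpy()
    raise KeyError(metric)


def _metric_table(metric, gene_metrics, dyad_metrics, mask_gene, mask_dyad):
    if metric == "prop_expressed":
        flag = gene_metrics["expressed"].astype(bool)
        groups = [~mask_gene, mask_gene]
        return np.array(
            [[int(flag[g].sum()), int((~flag[g]).sum())] for g in groups]
        )
    if metric == "H3K4me3_status":
        flag = gene_metrics["peak"].astype(bool)
        groups = [~mask_gene, mask_gene]
        return np.array(
            [[int(flag[g].sum()), int((~flag[g]).sum())] for g in groups]
        )
    if metric == "DCB":
        cats = ["balanced", "M_dominant", "U_dominant"]
        dom = dyad_metrics["dominance"]
        return np.array(
            [
                [int((dom[g] == c).sum()) for c in cats]
                for g in [~mask_dyad, mask_dyad]
            ]
        )
    raise KeyError(metric)


@dataclass
class ComparisonResult:
    metric: str
    scope: str
    n_control: int
    n_rearranged: int
    statistic: float
    p_raw: float
    p_adj: float = np.nan
    direction: str = "none"
    significant: bool = False
    stars: str = "ns"
    low_n: bool = False


def _results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# global and per-region comparisons
# ---------------------------------------------------------------------------


def compare_global(
    gene_metrics: pd.DataFrame,
    dyad_metrics: pd.DataFrame,
    alpha: float = ALPHA_STAR,
    categorical_test: str = "chi2",
) -> pd.DataFrame:
    """Compare all seven metrics between rearranged and control groups.

    ``gene_metrics`` needs label, global_tpm, expressed, summit_fe, peak;
    ``dyad_metrics`` needs label, heb, hphb, dominance.  Continuous metrics
    use Kruskal-Wallis; categorical ones the chi-square contingency test
    (``categorical_test='kw_codes'`` instead ranks integer-encoded
    categories with Kruskal-Wallis — statistically ill-posed for unordered
    categories, offered only for strict mimicry of rank-test-only reports).
    The seven p-values are BH-adjusted as one family.
    """
    mask_gene = _label_mask(gene_metrics, "gene")
    mask_dyad = _label_mask(dyad_metrics, "dyad")

    results = []
    for metric in ALL_METRICS:
        dyad_level = metric in ("HEB", "HPHB", "DCB")
        mask = mask_dyad if dyad_level else mask_gene
        n_ctl, n_sra = int((~mask).sum()), int(mask.sum())
        if n_ctl == 0 or n_sra == 0:
            raise StatisticsError(
                f"metric {metric}: a comparison group is empty "
                f"(control={n_ctl}, rearranged={n_sra})"
            )
        if metric in CATEGORICAL_METRICS:
            table = _metric_table(metric, gene_metrics, dyad_metrics, mask_gene, mask_dyad)
            if categorical_test == "kw_codes":
                groups = [np.repeat(np.arange(table.shape[1]), row) for row in table]
                stat, p = kruskal_wallis(*groups)
            elif categorical_test == "chi2":
                stat, p = proportion_test(table)
            else:
                raise ValueError("categorical_test must be 'chi2' or 'kw_codes'")
            if metric == "DCB":
                direction = "none"
            else:
                r_ctl = table[0, 0] / table[0].sum()
                r_sra = table[1, 0] / table[1].sum()
                direction = "up" if r_sra > r_ctl else ("down" if r_sra < r_ctl else "none")
        else:
            ctl, sra = _metric_values(metric, gene_metrics, dyad_metrics, mask_gene, mask_dyad)
            stat, p = kruskal_wallis(ctl, sra)
            direction = _direction(ctl, sra)
        results.append(
            ComparisonResult(
                metric=metric,
                scope="global",
                n_control=n_ctl,
                n_rearranged=n_sra,
                statistic=stat,
                p_raw=p,
                direction=direction,
            )
        )
    _adjust(results, alpha)
    return _results_frame(results)


def compare_per_region(
    gene_metrics: pd.DataFrame,
    dyad_metrics: pd.DataFrame,
    alpha: float = ALPHA_STAR,
    min_dyads: int = 5,
) -> pd.DataFrame:
    """Each SRA region against the pooled non-rearranged control.

    Continuous metrics use the rank-sum test, categorical the chi-square
    test; BH adjustment runs across regions within each metric.  Regions
    with fewer than ``min_dyads`` dyads are flagged low_n but still tested.
    Requires region_id columns on both metric tables.
    """
    mask_gene = _label_mask(gene_metrics, "gene")
    mask_dyad = _label_mask(dyad_metrics, "dyad")
    regions = sorted(
        set(gene_metrics.loc[mask_gene, "region_id"].dropna())
        | set(dyad_metrics.loc[mask_dyad, "region_id"].dropna())
    )

    all_results = []
    for metric in ALL_METRICS:
        dyad_level = metric in ("HEB", "HPHB", "DCB")
        per_metric = []
        for rid in regions:
            g_mask = gene_metrics["region_id"] == rid
            d_mask = dyad_metrics["region_id"] == rid
            mask = d_mask if dyad_level else g_mask
            low_n = int(d_mask.sum()) < min_dyads
            if metric in CATEGORICAL_METRICS:
                table = _metric_table(
                    metric,
                    gene_metrics,
                    dyad_metrics,
                    g_mask if not dyad_level else mask_gene,
                    d_mask if dyad_level else mask_dyad,
                )
                # control row must be the pooled non-rearranged group
                table_ctl = _metric_table(metric, gene_metrics, dyad_metrics, mask_gene, mask_dyad)
                table = np.vstack([table_ctl[0], table[1]])
                stat, p = proportion_test(table)
                if metric == "DCB":
                    direction = "none"
                else:
                    r_ctl = table[0, 0] / max(table[0].sum(), 1)
                    r_sra = table[1, 0] / max(table[1].sum(), 1)
                    direction = "up" if r_sra > r_ctl else ("down" if r_sra < r_ctl else "none")
                n_ctl, n_sra = int(table[0].sum()), int(table[1].sum())
            else:
                if dyad_level:
                    ctl, _ = _metric_values(metric, gene_metrics, dyad_metrics, mask_gene, mask_dyad)
                    v = dyad_metrics["heb" if metric == "HEB" else "hphb"]
                    sra = v[d_mask].dropna().to_numpy()
                else:
                    ctl, _ = _metric_values(metric, gene_metrics, dyad_metrics, mask_gene, mask_dyad)
                    col = "global_tpm" if metric == "TPM" else "summit_fe"
                    sra = gene_metrics.loc[g_mask, col].dropna().to_numpy()
                if len(sra) == 0:
                    continue
                stat, p = rank_sum(ctl, sra)
                direction = _direction(ctl, sra)
                n_ctl, n_sra = len(ctl), len(sra)
            per_metric.append(
                ComparisonResult(
                    metric=metric,
                    scope=str(rid),
                    n_control=n_ctl,
                    n_rearranged=n_sra,
                    statistic=stat,
                    p_raw=p,
                    direction=direction,
                    low_n=low_n,
                )
            )
        _adjust(per_metric, alpha)
        all_results.extend(per_metric)
    return _results_frame(all_results)


def _label_mask(frame: pd.DataFrame, kind: str) -> pd.Series:
    if "label" not in frame:
        raise StatisticsError(f"{kind} metrics table lacks a 'label' column")
    mask = frame["label"] == "rearranged"
    return mask


def _adjust(results: list[ComparisonResult], alpha: float):
    if not results:
        return
    adj = bh_adjust([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
        r.significant = pa <= alpha
        r.stars = _stars(pa)
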