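"""Expression filtering, CV classification, and homoeolog expression bias.

A gene is *expressed* in a tissue when its TPM is at least 1, and *retained*
for analysis when its cumulative TPM across tissues is at least 10.  The
global TPM of a retained gene is the mean over the tissues in which it is
expressed.

For a dyad (an M/U homoeologous pair) in a tissue:

    HEB       = log2(TPM_M / TPM_U)          (silenced copy -> 1e-6)
    normTPM_M = TPM_M / (TPM_M + TPM_U), normTPM_U = 1 - normTPM_M

and the dyad is assigned the dominance class whose expected ratio —
balanced (0.5, 0.5), M-dominant (1, 0), U-dominant (0, 1) — is nearest in
Euclidean distance, which reduces to thresholds at normTPM_M = 0.25 / 0.75
(exact boundary values fall to `balanced`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, logger

#: TPM assigned to a silenced homoeolog so log-ratios stay finite
SILENCED_TPM = 1e-6

CV_CONSERVED_MAX = 0.35
CV_VARIABLE_MIN = 1.0


def filter_expressed(matrix: ExpressionMatrix, min_cumulative: float = 10.0) -> pd.Index:
    """Genes whose cumulative TPM across tissues is >= ``min_cumulative``."""
    retained = matrix.retained(min_cumulative)
    return matrix.genes[retained]


def global_tpm(matrix: ExpressionMatrix) -> pd.Series:
    """Mean TPM over the tissues where each gene is expressed (TPM >= 1).

    Genes expressed in no tissue get 0 (silenced).
    """
    tpm = matrix.tpm
    expr = matrix.expressed
    n = expr.sum(axis=1)
    total = tpm.where(expr, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = total / n
    return out.fillna(0.0)


def cv_classify(matrix: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Coefficient of variation of TPM across all tissues, with classes.

    CV = sd/mean with the n-1 (sample) sd, zeros included.  Classes:
    conserved (CV < 0.35), intermediate (0.35 <= CV <= 1), highly variable
    (CV > 1); the printed boundaries are strict, so exact boundary values
    close onto the middle class.  Genes with mean 0 are excluded.
    """
    tpm = matrix.tpm if genes is None else matrix.tpm.loc[genes]
    mean = tpm.mean(axis=1)
    sd = tpm.std(axis=1, ddof=1)
    zero = mean == 0
    if zero.any():
        logger.warning("%d genes with zero mean TPM excluded from CV", int(zero.sum()))
    mean, sd = mean[~zero], sd[~zero]
    cv = sd / mean
    cls = pd.Series(
        np.where(
            cv < CV_CONSERVED_MAX,
            "conserved",
            np.where(cv > CV_VARIABLE_MIN, "highly_variable", "intermediate"),
        ),
        index=cv.index,
    )
    return pd.DataFrame(
        {"mean_tpm": mean, "sd_tpm": sd, "cv": cv, "cv_class": cls}
    ).rename_axis("gene_id")


def heb(tpm_m, tpm_u, silenced_value: float = SILENCED_TPM, expressed_tpm: float = 1.0):
    """Homoeolog expression bias log2(TPM_M / TPM_U).

    A copy below the expression threshold counts as silenced and is replaced
    by ``silenced_value`` so the ratio stays finite; positive values mean
    M-biased expression.  When both copies are silenced the bias is
    undefined and NaN is returned (such dyads are excluded upstream).
    """
    m = np.asarray(tpm_m, dtype=float)
    u = np.asarray(tpm_u, dtype=float)
    both_off = (m < expressed_tpm) & (u < expressed_tpm)
    m = np.where(m < expressed_tpm, silenced_value, m)
    u = np.where(u < expressed_tpm, silenced_value, u)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(m / u)
    out = np.where(both_off, np.nan, out)
    return out.item() if out.ndim == 0 else out


def norm_tpm(tpm_m, tpm_u):
    """Within-dyad expression proportions (normTPM_M, normTPM_U).

    Scale-invariant; NaN for dyads with zero total expression.
    """
    m = np.asarray(tpm_m, dtype=float)
    u = np.asarray(tpm_u, dtype=float)
    total = m + u
    with np.errstate(divide="ignore", invalid="ignore"):
        pm = np.where(total > 0, m / total, np.nan)
    pu = 1.0 - pm
    if pm.ndim == 0:
        return pm.item(), pu.item()
    return pm, pu


_EXPECTED = {"balanced": (0.5, 0.5), "M_dominant": (1.0, 0.0), "U_dominant": (0.0, 1.0)}


def classify_dominance(p_m, p_u=None):
    """Dominance class by shortest Euclidean distance to the expected ratios.

    Ties (normTPM_M exactly 0.25 or 0.75) resolve to `balanced`.  Accepts
    scalars or arrays; NaN input gives NaN class (None for scalars).
    """
    pm = np.asarray(p_m, dtype=float)
    if p_u is not None and not np.allclose(
        pm + np.asarray(p_u, dtype=float), 1.0, equal_nan=True
    ):
        raise ValueError("normTPM proportions must sum to 1")
    # nearest-centroid in (p_m, p_u) space reduces to thresholds on p_m
    out = np.where(
        np.isnan(pm),
        None,
        np.where(pm > 0.75, "M_dominant", np.where(pm < 0.25, "U_dominant", "balanced")),
    )
    return out.item() if out.ndim == 0 else out


def dyad_expression_table(matrix: ExpressionMatrix, dyads: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad, per-tissue expression bias table (long format).

    One row per dyad and tissue with TPM_M, TPM_U, HEB, normTPM_M/U,
    dominance and status (both_expressed / M_only / U_only / silenced).
    HEB, normTPM and dominance are only defined in tissues where at least
    one homoeolog is expressed; elsewhere they are NaN.
    """
    tissues = matrix.tissues
    m = matrix.tpm.reindex(dyads["m_gene"]).to_numpy()
    u = matrix.tpm.reindex(dyads["u_gene"]).to_numpy()
    em = m >= ExpressionMatrix.EXPRESSED_TPM
    eu = u >= ExpressionMatrix.EXPRESSED_TPM

    heb_v = heb(m, u)
    pm, pu = norm_tpm(m, u)
    any_expr = em | eu
    pm = np.where(any_expr, pm, np.nan)
    pu = np.where(any_expr, pu, np.nan)
    dom = classify_dominance(np.where(any_expr, pm, np.nan))
    status = np.where(
        em & eu, "both_expressed", np.where(em, "M_only", np.where(eu, "U_only", "silenced"))
    )

    nt = len(tissues)
    nd = len(dyads)
    long = pd.DataFrame(
        {
            "dyad_id": np.repeat(dyads["dyad_id"].to_numpy() if "dyad_id" in dyads else dyads.index.to_numpy(), nt),
            "m_gene": np.repeat(dyads["m_gene"].to_numpy(), nt),
            "u_gene": np.repeat(dyads["u_gene"].to_numpy(), nt),
            "tissue": np.tile(tissues, nd),
            "TPM_M": m.ravel(),
            "TPM_U": u.ravel(),
            "HEB": heb_v.ravel(),
            "normTPM_M": pm.ravel(),
            "normTPM_U": pu.ravel(),
            "dominance": dom.ravel(),
            "status": status.ravel(),
        }
    )
    return long


def dyad_global_table(matrix: ExpressionMatrix, dyads: pd.DataFrame) -> pd.DataFrame:
    """Dyad-level summary from global TPMs.

    Columns: global TPMs, expressed flags, global HEB / normTPM / dominance,
    and a status splitting dyads into both_expressed / M_only / U_only /
    silenced.  Both-silenced dyads carry NaN bias values.
    """
    gt = global_tpm(matrix)
    m = gt.reindex(dyads["m_gene"]).to_numpy()
    u = gt.reindex(dyads["u_gene"]).to_numpy()
    em = m >= ExpressionMatrix.EXPRESSED_TPM
    eu = u >= ExpressionMatrix.EXPRESSED_TPM
    any_expr = em | eu

    heb_v = heb(m, u)
    pm, _ = norm_tpm(m, u)
    pm = np.where(any_expr, pm, np.nan)
    out = dyads.copy().reset_index(drop=True)
    out["global_tpm_m"] = m
    out["global_tpm_u"] = u
    out["expressed_m"] = em
    out["expressed_u"] = eu
    out["heb"] = heb_v
    out["norm_tpm_m"] = pm
    out["dominance"] = classify_dominance(pm)
    out["status"] = np.where(
        em & eu, "both_expressed", np.where(em, "M_only", np.where(eu, "U_only", "silenced"))
    )
    return out
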