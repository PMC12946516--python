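"""Stable / intermediate / dynamic dyad classification (CMD deciles).

For each dyad, the tissue-level homoeolog proportion vector
(normTPM_M, normTPM_U) is compared with the dyad's global proportion vector
(computed from global TPMs); the coefficient of mean distance (CMD) is the
mean Euclidean distance over the tissues where the dyad is expressed.  Dyads
are ranked by CMD and cut into deciles: the first two deciles are `stable`,
the last two `dynamic`, the middle six `intermediate`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import global_tpm, norm_tpm
from .io import ExpressionMatrix

CLASS_BY_DECILE = {0: "stable", 1: "stable", 8: "dynamic", 9: "dynamic"}


def tissue_distance(tissue_ratio, global_ratio) -> float:
    """Euclidean distance between two (normTPM_M, normTPM_U) vectors.

    Ranges from 0 (tissue bias equals the global bias) to sqrt(2) (complete
    reversal of a fully dominant dyad).
    """
    t = np.asarray(tissue_ratio, dtype=float)
    g = np.asarray(global_ratio, dtype=float)
    return float(np.sqrt(np.sum((t - g) ** 2)))


def cmd(tissue_ratios, global_ratio) -> float:
    """Mean of the per-tissue distances (the dyad's CMD), in [0, sqrt(2)]."""
    d = [tissue_distance(t, global_ratio) for t in tissue_ratios]
    if not d:
        raise ValueError("CMD undefined: dyad expressed in no tissue")
    return float(np.mean(d))


def cmd_table(matrix: ExpressionMatrix, dyads: pd.DataFrame) -> pd.DataFrame:
    """CMD per dyad, vectorised over the dyad table.

    Tissues where neither homoeolog is expressed are skipped; dyads with no
    expressed tissue (or an undefined global ratio) are excluded.
    """
    gt = global_tpm(matrix)
    m = matrix.tpm.reindex(dyads["m_gene"]).to_numpy()
    u = matrix.tpm.reindex(dyads["u_gene"]).to_numpy()
    gm = gt.reindex(dyads["m_gene"]).to_numpy()
    gu = gt.reindex(dyads["u_gene"]).to_numpy()

    expressed = (m >= ExpressionMatrix.EXPRESSED_TPM) | (u >= ExpressionMatrix.EXPRESSED_TPM)
    with np.errstate(divide="ignore", invalid="ignore"):
        pm_t = m / (m + u)  # per-tissue M proportion
        pm_g = gm / (gm + gu)  # global M proportion
    # distance between 2-vectors (p, 1-p) is sqrt(2)*|delta p|
    d = np.sqrt(2.0) * np.abs(pm_t - pm_g[:, None])
    d = np.where(expressed & np.isfinite(d), d, np.nan)

    n_used = np.sum(~np.isnan(d), axis=1)
    cmd_v = np.where(
        n_used > 0, np.nansum(np.where(np.isnan(d), 0.0, d), axis=1) / np.maximum(n_used, 1), np.nan
    )

    ids = dyads["dyad_id"] if "dyad_id" in dyads else dyads.index
    out = pd.DataFrame(
        {"dyad_id": np.asarray(ids), "cmd": cmd_v, "n_tissues_used": n_used}
    )
    return out[out["n_tissues_used"] > 0].reset_index(drop=True)


def classify_dynamics(cmds: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Rank dyads by CMD (ascending) and classify by decile.

    decile = floor(10 * (rank - 1) / n) with rank ties broken by dyad_id for
    determinism; deciles {0, 1} are stable, {8, 9} dynamic, the rest
    intermediate.  With n divisible by 10 the split is exactly 20/60/20.
    Requires at least 10 dyads.
    """
    if isinstance(cmds, pd.Series):
        df = pd.DataFrame({"dyad_id": cmds.index, "cmd": cmds.to_numpy()})
    else:
        df = cmds[["dyad_id", "cmd"]].copy()
    n = len(df)
    if n < 10:
        raise ValueError(f"decile classification needs >= 10 dyads, got {n}")
    df = df.sort_values(["cmd", "dyad_id"], kind="stable").reset_index(drop=True)
    rank = np.arange(1, n + 1)
    decile = (10 * (rank - 1)) // n
    df["rank"] = rank
    df["decile"] = decile
    df["dynamics_class"] = [CLASS_BY_DECILE.get(d, "intermediate") for d in decile]
    return df
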