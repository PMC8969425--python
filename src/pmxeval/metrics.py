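"""Prediction-based evaluation statistics.

Observed concentrations are compared with population predictions through
four pooled statistics (observations indexed directly, no per-subject
averaging):

    PE   = mean(PRED - OBS)                      [nmol/mL]
    RMSE = sqrt(mean((PRED - OBS)^2))            [nmol/mL]
    MPE  = 100 * mean((PRED - OBS) / OBS)        [%]
    MAPE = 100 * mean(|PRED - OBS| / OBS)        [%]

The sign convention is prediction minus observation throughout: positive
PE/MPE means the model over-predicts on average.  An optional log-scale
variant applies the same formulas to log-transformed values (for models
whose residual error lives on the log scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["prediction_metrics", "metrics_table", "rank_models"]


def prediction_metrics(obs, pred, log_scale: bool = False) -> dict[str, float]:
    """PE, RMSE, MPE and MAPE for one pooled set of observations.

    ``obs`` must be strictly positive (below-quantification records are
    excluded upstream).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    bad = np.nonzero(~(obs > 0))[0]
    if len(bad):
        raise ValueError(f"non-positive observation at record(s) {bad.tolist()}")
    if log_scale:
        if np.any(pred <= 0):
            raise ValueError("log-scale metrics require positive predictions")
        err = np.log(pred) - np.log(obs)
        # log differences are already relative errors; no further scaling
        rel = err
    else:
        err = pred - obs
        rel = err / obs
    return {
        "n": int(len(obs)),
        "pe": float(np.mean(err)),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mpe": float(100.0 * np.mean(rel)),
        "mape": float(100.0 * np.mean(np.abs(rel))),
    }


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy table (model, analyte, N, PE, RMSE, MPE, MAPE) from row dicts."""
    df = pd.DataFrame(rows, columns=["model", "analyte", "n", "pe", "rmse", "mpe", "mape"])
    return df


def rank_models(table: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte ranks by RMSE (precision) and |MPE| (bias)."""
    out = table.copy()
    out["rank_rmse"] = out.groupby("analyte")["rmse"].rank(method="min").astype(int)
    out["rank_bias"] = (
        out.groupby("analyte")["mpe"].transform(lambda s: s.abs().rank(method="min")).astype(int)
    )
    return out.sort_values(["analyte", "rank_rmse"]).reset_index(drop=True)
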