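"""Prediction-corrected visual predictive checks (pcVPC).

Observed and simulated concentrations are rescaled within each time bin by
``bin-median PRED / record PRED`` (prediction correction), which removes
the variability that differing doses and covariates would otherwise smear
across a bin.  The simulated prediction band in each bin is the 2.5th to
97.5th percentile of the pooled corrected simulated values (a 95%
prediction interval for concentrations); observations falling strictly
outside their bin's band are counted and reported as a percentage rounded
half away from zero to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SimulationEnsemble

__all__ = [
    "assign_bins",
    "prediction_correct",
    "vpc_bands",
    "outside_percentage",
    "round_half_away",
    "VpcResult",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with halves away from zero (so 11.65 -> 11.7 at 1 decimal)."""
    scale = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale)


def outside_percentage(count: int, total: int) -> float:
    """Percentage of observations outside the band, one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must be within [0, total]")
    return round_half_away(100.0 * count / total, 1)


def assign_bins(times, n_bins: int = 8, strategy: str = "quantile", edges=None):
    """Bin labels on time after first dose.

    ``quantile`` places cut points at empirical quantiles for near-equal
    occupancy; ``fixed-edges`` uses the supplied interior ``edges``.  A
    record whose time equals a cut point goes to the lower bin.  When there
    are fewer distinct times than bins the duplicate cuts are merged with a
    warning.

    Returns ``(labels, cuts)`` with labels in ``0..len(cuts)``.
    """
    times = np.asarray(times, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if strategy == "fixed-edges":
        cuts = np.asarray(edges if edges is not None else [], dtype=float)
    elif strategy == "quantile":
        if n_bins == 1 or len(times) == 0:
            cuts = np.array([])
        else:
            qs = np.arange(1, n_bins) / n_bins
            cuts = np.unique(np.quantile(times, qs))
            if len(cuts) < n_bins - 1:
                warnings.warn(
                    "fewer distinct times than requested bins; bins merged",
                    stacklevel=2,
                )
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")
    labels = np.searchsorted(cuts, times, side="left")
    return labels, cuts


def prediction_correct(values, pred, labels):
    """Rescale values by bin-median PRED over record PRED.

    ``values`` may be (n,) observed or (K, n) simulated; the same
    correction factor applies to every replicate of a record.
    """
    values = np.asarray(values, dtype=float)
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels)
    if np.any(pred <= 0):
        raise ValueError("prediction correction requires strictly positive PRED")
    med = np.empty_like(pred)
    for b in np.unique(labels):
        mask = labels == b
        med[mask] = np.median(pred[mask])
    factor = med / pred
    return values * factor


@dataclass
class VpcResult:
    """Binned pcVPC summary for one analyte."""

    analyte: str
    cuts: np.ndarray
    labels: np.ndarray
    bin_table: pd.DataFrame
    outside: np.ndarray
    n_outside: int
    n_total: int
    pct_outside: float
    corrected_obs: np.ndarray
    prediction_corrected: bool = True

    def flagged_records(self, records: pd.DataFrame) -> pd.DataFrame:
        out = records.copy().reset_index(drop=True)
        out["bin"] = self.labels
        out["corrected"] = self.corrected_obs
        out["outside"] = self.outside
        return out[out["outside"]]


def vpc_bands(
    obs_values,
    obs_times,
    pred,
    sims,
    n_bins: int = 8,
    correct: bool = True,
    band=(2.5, 97.5),
    obs_percentiles=(5.0, 50.0, 95.0),
    analyte: str = "",
    max_time: float | None = None,
) -> VpcResult:
    """pcVPC bands and outside-band counts for one analyte.

    ``sims`` is the (K, n) simulated ensemble slice aligned to the
    observation vectors.  ``max_time`` optionally drops very late samples
    from binning and counting (both inclusion modes are valid).
    """
    obs_values = np.asarray(obs_values, dtype=float)
    obs_times = np.asarray(obs_times, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sims = np.asarray(sims, dtype=float)
    if sims.ndim != 2 or sims.shape[1] != len(obs_values):
        raise ValueError("simulated ensemble not aligned to observations")
    if sims.shape[0] < 2:
        raise ValueError("pcVPC needs at least 2 simulation replicates")
    if max_time is not None:
        keep = obs_times <= max_time
        obs_values, obs_times = obs_values[keep], obs_times[keep]
        pred, sims = pred[keep], sims[:, keep]
    n = len(obs_values)
    if n == 0:
        raise ValueError("no observations to bin")

    labels, cuts = assign_bins(obs_times, n_bins=n_bins)
    if correct:
        cobs = prediction_correct(obs_values, pred, labels)
        csim = prediction_correct(sims, pred, labels)
    else:
        cobs, csim = obs_values, sims

    rows = []
    outside = np.zeros(n, dtype=bool)
    for b in range(len(cuts) + 1):
        mask = labels == b
        if not mask.any():
            raise ValueError(f"empty bin {b}")
        pool = csim[:, mask].ravel()
        lo, hi = np.percentile(pool, band)
        obs_p = np.percentile(cobs[mask], obs_percentiles)
        outside[mask] = (cobs[mask] < lo) | (cobs[mask] > hi)
        rows.append(
            {
                "bin": b,
                "t_lo": float(obs_times[mask].min()),
                "t_hi": float(obs_times[mask].max()),
                "n": int(mask.sum()),
                "sim_lo": float(lo),
                "sim_hi": float(hi),
                **{f"obs_p{int(p)}": float(v) for p, v in zip(obs_percentiles, obs_p)},
            }
        )
    n_out = int(outside.sum())
    return VpcResult(
        analyte=analyte,
        cuts=cuts,
        labels=labels,
        bin_table=pd.DataFrame(rows),
        outside=outside,
        n_outside=n_out,
        n_total=n,
        pct_outside=outside_percentage(n_out, n),
        corrected_obs=cobs,
        prediction_corrected=correct,
    )


def vpc_for_analyte(
    ensemble: SimulationEnsemble,
    records: pd.DataFrame,
    pred: np.ndarray,
    analyte: str,
    quantifiable: np.ndarray,
    **kwargs,
) -> VpcResult:
    """Convenience wrapper slicing one analyte's quantifiable records."""
    mask = ((records["analyte"] == analyte).to_numpy()) & quantifiable
    idx = np.nonzero(mask)[0]
    return vpc_bands(
        records["value"].to_numpy()[idx],
        records["time"].to_numpy()[idx],
        np.asarray(pred)[idx],
        ensemble.values[:, idx],
        analyte=analyte,
        **kwargs,
    )


def plot_vpc(result: VpcResult, path, log_scale: bool = True):
    """Write a standard pcVPC figure (band, observed percentiles, points)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    bt = result.bin_table
    mid = 0.5 * (bt["t_lo"] + bt["t_hi"])
    ax.fill_between(mid, bt["sim_lo"], bt["sim_hi"], color="0.8", label="95% PI (sim)")
    for col, style in (("obs_p5", "--"), ("obs_p50", "-"), ("obs_p95", "--")):
        if col in bt:
            ax.plot(mid, bt[col], style, color="tab:blue")
    ax.set_xlabel("time after first dose (h)")
    ax.set_ylabel("prediction-corrected concentration (nmol/mL)")
    if log_scale:
        ax.set_yscale("log")
    ax.set_title(f"pcVPC {result.analyte} ({result.pct_outside}% outside)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
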