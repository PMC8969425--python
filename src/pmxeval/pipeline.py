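"""End-to-end external-evaluation pipeline.

For each model under evaluation: population predictions and the pooled
prediction-based statistics (PE/RMSE/MPE/MAPE), empirical-Bayes fits and
CWRES for goodness-of-fit tables, a K-replicate simulation ensemble, the
prediction-corrected VPC with outside-band counts, and the NPDE with its
three adequacy tests.  Models are evaluated independently: a failure in
one model's branch is recorded and does not abort the run.  P-values are
reported per model without cross-model multiplicity adjustment (the
comparison across models is descriptive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import bql_filter
from .estimate import compute_cwres, fit_dataset, pred_for_dataset
from .metrics import metrics_table, prediction_metrics, rank_models
from .models import PopulationModel, StudyDataset
from .npde import NpdeTests, compute_npde, npde_tests
from .simulate import simulate_ensemble
from .vpc import VpcResult, vpc_bands

__all__ = ["ModelReport", "EvaluationReport", "run_evaluation"]

log = logging.getLogger(__name__)


@dataclass
class ModelReport:
    label: str
    metrics: pd.DataFrame
    gof: pd.DataFrame
    vpc: dict[str, VpcResult] = field(default_factory=dict)
    npde: dict[str, pd.DataFrame] = field(default_factory=dict)
    npde_tests: dict[str, NpdeTests] = field(default_factory=dict)
    error: str | None = None


@dataclass
class EvaluationReport:
    reports: list[ModelReport]
    comparison: pd.DataFrame
    excluded_bql: dict[str, int]

    def report_for(self, label: str) -> ModelReport:
        for r in self.reports:
            if r.label == label:
                return r
        raise KeyError(label)

    def write(self, out_dir) -> None:
        """Write all tables as CSV under out_dir (deterministic layout)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        all_metrics = pd.concat([r.metrics for r in self.reports if r.error is None])
        all_metrics.to_csv(out / "metrics.csv", index=False, float_format=fmt)
        self.comparison.to_csv(out / "comparison.csv", index=False, float_format=fmt)
        for r in self.reports:
            if r.error is not None:
                (out / f"error_{r.label}.txt").write_text(r.error + "\n")
                continue
            r.gof.to_csv(out / f"gof_{r.label}.csv", index=False, float_format=fmt)
            for analyte, v in r.vpc.items():
                tag = analyte.replace("/", "_").replace(" ", "_")
                v.bin_table.to_csv(
                    out / f"vpc_{r.label}_{tag}.csv", index=False, float_format=fmt
                )
            for analyte, tab in r.npde.items():
                tag = analyte.replace("/", "_").replace(" ", "_")
                tab.to_csv(
                    out / f"npde_{r.label}_{tag}.csv", index=False, float_format=fmt
                )
        rows = []
        for r in self.reports:
            for analyte, v in r.vpc.items():
                rows.append(
                    {
                        "model": r.label,
                        "analyte": analyte,
                        "n": v.n_total,
                        "n_outside": v.n_outside,
                        "pct_outside": v.pct_outside,
                    }
                )
        pd.DataFrame(rows, columns=["model", "analyte", "n", "n_outside", "pct_outside"]).to_csv(
            out / "vpc_summary.csv", index=False, float_format=fmt
        )
        nrows = [
            {
                "model": r.label,
                "analyte": analyte,
                "n": t.n,
                "mean": t.mean,
                "variance": t.variance,
                "t_pvalue": t.t_pvalue,
                "variance_pvalue": t.variance_pvalue,
                "shapiro_pvalue": t.shapiro_pvalue,
                "global_reject": t.global_reject,
            }
            for r in self.reports
            for analyte, t in r.npde_tests.items()
        ]
        pd.DataFrame(
            nrows,
            columns=[
                "model",
                "analyte",
                "n",
                "mean",
                "variance",
                "t_pvalue",
                "variance_pvalue",
                "shapiro_pvalue",
                "global_reject",
            ],
        ).to_csv(out / "npde_summary.csv", index=False, float_format=fmt)


def _evaluate_one(
    model: PopulationModel,
    dataset: StudyDataset,
    K: int,
    seed: int,
    n_bins: int,
    mixture_handling: str,
    max_time: float | None,
) -> ModelReport:
    # a parent-only model is evaluated on parent records only
    dataset = dataset.subset_analytes({a.name for a in model.analytes})
    records = dataset.observation_records()
    quant = ~records["bql"].to_numpy()
    pred = pred_for_dataset(dataset=dataset, model=model, mixture_handling=mixture_handling)

    metric_rows = []
    for analyte in model.analytes:
        mask = (records["analyte"] == analyte.name).to_numpy() & quant
        if not mask.any():
            continue
        row = prediction_metrics(
            records["value"].to_numpy()[mask], np.asarray(pred)[mask]
        )
        metric_rows.append({"model": model.label, "analyte": analyte.name, **row})
    metrics = metrics_table(metric_rows)

    fits = fit_dataset(model, dataset, seed=seed)
    cwres = compute_cwres(model, dataset, fits)
    ipred = np.concatenate([f.ipred for f in fits]) if fits else np.array([])
    gof = records.copy()
    gof["pred"] = pred
    gof["ipred"] = ipred
    gof["cwres"] = cwres
    labels = model.subpopulation_labels
    post = np.concatenate(
        [np.tile(f.subpop_posterior, (dataset.subjects[i].n_obs, 1)) for i, f in enumerate(fits)]
    ) if fits else np.zeros((0, len(labels)))
    for j, lab in enumerate(labels):
        if lab:
            gof[f"p_{lab}"] = post[:, j]

    report = ModelReport(label=model.label, metrics=metrics, gof=gof)

    if K < 2:
        report.error = None
        log.warning(
            "model %s: K=%d is too small for pcVPC/NPDE; metrics only", model.label, K
        )
        return report

    ens = simulate_ensemble(model, dataset, K=K, seed=seed)
    for analyte in model.analytes:
        mask = (records["analyte"] == analyte.name).to_numpy() & quant
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        obs = records["value"].to_numpy()[idx]
        sims = ens.values[:, idx]
        report.vpc[analyte.name] = vpc_bands(
            obs,
            records["time"].to_numpy()[idx],
            np.asarray(pred)[idx],
            sims,
            n_bins=n_bins,
            analyte=analyte.name,
            max_time=max_time,
        )
        if model.error[analyte.name].scale == "log":
            nres = compute_npde(
                np.log(obs), np.log(np.clip(sims, 1e-300, None)),
                records["sid"].to_numpy()[idx],
            )
        else:
            nres = compute_npde(obs, sims, records["sid"].to_numpy()[idx])
        report.npde[analyte.name] = pd.DataFrame(
            {
                "sid": records["sid"].to_numpy()[idx],
                "time": records["time"].to_numpy()[idx],
                "pde": nres.pde,
                "npde": nres.npde,
            }
        )
        report.npde_tests[analyte.name] = npde_tests(nres.npde)
    return report


def run_evaluation(
    models: list[PopulationModel],
    dataset: StudyDataset,
    K: int = 1000,
    seed: int = 0,
    n_bins: int = 8,
    mixture_handling: str = "weighted",
    max_time: float | None = None,
    out_dir=None,
) -> EvaluationReport:
    """Evaluate every model on the dataset; optionally write CSV tables.

    Below-quantification records are excluded up front (only quantifiable
    concentrations enter any diagnostic); the per-analyte exclusion counts
    are reported.  The same seed drives every model's simulations so two
    identical configurations yield identical reports.
    """
    if not models:
        raise ValueError("need at least one model")
    filtered, excluded = bql_filter(dataset)
    log.info("excluded BQL records per analyte: %s", excluded)
    reports = []
    for model in models:
        try:
            reports.append(
                _evaluate_one(
                    model, filtered, K, seed, n_bins, mixture_handling, max_time
                )
            )
        except Exception as exc:  # noqa: BLE001 - one model must not kill the run
            log.exception("evaluation failed for model %s", model.label)
            reports.append(
                ModelReport(
                    label=model.label,
                    metrics=metrics_table([]),
                    gof=pd.DataFrame(),
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    ok = [r.metrics for r in reports if r.error is None and len(r.metrics)]
    comparison = (
        rank_models(pd.concat(ok, ignore_index=True)) if ok else pd.DataFrame()
    )
    report = EvaluationReport(reports=reports, comparison=comparison, excluded_bql=excluded)
    if out_dir is not None:
        report.write(out_dir)
    return report
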