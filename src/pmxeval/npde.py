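"""Normalized prediction distribution errors (NPDE) and their tests.

Per subject, the K simulated replicate vectors define an empirical
predictive distribution for that subject's observation vector.  Both are
centered on the simulated mean and whitened with the inverse lower
Cholesky factor of the empirical simulation covariance (decorrelation in
record order).  The prediction distribution error of each record is then
the rank of the whitened observation among the whitened replicates scaled
by 1/K — uniform on (0, 1) under the simulating model — and the NPDE is
its standard-normal quantile.  Ties count one half; ranks are clamped to
[1/(2K), 1 - 1/(2K)] so the quantile stays finite.

Under a correct model the pooled NPDE are approximately N(0, 1); this is
probed with a t-test of mean 0, a variance test of sigma^2 = 1 (the
(n-1) s^2 ~ chi-square reference, two-sided), and a Shapiro-Wilk normality
test, combined into a global verdict with a Bonferroni correction over the
three tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["NpdeResult", "NpdeTests", "compute_npde", "npde_tests"]

log = logging.getLogger(__name__)


@dataclass
class NpdeResult:
    """Per-observation pde/npde values, aligned to the input record order."""

    pde: np.ndarray
    npde: np.ndarray
    subject_index: np.ndarray


@dataclass
class NpdeTests:
    n: int
    mean: float
    variance: float
    t_pvalue: float
    variance_pvalue: float
    shapiro_pvalue: float
    alpha: float
    global_reject: bool

    @property
    def verdict(self) -> str:
        return "rejected" if self.global_reject else "not rejected"


def _whiten(y: np.ndarray, sims: np.ndarray, ridge: float = 1e-10):
    """Center on the simulated mean, decorrelate with the empirical Cholesky."""
    K, m = sims.shape
    mu = sims.mean(axis=0)
    yc = y - mu
    sc = sims - mu
    if m == 1:
        return yc, sc  # scalar path: ranks are invariant to positive scaling
    cov = np.cov(sc, rowvar=False, ddof=1)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        log.warning("singular empirical simulation covariance; ridge added")
        L = np.linalg.cholesky(cov + ridge * max(np.trace(cov) / m, 1e-30) * np.eye(m))
    yw = np.linalg.solve(L, yc)
    sw = np.linalg.solve(L, sc.T).T
    return yw, sw


def compute_npde(obs, sims, subject_index) -> NpdeResult:
    """NPDE for pooled observations against a simulated ensemble.

    Parameters
    ----------
    obs : (n,) array
        Observed values (any monotone scale, matching the simulations).
    sims : (K, n) array
        Simulated replicates aligned to ``obs``.
    subject_index : (n,) array
        Subject label per record; decorrelation happens within subject.
    """
    obs = np.asarray(obs, dtype=float)
    sims = np.asarray(sims, dtype=float)
    subject_index = np.asarray(subject_index)
    if sims.ndim != 2 or sims.shape[1] != len(obs):
        raise ValueError("simulated ensemble not aligned to observations")
    K = sims.shape[0]
    if K < 2:
        raise ValueError("NPDE needs at least 2 replicates (>= 100 recommended)")

    pde = np.empty(len(obs))
    for sid in pd.unique(subject_index):
        idx = np.nonzero(subject_index == sid)[0]
        yw, sw = _whiten(obs[idx], sims[:, idx])
        below = (sw < yw).sum(axis=0)
        ties = (sw == yw).sum(axis=0)
        p = (below + 0.5 * ties) / K
        pde[idx] = np.clip(p, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
    return NpdeResult(pde=pde, npde=stats.norm.ppf(pde), subject_index=subject_index)


def npde_tests(npde, alpha: float = 0.05) -> NpdeTests:
    """The three N(0,1) adequacy tests plus a Bonferroni global verdict."""
    npde = np.asarray(npde, dtype=float)
    npde = npde[np.isfinite(npde)]
    n = len(npde)
    if n < 3:
        raise ValueError("need at least 3 npde values")
    if np.ptp(npde) == 0:
        raise ValueError("constant npde vector: normality test undefined")
    t_p = float(stats.ttest_1samp(npde, 0.0).pvalue)
    s2 = float(np.var(npde, ddof=1))
    chi = (n - 1) * s2
    var_p = float(2 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1)))
    var_p = min(var_p, 1.0)
    sw_p = float(stats.shapiro(npde).pvalue)
    reject = min(t_p, var_p, sw_p) < alpha / 3.0
    return NpdeTests(
        n=n,
        mean=float(np.mean(npde)),
        variance=s2,
        t_pvalue=t_p,
        variance_pvalue=var_p,
        shapiro_pvalue=sw_p,
        alpha=alpha,
        global_reject=bool(reject),
    )


def plot_npde(npde, path):
    """Histogram + normal Q-Q plot of the npde values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    npde = np.asarray(npde, dtype=float)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].hist(npde, bins=20, density=True, color="0.7")
    x = np.linspace(-4, 4, 200)
    axes[0].plot(x, stats.norm.pdf(x), "r-")
    axes[0].set_title("npde histogram")
    stats.probplot(npde, dist="norm", plot=axes[1])
    axes[1].set_title("normal Q-Q")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
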