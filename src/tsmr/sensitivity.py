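"""Heterogeneity, pleiotropy and robustness diagnostics.

Cochran Q quantifies heterogeneity of the per-variant Wald ratios around
the fixed-effects IVW estimate; its p-value drives the fixed-to-random
model switch. MR-PRESSO detects pleiotropic outlier instruments by
comparing each variant's leave-one-out residual sum of squares against a
seeded Monte-Carlo null, and re-estimates after removing flagged outliers.
Leave-one-out re-fits IVW J times to show no single variant drives the
pooled estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _estimate, _arrays, _ivw_core, ivw
from .exceptions import InsufficientInstrumentsError


@dataclass
class HeterogeneityResult:
    q_stat: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """MR-PRESSO global test, per-variant outlier tests, and distortion check."""

    rss_obs: float
    global_pval: float
    outlier_pvals: pd.Series  # Bonferroni-adjusted, indexed by snp_id
    outlier_ids: list = field(default_factory=list)
    distortion_pval: float | None = None
    corrected: MREstimate | None = None


def cochran_q(instruments: pd.DataFrame) -> HeterogeneityResult:
    """Cochran Q over the Wald ratios: Q = sum w_j (ratio_j - beta_ivw)^2,
    upper-tail chi-square with J-1 degrees of freedom."""
    J = len(instruments)
    if J < 2:
        raise InsufficientInstrumentsError(f"Cochran Q needs at least 2 instruments, got {J}")
    _, _, q = _ivw_core(instruments)
    return HeterogeneityResult(q_stat=q, df=J - 1, pval=float(stats.chi2.sf(q, J - 1)))


def choose_ivw_model(het: HeterogeneityResult, q_switch_p: float = 0.05) -> str:
    """Random-effects IVW iff heterogeneity p falls strictly below the threshold."""
    return "random" if het.pval < q_switch_p else "fixed"


def _loo_slopes(x, y, w):
    """Leave-one-out origin-constrained WLS slopes, for observed or simulated data.

    Accepts 1-d arrays (one dataset) or 2-d (replicates, J) arrays.
    """
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    instruments: pd.DataFrame,
    n_sim: int = 1000,
    sig_level: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO pleiotropy residual-sum-and-outlier test.

    Observed residuals use each variant's leave-one-out IVW slope b_(-j):
    r_j^2 = (beta_out_j - b_(-j) beta_exp_j)^2 / se_out_j^2, RSSobs = sum.
    The null distribution comes from ``n_sim`` seeded replicates drawing
    beta_exp* ~ N(beta_exp_j, se_exp_j) and
    beta_out* ~ N(b_(-j) beta_exp_j, se_out_j) and recomputing the RSS with
    the replicate's own leave-one-out slopes; the global p carries the
    add-one Monte-Carlo correction. Per-variant outlier p-values are the
    replicate exceedance fractions, Bonferroni-multiplied by J, and flagged
    when below ``sig_level``. When outliers are flagged the estimate is
    recomputed without them and the distortion p compares the resulting
    shift against shifts from random same-size exclusions.
    """
    J = len(instruments)
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs at least 4 instruments, got {J}")
    x, sx, y, sy = _arrays(instruments)
    w = sy**-2.0
    snp_ids = (
        instruments["snp_id"].to_numpy() if "snp_id" in instruments else np.arange(J)
    )

    b_loo = np.asarray(_loo_slopes(x, y, w)).reshape(-1)
    r2_obs = w * (y - b_loo * x) ** 2
    rss_obs = float(np.sum(r2_obs))

    rng = np.random.default_rng(seed)
    xs = rng.normal(x, sx, size=(n_sim, J))
    ys = rng.normal(b_loo * x, sy, size=(n_sim, J))
    b_loo_s = _loo_slopes(xs, ys, w)
    r2_s = w * (ys - b_loo_s * xs) ** 2
    rss_s = r2_s.sum(axis=1)

    global_pval = float((np.sum(rss_s >= rss_obs) + 1) / (n_sim + 1))
    raw = (r2_s >= r2_obs[None, :]).mean(axis=0)
    adj = np.minimum(raw * J, 1.0)
    outlier_pvals = pd.Series(adj, index=snp_ids)
    flagged = [snp_ids[j] for j in range(J) if adj[j] < sig_level]

    corrected = None
    distortion_pval = None
    if flagged:
        mask = ~np.isin(snp_ids, flagged)
        if mask.sum() >= 2:
            corrected = ivw(instruments[mask].reset_index(drop=True), model="fixed")
            beta_all, _, _ = _ivw_core(instruments)
            shift_obs = beta_all - corrected.beta
            k = len(flagged)
            shifts = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(J, size=k, replace=False)
                keep = np.ones(J, bool)
                keep[drop] = False
                wk, xk, yk = w[keep], x[keep], y[keep]
                shifts[s] = beta_all - np.sum(wk * xk * yk) / np.sum(wk * xk * xk)
            distortion_pval = float(
                (np.sum(np.abs(shifts) >= abs(shift_obs)) + 1) / (n_sim + 1)
            )
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outlier_ids=list(flagged),
        distortion_pval=distortion_pval,
        corrected=corrected,
    )


def leave_one_out(instruments: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effects IVW re-fit J times, each excluding one instrument.

    Returns one row per left-out variant with the estimate on both scales.
    """
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs at least 3 instruments, got {J}")
    rows = []
    snp_ids = (
        instruments["snp_id"].to_numpy() if "snp_id" in instruments else np.arange(J)
    )
    for j in range(J):
        rest = instruments.drop(instruments.index[j]).reset_index(drop=True)
        est = ivw(rest, model="fixed")
        rows.append(
            {
                "left_out_id": snp_ids[j],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "or_": est.or_,
            }
        )
    return pd.DataFrame(rows)
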