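"""The five causal estimators over harmonized instruments.

Every estimator consumes a harmonized instrument table (columns beta_exp,
se_exp, beta_out, se_out; one row per variant) and pools per-variant Wald
ratios beta_out/beta_exp into a causal log-odds ratio of outcome per unit
log-odds of exposure. Weighting follows the first-order delta method:
se(ratio_j) = se_out_j/|beta_exp_j|, w_j = se(ratio_j)^-2 — so the
inverse-variance weighted (IVW) estimate coincides with weighted least
squares of beta_out on beta_exp through the origin with weights se_out^-2.

Estimates are reported on both the log-odds and the exponentiated
(odds-ratio) scale with 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientInstrumentsError, ValidationError

Z95 = 1.96  # 95% CI multiplier


@dataclass
class RatioEstimate:
    """Per-variant Wald ratio with first-order SE and inverse-variance weight."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass
class MREstimate:
    """A pooled causal estimate on log-odds and odds-ratio scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    n_snps: int


@dataclass
class EggerResult:
    """MR-Egger slope plus the pleiotropy-intercept test from the same fit."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _estimate(method, beta, se, n_snps, pval=None) -> MREstimate:
    beta, se = float(beta), float(se)
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    pval = float(max(pval, np.nextafter(0, 1)))  # pval in (0,1]
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return MREstimate(
        method=method, beta=beta, se=se, ci_low=lo, ci_high=hi, pval=min(pval, 1.0),
        or_=float(np.exp(beta)), or_ci_low=float(np.exp(lo)), or_ci_high=float(np.exp(hi)),
        n_snps=int(n_snps),
    )


def _arrays(instruments: pd.DataFrame):
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    sx = instruments["se_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    sy = instruments["se_out"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValidationError("instrument with beta_exp = 0: Wald ratio undefined")
    return bx, sx, by, sy


def wald_ratio(instrument) -> RatioEstimate:
    """Single-variant causal estimate beta_out/beta_exp with delta-method SE."""
    bx = float(instrument["beta_exp"])
    if bx == 0:
        raise ValidationError("beta_exp = 0: Wald ratio undefined")
    ratio = float(instrument["beta_out"]) / bx
    se_ratio = float(instrument["se_out"]) / abs(bx)
    return RatioEstimate(
        snp_id=str(instrument.get("snp_id", "")), ratio=ratio,
        se_ratio=se_ratio, weight=se_ratio**-2,
    )


def compute_ratios(instruments: pd.DataFrame) -> pd.DataFrame:
    """Wald ratios, SEs and weights for every instrument, as a table."""
    bx, _, by, sy = _arrays(instruments)
    ratio = by / bx
    se_ratio = sy / np.abs(bx)
    return pd.DataFrame(
        {
            "snp_id": instruments["snp_id"].to_numpy() if "snp_id" in instruments else np.arange(len(bx)),
            "ratio": ratio,
            "se_ratio": se_ratio,
            "weight": se_ratio**-2.0,
        }
    )


def _ivw_core(instruments: pd.DataFrame):
    """Pooled ratio, fixed-effects SE and Cochran Q for the instrument set."""
    bx, _, by, sy = _arrays(instruments)
    ratio = by / bx
    w = (bx / sy) ** 2
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratio - beta) ** 2))
    return beta, se_fixed, q


def ivw(
    instruments: pd.DataFrame, model: str = "auto", q_switch_p: float = 0.05
) -> MREstimate:
    """Inverse-variance weighted pooled causal estimate.

    ``model='fixed'`` uses SE = (sum w)^(-1/2); ``'random'`` is the
    multiplicative random-effects variant, inflating the fixed SE by
    sqrt(Q/(J-1)) clamped below at 1 (never down-weighting under
    underdispersion); ``'auto'`` picks random iff the Cochran Q p-value
    falls strictly below ``q_switch_p``.
    """
    J = len(instruments)
    if J < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs at least 2 instruments, got {J}; use wald_ratio for a single variant"
        )
    if model not in ("fixed", "random", "auto"):
        raise ValidationError(f"unknown IVW model {model!r}")
    beta, se_fixed, q = _ivw_core(instruments)
    if model == "auto":
        q_p = stats.chi2.sf(q, J - 1)
        model = "random" if q_p < q_switch_p else "fixed"
    if model == "fixed":
        return _estimate("ivw-fixed", beta, se_fixed, J)
    se = se_fixed * max(1.0, np.sqrt(q / (J - 1)))
    return _estimate("ivw-random", beta, se, J)


def egger(instruments: pd.DataFrame) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects with intercept.

    Instruments are first oriented so every beta_exp is positive (negating
    both betas where needed — the fit is invariant to instrument coding only
    after this step). Weights are se_out^-2. A non-zero intercept estimates
    the average directional pleiotropic effect; p-values use the t
    distribution with J-2 degrees of freedom. The coefficient covariance is
    scaled by max(1, sigma_hat), mirroring the multiplicative
    random-effects clamp used for IVW.
    """
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs at least 3 instruments, got {J}")
    bx, _, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    x, y = bx * flip, by * flip
    w = sy**-2.0
    X = np.column_stack([np.ones(J), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (J - 2))
    cov_unit = np.linalg.inv(xtwx)
    scale = max(1.0, np.sqrt(sigma2))
    se = np.sqrt(np.diag(cov_unit)) * scale
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), J - 2)
    slope = _estimate("egger", coef[1], se[1], J, pval=pvals[1])
    return EggerResult(
        slope=slope, intercept=float(coef[0]),
        intercept_se=float(se[0]), intercept_pval=float(pvals[0]),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _bootstrap_se(instruments, point_fn, n_boot, seed):
    """Parametric bootstrap: resample effects from normals at observed SEs."""
    bx, sx, by, sy = _arrays(instruments)
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        bx_s[bx_s == 0] = np.finfo(float).tiny  # measure-zero guard
        est[b] = point_fn(by_s / bx_s, (bx_s / sy) ** 2)
    return float(np.std(est, ddof=1))


def weighted_median(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios; consistent when valid instruments
    carry a majority of the weight. SE by seeded parametric bootstrap."""
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted median needs at least 3 instruments, got {J}")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} is small; bootstrap SE will be noisy", stacklevel=2)
    bx, _, by, sy = _arrays(instruments)
    point = _weighted_median_point(by / bx, (bx / sy) ** 2)
    se = _bootstrap_se(instruments, _weighted_median_point, n_boot, seed)
    return _estimate("weighted-median", point, se, J)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0,
                         n_grid: int = 2001) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0:  # all ratios identical
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def weighted_mode(
    instruments: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted mode of the Wald ratios: the causal effect of the largest
    cluster of agreeing instruments.

    A Gaussian kernel density over the ratios, weighted by w_j, with
    bandwidth h = phi * 0.9 * min(sd, IQR/1.34) * J^(-1/5), is maximized on
    a 2001-point grid padded by 3h beyond the ratio range. SE by the same
    parametric bootstrap as the weighted median.
    """
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs at least 3 instruments, got {J}")
    bx, _, by, sy = _arrays(instruments)
    point = _weighted_mode_point(by / bx, (bx / sy) ** 2, phi)
    se = _bootstrap_se(
        instruments, lambda r, w: _weighted_mode_point(r, w, phi), n_boot, seed
    )
    return _estimate("weighted-mode", point, se, J)
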