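"""End-to-end orchestration of one or both causal directions.

``run_direction`` applies the instrument-selection cascade, harmonizes the
two studies, runs all five estimators and the full sensitivity suite, and
returns a structured report. ``run_bidirectional`` does this for both
exposure/outcome role assignments independently. ``render_report`` writes
the tables (forest-layout estimates, one-line diagnostics) and the three
standard plots (scatter with fitted lines, per-variant forest,
leave-one-out forest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators, gwas_io, instrument_selection as sel, sensitivity
from .exceptions import InsufficientInstrumentsError
from .instrument_selection import InstrumentStrength, LDMatrix, SelectionConfig

ESTIMATOR_ORDER = ["ivw", "egger", "weighted-median", "weighted-mode"]


@dataclass
class DirectionReport:
    """All results for one exposure -> outcome direction."""

    direction: str
    instruments: pd.DataFrame
    estimates: dict  # method name -> MREstimate or None (not applicable)
    egger: estimators.EggerResult | None
    heterogeneity: sensitivity.HeterogeneityResult
    ivw_model: str
    presso: sensitivity.PressoResult | None
    loo: pd.DataFrame | None
    strength: InstrumentStrength
    harmonization_log: pd.DataFrame
    selection_log: list = field(default_factory=list)  # (stage, n_in, n_out)


@dataclass
class DirectionFailure:
    """Raised-as-value record when a direction cannot produce enough instruments."""

    direction: str
    stage: str
    message: str


def run_direction(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
    shared_loci=None,
    exclusion_list=None,
    preclumped: bool = False,
    palindrome_policy: str = "drop-ambiguous",
    eaf_ambiguity_band: float = 0.08,
    direction: str = "exposure->outcome",
    n_exposure: float | None = None,
    n_boot: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
) -> DirectionReport:
    """Run the full selection -> harmonization -> estimation -> sensitivity chain.

    ``ld`` may be omitted only with ``preclumped=True`` (clumping and
    shared-locus LD screening are then skipped/identity-only). Raises
    :class:`InsufficientInstrumentsError` naming the last filter applied
    when fewer than 2 instruments survive.
    """
    config = config or SelectionConfig()
    log: list[tuple[str, int, int]] = []

    def stage(name, before, table):
        log.append((name, len(before), len(table)))
        if len(table) < 2:
            raise InsufficientInstrumentsError(
                f"fewer than 2 instruments survive '{name}' "
                f"({len(before)} -> {len(table)}) in direction {direction}",
                stage=name,
            )
        return table

    t = stage("select_significant", exposure,
              sel.select_significant(exposure, config.p_threshold))
    if not preclumped:
        if ld is None:
            raise ValueError("an LD matrix is required unless preclumped=True")
        t = stage("ld_clump", t, sel.ld_clump(t, ld, config))
    if shared_loci:
        t = stage("exclude_shared_loci", t,
                  sel.exclude_shared_loci(t, shared_loci, ld, config.r2_max))
    if exclusion_list:
        t = stage("apply_exclusion_list", t, sel.apply_exclusion_list(t, exclusion_list))
    t = stage("filter_maf", t, sel.filter_maf(t, config.maf_min))
    instruments, harm_log = gwas_io.harmonize(
        t, outcome, palindrome_policy=palindrome_policy,
        eaf_ambiguity_band=eaf_ambiguity_band,
    )
    instruments = stage("harmonize", t, instruments)

    n_exp = n_exposure if n_exposure is not None else float(np.nanmax(t["n_total"]))
    strength = sel.instrument_strength(t[t["snp_id"].isin(instruments["snp_id"])], n_exp)

    J = len(instruments)
    het = sensitivity.cochran_q(instruments)
    model = sensitivity.choose_ivw_model(het)
    ests: dict = {"ivw": estimators.ivw(instruments, model=model)}
    egger_res = estimators.egger(instruments) if J >= 3 else None
    ests["egger"] = egger_res.slope if egger_res else None
    ests["weighted-median"] = (
        estimators.weighted_median(instruments, n_boot=n_boot, seed=seed) if J >= 3 else None
    )
    ests["weighted-mode"] = (
        estimators.weighted_mode(instruments, n_boot=n_boot, seed=seed + 1) if J >= 3 else None
    )
    presso = (
        sensitivity.mr_presso(instruments, n_sim=n_sim, seed=seed + 2) if J >= 4 else None
    )
    loo = sensitivity.leave_one_out(instruments) if J >= 3 else None

    return DirectionReport(
        direction=direction,
        instruments=instruments,
        estimates=ests,
        egger=egger_res,
        heterogeneity=het,
        ivw_model=model,
        presso=presso,
        loo=loo,
        strength=strength,
        harmonization_log=harm_log,
        selection_log=log,
    )


def run_bidirectional(
    trait_a: pd.DataFrame,
    trait_b: pd.DataFrame,
    ld_a: LDMatrix | None = None,
    ld_b: LDMatrix | None = None,
    names: tuple[str, str] = ("A", "B"),
    **kwargs,
):
    """Two independent ``run_direction`` calls with roles swapped.

    One direction failing for lack of instruments yields a
    :class:`DirectionFailure` in its slot without aborting the other.
    """
    out = []
    for exp, outc, ld, label in (
        (trait_a, trait_b, ld_a, f"{names[0]}->{names[1]}"),
        (trait_b, trait_a, ld_b, f"{names[1]}->{names[0]}"),
    ):
        try:
            out.append(run_direction(exp, outc, ld=ld, direction=label, **kwargs))
        except InsufficientInstrumentsError as exc:
            out.append(DirectionFailure(direction=label, stage=exc.stage or "?", message=str(exc)))
    return tuple(out)


def _estimate_row(direction, name, est):
    if est is None:
        return {
            "direction": direction, "method": name, "n_snps": "NA", "or": "NA",
            "or_ci_low": "NA", "or_ci_high": "NA", "beta": "NA", "se": "NA", "pval": "NA",
        }
    return {
        "direction": direction, "method": est.method, "n_snps": est.n_snps,
        "or": est.or_, "or_ci_low": est.or_ci_low, "or_ci_high": est.or_ci_high,
        "beta": est.beta, "se": est.se, "pval": est.pval,
    }


def estimates_table(report: DirectionReport) -> pd.DataFrame:
    """Forest-layout estimates: one row per method (NA markers where J was too small)."""
    return pd.DataFrame(
        [_estimate_row(report.direction, m, report.estimates.get(m)) for m in ESTIMATOR_ORDER]
    )


def diagnostics_row(report: DirectionReport) -> pd.DataFrame:
    """One-line heterogeneity/pleiotropy summary per direction."""
    p = report.presso
    e = report.egger
    return pd.DataFrame(
        [
            {
                "direction": report.direction,
                "rss_obs": p.rss_obs if p else "NA",
                "presso_global_pval": p.global_pval if p else "NA",
                "presso_outliers": ";".join(map(str, p.outlier_ids)) if p else "NA",
                "egger_intercept": e.intercept if e else "NA",
                "egger_intercept_pval": e.intercept_pval if e else "NA",
                "q_stat": report.heterogeneity.q_stat,
                "q_pval": report.heterogeneity.pval,
                "ivw_model": report.ivw_model,
            }
        ]
    )


def render_report(report: DirectionReport, outdir) -> list[str]:
    """Write tables, plots and a machine-readable summary for one direction.

    Produces estimates.tsv, diagnostics.tsv, scatter.png, forest.png,
    loo.png and summary.json under ``outdir``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    est_tab = estimates_table(report)
    path = outdir / "estimates.tsv"
    est_tab.to_csv(path, sep="\t", index=False)
    written.append(str(path))

    diag = diagnostics_row(report)
    path = outdir / "diagnostics.tsv"
    diag.to_csv(path, sep="\t", index=False)
    written.append(str(path))

    ins = report.instruments
    bx, by = ins["beta_exp"].to_numpy(), ins["beta_out"].to_numpy()
    flip = np.sign(bx)
    x, y = bx * flip, by * flip

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(x, y, xerr=ins["se_exp"], yerr=ins["se_out"], fmt="o", ms=4, lw=1, alpha=0.8)
    grid = np.linspace(0, x.max() * 1.05, 50)
    for m in ESTIMATOR_ORDER:
        est = report.estimates.get(m)
        if est is None:
            continue
        icept = report.egger.intercept if m == "egger" and report.egger else 0.0
        ax.plot(grid, icept + est.beta * grid, label=est.method, lw=1)
    ax.set_xlabel("SNP effect on exposure (log-odds)")
    ax.set_ylabel("SNP effect on outcome (log-odds)")
    ax.legend(fontsize=7)
    ax.set_title(report.direction)
    fig.tight_layout()
    path = outdir / "scatter.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    ratios = estimators.compute_ratios(ins)
    fig, ax = plt.subplots(figsize=(5, 0.4 * len(ratios) + 1.5))
    ypos = np.arange(len(ratios))[::-1]
    ax.errorbar(ratios["ratio"], ypos, xerr=1.96 * ratios["se_ratio"], fmt="o", ms=4)
    ivw_est = report.estimates["ivw"]
    ax.axvline(ivw_est.beta, color="firebrick", lw=1, label=f"{ivw_est.method}")
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_yticks(ypos, ratios["snp_id"])
    ax.set_xlabel("per-variant causal estimate (log-OR)")
    ax.legend(fontsize=7)
    ax.set_title(report.direction)
    fig.tight_layout()
    path = outdir / "forest.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(5, 0.4 * len(ins) + 1.5))
    if report.loo is not None:
        ypos = np.arange(len(report.loo))[::-1]
        ax.errorbar(
            report.loo["beta"], ypos,
            xerr=1.96 * report.loo["se"], fmt="o", ms=4,
        )
        ax.set_yticks(ypos, report.loo["left_out_id"])
        ax.axvline(ivw_est.beta, color="firebrick", lw=1)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("IVW estimate leaving one variant out (log-OR)")
    ax.set_title(report.direction)
    fig.tight_layout()
    path = outdir / "loo.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    summary = {
        "direction": report.direction,
        "ivw_model": report.ivw_model,
        "estimates": {
            m: (vars(e) if e is not None else None) for m, e in report.estimates.items()
        },
        "heterogeneity": vars(report.heterogeneity),
        "egger_intercept": report.egger.intercept if report.egger else None,
        "egger_intercept_pval": report.egger.intercept_pval if report.egger else None,
        "presso": (
            {
                "rss_obs": report.presso.rss_obs,
                "global_pval": report.presso.global_pval,
                "outlier_ids": list(map(str, report.presso.outlier_ids)),
                "distortion_pval": report.presso.distortion_pval,
            }
            if report.presso
            else None
        ),
        "instrument_strength": {
            "r2_total": report.strength.r2_total,
            "F_min": report.strength.F_min,
            "F_max": report.strength.F_max,
        },
        "selection_log": [list(row) for row in report.selection_log],
    }
    path = outdir / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    written.append(str(path))
    return written
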