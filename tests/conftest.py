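"""Shared fixtures and table builders for the test suite."""

import numpy as np
import pandas as pd
import pytest


def make_stats(
    snp_ids,
    betas,
    ses,
    pvals=None,
    eafs=None,
    effect_alleles=None,
    other_alleles=None,
    chroms=None,
    positions=None,
    n_total=50_000,
) -> pd.DataFrame:
    """Build a canonical summary-statistics table from parallel sequences."""
    J = len(snp_ids)
    from scipy import stats as st

    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if pvals is None:
        pvals = np.clip(2 * st.norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": chroms if chroms is not None else ["1"] * J,
            "pos_bp": positions if positions is not None else (1 + np.arange(J) * 10_000_000),
            "effect_allele": effect_alleles if effect_alleles is not None else ["A"] * J,
            "other_allele": other_alleles if other_alleles is not None else ["G"] * J,
            "eaf": eafs if eafs is not None else [0.3] * J,
            "beta": betas,
            "se": ses,
            "pval": pvals,
            "n_total": n_total,
            "n_case": np.nan,
            "n_control": np.nan,
        }
    )


def make_instruments(beta_exp, se_exp, beta_out, se_out, snp_ids=None) -> pd.DataFrame:
    """Build a harmonized instrument table from effect arrays."""
    J = len(beta_exp)
    return pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"rs{i}" for i in range(J)],
            "beta_exp": np.asarray(beta_exp, dtype=float),
            "se_exp": np.asarray(se_exp, dtype=float),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
        }
    )


def random_instruments(rng, J=8) -> pd.DataFrame:
    """A random but well-behaved instrument set (|beta_exp| bounded away from 0)."""
    bx = rng.uniform(0.05, 0.3, J) * rng.choice([-1.0, 1.0], J)
    sx = rng.uniform(0.005, 0.02, J)
    by = rng.normal(0.3 * bx, 0.05 * np.abs(bx) + 0.01)
    sy = rng.uniform(0.01, 0.05, J)
    return make_instruments(bx, sx, by, sy)


@pytest.fixture
def rng():
    return np.random.default_rng(20221018)


@pytest.fixture
def three_row_stats():
    return make_stats(
        ["rs1", "rs2", "rs3"],
        betas=[0.12, -0.08, 0.2],
        ses=[0.01, 0.02, 0.015],
        eafs=[0.3, 0.45, 0.12],
        effect_alleles=["A", "C", "T"],
        other_alleles=["G", "A", "C"],
        chroms=["1", "2", "X"],
    )
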