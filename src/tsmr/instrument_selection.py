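"""Instrument-selection cascade and instrument-strength measures.

The cascade mirrors standard two-sample MR practice for binary traits:
genome-wide significance, greedy LD clumping within a genomic window,
exclusion of loci shared between the two diseases (identity and LD overlap),
a confounder exclusion list from a manual phenome-scan, and a minor-allele
frequency floor. Instrument strength is summarized per variant by the
variance in the exposure explained (r^2) and the F statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Thresholds of the selection cascade.

    p_threshold : genome-wide significance cutoff (keep p strictly below).
    r2_max      : LD threshold; clumping removes r^2 >= r2_max, shared-locus
                  screening removes r^2 > r2_max (the two conventions the
                  cascade is defined with).
    window_kb   : clumping window half-width in kilobases.
    maf_min     : minimum minor-allele frequency.
    """

    p_threshold: float = 5e-8
    r2_max: float = 0.01
    window_kb: float = 5000.0
    maf_min: float = 0.01

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError(f"p_threshold must lie in (0,1), got {self.p_threshold}")
        if not (0.0 <= self.r2_max <= 1.0):
            raise ValidationError(f"r2_max must lie in [0,1], got {self.r2_max}")
        if not self.window_kb > 0:
            raise ValidationError(f"window_kb must be > 0, got {self.window_kb}")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValidationError(f"maf_min must lie in [0,0.5), got {self.maf_min}")


class LDMatrix:
    """Square matrix of pairwise squared correlations between variants."""

    def __init__(self, snp_ids, r2: np.ndarray):
        snp_ids = list(snp_ids)
        r2 = np.asarray(r2, dtype=float)
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("LD matrix snp_ids are not unique")
        if r2.shape != (len(snp_ids), len(snp_ids)):
            raise ValidationError(f"LD matrix shape {r2.shape} does not match {len(snp_ids)} ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValidationError("LD r^2 values must lie in [0,1]")
        self.snp_ids = snp_ids
        self.r2 = r2
        self._index = {s: i for i, s in enumerate(snp_ids)}

    def __contains__(self, snp_id) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())

    def to_tsv(self, path) -> str:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")
        return str(path)


@dataclass
class InstrumentStrength:
    """Per-variant and aggregate instrument-strength summaries."""

    snp_ids: list
    r2_j: np.ndarray
    F_j: np.ndarray
    r2_total: float = field(init=False)
    F_min: float = field(init=False)
    F_max: float = field(init=False)

    def __post_init__(self):
        self.r2_total = float(np.sum(self.r2_j))
        self.F_min = float(np.min(self.F_j))
        self.F_max = float(np.max(self.F_j))


def select_significant(records: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Keep rows with association p strictly below the threshold, order preserved."""
    return records[records["pval"] < p_threshold].reset_index(drop=True)


def _chrom_key(chrom) -> tuple:
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def ld_clump(records: pd.DataFrame, ld: LDMatrix, config: SelectionConfig) -> pd.DataFrame:
    """Greedy LD clumping: keep index variants, prune neighbours in LD.

    Candidates are visited in order of ascending p-value (ties: chromosome,
    position, then snp_id, for determinism under row permutation). Each
    index variant removes every remaining variant on the same chromosome
    within ``window_kb`` whose r^2 with it is >= ``r2_max``. Survivors are
    returned in their original row order.
    """
    missing = [s for s in records["snp_id"] if s not in ld]
    if missing:
        raise ValidationError(f"variant(s) absent from LD matrix: {', '.join(map(str, missing))}")
    order = sorted(
        records.index,
        key=lambda i: (
            records.at[i, "pval"],
            _chrom_key(records.at[i, "chrom"]),
            records.at[i, "pos_bp"],
            str(records.at[i, "snp_id"]),
        ),
    )
    window_bp = config.window_kb * 1000.0
    alive = set(records.index)
    index_variants = []
    for i in order:
        if i not in alive:
            continue
        index_variants.append(i)
        alive.discard(i)
        for j in list(alive):
            if str(records.at[j, "chrom"]) != str(records.at[i, "chrom"]):
                continue
            if abs(records.at[j, "pos_bp"] - records.at[i, "pos_bp"]) > window_bp:
                continue
            if ld.r2_between(records.at[i, "snp_id"], records.at[j, "snp_id"]) >= config.r2_max:
                alive.discard(j)
    keep = sorted(index_variants)
    return records.loc[keep].reset_index(drop=True)


def exclude_shared_loci(
    records: pd.DataFrame,
    shared_loci,
    ld: LDMatrix | None = None,
    r2_max: float = 0.01,
) -> pd.DataFrame:
    """Drop variants that are shared loci between the two traits, or in LD with one.

    A record is removed if its id is in ``shared_loci`` or if its r^2 with
    any shared locus exceeds ``r2_max`` (strict ``>``). Shared loci absent
    from the LD matrix trigger a warning; identity exclusion still applies.
    """
    shared = set(shared_loci)
    if ld is not None:
        for locus in shared:
            if locus not in ld:
                warnings.warn(
                    f"shared locus {locus} absent from LD matrix; identity-match exclusion only",
                    stacklevel=2,
                )
    keep = []
    for i, row in records.iterrows():
        sid = row["snp_id"]
        if sid in shared:
            logger.info("excluding %s: is a shared locus", sid)
            continue
        hit = None
        if ld is not None and sid in ld:
            for locus in shared:
                if locus in ld and ld.r2_between(sid, locus) > r2_max:
                    hit = locus
                    break
        if hit is not None:
            logger.info("excluding %s: r2 > %g with shared locus %s", sid, r2_max, hit)
            continue
        keep.append(i)
    return records.loc[keep].reset_index(drop=True)


def apply_exclusion_list(records: pd.DataFrame, excluded_ids) -> pd.DataFrame:
    """Set difference on snp_id (e.g. confounder-associated variants), order preserved."""
    excluded = set(excluded_ids)
    removed = records["snp_id"].isin(excluded)
    for sid in records.loc[removed, "snp_id"]:
        logger.info("excluding %s: on exclusion list", sid)
    return records[~removed].reset_index(drop=True)


def read_exclusion_list(path) -> list[str]:
    """One variant id per line; '#' starts a comment."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ids


def filter_maf(records: pd.DataFrame, maf_min: float = 0.01) -> pd.DataFrame:
    """Keep rows whose minor-allele frequency min(eaf, 1-eaf) is >= maf_min."""
    maf = np.minimum(records["eaf"], 1.0 - records["eaf"])
    return records[maf >= maf_min].reset_index(drop=True)


def instrument_strength(
    records: pd.DataFrame, n: float, formula: str = "variance-explained"
) -> InstrumentStrength:
    """Per-variant variance explained and F statistics for the exposure association.

    With ``variance-explained`` (default),

        r2_j = 2 p q b^2 / (2 p q b^2 + 2 p q n se^2),   F_j = r2_j (n-2) / (1-r2_j)

    where p is the effect-allele frequency, q = 1-p. The cruder ``t-ratio``
    alternative uses F_j = (b/se)^2 and inverts the same relation for r2_j;
    the two agree to first order when r2_j is small.
    """
    if n <= 2:
        raise ValidationError(f"sample size must exceed 2, got {n}")
    eaf = records["eaf"].to_numpy(dtype=float)
    beta = records["beta"].to_numpy(dtype=float)
    se = records["se"].to_numpy(dtype=float)
    het = 2.0 * eaf * (1.0 - eaf)
    if formula == "variance-explained":
        r2 = het * beta**2 / (het * beta**2 + het * n * se**2)
        F = r2 * (n - 2) / (1.0 - r2)
    elif formula == "t-ratio":
        F = (beta / se) ** 2
        r2 = F / (F + n - 2)
    else:
        raise ValidationError(f"unknown F-statistic formula {formula!r}")
    return InstrumentStrength(list(records["snp_id"]), r2, F)
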