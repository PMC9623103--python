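"""Reading, validating, writing GWAS summary statistics, and allele harmonization.

Summary statistics live in pandas DataFrames with a fixed canonical schema
(one row per variant, effects on the log-odds scale). Harmonization aligns
the outcome study's effect allele to the exposure study's, flipping signs
and frequencies where the allele coding is swapped and resolving palindromic
(A/T, C/G) variants by allele frequency.

Coordinates are 1-based; strand is assumed forward, so strand differences
are expressed only through allele complementarity.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: Canonical column order for summary-statistics tables. ``n_case`` and
#: ``n_control`` are optional and written as "NA" when absent.
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos_bp",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n_total",
    "n_case",
    "n_control",
]

MANDATORY_COLUMNS = CANONICAL_COLUMNS[:10]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Actions a kept harmonized instrument can carry.
HARMONIZE_ACTIONS = (
    "kept-as-is",
    "allele-flipped",
    "palindromic-dropped",
    "palindromic-eaf-aligned",
)


def _check_allele(allele: object, row: object, field: str) -> str:
    if not isinstance(allele, str) or allele.upper() not in _COMPLEMENT:
        raise ValidationError(
            f"row {row}: field '{field}' must be a single base in A/C/G/T, got {allele!r}"
        )
    return allele.upper()


def validate_summary_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary-statistics table against the schema invariants.

    Returns the table with canonical column order and uppercase alleles.
    ``eaf`` may be NaN (frequency unknown); every other mandatory field must
    be populated. Raises :class:`ValidationError` naming the offending row
    and field.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df.copy()
    for opt in ("n_case", "n_control"):
        if opt not in df.columns:
            df[opt] = np.nan
    df = df[CANONICAL_COLUMNS]

    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate snp_id: {dup.iloc[0]!r}")

    for i, row in df.iterrows():
        ea = _check_allele(row["effect_allele"], i, "effect_allele")
        oa = _check_allele(row["other_allele"], i, "other_allele")
        if ea == oa:
            raise ValidationError(f"row {i}: effect_allele equals other_allele ({ea})")
        df.at[i, "effect_allele"], df.at[i, "other_allele"] = ea, oa
        eaf = row["eaf"]
        if pd.notna(eaf) and not (0.0 < eaf < 1.0):
            raise ValidationError(f"row {i}: field 'eaf' must lie strictly in (0,1), got {eaf}")
        if not row["se"] > 0:
            raise ValidationError(f"row {i}: field 'se' must be > 0, got {row['se']}")
        if not (0.0 < row["pval"] <= 1.0):
            raise ValidationError(f"row {i}: field 'pval' must lie in (0,1], got {row['pval']}")
        if not row["pos_bp"] >= 1:
            raise ValidationError(f"row {i}: field 'pos_bp' must be >= 1, got {row['pos_bp']}")
        nc, nk = row["n_case"], row["n_control"]
        if pd.notna(nc) and pd.notna(nk) and nc + nk != row["n_total"]:
            raise ValidationError(
                f"row {i}: n_case + n_control ({nc + nk}) != n_total ({row['n_total']})"
            )
    return df


def read_summary_stats(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-separated summary-statistics file.

    ``dialect`` maps source column headers to canonical names, e.g.
    ``{"SNP": "snp_id", "A1": "effect_allele"}``. Rows are validated and
    order is preserved; duplicate variant ids are an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if dialect:
        df = df.rename(columns=dict(dialect))
    df = validate_summary_stats(df)
    return df.reset_index(drop=True)


def write_summary_stats(records: pd.DataFrame, path) -> str:
    """Write a validated table in canonical column order; NA for missing optionals."""
    df = validate_summary_stats(records)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return str(path)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is complementary (A/T or C/G in either order)."""
    ea = _check_allele(effect_allele, "-", "effect_allele")
    oa = _check_allele(other_allele, "-", "other_allele")
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "drop-ambiguous",
    eaf_ambiguity_band: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome effect alleles to the exposure's and merge the two studies.

    Returns ``(instruments, log)``. ``instruments`` has one row per kept
    variant with columns snp_id, chrom, pos_bp, effect_allele, other_allele,
    beta_exp, se_exp, eaf_exp, pval_exp, beta_out, se_out, eaf_out, action.
    ``log`` records one action per exposure variant (snp_id, action, reason).

    Outcome rows with swapped alleles get their beta negated and eaf replaced
    by 1-eaf; complementary-strand codings are mapped to the forward strand
    first. Palindromic variants cannot be resolved by allele matching and are
    oriented by frequency: under ``drop-ambiguous`` they are dropped when the
    minor-allele frequency of either study lies within ``eaf_ambiguity_band``
    of 0.5, under ``eaf-infer`` they are always frequency-oriented. A missing
    outcome frequency makes a palindromic variant non-inferable (dropped).
    """
    if palindrome_policy not in ("drop-ambiguous", "eaf-infer"):
        raise ValidationError(f"unknown palindrome_policy {palindrome_policy!r}")
    out_by_id = outcome.set_index("snp_id")
    kept, log = [], []

    for _, ex in exposure.iterrows():
        sid = ex["snp_id"]
        if sid not in out_by_id.index:
            log.append((sid, "dropped", "absent-from-outcome"))
            continue
        oc = out_by_id.loc[sid]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = oc["effect_allele"], oc["other_allele"]
        beta_out, eaf_out = oc["beta"], oc["eaf"]

        if is_palindromic(ea_x, oa_x):
            action, reason = _orient_palindromic(
                ex["eaf"], eaf_out, palindrome_policy, eaf_ambiguity_band
            )
            if action == "palindromic-dropped":
                log.append((sid, action, reason))
                continue
            if reason == "flip":
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            log.append((sid, action, reason))
        else:
            # Map a complementary-strand outcome coding onto the forward strand.
            if {ea_y, oa_y} != {ea_x, oa_x}:
                ea_y, oa_y = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]
            if (ea_y, oa_y) == (ea_x, oa_x):
                action = "kept-as-is"
            elif (ea_y, oa_y) == (oa_x, ea_x):
                action = "allele-flipped"
                beta_out = -beta_out
                if pd.notna(eaf_out):
                    eaf_out = 1.0 - eaf_out
            else:
                log.append((sid, "dropped", f"irreconcilable-alleles {ea_y}/{oa_y} vs {ea_x}/{oa_x}"))
                continue
            log.append((sid, action, "allele-match"))

        kept.append(
            {
                "snp_id": sid,
                "chrom": ex["chrom"],
                "pos_bp": ex["pos_bp"],
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "beta_exp": ex["beta"],
                "se_exp": ex["se"],
                "eaf_exp": ex["eaf"],
                "pval_exp": ex["pval"],
                "beta_out": beta_out,
                "se_out": oc["se"],
                "eaf_out": eaf_out,
                "action": action,
            }
        )

    cols = [
        "snp_id", "chrom", "pos_bp", "effect_allele", "other_allele",
        "beta_exp", "se_exp", "eaf_exp", "pval_exp",
        "beta_out", "se_out", "eaf_out", "action",
    ]
    instruments = pd.DataFrame(kept, columns=cols)
    log_df = pd.DataFrame(log, columns=["snp_id", "action", "reason"])
    return instruments, log_df


def _orient_palindromic(eaf_exp, eaf_out, policy, band):
    if pd.isna(eaf_out) or pd.isna(eaf_exp):
        return "palindromic-dropped", "eaf-missing"
    if policy == "drop-ambiguous":
        if abs(eaf_exp - 0.5) <= band or abs(eaf_out - 0.5) <= band:
            return "palindromic-dropped", "eaf-ambiguous"
    same_side = (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
    return "palindromic-eaf-aligned", ("keep" if same_side else "flip")


def write_harmonization_log(log: pd.DataFrame, path) -> str:
    log.to_csv(path, sep="\t", index=False)
    return str(path)
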