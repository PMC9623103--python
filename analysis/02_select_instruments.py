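#!/usr/bin/env python
"""Walk a candidate SNP set through the full instrument-selection cascade.

Simulates a 30-variant association region with a range of effect sizes
(so some candidates miss genome-wide significance), clusters variants into
LD blocks, then applies in order: the p < 5e-8 significance filter, greedy
LD clumping (r^2 < 0.01, 5,000-kb window), exclusion of loci shared between
the two traits (identity and LD overlap), a confounder exclusion list, and
the MAF >= 0.01 floor. Writes the per-stage survivor counts to
results/selection_log.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tsmr.instrument_selection import (
    SelectionConfig,
    apply_exclusion_list,
    exclude_shared_loci,
    filter_maf,
    ld_clump,
    select_significant,
)
from tsmr.synthetic_data import SimulationConfig, make_ld_matrix, simulate_summary_stats

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cfg = SimulationConfig(J=30, gamma_low=0.0, gamma_high=0.16,
                           maf_low=0.005, maf_high=0.45, seed=2022)
    candidates, _, _ = simulate_summary_stats(cfg)
    # place everything in one region so clumping has work to do
    candidates["chrom"] = "6"
    candidates["pos_bp"] = 1_000_000 + np.arange(len(candidates)) * 1_000_000
    ld = make_ld_matrix(candidates["snp_id"], block_size=3, within_r2=0.5)
    shared_loci = list(candidates["snp_id"].iloc[[0, 9]])   # stand-ins for known shared loci
    confounders = list(candidates["snp_id"].iloc[[3, 15]])  # stand-ins for a phenome-scan hit list

    sel_cfg = SelectionConfig()
    stages = [("candidates", candidates)]
    stages.append(("significant", select_significant(stages[-1][1], sel_cfg.p_threshold)))
    stages.append(("clumped", ld_clump(stages[-1][1], ld, sel_cfg)))
    stages.append(("shared_loci_excluded",
                   exclude_shared_loci(stages[-1][1], shared_loci, ld, sel_cfg.r2_max)))
    stages.append(("confounders_excluded",
                   apply_exclusion_list(stages[-1][1], confounders)))
    stages.append(("maf_filtered", filter_maf(stages[-1][1], sel_cfg.maf_min)))

    log = pd.DataFrame(
        [(name, len(tab)) for name, tab in stages], columns=["stage", "n_variants"]
    )
    OUT.mkdir(parents=True, exist_ok=True)
    log.to_csv(OUT / "selection_log.tsv", sep="\t", index=False)
    print(log.to_string(index=False))
    final = stages[-1][1]
    print(f"\nretained instruments: {', '.join(final['snp_id'])}")
    print(f"wrote {OUT / 'selection_log.tsv'}")


if __name__ == "__main__":
    main()
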