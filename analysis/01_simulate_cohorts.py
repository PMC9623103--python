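#!/usr/bin/env python
"""Generate the two synthetic GWAS study pairs the analysis runs on.

The "paper-forward" scenario emulates using rheumatoid-arthritis (RA)
instruments (5 SNPs, exposure study n=58,284) against a celiac-disease (CD)
outcome study (n=15,283) with a planted causal odds ratio of 1.46; the
"paper-reverse" scenario swaps the roles (4 CD instruments, planted OR
1.05). Writes the four summary-statistics tables under results/data/ and
reports instrument strength for each exposure.
"""

import math
from pathlib import Path

from tsmr.gwas_io import write_summary_stats
from tsmr.instrument_selection import instrument_strength
from tsmr.synthetic_data import scenario_preset, simulate_summary_stats

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name, label in (("paper-forward", "ra_to_cd"), ("paper-reverse", "cd_to_ra")):
        cfg = scenario_preset(name)
        exposure, outcome, truth = simulate_summary_stats(cfg)
        write_summary_stats(exposure, OUT / f"{label}_exposure.tsv")
        write_summary_stats(outcome, OUT / f"{label}_outcome.tsv")
        s = instrument_strength(exposure, cfg.n_exp)
        print(
            f"{name}: J={cfg.J}, n_exp={cfg.n_exp:,}, n_out={cfg.n_out:,}, "
            f"true OR={math.exp(cfg.theta):.2f}"
        )
        print(
            f"  instruments explain {100 * s.r2_total:.1f}% of exposure variance; "
            f"F statistics range {s.F_min:.0f} to {s.F_max:.0f}"
        )
    print(f"wrote summary statistics to {OUT}")


if __name__ == "__main__":
    main()
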