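#!/usr/bin/env python
"""Half-maximum latency of pulse responses across behavioural conditions.

Simulates a 16-animal cohort stimulated with 50 ms light pulses at 1 Hz,
estimates each animal's half-maximum latency in the before / walking /
after epochs (mean of five pulses per 5 s segment), and compares
conditions with paired Wilcoxon tests (Bonferroni-corrected).

Expected outcome: latency is shortest while walking (generating medians
10.3 / 8.7 / 10.1 ms) and the walking-vs-sitting contrasts are clearly
significant.  Note the generator shares one latency offset per animal
across epochs, so even the small 0.2 ms before/after difference is
perfectly paired and can reach significance — unlike noisy real
recordings.
"""

import argparse
from pathlib import Path

from ergpipe.experiments import pulse_cohort_recovery
from ergpipe.stats import paired_wilcoxon_bonferroni

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/pulse"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    out = pulse_cohort_recovery(n_animals=16, seed=args.seed)
    table = out["table"]
    table.to_csv(args.out / "per_animal.csv", index=False, float_format="%.6g")

    med = out["median_latency_ms"]
    print("median half-max latency (ms):",
          {k: round(v, 2) for k, v in med.items()},
          "| generating:", out["generating_medians"])

    wide = table.pivot_table(index="animal", columns="condition",
                             values="latency_ms").dropna()
    comps = paired_wilcoxon_bonferroni(wide)
    stats = pd.DataFrame([vars(c) for c in comps])
    stats.to_csv(args.out / "wilcoxon.csv", index=False, float_format="%.6g")
    print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
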