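#!/usr/bin/env python
"""Quantify snRNA m6Am by conversion sequencing and test a condition shift.

Simulates triplicate conversion-sequencing base counts for 28 snRNA
transcription start sites (conversion efficiency 0.98, 1,000 reads per
TSS) under a control condition and a condition whose true m6Am
stoichiometry is raised by +0.2 at every snRNA — the kind of global
increase a demethylase knockdown produces at these sites. Runs the
per-snRNA paired analysis.

Writes results/crown_snrna_stats.tsv and results/crown_summary.json.
"""

import json
from pathlib import Path

import numpy as np

from modstoich.crown import per_snrna_condition_stats
from modstoich.simulate import CrownSimConfig, simulate_crown_counts

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    truth = {
        f"RNU-{i}": f for i, f in enumerate(np.linspace(0.05, 0.6, 28))
    }
    ctrl_cfg = CrownSimConfig(
        tss=truth, coverage=1000, replicates=3, seed=SEED
    )
    treat_cfg = CrownSimConfig(
        tss={g: min(1.0, f + 0.2) for g, f in truth.items()},
        coverage=1000, replicates=3, seed=SEED + 7919,
    )
    ctrl, _ = simulate_crown_counts(ctrl_cfg)
    treat, _ = simulate_crown_counts(treat_cfg)
    per, res = per_snrna_condition_stats(ctrl, treat)
    per.to_csv(OUT / "crown_snrna_stats.tsv", sep="\t", index=False)
    summary = {
        "n_snrna": res.n,
        "mean_delta": res.mean_delta,
        "t": res.t,
        "p_value": res.p_value,
    }
    with open(OUT / "crown_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(
        f"paired analysis over {res.n} snRNAs: mean m6Am increase "
        f"{res.mean_delta:+.3f}, t={res.t:.2f}, p={res.p_value:.3g}"
    )
    print("per-snRNA condition means in results/crown_snrna_stats.tsv")


if __name__ == "__main__":
    main()
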