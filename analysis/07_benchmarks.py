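#!/usr/bin/env python
"""Frozen study-condition benchmarks: sweep recovery, CLR localization,
GWAS calibration, bottleneck-test calibration.

These are the same experiment definitions the test suite and
scripts/acceptance.py use (peachpop.experiments); this driver runs them
once and writes results/benchmarks.json.
"""

import json
from pathlib import Path

from peachpop.experiments import (
    bottleneck_calibration_experiment,
    gwas_calibration_experiment,
    sweep_recovery_experiment,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "benchmarks.json"


def main():
    out = {}
    rec = sweep_recovery_experiment(n_replicates=10, base_seed=1)
    print(f"sweep recovery (ROD top-5%): {rec['recovery_fraction']:.0%} of "
          f"{rec['n_truth']} planted sweeps")
    print(f"CLR localization within 100 kb: {rec['clr_localized_fraction']:.0%} of "
          f"{rec['n_clr_scanned']} recovered sweeps")
    out["sweep_recovery"] = rec

    gw = gwas_calibration_experiment(seed=1, n_power_reps=10)
    print(f"GWAS: type-I {gw['type1_rate']:.3f} at alpha=0.05 over {gw['n_snps']} SNPs; "
          f"planted-QTL top-5 power {gw['power_top5']:.0%}")
    out["gwas"] = gw

    bt = bottleneck_calibration_experiment(base_seed=1, n_eq_reps=50, n_bott_reps=10)
    print(f"bottleneck test: false-positive rate {bt['false_positive_rate']:.2f} at "
          f"equilibrium; power {bt['power']:.0%} against a recent 10-fold bottleneck")
    out["bottleneck"] = bt

    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(out, indent=2))
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
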