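#!/usr/bin/env python
"""Photobleaching decay over 50 irradiation cycles.

Simulates the fixed-cell photostability scenario for three probes whose
end-point losses are 12% (the photostable acid-bright probe), 83%
(fluorescein) and 82% (Oregon Green), normalizes each field to its
first cycle (F/F0) and reports the measured fraction lost.

Writes results/photobleach_curves.csv and results/photobleach_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import lysoratio as lr

SCENARIOS = {"aphid": 0.12, "fluorescein": 0.83, "oregon_green": 0.82}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    curves, summary = [], []
    for i, (probe, lost) in enumerate(SCENARIOS.items()):
        series = lr.simulate_photobleach(1500.0, lost, n_cycles=50,
                                         noise_cv=0.005, seed=args.seed + i,
                                         probe=probe)
        measured = lr.photobleach_curve(series.table["intensity"], probe=probe)
        curves.append(measured.table.assign(probe=probe))
        summary.append({"probe": probe, "generating_fraction_lost": lost,
                        "measured_fraction_lost": measured.fraction_lost})
        print(f"{probe}: lost {100 * measured.fraction_lost:.1f}% "
              f"(generating {100 * lost:.0f}%)")

    args.out.mkdir(parents=True, exist_ok=True)
    pd.concat(curves, ignore_index=True).to_csv(
        args.out / "photobleach_curves.csv", index=False)
    pd.DataFrame(summary).to_csv(args.out / "photobleach_summary.csv",
                                 index=False)
    print(f"wrote {args.out / 'photobleach_summary.csv'}")


if __name__ == "__main__":
    main()
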