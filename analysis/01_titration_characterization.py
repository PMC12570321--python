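#!/usr/bin/env python
"""Characterize probe pH titrations: pKa and dynamic range.

Simulates plate-reader titrations (25 pH points in 1.5-8.5, duplicate
wells, 2% CV) for an acid-bright probe with pKa 5.4 and a base-bright
fluorescein-like probe, fits the 4-parameter logistic to each, and
tabulates fitted pKa, slope and the pH 4 vs 6 fold-change.

Writes results/titration_fits.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import lysoratio as lr


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    grid = np.linspace(1.5, 8.5, 25)
    rows = []
    for i, probe in enumerate((lr.APHID_LIKE, lr.FLUORESCEIN_LIKE)):
        series = lr.simulate_titration(probe, grid, replicates=2,
                                       noise_cv=0.02, seed=args.seed + i)
        fit = lr.fit_sigmoid(series)
        dr = lr.dynamic_range(fit, 4.0, 6.0)
        rows.append({
            "probe": probe.name, "true_pka": probe.pka,
            "fitted_pka": fit.pka, "pka_se": fit.se.get("pka", np.nan),
            "fitted_slope": fit.slope, "polarity": probe.polarity,
            "fold_ph4_vs_ph6": dr.fold, "brighter_at": dr.brighter_at,
            "converged": fit.converged,
        })
        print(f"{probe.name}: pKa {fit.pka:.3f} (true {probe.pka}), "
              f"{dr.fold:.1f}x brighter at pH {dr.brighter_at:g}")

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "titration_fits.csv", index=False)
    print(f"wrote {args.out / 'titration_fits.csv'}")


if __name__ == "__main__":
    main()
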