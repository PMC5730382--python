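#!/usr/bin/env python
"""Protein stability and mobility: chase half-life and FRAP rate comparison.

Fits exponential decays to 10 synthetic cycloheximide-chase recordings
(11 points over 10 min each, 2% noise, true half-life 40 min) and reports the
per-recording and mean extrapolated half-life. Then fits linear recovery to
a FRAP pair generated with identical true slope (with/without translation
block) and checks that the rates are statistically comparable.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from slamkit.io import write_json
from slamkit.kinetics import compare_rates, fit_exponential_decay, fit_linear_recovery
from slamkit.synthetic import gen_decay_trace, gen_recovery_trace

OUT = Path(__file__).resolve().parents[1] / "results" / "03_protein_kinetics"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(10):
        trace = gen_decay_trace(t_half=40.0, seed=args.seed * 1000 + i)
        fit = fit_exponential_decay(trace)
        rows.append(
            {"recording": i, "t_half_min": fit.t_half, "k_per_min": fit.k,
             "window_min": fit.window_span, "extrapolated": fit.extrapolated}
        )
    chase = pd.DataFrame(rows)
    chase.to_csv(OUT / "chase_fits.tsv", sep="\t", index=False)
    mean_thalf = chase["t_half_min"].mean()
    print(
        f"chase: mean extrapolated half-life {mean_thalf:.1f} min over "
        f"{len(chase)} recordings (sd {chase['t_half_min'].std(ddof=1):.1f}); "
        f"every fit window (10 min) is shorter than t1/2 -> extrapolated"
    )

    buffer_fit = fit_linear_recovery(gen_recovery_trace(slope=2.0, seed=args.seed * 2000))
    cyhx_fit = fit_linear_recovery(gen_recovery_trace(slope=2.0, seed=args.seed * 2000 + 1))
    cmp = compare_rates(buffer_fit, cyhx_fit)
    write_json(
        {
            "chase_mean_t_half_min": mean_thalf,
            "frap_slope_buffer": buffer_fit.slope,
            "frap_slope_cyhx": cyhx_fit.slope,
            "frap_rate_ratio": cmp.ratio,
            "frap_ci_overlap": cmp.intervals_overlap,
        },
        OUT / "summary.json",
    )
    print(
        f"FRAP: recovery rate {cyhx_fit.slope:.2f} with vs {buffer_fit.slope:.2f} "
        f"without translation block (ratio {cmp.ratio:.2f}); "
        f"95% CIs overlap: {cmp.intervals_overlap} -> rates comparable, so "
        f"recovery reflects exchange of molecules, not new synthesis"
    )


if __name__ == "__main__":
    main()
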