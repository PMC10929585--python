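"""Energy landscape of mean binarized activity, before vs after.

Binarizes each trace at the activity threshold, computes the mean-field
order parameter m(t), estimates -log p(m') by Gaussian KDE on a
million-bin grid over [-2.7, 2.7], fits the quartic energy, and reports
the scaled (c) and unscaled (a) coefficients with the stability verdict.
"""

import pandas as pd

from _common import RESULTS, config
from calcinet import binarize, estimate_landscape, load_traces, mean_activity
from calcinet.io import dump_json


def main() -> None:
    cfg = config()
    rows = []
    for condition in ("before", "after"):
        ts = load_traces(RESULTS / f"traces_{condition}.csv", condition=condition)
        series = mean_activity(
            binarize(ts, cfg.binarize_threshold), dt=ts.dt, condition=condition
        )
        landscape = estimate_landscape(
            series, support=tuple(cfg.grid_support), n_bins=cfg.grid_bins
        )
        dump_json(landscape.to_dict(), RESULTS / f"landscape_{condition}.json")
        row = {
            "condition": condition,
            "mu_m": landscape.mu_m,
            "sigma_m": landscape.sigma_m,
            **{f"c{j}": landscape.c[j] for j in range(5)},
            "verdict": landscape.stability.label,
        }
        rows.append(row)
        print(
            f"{condition:7s}: mu_m {landscape.mu_m:.3f}, sigma_m {landscape.sigma_m:.3f}, "
            f"c = {[round(float(x), 4) for x in landscape.c]} -> {landscape.stability.label}"
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "landscape_parameters.csv", index=False)
    print(f"wrote {RESULTS / 'landscape_parameters.csv'}")


if __name__ == "__main__":
    main()
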