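"""Infer the functional coupling matrix per condition and compare to truth.

Fits the lag-1 autoregression (75% contiguous training split) to each
condition, reports train/test error and the excitatory:inhibitory sign
ratio, validates the estimate against the generating matrix, and writes
the coupling-change histogram between conditions.
"""

import json

import numpy as np
import pandas as pd

from _common import RESULTS, config
from calcinet import (
    connection_sign_counts,
    delta_connectivity,
    fit_connectivity,
    load_traces,
)
from calcinet.io import dump_json


def main() -> None:
    cfg = config()
    fits = {}
    for condition in ("before", "after"):
        ts = load_traces(RESULTS / f"traces_{condition}.csv", condition=condition)
        fc = fit_connectivity(ts, train_frac=cfg.train_frac)
        fits[condition] = fc
        truth = np.asarray(
            json.loads((RESULTS / f"ground_truth_{condition}.json").read_text())["T_true"]
        )
        r = np.corrcoef(fc.T.ravel(), truth.ravel())[0, 1]
        n_pos, n_neg, ratio = connection_sign_counts(fc)
        print(
            f"{condition:7s}: train MSE {fc.train_error:.4f}, test MSE {fc.test_error:.4f}; "
            f"{n_pos} exc / {n_neg} inh couplings (ratio {ratio:.2f}); "
            f"r(T_hat, T_true) = {r:.3f}"
        )
        dump_json(fc.to_dict(), RESULTS / f"connectivity_{condition}.json")
        np.savetxt(RESULTS / f"T_{condition}.csv", fc.T, delimiter=",")

    delta, (counts, edges) = delta_connectivity(fits["before"], fits["after"], bins=40)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}).to_csv(
        RESULTS / "delta_T_histogram.csv", index=False
    )
    up = int((delta[~np.eye(delta.shape[0], dtype=bool)] > 0).sum())
    down = int((delta[~np.eye(delta.shape[0], dtype=bool)] < 0).sum())
    print(f"coupling changes: {up} increased, {down} decreased (histogram written)")


if __name__ == "__main__":
    main()
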