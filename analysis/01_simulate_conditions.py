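"""Generate the synthetic before/after recordings with known ground truth.

Two 20-neuron networks are drawn: the "after" network re-draws half of the
synaptic matrix entries of the "before" network, so couplings move in both
directions.  Each network is simulated for 4,000 frames at 10 Hz with a
Gaussian noise floor, and the traces plus ground-truth couplings are
written under results/analysis/.
"""

import numpy as np

from _common import config
from calcinet import connection_sign_counts, make_fixture


def main() -> None:
    cfg = config()
    result = make_fixture(cfg)
    cfg.to_yaml(f"{cfg.out_dir}/config.yaml")

    for condition, net in result["networks"].items():
        n_pos, n_neg, ratio = connection_sign_counts(net.T_true)
        print(
            f"{condition:7s} ground truth: {n_pos} positive / {n_neg} negative "
            f"couplings (ratio {ratio:.2f}), spectral radius "
            f"{np.abs(np.linalg.eigvals(net.T_true)).max():.3f}"
        )
    delta = result["networks"]["after"].T_true - result["networks"]["before"].T_true
    off = delta[~np.eye(cfg.n_neurons, dtype=bool)]
    print(
        f"perturbation moved {int((off > 0).sum())} couplings up and "
        f"{int((off < 0).sum())} down"
    )
    for condition, path in result["paths"].items():
        print(f"wrote {condition} traces -> {path}")


if __name__ == "__main__":
    main()
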