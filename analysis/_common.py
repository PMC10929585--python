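"""Shared configuration for the numbered analysis scripts.

The scripts emulate the study design: two ~30 min-equivalent recording
conditions ("before" / "after") from related ground-truth networks, at
10 Hz with 20 neurons.  Outputs accumulate under results/analysis/.
"""

from pathlib import Path

from calcinet import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        out_dir=str(RESULTS),
        seed=seed,
        n_neurons=20,
        n_hidden=20,
        n_frames=4000,
        noise_sd=0.8,
        baseline_range=(8.0, 14.0),
        perturbation=0.5,
        thresholds=[float(t) for t in range(0, 5)],
        binarize_threshold=11.0,
        grid_bins=1_000_000,
    )
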