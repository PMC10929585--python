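# calcinet

Mesoscale analysis of neuronal calcium recordings: infer a signed
functional connectivity matrix from ΔF/F traces under a linearized
Hopfield model, quantify network robustness with weighted graph metrics,
forecast responses to external stimulation, and estimate a quartic energy
landscape of mean population activity with a stability classification.
The package is aimed at labs doing miniscope / GRIN-lens calcium imaging
of a few dozen neurons who want a quantitative before/after comparison of
a pharmacological or behavioral perturbation, validated end-to-end on
synthetic data with known ground truth.

## The model

Recorded ("feature") neurons are coupled through unrecorded hidden
neurons by a synaptic matrix ξ; eliminating the fast hidden dynamics
leaves an effective coupling T = ξξᵀ among the recorded neurons.
Discretized at the frame interval δt (0.1 s at 10 frames/s), the currents
obey the lag-1 autoregression

    V_i(t + δt) = Σ_j T_ij V_j(t) + V_i^ext,

fitted per neuron by ordinary least squares (contiguous 75/25 train/test
split). Positive T_ij are functional-excitatory couplings, negative ones
functional-inhibitory; they define two weighted digraphs whose weighted
diameters and betweenness centralities quantify robustness. The fitted T
(diagonal dropped) forecasts the response to any external current via

    V(nδt) = Tⁿ V(0) + Σ_{k=0}^{n-1} Tᵏ V_ext((n-k-1)δt).

Separately, binarized activity gives the order parameter
m(t) = (1/N) Σ_i b_i(t); treating the stationary distribution p(m) as a
Boltzmann weight, the energy E[m] = −log p(m) is estimated by Gaussian
KDE of the standardized m′ on a million-bin grid over [−2.7, 2.7] and a
weighted quartic fit E = Σ_j c_j m′ʲ. The network state is *stable* iff E
has an interior local minimum over the observed activity range.

## Worked example

The numbered scripts under `analysis/` run the full study design on
synthetic before/after recordings (20 neurons, 4,000 frames at 10 Hz,
the "after" network re-drawing half the synaptic entries):

```
cd analysis
python 01_simulate_conditions.py
python 02_select_threshold.py
python 03_infer_connectivity.py
python 04_network_robustness.py
python 05_stimulate_network.py
python 06_energy_landscape.py
```

Representative output (seed 1):

```
before : train MSE 0.6269, test MSE 0.6367; 246 exc / 134 inh couplings (ratio 1.84); r(T_hat, T_true) = 0.977
after  : train MSE 0.6409, test MSE 0.6386; 235 exc / 145 inh couplings (ratio 1.62); r(T_hat, T_true) = 0.979
...
before : mu_m 0.452, sigma_m 0.078, c = [0.9183, 0.1736, 0.4414, -0.0609, 0.0101] -> stable
```

Reading: the inferred coupling matrix correlates with the generating one
at r ≈ 0.98 under a ~10% noise floor; roughly twice as many couplings are
functional-excitatory as functional-inhibitory; and the mean-activity
landscape of this (stationary) synthetic network has a well-defined
interior minimum, i.e. a stable collective state. Tables land under
`results/analysis/`. The same stages are scriptable via the `calcinet`
CLI (`calcinet simulate|preprocess|infer|graph|stimulate|landscape|run`)
or the library API (`calcinet.fit_connectivity`, `calcinet.estimate_landscape`, ...).

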