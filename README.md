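# spikemap

Gradient-free, label-free visual explanations for spiking neural networks
(SNNs), built on inter-spike-interval statistics, together with everything
needed to exercise the method end to end at desk scale: a discrete-time
leaky integrate-and-fire (LIF) simulator with per-time-step batch
normalization, Poisson rate coding, surrogate-gradient training (BPTT),
ANN-to-SNN conversion by layer-wise threshold normalization, Grad-CAM
baselines (on a reference ReLU network and a surrogate-gradient spiking
variant), single-step gradient-sign attacks, quantitative heatmap metrics,
and a synthetic glyph dataset with ground-truth masks.

The core idea: each neuron keeps a running *contribution score* — past
spikes weighted by an exponential kernel `exp(-gamma * gap)` so that bursts
(short inter-spike intervals) count more than sparse firing.  Channel-summing
`score x current spike` yields one non-negative heatmap per time-step from
the forward pass alone: no labels, no gradients, no backward pass.

Everything is pure NumPy/SciPy (no deep-learning framework); the backward
passes (surrogate BPTT, exact ANN backprop) are hand-written and
finite-difference checked in the test suite.

## Command-line usage

```sh
spikemap gen-data  --n-classes 4 --n-per-class 100 --seed 1 --outdir out
spikemap train-snn --data out/dataset.npz --epochs 10 --timesteps 20 --outdir out
spikemap train-ann --data out/dataset.npz --epochs 40 --outdir out
spikemap convert   --ann out/ann.npz --data out/dataset.npz --timesteps 128 --outdir out
spikemap explain   --model out/snn.npz --data out/dataset.npz --method sam \
                   --layer 0 --gamma 0.2 --outdir out
spikemap attack    --model out/ann.npz --mode ann --data out/dataset.npz \
                   --eps 4/255 --outdir out
spikemap evaluate  --model out/snn.npz --ann out/ann.npz --data out/dataset.npz \
                   --outdir out
spikemap demo-suppression --model out/snn.npz --data out/dataset.npz --outdir out
```

Every command writes a JSON run manifest next to its outputs; checkpoints,
rasters and heatmaps go into compressed `.npz` bundles; heatmap overlays
are PNGs (blue = 0 ... red = 1, alpha-blended over the input).

## Package layout

| module | role |
| --- | --- |
| `spikemap.snn_core` | LIF layers, per-time-step normalization, network simulation and surrogate BPTT |
| `spikemap.encoding` | Poisson rate coding, PNG I/O |
| `spikemap.sam` | contribution-score kernel, heatmap computation, normalization, resizing |
| `spikemap.gradcam` | ANN Grad-CAM reference and spiking Grad-CAM baseline |
| `spikemap.training` | surrogate training, ANN training, threshold-normalization conversion |
| `spikemap.attacks` | FGSM for both model families |
| `spikemap.metrics` | localization error, variance, L1 distance, mask score |
| `spikemap.synthetic_data` | glyph dataset with ground-truth masks, two-object composites |
| `spikemap.cli_io` / `spikemap.cli` | bundles, manifests, overlays, command-line interface |
| `spikemap.experiments` | the desk-scale evaluation protocol used by tests and the acceptance script |
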