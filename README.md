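# eiclust

Simulation and analysis toolbox for **E/I-clustered spiking attractor
networks**: leaky integrate-and-fire networks of excitatory and inhibitory
neurons whose joint clustering produces metastable winnerless switching
between cluster activations.  The package covers the full pipeline from
first-principles parameter calibration to a cued motor-decision task with a
threshold readout.

## Modules

| Module | Purpose |
| --- | --- |
| `eiclust.params` | Parameter dataclasses, presets (`table1`, `table2`), YAML round trip |
| `eiclust.calibration` | Scale-free synaptic weights from PSP maxima, rheobase and external currents, cluster weight scaling |
| `eiclust.topology` | Sparse connectivity builders: unclustered balanced, E-clustered, E/I-clustered, and an E-cluster + I-weight variant |
| `eiclust.dynamics` | Exponential-Euler LIF simulation engine (numba) with stimulus protocols, state probes and current recording |
| `eiclust.stats` | Spike-train variability statistics: Fano factor, CV/CV2, time-resolved traces, synchrony, stimulus Δ-statistics, renewal consistency |
| `eiclust.task` | Cued reach-direction task: protocol generation, leaky-integrator decision variable, threshold readout, reaction times, time-resolved decoding |
| `eiclust.fixtures` | Surrogate spike-train generators (Poisson, gamma-renewal, rate-switching) and scripted simulation scans |
| `eiclust.cli` | `eiclust` command-line interface over all of the above |

## Quick start

```python
import eiclust as ec

spec = ec.table1(Q=50, J_Eplus=10.5, R_J=0.75)        # 5000-neuron preset
conn = ec.build_ei_clustered(spec, spec.scaling, seed=1)
data = ec.simulate(conn, spec, duration=2000.0, seed=2)
print(data.rate(data.population_units("E")), "spikes/s")
```

Command line:

```sh
eiclust calibrate --config table1 --out weights.json
eiclust simulate --config table1 --topology random --duration 2000 --seed 1 --out-dir run/
eiclust fig2-scan --out-dir scan/        # Fano factor vs clustering strength
eiclust task run --trials 30 --seed 7 --out-dir task/
```

The acceptance script reproduces the package's headline numbers
(calibrated weights, balanced-state rate, metastable Fano factor):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Tests

```sh
pytest -q
```

`tests/test_acceptance.py` holds one test per acceptance criterion,
including multi-minute network simulations; the remaining files are fast
unit/property suites per module.  Known limitations (see `docs/methods.md`):
under the task preset a 0.1 pA cue does not reliably capture the cued
attractor within the 1 s preparatory period, so the tests on preparatory
Fano-factor ordering and CV2 level fail honestly; and in the E-clustered
network the continuous trial protocol samples slow attractor switching,
which inflates spontaneous variability and flips the sign of the
stimulus-evoked Fano-factor change expected of that topology.
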