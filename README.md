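# ecwm — efficient-coding models of visual working memory

`ecwm` implements a neural resource model of continuous-report working
memory in which a heterogeneous population code arises from efficient
coding: von Mises tuning functions are warped through the CDF of a
stimulus prior, population activity is divisively normalized by set size,
spiking is Poisson, and recall is the circular posterior mean of a
Bayesian decoder that reuses the prior. The package also provides:

- an extended **slots-plus-averaging** competitor with orientation-dependent
  precision and bias modulation;
- **grid-search maximum-likelihood fitting** of both models through binned
  J×Q stimulus-by-response matrices (Monte Carlo with common random
  numbers for the neural model, exact quadrature for slots-plus-averaging),
  with AIC model comparison and resampled model-prediction curves;
- **circular statistics**: weighted circular means/SDs and von Mises
  kernel-smoothed bias/precision curves over the orientation dimension;
- a **contamination mixture model** (von Mises + uniform, mean
  `eta*sin(2*theta)`) for denoised per-block bias estimation, with
  multi-start Nelder–Mead fitting and per-subject adaptation-slope
  summaries;
- **synthetic data generators** for model observers and a full
  block-structured adaptation experiment with bimodal nontarget
  distributions.

Orientations live on the half-circle [−90°, 90°), mapped internally to
[−π, π) radians (`theta_rad = theta_deg * pi / 90`). Files use degrees;
all computation uses mapped radians.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the heavier end-to-end acceptance
criteria (parameter recovery on reduced grids, qualitative model
signatures, pipeline recovery); the remaining files are per-module unit
and property tests.

## Command line

All commands accept `--config <yaml>` (validated strictly; unknown keys
error), `--seed`, and `--verbose`.

```sh
# simulate a synthetic observer -> trial CSV (degrees)
ecwm simulate --seed 1 --out trials.csv

# simulate the 8-block adaptation experiment
ecwm simulate-experiment --seed 1 --out exp.csv

# grid-search fit (family: neural | spa; grid: coarse | full)
ecwm fit --trials trials.csv --family neural --grid coarse --seed 1 --out fit.json

# AIC comparison table from fit JSONs
ecwm compare --neural n1.json --spa s1.json --out compare.csv

# kernel-smoothed bias/precision curves per set size
ecwm curves --trials trials.csv --out curves.csv

# per-block contamination-mixture bias estimates
ecwm fit-bias --trials exp.csv --out bias.csv
```

Trial CSV header:
`subject,condition,block,set_size,target_deg,nontargets_deg,response_deg`
(`nontargets_deg` is a `;`-separated list with `set_size - 1` entries).

## Library sketch

```python
import numpy as np
from ecwm import Prior, PopulationConfig, simulate_trials, circ_diff, smooth_curves

prior = Prior("natural_cardinal")              # p(theta) ∝ 2 - |sin theta|
config = PopulationConfig(M=100, kappa=2.0, gamma=50.0, prior=prior)
targets = np.linspace(-np.pi, np.pi, 25, endpoint=False)
tt, responses = simulate_trials(config, targets, N=4, reps=2000, seed=0)
bias, precision = smooth_curves(tt, circ_diff(responses, tt))
```
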