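# ceemi

**Cell-state-conditioned mutual information for heterogeneous cell
populations.**

Channel-capacity estimates for mammalian signaling networks are
famously low (~1 bit): judged by its population-averaged dose response,
a cell can barely tell whether a ligand is present.  But cell
populations are heterogeneous in stable state variables θ — receptor
numbers, enzyme levels, effective rates — and averaging over that
heterogeneity conflates cell-to-cell variability with sensing noise.
`ceemi` treats each cell as its own channel p(x|u,θ) and estimates the
population distribution of single-cell sensing fidelities:

- **I(θ)** — mutual information between dose u and output x for one
  cell, in bits;
- **I_Cee = ⟨I(θ)⟩_p(θ)** — the conditional mutual information;
- **I_CSA** — the conventional cell-state-agnostic MI of the pooled
  channel p(x|u) = ∫ p(x|u,θ) p(θ) dθ;
- **p_CeeMI(I)** — the distribution of I(θ) across the population, and
  its joint p_CeeMI(I, χ) with biochemical covariates χ(θ).

Because I_CSA − I_Cee = −I(U;Θ|R) ≤ 0 whenever the experimenter picks
the inputs, typical cells resolve their environment better than the
"average cell" suggests.

The package is aimed at quantitative cell biologists with single-cell
dose-response data (flow cytometry or live-cell imaging snapshots,
repeated-stimulation trajectories) and at modelers studying information
flow in signaling networks.  It provides:

- discrete-channel information theory with IQR-fraction binning and
  capacity optimization over the input simplex (`ceemi.info_core`);
- an analytic receptor-ligand toy population (`ceemi.toy_model`);
- stochastic EGF/EGFR and IGF/FoxO network models with Gaussian moment
  closure, exact Gillespie simulation and fluorescence-to-molecule
  calibration (`ceemi.pathway_models`);
- maximum-entropy (MERIDIAN-style) inference of the cell-state
  distribution from percentile constraints (`ceemi.maxent`);
- population summaries: p_CeeMI(I), covariate correlations, optimal
  inputs (`ceemi.estimation`);
- a cell-state-dynamics study of how mRNA turnover sets the divergence
  between conditioned and agnostic sensing (`ceemi.dynamics`);
- a repeated-stimulation trajectory pipeline with the δ/δ₀
  repeatability contrast (`ceemi.experimental`);
- seeded synthetic-data generators with ground-truth sidecars
  (`ceemi.synth`).

## Worked example

Build a heterogeneous in-silico population of the toy receptor model
(bound-receptor mean μ_B = R0·L·kbind/(L·kbind + kdeg + kunbind),
Poisson per cell, R0 gamma-distributed across cells) and compare the
pooled channel with the typical cell:

```python
import numpy as np
from ceemi import conditional_mi, cell_state_agnostic_mi
from ceemi.toy_model import (
    ToyPopulation, build_input_gamma, dose_response_models,
    quantile_grid_ensemble,
)

p_L = build_input_gamma(mean=10.0, cv=1.0, n_bins=25)  # discretized gamma input
pop = ToyPopulation("R0", mean=500.0, cv=0.3)          # receptor heterogeneity
ensemble = quantile_grid_ensemble(pop, 21)             # deterministic 21-cell grid
forward = lambda theta: dose_response_models(theta, p_L.doses)

icee = conditional_mi(ensemble, forward, p_L)
icsa = cell_state_agnostic_mi(ensemble, forward, p_L)
print(f"I_Cee = {icee:.3f} bits, I_CSA = {icsa:.3f} bits, "
      f"interaction = {icsa - icee:.3f} bits")
```

Output:

```
I_Cee = 2.987 bits, I_CSA = 1.420 bits, interaction = -1.567 bits
```

The typical cell resolves ~3 bits of ligand information; the pooled
"average cell" only ~1.4 bits — the 1.57-bit difference is information
hidden by population heterogeneity, not lost to noise.  The same
comparison from the command line:

```sh
ceemi simulate-toy --variable R0 --cv-grid 0.0316,0.1,0.316 --seed 0 --out sweep.csv
```

Other entry points: `ceemi capacity` (capacity of a serialized channel),
`ceemi synth` (synthetic data with ground truth), `ceemi analyze-cells`
(repeated-stimulation trajectories → per-cell MI), `ceemi fit-maxent`
(maxent fit of toy heterogeneity to a snapshot), `ceemi
simulate-dynamics` (conditioned MI vs mRNA turnover).

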