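# sectransport

Kinetic analysis of SecA/SecYEG-mediated protein transport assays, and the
Lys/Arg composition bias of secreted proteomes.

Bacterial secretory proteins cross the plasma membrane through the Sec
machinery: the SecYEG channel driven by the SecA ATPase. The split-NanoLuc
transport assay reports the instant a pep86-tagged pre-protein finishes
crossing into a vesicle, producing sigmoidal luminescence time courses
whose *lag* measures total transport time. This package implements the
computational side of that experiment end to end, with a synthetic-data
generator standing in for the wet-lab assay:

- a sequential-step kinetic ODE model of transport (binding equilibrium →
  initiation → n steps at rate k_step, with failure/restart k_fail and
  permanent blocking k_block), in single- and two-segment (native +
  variable central region) form;
- lag + single-exponential trace fits, and step-number selection by a
  normalized-RMSD scan over n, including detection of the unresolvable
  "plateau" regime where steps are uniformly too fast to count;
- the proton-motive-force effect statistic,
  PMF effect (%) = 100·(lag₋PMF/lag₊PMF − 1), with SEM-derived bounds, and
  the lag-vs-tag-position transport-rate line;
- per-protein Lys/(Lys+Arg) fractions by localization class (cytosolic /
  Sec / Tat), Sturges-rule histograms, Gaussian fits and class comparisons
  — the proteome-scale signature of arginine being the slowest residue to
  transport;
- sliding-window residue property profiles (Kyte–Doolittle hydrophobicity,
  Deleage–Roux helical propensity, Zimmerman bulkiness).

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Generate twelve replicate traces from the baseline-construct kinetics
(6 steps at 5.31 min⁻¹), then ask the scan which step number the data
support:

```python
import numpy as np
from sectransport.fitting import average_traces, fit_lag_exponential, scan_steps
from sectransport.synthetic_data import LXX_PARAMS, TraceGenSpec, make_trace_dataset

traces = make_trace_dataset(TraceGenSpec(params=LXX_PARAMS, noise_sd=0.01,
                                         replicates=12, seed=1))
lag_fit = fit_lag_exponential(average_traces(traces))
print(f"lag = {lag_fit.lag:.3f} min, A = {lag_fit.A:.3f}, "
      f"lambda = {lag_fit.lam:.3f} min^-1")

scan = scan_steps(traces, n_range=range(1, 16))
print(f"best n = {scan.best_n}, k_step = {scan.best_params['k_step']:.2f} min^-1, "
      f"k_fail = {scan.best_params['k_fail']:.2f} min^-1")
print("normalized RMSD:", np.round(scan.normalized_rmsd, 2))
```

Output:

```
lag = 0.642 min, A = 0.716, lambda = 0.894 min^-1
best n = 6, k_step = 5.32 min^-1, k_fail = 0.50 min^-1
normalized RMSD: [4.33 2.66 1.86 1.35 1.08 1.   1.06 1.19 1.34 1.5  1.65 1.79 1.92 2.04
 2.16]
```

The lag (0.64 min) is the transport time of everything up to and including
the tag crossing; the amplitude sits below 1 because a fraction of
substrates fails or blocks before completing. The RMSD profile, normalised
to its minimum, dips sharply at n = 6 — the generating step count — and the
per-step rate is recovered within 1%. A profile that keeps falling and
flattens as n grows instead (`scan.plateau`) means the step number is
unresolvable, the signature of uniformly fast steps.

A command-line interface mirrors the library
(`sectransport simulate|fit-trace|scan-steps|fit-variant|pmf-effect|lysarg|profile`);
every run writes a manifest with inputs, configuration and seed.

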