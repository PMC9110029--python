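# Methods

## The kinetic model

The package models the split-NanoLuc protein transport assay for the
bacterial Sec machinery. A pre-protein substrate S carrying the pep86 tag
binds reversibly to an active transport site Y (SecYEG with the 11S
luciferase fragment enclosed in the vesicle), forming a pre-initiation
complex C0. The reaction mixture is assumed to be at binding equilibrium
before ATP addition, which defines t = 0; the initial occupancy of C0 is
the exact solution of the bimolecular equilibrium
[C0]/([S][Y]) = k_on/k_off under both mass balances.

After initiation (rate `k_init`, by default equal to `k_step`), transport
proceeds through n sequential kinetic steps, each an exponential transition
at rate `k_step`. The final step moves the pep86 tag across the membrane;
NanoLuc complementation is effectively instantaneous relative to transport,
so the luminescent species L is produced by the last transition directly.
The reaction network is

    S + Y  ⇌  C0        (k_on, k_off)
    C0     →  I_1       (k_init)
    I_i    →  I_{i+1}   (k_step, i = 1..n-1)
    I_n    →  L         (k_step)
    I_i    →  S + Y     (k_fail,  i = 1..n-1)   restart, no memory of progress
    I_i    →  B_i       (k_block, i = 1..n-1)   site permanently trapped

and the observable is `signal(t) = brightness · [L](t) / site_total`.
Blocked states are lumped into one absorbing pool, since only their total
affects the signal. With failure and blocking off and sites saturated with
pre-bound substrate, the chain is a pure first-passage process over n+1
equal-rate transitions, so the signal equals the Erlang CDF with shape n+1
and rate `k_step`; this closed form is the simulator's analytic oracle
(agreement < 1e-9 in practice, asserted at < 1e-4). With `k_fail` = 0 the
completion probability is `(k_step/(k_step+k_block))^(n-1)` — only the n−1
interior intermediates carry the failure/blocking branches; the state about
to complete does not, which is what makes both closed forms consistent.

The two-segment variant assigns separate `n_var`, `k_step_var`,
`k_fail_var`, `k_block_var` to a central "variable" region flanked by
native sequence. The chain runs: initiation and the first native steps at
native rates, then the variable block, then the final native (tag-crossing)
step. Because the ODE system is linear past the binding step, segment
placement does not otherwise affect the signal. The segmented chain reduces
exactly to the single-segment chain when the variable rates equal the
native ones, and to the native-only chain when `n_var` = 0 or
`k_step_var` → ∞.

### Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| n | kinetic transport steps after initiation | — | count |
| k_step | per-step translocation rate | — | min⁻¹ |
| k_init | initiation rate | = k_step | min⁻¹ |
| k_fail | dissociate-and-restart rate | 0 (generator: 0.5) | min⁻¹ |
| k_block | permanent channel-trapping rate | 0.31 | min⁻¹ |
| k_on | substrate association rate | 0.96 | µM⁻¹·min⁻¹ |
| k_off | pre-initiation dissociation rate | 0.085 | min⁻¹ |
| brightness | signal per completed NanoLuc | 1.0 | — |
| substrate_conc | pre-protein concentration | 2.0 | µM |
| site_conc | active site concentration | 0.1 | µM |

`k_block`, `k_on` and `k_off` default to the previously determined assay
constants and are held fixed during fitting. The site concentration is not
directly measurable in the assay; 0.1 µM against 2 µM substrate keeps the
system saturating and largely single-turnover, and both concentrations are
exposed in `AssayConditions`. The default time grid is 0–30 min at 0.1 min
spacing (plate-reader cadence).

### Numerics

The ODE system is integrated with LSODA (stiff-capable, via
`scipy.integrate.odeint`) at rtol 1e-8 / atol 1e-10; rate constants can
span four orders of magnitude in the fast-segment limit, and the implicit
branch handles that regime. The right-hand side is numba-compiled, which
brings one solve on the default grid to ~1.5 ms and makes the multi-start
scans practical. Tiny negative signal excursions (below 10·atol) are
clipped to zero. Mass conservation holds to < 1e-6 of the totals at every
time point (property-tested).

## Fitting

The empirical trace summary is the lag + single-exponential model
`signal(t) = A · (1 − exp(−λ (t − lag)))` for t ≥ lag, zero before. It is
fit by bounded least squares with geometric initialisation (lag from the
10%-of-maximum crossing, λ from the 10–90% rise time). The fitted lag
grows linearly with the generating step number n at fixed `k_step`
(r² > 0.99) and scales exactly as 1/k under time rescaling, but its slope
is ≈ 0.62/k_step rather than 1/k_step: the decomposition assigns part of
the chain's rise to the exponential, so the lag is a proportional
underestimate of the chain's mean transit time. Tests freeze this
empirically (fitted lag of an Erlang(7, 5.31 min⁻¹) curve = 0.7785 min,
0.59 of the 1.32 min mean). Lag *differences* between matched constructs
share the underestimate, so ratios of variable-region lags remain faithful
(a halved variable-segment rate doubles the measured region lag).

Step-number selection is a scan: at each candidate n the mechanistic model
is fit to the (replicate-averaged, by default) trace with `k_step`,
`k_fail` and brightness floating, the other rates fixed. Brightness enters
the signal linearly and is profiled analytically, leaving a 2-parameter
nonlinear problem solved in log-space by bounded least squares from 5
log-spaced starting rates in [0.5, 50] min⁻¹, plus a warm start carried
from the neighbouring n with `k_step` rescaled by n/n_prev. The warm start
matters in the unresolvable regime, where all large n fit equally well and
independent restarts would leave convergence jitter in the profile. The
RMSD profile is normalised to its minimum (exactly 1 there); `best_n` is
the smallest n within 0.1% of the minimum. When the profile at the top of
the scan range is within 1% of the minimum and non-increasing over the
last five n values, the step number is declared unresolved (`plateau`):
this operationalises the regime where steps are uniformly too fast to
count, and also fires, correctly, when a truncated scan ends before the
minimum. Per-replicate fitting (parameter means with SEM) is available as
a mode; which convention the original analysis used is not recorded, so
the averaged-trace mode is the default.

Variant fitting holds the native segment (from a prior baseline-construct
scan) bit-identical, fixes brightness to the variant's measured value
relative to the native construct, and scans `n_var` with `k_step_var` and
`k_fail_var` floating (`k_block_var` optionally). Recovery tests show the
generating `n_var` and rate are returned within 10% at 1% noise, including
when the generating brightness is halved.

## PMF analysis

The PMF effect is `100 · (lag₋PMF/lag₊PMF − 1)` on baseline-subtracted
variable-region lags: 0% means no effect, 100% a halving of lag with PMF.
Error bounds are the worst-case SEM combinations,
upper = `100·((lag₋+sem₋)/(lag₊−sem₊) − 1)` and symmetrically for the
lower bound; bounds are undefined (an error) when `lag₊ − sem₊ ≤ 0`. SEMs
of derived lags combine in quadrature (independent replicates). The
lag-vs-tag-position line is fit by ordinary least squares by default
(weighted 1/sem² mode available); its slope is the time per transported
domain and the reciprocal the transport rate in domains·min⁻¹.

## Proteome statistics

Per protein, the statistic is K/(K+R) over the mature sequence — the
signal peptide (1-based inclusive span) is removed for secreted classes
first. Proteins with no K and no R are excluded; the histogram denominator
n counts only defined values. Bin counts follow Sturges' rule
`round(1 + 3.322·log10 n)` (3.322·log10 = log2, recovering the original
1 + log2 n); bins are half-open on [0, 1] with the final bin closed, so
the boundary values 0 and 1 are assigned deterministically. Single
Gaussians are fit to (bin-center, frequency) pairs by least squares; a
large residual RMSD flags a distribution a single Gaussian cannot
describe. Class comparisons default to a two-tailed Welch t-test, with a
two-sided permutation test (difference of means, add-one-corrected
Monte-Carlo p) as the alternative; the two agree within Monte-Carlo error
on moderate samples, which is property-tested.

## Sequence properties

Window profiles are unweighted means of per-residue scale values over an
odd window (default 9), the ProtScale convention; positions within half a
window of an end are undefined rather than computed on shrunken windows.
Three published scales ship as data: Kyte–Doolittle hydrophobicity,
Deleage–Roux α-helix propensity, and Zimmerman bulkiness. Unknown residues
(X) are excluded from window means; a window over 20% unknown is
undefined, and any letter outside the 20-residue alphabet plus X is an
error. Region averages use raw per-residue values (not windowed ones);
a windowed average can be had via a full-length window.

## Synthetic data

The trace generator forward-simulates the kinetic model and adds i.i.d.
additive Gaussian noise on the normalized signal, default SD 0.01 —
plate-reader-like noise on smooth replicate-averaged traces. The default
baseline parameters are the published best fit of the short-topology
construct (n = 6, k_step = 5.31 min⁻¹); the native two-segment truth adds
n_var = 6 at 6.74 min⁻¹. The failure rate is not separately published for
the baseline construct, so the generator uses 0.5 min⁻¹, chosen once as an
order of magnitude below `k_step` (mild amplitude loss). The variant panel
adds a "fast" family (n_var = 20 at 60 min⁻¹ — uniformly fast steps, the
arginine-free regime whose scan plateaus) and a "slow" family (n_var = 6
at 1.3 min⁻¹, a ~3 min variable-region lag). The proteome generator draws
each protein's target K/(K+R) from a truncated normal per class, composes
the mature region to realize the target within one positive residue
(positives at 11% of residues, remaining composition from Swiss-Prot
average frequencies), and attaches signal peptides whose composition is
independent of the mature-region bias.

What the generators do *not* emulate: instrument drift and
replicate-to-replicate amplitude variation in traces; real proteome
length/composition covariation, genuine signal-peptide composition, and
annotation noise. Passing recovery tests therefore demonstrate the
correctness and identifiability of the analysis under the stated noise
model, not robustness to every artefact of real assay or annotation data.

## Problem sizes

Tests and the acceptance script use 12 replicates at 1% noise for
step-number recovery (scan n = 1..15, ~10 s), 6 replicates for the
20-dataset recovery sweep, and 500 proteins per class for the proteome
round trip — sizes at which the selection behaviour is stable across
seeds.

## Known limitations

- The scan selects n by raw normalized RMSD with a fixed tie-break and
  plateau rule; no information criterion penalises the extra parameters,
  by design (matching the original analysis), so closely tied n values at
  low replication resolve to the smaller n.
- The lag + exponential lag underestimates absolute transit times (above);
  only matched differences and ratios should be interpreted quantitatively.
- The exact placement of the variable segment relative to the native steps
  is unidentifiable from the signal (linear chain); the implementation
  fixes a topology-consistent order.
- The binding step is bimolecular, so brightness profiling is exact only
  given fixed binding parameters, which are always held fixed here.
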