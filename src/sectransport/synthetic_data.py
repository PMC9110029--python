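"""Generators standing in for the wet-lab inputs of the pipeline.

Three generators cover the pipeline's input surface without any downloads:

- :func:`make_trace_dataset` forward-simulates luminescence transport traces
  from the kinetic model and adds plate-reader-like additive Gaussian noise
  (default SD 0.01 on the normalized signal).
- :func:`make_variant_panel` emits a matched experimental design: a
  short-topology baseline construct (tag after the first domain) plus
  variant constructs with distinct variable-segment kinetics, together with
  a ground-truth manifest.
- :func:`make_proteome` composes an annotated synthetic proteome whose
  per-class Lys/(Lys+Arg) distributions follow prescribed truncated-normal
  targets, with signal peptides whose composition is independent of the
  mature-region bias.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Union

import numpy as np

from .errors import ParameterError
from .fitting import TransportTrace
from .kinetic_model import (
    AssayConditions,
    RateParameters,
    SegmentedRateParameters,
    simulate_segmented_trace,
    simulate_trace,
)
from .proteome_stats import ProteinRecord

__all__ = [
    "TraceGenSpec",
    "ClassSpec",
    "ProteomeGenSpec",
    "make_trace_dataset",
    "make_proteome",
    "make_variant_panel",
    "LXX_PARAMS",
    "XLX_WT_SEGMENTS",
    "BACKGROUND_FREQUENCIES",
]

#: Best-fit kinetics of the baseline (tag-after-first-domain) construct:
#: 6 steps at 5.31 min^-1 with the standard fixed assay constants.  The
#: failure rate is not separately published for this construct; 0.5 min^-1
#: (an order of magnitude below k_step) gives the mild amplitude loss seen
#: in real traces.
LXX_PARAMS = RateParameters(n=6, k_step=5.31, k_fail=0.5)

#: Two-segment kinetics of the native full-length construct: the variable
#: central domain adds 6 steps at 6.74 min^-1.
XLX_WT_SEGMENTS = SegmentedRateParameters(
    native=LXX_PARAMS, n_var=6, k_step_var=6.74, k_fail_var=0.5, k_block_var=0.31
)

# Swiss-Prot average amino-acid frequencies (percent), used as the sequence
# background outside the controlled K/R statistic.
BACKGROUND_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


@dataclass(frozen=True)
class TraceGenSpec:
    """Specification of one synthetic replicate trace set."""

    params: Union[RateParameters, SegmentedRateParameters]
    noise_sd: float = 0.01
    replicates: int = 3
    seed: int = 0
    conditions: AssayConditions = field(default_factory=AssayConditions)
    construct: str = "synthetic"
    condition: str = "synthetic"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")


@dataclass(frozen=True)
class ClassSpec:
    """Per-class targets for the synthetic proteome generator."""

    n: int
    lys_frac_mean: float
    lys_frac_sd: float = 0.12
    length_mean: float = 300.0
    length_sd: float = 80.0
    ss_length_mean: float = 22.0
    ss_length_sd: float = 3.0

    def __post_init__(self):
        if self.n < 10:
            raise ParameterError("need at least 10 proteins per class")
        if not 0.0 <= self.lys_frac_mean <= 1.0:
            raise ParameterError("lys_frac_mean must lie in [0, 1]")


@dataclass(frozen=True)
class ProteomeGenSpec:
    """Class layout of a synthetic annotated proteome."""

    classes: Mapping[str, ClassSpec]
    seed: int = 0
    positive_fraction: float = 0.11  # K+R content of the mature region


def make_trace_dataset(spec: TraceGenSpec) -> List[TransportTrace]:
    """Forward-simulate replicate traces with additive Gaussian noise."""
    if isinstance(spec.params, SegmentedRateParameters):
        clean = simulate_segmented_trace(spec.params, spec.conditions)
    else:
        clean = simulate_trace(spec.params, spec.conditions)
    rng = np.random.default_rng(spec.seed)
    traces = []
    for rep in range(spec.replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=clean.signal.shape) if spec.noise_sd else 0.0
        traces.append(
            TransportTrace(
                times=clean.times.copy(),
                signal=clean.signal + noise,
                construct=spec.construct,
                condition=spec.condition,
                replicate=rep,
            )
        )
    return traces


def _compose_region(rng, length: int, target_frac: float, positive_fraction: float) -> str:
    """A sequence whose realized K/(K+R) matches target within 1/(K+R)."""
    n_pos = max(int(round(positive_fraction * length)), 1)
    n_pos = min(n_pos, length)
    n_k = int(round(target_frac * n_pos))
    letters_bg = [aa for aa in BACKGROUND_FREQUENCIES if aa not in "KR"]
    probs = np.array([BACKGROUND_FREQUENCIES[aa] for aa in letters_bg])
    probs /= probs.sum()
    body = rng.choice(letters_bg, size=length - n_pos, p=probs)
    seq = np.concatenate([body, ["K"] * n_k, ["R"] * (n_pos - n_k)])
    rng.shuffle(seq)
    return "".join(seq)


def _compose_signal_peptide(rng, length: int) -> str:
    """Background-composition signal peptide starting with Met."""
    letters = list(BACKGROUND_FREQUENCIES)
    probs = np.array([BACKGROUND_FREQUENCIES[aa] for aa in letters])
    probs /= probs.sum()
    return "M" + "".join(rng.choice(letters, size=max(length - 1, 0), p=probs))


def make_proteome(spec: ProteomeGenSpec) -> List[ProteinRecord]:
    """Annotated synthetic proteome with a controllable per-class K/R bias.

    Per protein, a target K/(K+R) is drawn from a normal truncated to [0, 1]
    around the class mean; the mature region is composed to realize it to
    within one positive residue.  Secreted (Sec/Tat) records get a signal
    peptide span whose composition is independent of the mature-region bias.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for label, cls in spec.classes.items():
        secreted = label != "cytosolic"
        for i in range(cls.n):
            target = np.clip(rng.normal(cls.lys_frac_mean, cls.lys_frac_sd), 0.0, 1.0)
            length = max(int(round(rng.normal(cls.length_mean, cls.length_sd))), 50)
            mature = _compose_region(rng, length, float(target), spec.positive_fraction)
            if secreted:
                ss_len = int(np.clip(round(rng.normal(cls.ss_length_mean, cls.ss_length_sd)),
                                     10, 45))
                seq = _compose_signal_peptide(rng, ss_len) + mature
                span = (1, ss_len)
            else:
                seq = mature
                span = None
            records.append(
                ProteinRecord(id=f"SYN_{label.upper()}_{i:05d}", sequence=seq,
                              loc_class=label, ss_span=span)
            )
    return records


_DEFAULT_VARIANTS: Dict[str, dict] = {
    "wt": {"n_var": 6, "k_step_var": 6.74},
    # all-arginines-removed analogue: many uniformly fast steps, so the
    # RMSD scan over n_var plateaus instead of resolving a minimum
    "fast": {"n_var": 20, "k_step_var": 60.0},
    # extra-arginine analogue: same step count, much slower steps
    "slow": {"n_var": 6, "k_step_var": 1.3},
}


def make_variant_panel(
    seed: int = 0,
    variants: Optional[Mapping[str, dict]] = None,
    noise_sd: float = 0.01,
    replicates_baseline: int = 4,
    replicates_variant: int = 3,
    conditions: Optional[AssayConditions] = None,
    native: RateParameters = LXX_PARAMS,
) -> dict:
    """Matched baseline + variant trace sets with a ground-truth manifest.

    Returns ``{"traces": {name: [TransportTrace, ...]}, "manifest": {...}}``
    where name "LXX" is the baseline (native-only chain) and every other
    name is a two-segment variant whose variable kinetics come from
    ``variants`` (mapping name -> kwargs of variable-segment parameters).
    """
    variants = dict(variants if variants is not None else _DEFAULT_VARIANTS)
    conditions = conditions or AssayConditions()
    rng = np.random.default_rng(seed)
    traces: Dict[str, List[TransportTrace]] = {}
    manifest: Dict[str, dict] = {"seed": seed, "noise_sd": noise_sd,
                                 "native": native.to_dict(), "variants": {}}

    base_spec = TraceGenSpec(params=native, noise_sd=noise_sd,
                             replicates=replicates_baseline,
                             seed=int(rng.integers(2**31)),
                             conditions=conditions, construct="LXX")
    traces["LXX"] = make_trace_dataset(base_spec)

    for name, kwargs in variants.items():
        seg = SegmentedRateParameters(
            native=native,
            n_var=kwargs["n_var"],
            k_step_var=kwargs["k_step_var"],
            k_fail_var=kwargs.get("k_fail_var", native.k_fail),
            k_block_var=kwargs.get("k_block_var", native.k_block),
            brightness=kwargs.get("brightness", native.brightness),
        )
        vspec = TraceGenSpec(params=seg, noise_sd=noise_sd,
                             replicates=replicates_variant,
                             seed=int(rng.integers(2**31)),
                             conditions=conditions, construct=f"XLX_{name}")
        traces[name] = make_trace_dataset(vspec)
        manifest["variants"][name] = {
            "n_var": seg.n_var, "k_step_var": seg.k_step_var,
            "k_fail_var": seg.k_fail_var, "k_block_var": seg.k_block_var,
            "brightness": seg.brightness,
        }
    return {"traces": traces, "manifest": manifest}
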