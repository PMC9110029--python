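"""Lys/(Lys+Arg) secretion-bias statistics over annotated proteomes.

Secreted proteins cross the membrane through machinery for which arginine is
the slowest residue to transport, so exported (Sec-substrate) proteomes are
expected to favour lysine over arginine relative to cytosolic proteins.  The
statistic analysed here is, per protein, the proportion of positively charged
residues that are lysine, K/(K+R), computed on the mature sequence (signal
peptide removed).  Per-class distributions are binned by Sturges' rule,
summarised by single-Gaussian fits, and compared with a two-tailed Welch
t-test (permutation test available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .errors import DataError, FitError

__all__ = [
    "LOC_CLASSES",
    "ProteinRecord",
    "ClassHistogram",
    "GaussianFit",
    "ClassComparison",
    "mature_sequence",
    "lys_fraction",
    "sturges_bins",
    "build_histogram",
    "fit_gaussian",
    "compare_classes",
    "fractions_by_class",
    "analyze_proteome",
]

LOC_CLASSES = ("cytosolic", "Sec", "Tat")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with localization class and optional signal-peptide span.

    ``ss_span`` is 1-based inclusive (UniProt convention) and only allowed
    for secreted (Sec/Tat) classes.
    """

    id: str
    sequence: str
    loc_class: str
    ss_span: Optional[tuple] = None

    def __post_init__(self):
        if self.loc_class not in LOC_CLASSES:
            raise DataError(f"{self.id}: unknown localization class {self.loc_class!r}")
        bad = set(self.sequence) - _AA20 - {"X"}
        if bad:
            raise DataError(f"{self.id}: invalid residue letters {sorted(bad)}")
        if self.ss_span is not None:
            if self.loc_class == "cytosolic":
                raise DataError(f"{self.id}: cytosolic record cannot carry a signal peptide")
            start, end = self.ss_span
            if start < 1 or end < start:
                raise DataError(f"{self.id}: invalid ss_span {self.ss_span}")
            if end >= len(self.sequence):
                raise DataError(
                    f"{self.id}: ss_span {self.ss_span} leaves no mature sequence "
                    f"(length {len(self.sequence)})"
                )
            object.__setattr__(self, "ss_span", (int(start), int(end)))


@dataclass
class ClassHistogram:
    """Sturges-binned frequency histogram of one class's K/(K+R) values."""

    class_label: str
    n: int
    bin_edges: np.ndarray
    frequencies: np.ndarray
    gaussian: Optional["GaussianFit"] = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class GaussianFit:
    amplitude: float
    mean: float
    sd: float
    residual_rmsd: float


@dataclass(frozen=True)
class ClassComparison:
    statistic: float
    df: Optional[float]
    pvalue: float
    method: str


def mature_sequence(rec: ProteinRecord) -> str:
    """Sequence with the signal peptide removed (secreted classes only)."""
    if rec.ss_span is None:
        return rec.sequence
    start, end = rec.ss_span
    return rec.sequence[:start - 1] + rec.sequence[end:]


def lys_fraction(seq: str) -> Optional[float]:
    """K/(K+R) for one sequence; None when it has no K or R (undefined)."""
    if not seq:
        raise DataError("empty sequence")
    k = seq.count("K")
    r = seq.count("R")
    if k + r == 0:
        return None
    return k / (k + r)


def sturges_bins(n: int) -> int:
    """Sturges' rule bin count: 1 + 3.322 log10(n), rounded to nearest."""
    if n < 2:
        raise DataError("Sturges' rule needs n >= 2")
    return int(np.rint(1.0 + 3.322 * np.log10(n)))


def build_histogram(values: Iterable[float], class_label: str = "") -> ClassHistogram:
    """Frequency histogram over [0, 1] with Sturges' bin count.

    Frequencies are bin counts divided by the sample size n, so they sum to
    one.  Bins are half-open [a, b) with the final bin closed, making the
    assignment of the boundary values 0 and 1 deterministic.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size < 2:
        raise DataError("need at least 2 defined values to build a histogram")
    nbins = sturges_bins(vals.size)
    counts, edges = np.histogram(vals, bins=nbins, range=(0.0, 1.0))
    return ClassHistogram(
        class_label=class_label,
        n=int(vals.size),
        bin_edges=edges,
        frequencies=counts / vals.size,
    )


def _gauss(x, a, mu, sd):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def fit_gaussian(hist: ClassHistogram) -> GaussianFit:
    """Least-squares single-Gaussian fit to (bin center, frequency) pairs."""
    x = hist.bin_centers
    y = hist.frequencies
    if np.count_nonzero(y) < 4:
        raise FitError("need at least 4 occupied bins for a Gaussian fit")
    mu0 = float(np.sum(x * y) / np.sum(y))
    sd0 = float(np.sqrt(np.sum(y * (x - mu0) ** 2) / np.sum(y))) or 0.1
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=[float(y.max()), mu0, sd0],
            bounds=([0.0, -0.5, 1e-4], [np.inf, 1.5, 10.0]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    resid = y - _gauss(x, *popt)
    return GaussianFit(
        amplitude=float(popt[0]), mean=float(popt[1]), sd=float(abs(popt[2])),
        residual_rmsd=float(np.sqrt(np.mean(resid**2))),
    )


def compare_classes(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "welch",
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> ClassComparison:
    """Two-tailed location comparison of two classes' per-protein fractions.

    Default is the unequal-variance (Welch) t-test; ``method="permutation"``
    runs a two-sided permutation test on the difference of means.
    """
    a = np.asarray([v for v in values_a if v is not None], dtype=float)
    b = np.asarray([v for v in values_b if v is not None], dtype=float)
    if a.size < 3 or b.size < 3:
        raise DataError("each class needs at least 3 defined values")
    if a.std() == 0 and b.std() == 0:
        raise DataError("degenerate samples: both classes have zero variance")
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return ClassComparison(statistic=float(res.statistic), df=float(res.df),
                               pvalue=float(res.pvalue), method="welch")
    if method == "permutation":
        rng = np.random.default_rng(seed)
        obs = a.mean() - b.mean()
        pooled = np.concatenate([a, b])
        na = a.size
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            if abs(pooled[:na].mean() - pooled[na:].mean()) >= abs(obs) - 1e-15:
                count += 1
        # add-one correction keeps the Monte-Carlo p-value away from 0
        p = (count + 1) / (n_permutations + 1)
        return ClassComparison(statistic=float(obs), df=None, pvalue=float(p),
                               method="permutation")
    raise DataError(f"unknown method {method!r}")


def fractions_by_class(records: Iterable[ProteinRecord]) -> dict:
    """Defined mature-sequence K/(K+R) values grouped by localization class."""
    out = {}
    for rec in records:
        f = lys_fraction(mature_sequence(rec))
        if f is not None:
            out.setdefault(rec.loc_class, []).append(f)
    return {k: np.asarray(v) for k, v in out.items()}


def analyze_proteome(
    records: Iterable[ProteinRecord],
    classes: Sequence[str] = LOC_CLASSES,
    fit_gaussians: bool = True,
    comparison_method: str = "welch",
) -> dict:
    """Full class-composition analysis of an annotated proteome.

    Returns ``{"fractions", "histograms", "comparisons"}`` where comparisons
    maps each class pair to a :class:`ClassComparison`.
    """
    fracs = fractions_by_class(records)
    present = [c for c in classes if c in fracs and len(fracs[c]) >= 2]
    hists = {}
    for c in present:
        h = build_histogram(fracs[c], c)
        if fit_gaussians:
            try:
                h.gaussian = fit_gaussian(h)
            except FitError:
                h.gaussian = None
        hists[c] = h
    comps = {}
    for i, ca in enumerate(present):
        for cb in present[i + 1:]:
            try:
                comps[(ca, cb)] = compare_classes(fracs[ca], fracs[cb],
                                                  method=comparison_method)
            except DataError:
                comps[(ca, cb)] = None
    return {"fractions": fracs, "histograms": hists, "comparisons": comps}
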