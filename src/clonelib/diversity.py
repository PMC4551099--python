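"""Diversity statistics for clone libraries.

A clone library is summarized by its OTU abundance vector (clones per
OTU). The statistics implemented are the ones standard for clone-library
surveys: library coverage, the Chao1 nonparametric richness estimator
with a log-normal 95% CI, the Shannon entropy with a first-order analytic
CI, and the Coleman analytical rarefaction curve.

Coverage note: the classic Good estimator is 1 - F1/N (F1 = singleton
OTUs). Some studies instead print 1 - n/N with n the total OTU count;
both variants are exposed (`variant="otu_count"` is the default here to
mirror that reporting style, `variant="singleton"` is classic Good).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneLibrary",
    "EstimateCI",
    "good_coverage",
    "chao1",
    "shannon",
    "coleman_rarefaction",
    "diversity_table",
]

MARKERS = ("16S-bacteria", "16S-archaea", "mcrA", "dsrB")


@dataclass(frozen=True)
class CloneLibrary:
    """OTU abundance vector for one marker/sample/year."""

    abundances: tuple[int, ...]
    sample_id: str = ""
    year: int = 0
    marker: str = "16S-bacteria"

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", tuple(int(a) for a in self.abundances))
        if len(self.abundances) == 0:
            raise ValueError("abundance vector is empty")
        if any(a < 1 for a in self.abundances):
            raise ValueError("abundances must be positive integers")

    @property
    def n_otus(self) -> int:
        return len(self.abundances)

    @property
    def n_clones(self) -> int:
        return sum(self.abundances)

    def count_of_count(self, k: int) -> int:
        """Number of OTUs observed exactly k times (F_k)."""
        return sum(1 for a in self.abundances if a == k)


class EstimateCI(NamedTuple):
    """Point estimate with a 95% confidence interval."""

    estimate: float
    lo: float
    hi: float


def _as_library(lib) -> CloneLibrary:
    if isinstance(lib, CloneLibrary):
        return lib
    return CloneLibrary(tuple(lib))


def good_coverage(lib, variant: str = "otu_count") -> float:
    """Library coverage C.

    variant="otu_count": C = 1 - n/N with n the number of OTUs.
    variant="singleton": classic Good, C = 1 - F1/N with F1 the number of
    singleton OTUs.
    """
    lib = _as_library(lib)
    n_total = lib.n_clones
    if variant == "otu_count":
        top = lib.n_otus
    elif variant == "singleton":
        top = lib.count_of_count(1)
    else:
        raise ValueError(f"unknown coverage variant {variant!r}")
    return 1.0 - top / n_total


def chao1(lib) -> EstimateCI:
    """Bias-corrected Chao1 richness estimate with log-normal 95% CI.

    estimate = S + F1(F1-1) / (2(F2+1)), defined also when F2 = 0.
    The CI follows the log-normal construction on T = estimate - S
    (Chao's 1987 approach): with K = exp(1.96 * sqrt(ln(1 + var/T^2))),
    CI = (S + T/K, S + T*K). When F1 = 0 the estimate equals S and the
    interval collapses to (S, S).
    """
    lib = _as_library(lib)
    s_obs = lib.n_otus
    f1 = lib.count_of_count(1)
    f2 = lib.count_of_count(2)
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    t = est - s_obs
    if f1 == 0 or t <= 0:
        return EstimateCI(float(s_obs), float(s_obs), float(s_obs))
    # variance of the bias-corrected estimator
    var = (
        f1 * (f1 - 1) / (2.0 * (f2 + 1))
        + f1 * (2 * f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 2)
        + f1**2 * f2 * (f1 - 1) ** 2 / (4.0 * (f2 + 1) ** 4)
    )
    k = math.exp(1.96 * math.sqrt(math.log(1.0 + var / t**2)))
    return EstimateCI(est, s_obs + t / k, s_obs + t * k)


def shannon(lib) -> EstimateCI:
    """Shannon entropy H' = -sum p_i ln p_i with first-order analytic 95% CI.

    var(H') = (sum p_i (ln p_i)^2 - H'^2) / N; CI = H' +/- 1.96 sqrt(var).
    """
    lib = _as_library(lib)
    n_total = lib.n_clones
    p = np.asarray(lib.abundances, dtype=float) / n_total
    logp = np.log(p)
    h = float(-(p * logp).sum())
    if h == 0:
        h = 0.0  # avoid -0.0 for single-OTU libraries
    var = float(((p * logp**2).sum() - h**2) / n_total)
    var = max(var, 0.0)  # guard tiny negative from float cancellation
    half = 1.96 * math.sqrt(var)
    return EstimateCI(h, h - half, h + half)


def shannon_bootstrap_ci(lib, n_boot: int = 1000, seed: int = 0) -> EstimateCI:
    """Percentile bootstrap 95% CI for H' (multinomial resampling)."""
    lib = _as_library(lib)
    rng = np.random.default_rng(seed)
    n_total = lib.n_clones
    p = np.asarray(lib.abundances, dtype=float) / n_total
    h = shannon(lib).estimate
    draws = rng.multinomial(n_total, p, size=n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = draws / n_total
        terms = np.where(draws > 0, -q * np.log(np.where(draws > 0, q, 1.0)), 0.0)
    hs = terms.sum(axis=1)
    lo, hi = np.percentile(hs, [2.5, 97.5])
    return EstimateCI(h, float(lo), float(hi))


def coleman_rarefaction(lib, depths: Sequence[int]) -> np.ndarray:
    """Coleman expected richness E[S | m] = S - sum_i (1 - m/N)^{a_i}.

    An analytic approximation to the exact hypergeometric rarefaction;
    monotone non-decreasing in the subsample depth m.
    """
    lib = _as_library(lib)
    n_total = lib.n_clones
    depths = np.asarray(depths, dtype=int)
    if depths.size == 0:
        return np.empty(0)
    if depths.min() < 1 or depths.max() > n_total:
        raise ValueError(f"depths must lie in [1, {n_total}]")
    a = np.asarray(lib.abundances, dtype=float)
    m = depths[:, None] / n_total
    return lib.n_otus - ((1.0 - m) ** a[None, :]).sum(axis=1)


def diversity_table(libraries: Sequence[CloneLibrary]) -> pd.DataFrame:
    """Per-library report table: coverage (both variants), Chao1 and
    Shannon with 95% CIs, rounded to 2 decimals for display."""
    rows = []
    for lib in libraries:
        c = chao1(lib)
        h = shannon(lib)
        rows.append({
            "sample": lib.sample_id,
            "year": lib.year,
            "marker": lib.marker,
            "OTUs": lib.n_otus,
            "clones": lib.n_clones,
            "coverage": round(good_coverage(lib, "otu_count"), 2),
            "coverage_good": round(good_coverage(lib, "singleton"), 2),
            "chao1": round(c.estimate, 2),
            "chao1_lo": round(c.lo, 2),
            "chao1_hi": round(c.hi, 2),
            "shannon": round(h.estimate, 2),
            "shannon_lo": round(h.lo, 2),
            "shannon_hi": round(h.hi, 2),
        })
    return pd.DataFrame(rows)
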