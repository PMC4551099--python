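"""Synthetic community and qPCR panel generators.

Every pipeline stage is testable without external downloads: this module
plants a fully known truth — OTU membership, per-OTU G+C content, pairwise
divergence structure, cell densities — and emits the same file formats the
real pipeline consumes (primer-flanked FASTA, TSV truth/panel tables).

Construction guarantees rather than approximates the planted structure:

* regions get exact G+C base counts (non-integer targets resolved to the
  nearest count; the truth table records the realized value);
* point mutations are G+C-preserving swaps (A<->T, G<->C) at OTU-private
  or clone-private positions, so divergence is planted exactly and never
  perturbs the planted G+C;
* all generators are pure functions of (spec, seed): same seed, same bytes.

What is *not* emulated: chimeras, indels, sequencing error beyond point
substitutions, and PCR amplification bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .qpcr import DEFAULT_COPIES_PER_GENOME, QpcrMeasurement
from .sequences import (
    DEFAULT_PRIMERS,
    IUPAC_DNA,
    Primer,
    SequenceRecord,
    gc_percent,
    reverse_complement,
)

__all__ = [
    "SyntheticCommunitySpec",
    "SyntheticQpcrSpec",
    "simulate_library",
    "simulate_qpcr",
    "panel_to_measurements",
]

_SWAP = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Default 2005-like cell-density truth (cells per g wet weight).
DEFAULT_TRUE_CELLS = {
    "16S-bacteria": 2.5e7,
    "16S-archaea": 2.75e6,
    "mcrA": 1.0e6,
    "dsrB": 1.1e6,
}


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """Planted truth for one simulated clone library.

    Defaults mirror a low-diversity archaeal library: 3 OTUs, 96 clones,
    an 800 bp primer-flanked region, 0.5% intra-OTU and 10% inter-OTU
    divergence, per-OTU G+C spanning the 52-66% range typical of mixed
    mesophile/thermophile communities.
    """

    seed: int = 0
    n_otus: int = 3
    library_size: int = 96
    abundance_model: str = "geometric"  # geometric | log-series | uniform
    abundance_param: float = 0.6
    region_gc: float | Sequence[float] | None = None
    intra_otu_divergence: float = 0.005
    inter_otu_divergence: float = 0.10
    region_len: int = 800
    fwd_primer: Primer = field(default_factory=lambda: DEFAULT_PRIMERS["109F"])
    rev_primer: Primer = field(default_factory=lambda: DEFAULT_PRIMERS["915R"])
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ValueError("n_otus must be >= 1")
        if self.library_size < self.n_otus:
            raise ValueError("library_size must be >= n_otus")
        if not 0 <= self.intra_otu_divergence < 1:
            raise ValueError("intra_otu_divergence must be in [0, 1)")
        if not 0 <= self.inter_otu_divergence < 1:
            raise ValueError("inter_otu_divergence must be in [0, 1)")
        gcs = self.per_otu_gc()
        if any(not 0 < g < 100 for g in gcs):
            raise ValueError("region_gc values must be in (0, 100)")

    def per_otu_gc(self) -> list[float]:
        if self.region_gc is None:
            if self.n_otus == 1:
                return [55.0]
            return list(np.linspace(52.0, 66.0, self.n_otus))
        if np.isscalar(self.region_gc):
            return [float(self.region_gc)] * self.n_otus
        gcs = [float(g) for g in self.region_gc]
        if len(gcs) != self.n_otus:
            raise ValueError("region_gc must be scalar or one value per OTU")
        return gcs


@dataclass(frozen=True)
class SyntheticQpcrSpec:
    """Planted truth for a noisy qPCR panel."""

    seed: int = 0
    true_cells: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_CELLS))
    copies_per_genome: dict = field(
        default_factory=lambda: dict(DEFAULT_COPIES_PER_GENOME)
    )
    lognormal_sigma: float = 0.2
    year: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.true_cells.values()):
            raise ValueError("true cell densities must be positive")
        if any(v <= 0 for v in self.copies_per_genome.values()):
            raise ValueError("copies per genome must be positive")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


def _instantiate_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Pick one concrete base per IUPAC symbol (uniformly at random)."""
    out = []
    for sym in pattern.upper():
        allowed = sorted(IUPAC_DNA[sym])
        out.append(allowed[rng.integers(len(allowed))])
    return "".join(out)


def _region_with_gc(length: int, gc_pct: float, rng: np.random.Generator) -> np.ndarray:
    """Random region with exactly round(gc_pct/100 * length) G+C bases."""
    n_gc = int(round(gc_pct / 100.0 * length))
    bases = np.empty(length, dtype="U1")
    gc_positions = rng.choice(length, size=n_gc, replace=False)
    mask = np.zeros(length, dtype=bool)
    mask[gc_positions] = True
    bases[mask] = rng.choice(np.array(["G", "C"]), size=n_gc)
    bases[~mask] = rng.choice(np.array(["A", "T"]), size=length - n_gc)
    return bases


def _sample_abundances(spec: SyntheticCommunitySpec, rng: np.random.Generator) -> np.ndarray:
    """Clones per OTU: one guaranteed clone each, the rest multinomial
    on the abundance-model weights. Sums to library_size exactly."""
    k = spec.n_otus
    if spec.abundance_model == "geometric":
        p = spec.abundance_param
        if not 0 < p < 1:
            raise ValueError("geometric abundance_param must be in (0, 1)")
        w = p * (1 - p) ** np.arange(k)
    elif spec.abundance_model == "log-series":
        a = spec.abundance_param
        if not 0 < a < 1:
            raise ValueError("log-series abundance_param must be in (0, 1)")
        ranks = np.arange(1, k + 1)
        w = a**ranks / ranks
    elif spec.abundance_model == "uniform":
        w = np.ones(k)
    else:
        raise ValueError(f"unknown abundance model {spec.abundance_model!r}")
    w = w / w.sum()
    extra = rng.multinomial(spec.library_size - k, w)
    return extra + 1


def _build_centroids(spec: SyntheticCommunitySpec, rng: np.random.Generator):
    """Centroid regions: a shared backbone mutated at OTU-private positions.

    Each OTU gets a disjoint set of positions where (a) G+C is shifted to
    its planted target by AT<->GC conversions and (b) G+C-preserving swaps
    top the private-set size up to round(inter_otu_divergence/2 * L), so
    pairwise centroid divergence is at least the planted value.
    """
    L = spec.region_len
    gcs = spec.per_otu_gc()
    backbone_gc = float(np.mean(gcs))
    backbone = _region_with_gc(L, backbone_gc, rng)
    n0 = int(np.count_nonzero((backbone == "G") | (backbone == "C")))
    half_k = int(round(spec.inter_otu_divergence / 2.0 * L))

    used = np.zeros(L, dtype=bool)
    centroids = []
    for j in range(spec.n_otus):
        target_gc_count = int(round(gcs[j] / 100.0 * L))
        delta = target_gc_count - n0
        want_gc_state = delta < 0  # converting GC -> AT needs current G/C
        n_convert = abs(delta)
        n_swap = max(half_k - n_convert, 0)
        centroid = backbone.copy()
        is_gc = (centroid == "G") | (centroid == "C")
        free = ~used
        conv_pool = np.flatnonzero(free & (is_gc if want_gc_state else ~is_gc))
        if n_convert > len(conv_pool):
            raise ValueError(
                "infeasible spec: not enough free positions to plant per-OTU GC"
            )
        conv_pos = rng.choice(conv_pool, size=n_convert, replace=False) \
            if n_convert else np.empty(0, dtype=int)
        for pos in conv_pos:
            centroid[pos] = rng.choice(["A", "T"] if want_gc_state else ["G", "C"])
        used[conv_pos] = True
        swap_pool = np.flatnonzero(~used)
        if n_swap > len(swap_pool):
            raise ValueError(
                "infeasible spec: inter-OTU divergence exceeds available positions"
            )
        swap_pos = rng.choice(swap_pool, size=n_swap, replace=False) \
            if n_swap else np.empty(0, dtype=int)
        for pos in swap_pos:
            centroid[pos] = _SWAP[centroid[pos]]
        used[swap_pos] = True
        centroids.append(centroid)
    return centroids


def _mutate_clone(centroid: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """G+C-preserving point substitutions at round(rate * L) positions."""
    n_mut = int(round(rate * len(centroid)))
    if n_mut == 0:
        return centroid.copy()
    pos = rng.choice(len(centroid), size=n_mut, replace=False)
    clone = centroid.copy()
    for p in pos:
        clone[p] = _SWAP[clone[p]]
    return clone


def simulate_library(spec: SyntheticCommunitySpec):
    """Simulate one clone library.

    Returns
    -------
    records : list of SequenceRecord
        Equal-length, ungapped, primer-flanked clone sequences in a
        seeded random order (trivially alignable: no indels are planted).
    truth : pandas.DataFrame
        One row per clone: clone_id, otu_id, planted and realized region
        G+C, region coordinates within the flanked sequence.
    """
    rng = np.random.default_rng(spec.seed)
    abundances = _sample_abundances(spec, rng)
    centroids = _build_centroids(spec, rng)
    gcs = spec.per_otu_gc()

    fwd_site = _instantiate_pattern(spec.fwd_primer.pattern, rng)
    rev_site = reverse_complement(_instantiate_pattern(spec.rev_primer.pattern, rng))
    region_start = len(fwd_site)
    region_end = region_start + spec.region_len

    rows = []
    sequences = []
    clone_no = 0
    for j, (centroid, count) in enumerate(zip(centroids, abundances)):
        for _ in range(count):
            clone_no += 1
            region = _mutate_clone(centroid, spec.intra_otu_divergence, rng)
            region_str = "".join(region)
            rows.append({
                "clone_id": f"{spec.sample_id}_c{clone_no:04d}",
                "otu_id": f"OTU_{j + 1}",
                "planted_gc": round(gcs[j], 2),
                "realized_gc": gc_percent(region_str),
                "region_start": region_start,
                "region_end": region_end,
            })
            sequences.append(fwd_site + region_str + rev_site)

    order = rng.permutation(clone_no)
    truth = pd.DataFrame([rows[i] for i in order])
    records = [
        SequenceRecord(
            id=rows[i]["clone_id"],
            residues=sequences[i],
            description=f"synthetic clone of {rows[i]['otu_id']}",
            is_aligned=False,
        )
        for i in order
    ]
    return records, truth


def simulate_qpcr(spec: SyntheticQpcrSpec, replicates: int = 3) -> pd.DataFrame:
    """Noisy qPCR panel: per target and replicate,
    copies = true_cells * copies_per_genome * exp(N(0, sigma))."""
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for target in sorted(spec.true_cells):
        cells = spec.true_cells[target]
        cpg = spec.copies_per_genome.get(target, 1.0)
        noise = np.exp(rng.normal(0.0, spec.lognormal_sigma, size=replicates)) \
            if spec.lognormal_sigma > 0 else np.ones(replicates)
        for r in range(replicates):
            rows.append({
                "year": spec.year,
                "target": target,
                "replicate": r + 1,
                "true_cells_per_gww": cells,
                "copies_per_gww": cells * cpg * noise[r],
            })
    return pd.DataFrame(rows)


def panel_to_measurements(panel: pd.DataFrame) -> list[QpcrMeasurement]:
    """Collapse a replicate panel to per-target mean +/- sd measurements."""
    out = []
    for (year, target), grp in panel.groupby(["year", "target"], sort=True):
        copies = grp["copies_per_gww"].to_numpy()
        out.append(QpcrMeasurement(
            target=target,
            copies_per_gww=float(copies.mean()),
            sd=float(copies.std(ddof=1)) if len(copies) > 1 else 0.0,
            year=int(year),
        ))
    return out
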