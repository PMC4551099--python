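# clonelib

Community analysis for marker-gene **clone libraries** — the Sanger-era
workhorse still standard for low-throughput surveys of extreme
environments (hydrothermal chimneys, serpentinizing springs, subsurface
aquifers), where a library of 30–120 cloned 16S rRNA, *mcrA* or *dsrB*
amplicons per sample is the primary window into the community.

The package covers the four quantitative steps such a survey needs, as a
library with a thin `clonelib` CLI on top:

1. **OTU clustering** — uncorrected p-distances with pairwise gap
   deletion on pre-aligned sequences, average-linkage agglomeration at a
   distance threshold (default 0.03, the 97 %-identity species proxy),
   with deterministic lexicographic tie-breaking so partitions are
   bit-reproducible.
2. **Diversity estimation** — library coverage `C = 1 − n/N` (and the
   classic Good variant `1 − F₁/N`), bias-corrected Chao1
   `S + F₁(F₁−1)/(2(F₂+1))` with a log-normal 95 % CI, Shannon entropy
   `H′ = −Σ pᵢ ln pᵢ` with a first-order analytic CI, and the Coleman
   rarefaction curve `E[S|m] = S − Σᵢ (1 − m/N)^{aᵢ}`.
3. **qPCR abundance modelling** — gene copies g⁻¹ (wet weight) divided
   by per-genome copy numbers (16S: 3.6 bacteria, 1.2 archaea; *mcrA*,
   *dsrB*: single copy) to give cell densities, plus domain fractions
   (archaea among prokaryotes) and guild fractions (methanogens among
   archaea, sulfate reducers among bacteria).
4. **Growth-temperature inference** — the G+C fraction (P_GC) of the
   800 bp internal 16S region between the archaeal primers 109F and 915R
   correlates positively with growth temperature; ordinary least squares
   on a packaged calibration table of (P_GC, T_min, T_opt, T_max) pairs
   yields `T_k = slope_k · P_GC + intercept_k` (slopes ≈ 4.4–5.0 °C per
   %GC), classifying uncultured phylotypes as psychro-/meso-/thermo-/
   hyperthermophilic from sequence alone.

A seeded **synthetic-community generator** plants all of the above —
OTU membership, abundance distributions, per-OTU G+C, divergence
structure, noisy qPCR panels — so the whole pipeline is testable end to
end without any sequence downloads.

## Worked example

```python
from clonelib import (
    CloneLibrary, chao1, good_coverage, shannon,
    QpcrMeasurement, cells_from_copies, domain_fraction, round_sig,
    fit_temp_model, load_calibration, predict_growth_temp,
    SyntheticCommunitySpec, simulate_library, pairwise_p_distance, cluster_otus,
)

# simulate a 3-OTU, 96-clone archaeal library and recover it
spec = SyntheticCommunitySpec(seed=1)
records, truth = simulate_library(spec)
otus = cluster_otus(pairwise_p_distance(records), threshold=0.03)
print("OTUs recovered:", otus.n_otus, "abundances:", otus.abundances)

lib = CloneLibrary(tuple(otus.abundances), marker="16S-archaea")
print("coverage:", round(good_coverage(lib), 2))
print("shannon: %.2f" % shannon(lib).estimate)

# qPCR copies -> cells
arch = cells_from_copies(QpcrMeasurement("16S-archaea", 3.3e6, 0.8e6, year=2005))
bact = cells_from_copies(QpcrMeasurement("16S-bacteria", 9.1e7, 0.1e7, year=2005))
print("archaeal cells/gww:", round_sig(arch.cells_per_gww))
print("archaeal share: %.1f%%" % domain_fraction(arch, bact))

# thermal typing from 16S G+C content
model = fit_temp_model(load_calibration())
print(predict_growth_temp(65.75, model))
```

prints

```
OTUs recovered: 3 abundances: [65, 23, 8]
coverage: 0.97
shannon: 0.81
archaeal cells/gww: 2700000.0
archaeal share: 9.8%
ThermalPrediction(p_gc=65.75, t_min=63, t_opt=86, t_max=93, lifestyle='hyperthermophile')
```

Reading: the simulated 96-clone library clusters back into its three
planted OTUs, giving coverage 0.97 (only 3 % of the community estimated
unseen). 3.3 × 10⁶ archaeal 16S copies g⁻¹ ÷ 1.2 copies per genome is
2.7 × 10⁶ cells g⁻¹, 9.8 % of prokaryotic cells. A phylotype whose 16S
region is 65.75 % G+C is predicted to grow optimally at 86 °C — a
hyperthermophile.

The same stages run from the shell: `clonelib simulate`,
`clonelib cluster`, `clonelib diversity`, `clonelib qpcr`,
`clonelib thermotype`, `clonelib compose`, or `clonelib all --config
run.yaml` for the orchestrated pipeline with a JSON run manifest.

## Documentation

`docs/methods.md` describes the statistical models, their assumptions,
the synthetic generator's guarantees and limits, and the numerical
conventions (rounding, tie-breaking, degenerate inputs).
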