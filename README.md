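# breakscape

Quantification of protein occupancy and RNA:DNA hybrids around
sequence-specific DNA double-strand breaks (DSBs), for experiments of the
DIvA type: a restriction enzyme (AsiSI, 8 bp recognition site) is
activated in cells, cutting a subset of its ~1200 annotated genomic sites,
and ChIP-seq / DRIP-seq coverage is compared between the undamaged
(−4OHT) and damaged (+4OHT) conditions.  The package is aimed at analysts
of such site-anchored damage experiments: it turns coverage tracks plus a
break-site annotation into window counts, enrichment statistics,
heatmaps, averaged and metagene profiles, and implements the qPCR-derived
assay formulas used around such experiments (resection ssDNA%, repair
kinetics, translocation frequency, DRIP percent-input).

## Core computations

For a coverage track $x(b)$ (per-base signal normalized to reads per
million: $x \mapsto x \cdot 10^6/N$ with $N$ the library size), a break
site at position $c$ and window half-width $h$, the windowed signal is

$$W(c, h) = \sum_{b = c-h}^{c+h-1} x(b),$$

truncated at chromosome ends.  Cut vs uncut sites are compared with the
two-sided Mann–Whitney $U$ test (exact enumeration for tie-free groups of
≤ 8, tie-corrected normal approximation otherwise); the same sites before
vs after damage with the paired Wilcoxon signed-rank test.  Cut sites are
stratified into four RNA PolII occupancy classes (low / medium-low /
medium-high / high) of equal size.  Heatmaps average the signal in 500 bp
bins on ±5 kb windows, ordered by decreasing cleavage efficiency.
Metagene profiles use 200 bp bins on 3 kb flanks plus 100
percent-of-gene-length body bins (strand-aware).  Boxplot summaries use
Tukey fences (q1 − 1.5 IQR, q3 + 1.5 IQR).

The qPCR assays, with Ct the cycle threshold at amplification
efficiency 2:

* resection: $\text{ssDNA\%} = \dfrac{100}{2^{\Delta Ct - 1} + 0.5}$,
  $\Delta Ct = Ct_\text{digested} - Ct_\text{undigested}$;
* repair kinetics: broken-end signal $s(t) = 2^{Ct_\text{input} -
  Ct_\text{pulldown}}$, percent still broken $= 100\, s(t)/s(t_\text{ref})$;
* translocation: $\Delta\Delta Ct$ against the arithmetic mean of two
  control-region Cts, frequency $= 2^{-\Delta\Delta Ct}$;
* DRIP-qPCR: percent input $= 100 \cdot f_\text{input} \cdot
  2^{Ct_\text{input} - Ct_\text{IP}}$.

A synthetic-data module generates genomes, break-site annotations,
coverage tracks and Ct tables with this exact statistical structure and
known ground truth, so the entire pipeline runs end-to-end with no
download; see `docs/methods.md` for the generative model.

## Worked example

```python
from breakscape import (SimConfig, simulate_genome, simulate_chip_coverage,
                        quantify_sites, compare_cut_uncut)

genome = simulate_genome(SimConfig(seed=1))        # 120 sites, 20 cut
track = simulate_chip_coverage(genome, "senataxin", "damaged")
quants = quantify_sites(track, genome.sites, halfwidth=5000)
result = compare_cut_uncut(quants)
print(f"U={result.statistic:.0f}, p={result.p_value:.3g}, "
      f"higher in {result.direction} sites")
```

prints

```
U=1757, p=9.97e-08, higher in cut sites
```

— the senataxin window signal is strongly enriched at the 20 cut sites
relative to the 100 uncut annotated sites after damage induction
(running the same comparison on the undamaged track gives p = 0.326:
no enrichment before cutting).

The numbered scripts under `analysis/` run the full narrative —
simulation, senataxin recruitment and transcription stratification,
R-loop remodeling profiles, qPCR assays — and write their tables under
`results/`:

```bash
python analysis/01_simulate_experiment.py
python analysis/02_senataxin_recruitment.py
python analysis/03_rloop_remodeling.py
python analysis/04_qpcr_assays.py
```

The same stages are available as a CLI (`breakscape simulate | quantify |
compare | heatmap | profile | metagene | qpcr | run`) for user-supplied
bedGraph/BED/Ct-table inputs; `breakscape run --config cfg.yaml --out DIR`
executes everything and writes a manifest with config, seed and output
checksums.

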