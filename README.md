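# latticetumour

Spatial stochastic simulation of tumour growth with synthetic sequencing
and likelihood-free inference of evolutionary parameters.

Solid tumours grow in space: whether every cell can divide (homogeneous,
exponential growth) or only cells near the invasive front (boundary-driven
growth) changes which lineages expand, what multi-region biopsies capture,
and whether patterns in sequencing data reflect selection or mere spatial
drift. `latticetumour` is a toolkit for studying exactly that, aimed at
cancer-evolution researchers who work with variant-allele-frequency (VAF)
spectra, multi-region bulk data or single-cell phylogenies:

* a cellular-automaton **simulator** on a 2D/3D lattice — Gillespie
  (next-reaction) birth/death dynamics with rates `b·x` and `d·x`,
  `Pois(u)` unique mutations per division shared by both daughters
  (infinite sites), one driver event at time `t_driver` with selection
  coefficient `s` defined by `1 + s = (b_mut − d_mut)/(b_wt − d_wt)`, and a
  boundary parameter `a` (the fraction of the tumour radius, measured from
  the front, within which space-less cells may still divide by pushing
  neighbours outward);
* **sampling and sequencing** — punch/needle biopsies, whole-tumour and
  concentric-ring samples, random or bulk-clumped single cells; read
  counts with `Poisson(Z)` coverage and `Binomial(depth, n/2)` variant
  reads, and a 5-variant-read detection floor (minimum VAF 0.05 at 100×);
* **summaries** — the neutral `M(f) = μ(1/f − 1/f_max)` cumulative fit
  that recovers the mutation rate per division, the AUC neutrality test
  (p < 0.05 rejects neutrality), power-law exponents, site-frequency
  spectra, mutational load vs distance from the centre, and Moran's I
  clonal-intermixing statistics;
* **phylogenies** — perfect-phylogeny reconstruction from single-cell
  genotype matrices (exact maximum parsimony under infinite sites),
  lineage-tree oracles, balance/cophenetic tree statistics, Newick I/O;
* **inference** — ABC-SMC over θ = (u, t_driver, s, d, a) with uniform
  priors, Euclidean distances on multi-bulk VAF histograms or Wasserstein
  distances on whole-tumour VAFs / tree branch lengths / branching times,
  uniform perturbation kernels, importance reweighting, shrinking-ε
  schedules and sequential parameter fixing.

## Worked example

Grow a neutral homogeneous tumour (b = 1, d = 0, u = 10, a = 1) to 20 000
cells, sequence the whole tumour at 100×, and test the subclonal tail:

```python
import numpy as np
from latticetumour import (SimulationParams, run_with_restarts, whole_tumour,
                           sequence_bulk, cumulative_spectrum,
                           fit_neutral_tail, auc_neutrality_test)

params = SimulationParams(seed=7000, max_cells=20000, b=1.0, d=0.0,
                          u=10.0, a=1.0, t_driver=4.0, s=0.0)
state = run_with_restarts(params)
spectrum = sequence_bulk(whole_tumour(state), Z=100, min_alt=5,
                         rng=np.random.default_rng(0))
cum = cumulative_spectrum(spectrum)
u_hat, r2 = fit_neutral_tail(cum)
res = auc_neutrality_test(cum, rng=np.random.default_rng(0))
clonal = spectrum.df[spectrum.df.clone == "truncal"]
print(f"cells={state.n_cells}  mutations detected={len(spectrum)}")
print(f"u_hat={u_hat:.2f} (R^2={r2:.3f})  clonal VAF={clonal.vaf.mean():.3f}")
print(f"AUC={res.auc:.3f}  p={res.p_value:.2f}  neutral={res.neutral}")
```

prints

```
cells=20000  mutations detected=239
u_hat=9.03 (R^2=0.933)  clonal VAF=0.506
AUC=0.076  p=0.09  neutral=True
```

The fitted mutation rate (9.0) recovers the simulated 10 mutations per
division from the 1/f² tail alone; mutations carried by every cell
cluster at VAF ≈ 0.5 (diploid, 100 % purity); and the AUC test does not
reject neutrality — as it should not, since no selection was simulated.

The command line exposes the same pipeline (`latticetumour scenario
--name selective_homogeneous --seed 1 --out out/ --max-cells 20000`,
plus `simulate`, `summarise`, `abc`, `make-testset`); every artifact is a
plain TSV/JSON/Newick file regenerable bit-identically from its config
and seed.

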