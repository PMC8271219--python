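# emtres

Simulation framework for the coupled dynamics of epithelial–mesenchymal
plasticity (EMP) and endocrine-therapy resistance in ER+ breast cancer.

Tamoxifen resistance in estrogen-receptor-positive breast cancer is often
reversible and non-genetic: cells slide along an epithelial–mesenchymal
axis and, in parallel, between drug-sensitive and drug-tolerant states.
`emtres` implements two coupled models of this behavior:

1. **A random-circuit ensemble analysis** of the 5-node gene regulatory
   network linking full-length ERα (ERα66), its truncated variant ERα36,
   and the EMT regulators SLUG, ZEB1 and miR-200. Each node follows a
   shifted-Hill ODE

   $$\frac{dX_i}{dt} = g_i \prod_j H^s\!\left(X_j;\, X^0_{ji}, n_{ji}, \lambda_{ji}\right) - k_i X_i,
   \qquad H^s(X) = \lambda + \frac{1-\lambda}{1+(X/X^0)^n},$$

   with kinetic parameters drawn from biologically plausible ranges.
   Steady states are enumerated per parameter set, z-normalized, and
   placed on two axes — EM score $= z(\mathrm{ZEB1}) - z(\mathrm{miR200})$
   and resistance score $= z(\mathrm{ER\alpha36}) - z(\mathrm{ER\alpha66})$
   — whose Gaussian-mixture cutpoints define six phenotypes (ES, ER, HS,
   HR, MS, MR). Euler–Maruyama simulations of multistable parameter sets
   yield pseudo-potential landscapes $-\log P$ over the score plane and
   noise-driven phenotype transitions.

2. **An agent-based population model** of drug-treated cells that switch
   between sensitive (S) and resistant (R) states with probabilities
   $P_{SR}$, $P_{RS}$. Each cell carries Gaussian-distributed scores
   (means −2 and +2, SD = non-genetic heterogeneity), survives drug
   exposure per step with probability $e^x/(e^x + c)$ of its active score
   $x$, divides logistically toward a carrying capacity, and may be pushed
   S→R by drug-induced plasticity or R→S by a MET-inducing signal. The
   model measures growth curves and extinction probability — the fraction
   of replicate tumors eliminated by the therapy.

The package is aimed at systems-biology researchers studying non-genetic
drug resistance, multistable regulatory circuits and phenotype-switching
population dynamics.

## Worked example

```python
import numpy as np
import emtres as em
from emtres.scoring import score_ensemble, correlate_em_resistance, label_frequencies

rng = np.random.default_rng(7)
topology = em.load_default_topology()
scores, stats, thresholds = score_ensemble(
    topology, em.SamplingRanges(), n_sets=1000, n_init=100, rng=rng
)
rho, pval = correlate_em_resistance(scores)
print(f"Spearman rho(EM, resistance) = {rho:.3f}")
print(label_frequencies(scores["label"].to_numpy()).round(3))
```

prints (about a minute on one core):

```
Spearman rho(EM, resistance) = 0.812
ES    0.420
ER    0.042
HS    0.054
HR    0.077
MS    0.010
MR    0.396
```

The strong positive rank correlation (ρ ≈ 0.81) says that across the whole
kinetic ensemble, the more mesenchymal a stable cell state is, the more
tamoxifen-resistant it is; the frequency table shows the two poles —
epithelial-sensitive and mesenchymal-resistant — dominating, with rarer
hybrid and mixed states between them (mesenchymal-sensitive being the
rarest). The `examples/` directory has one short script per capability:
multistability census, phenotype scoring, noisy state transitions and
landscapes, and extinction probability under drug.

## Command line

The same workflows are exposed as a thin CLI for batch runs, each writing
TSV/JSON outputs plus a manifest with checksums for exact replay:

```bash
emtres ensemble --seed 1 --out runs/ensemble
emtres landscape --seed 1 --ensemble-dir runs/ensemble --set-id 4 --out runs/landscape
emtres popdyn --seed 1 --preset fig6a --out runs/popdyn
```

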