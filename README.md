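# clonedyn

Quantitative analysis of clonal fate dynamics in oncogene-expressing
epidermis: division-type scoring and renewal-rate estimation for
pulse-chase (EdU/BrdU) cell-fate-identification data, clone morphometrics
with edge/inner cell classification, a stochastic lattice simulator of
the renewing-edge / differentiating-core clone model, and pooled shRNA
screen enrichment with gene-level hit calling.

## The science

Basal progenitors of the interfollicular epidermis divide in three ways:
**symmetric renewal** (SR, two basal daughters), **asymmetric division**
(AD, one basal and one suprabasal daughter) and **symmetric
differentiation** (SD, two suprabasal daughters). The *renewal rate*

> r = f_SR + f_AD / 2

is the proportion of daughter cells that remain progenitors. r = 0.5 is
homeostasis; wild-type epidermis sits there (fractions ≈ 29 / 44 / 27 %,
r ≈ 0.5). Progenitors expressing oncogenic Hras^G12V shift to 48 / 42 /
10 %, giving r = 0.69 — yet their clones do not take over the tissue.
The resolution is spatial: clone cells in contact with wild-type
neighbours ("edge" cells, along the clone circumference) keep renewing
at the single-cell rate, while cells surrounded entirely by other
mutant cells ("inner" cells) differentiate at elevated rates, pulling
the whole-clone renewal back toward 0.5 as the inner compartment grows.

`clonedyn` implements, as reusable and tested Python:

- **fate_stats** — division classification, fate-fraction and
  renewal-rate estimators (division-based and population-based
  EdU+/K10− counting), per-animal two-tailed t-tests, bootstrap CIs;
- **morphometry** — pruned-Delaunay contact graphs, edge/inner
  classification (wild-type-contact or alpha-shape boundary modes),
  moment-matched fitted ellipses, circularity 4π·area/perimeter², clone
  density;
- **simulator** — a seeded hexagonal-lattice clone-growth model with
  context-dependent fate probabilities, plus multinomial pulse-chase
  samplers and negative-binomial shRNA screen count generators that
  feed every other module;
- **screen** — median-of-ratios normalisation, per-hairpin
  basal/suprabasal NB Wald or permutation enrichment tests,
  Benjamini–Hochberg correction, and the "≥2 significant, consistent
  hairpins" gene-level hit rule;
- **io** — schema-validated TSV/CSV readers and writers and the
  `clonedyn` command-line interface.

## Worked example

Score a synthetic pulse-chase experiment at the mutant single-cell fate
probabilities, at the scale of the real assay (3 animals × 75 scored
doublets), then watch a simulated clone stabilise:

```python
import numpy as np
from clonedyn import fate_stats as fs, simulator as sim

events = sim.sample_cfi_dataset((0.48, 0.42, 0.10), 225, n_animals=3, seed=7)
f = fs.estimate_fate_fractions(events)
est = fs.renewal_rate_from_fractions(f)
print(f"fractions: SR={f.f_sr:.3f} AD={f.f_ad:.3f} SD={f.f_sd:.3f}")
print(f"renewal rate: {est.rate:.3f}")

cfg = sim.SimConfig(seed=7, duration_days=112.0, init="mutant_rosette")
traj, cells, ev = sim.run(cfg)
last = traj.iloc[-1]
print(f"clone at 16 weeks: {int(last.n_basal)} basal cells, "
      f"edge fraction {last.edge_fraction:.2f}, "
      f"realized renewal {last.renewal_rate:.2f}")
```

prints

```
fractions: SR=0.480 AD=0.427 SD=0.093
renewal rate: 0.693
clone at 16 weeks: 56 basal cells, edge fraction 0.55, realized renewal 0.54
```

The recovered renewal rate matches the generating 0.69; the simulated
clone, started from a 7-cell rosette whose cells all renew at 0.69, has
built a differentiating core — its edge fraction has fallen from 86% to
55% and its cumulative renewal rate has decayed to near-homeostatic
0.54, so growth has slowed by orders of magnitude relative to unchecked
exponential expansion.

The same operations are available from the shell:

```sh
clonedyn cfi-score   --events events.tsv --group-by context,week --out fractions.tsv
clonedyn morphometry --cells cells.tsv --max-dist 15 --mode neighbor_cells --out morpho.tsv
clonedyn screen      --counts counts.tsv --method nb_wald --q 0.05 --out hits.tsv
clonedyn simulate    --config sim.yaml --out rundir/
clonedyn report      --run-dir rundir/
```

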