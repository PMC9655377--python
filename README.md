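# stabselect

Stability selection for crop genotypes screened under multiple abiotic
stresses. Given replicated trait measurements of each genotype in a
non-stressed control and in two stress environments (typically saline and
drought, imposed as iso-osmotic −0.20 MPa NaCl and PEG-6000 treatments in a
germination assay), `stabselect` answers: *which genotypes change least
under stress in both environments at once?*

It is written for plant breeders and quantitative geneticists running
multi-environment screening trials, but the machinery (distance in a
normalized trait space + multi-criteria fusion) applies to any replicated
control-vs-stress phenotyping design.

## The method

Each genotype × environment combination is a point
**x** ∈ ℝⁿ in a trait space (n = 7 by default: GERM, SL, RL, TL, SDM, RDM,
TDM — germination %, shoot/root/total seedling length, shoot/root/total dry
matter). Traits are made dimensionless by dividing by their maximum over
the whole dataset, x̃ᵢ = xᵢ / max(xᵢ), replicates are averaged, and
stability under stress is measured as the Minkowski distance

d(x, y, p) = ( Σᵢ |xᵢ − yᵢ|ᵖ )^(1/p)

between the genotype's control mean vector and its stress mean vector,
with p = 1 (Manhattan) by default. Small distance = the phenotype barely
moved = a stable genotype.

A genotype that is most stable under salt is rarely the most stable under
drought, so the per-genotype distance pair (ds, dd) is fused with
**TOPSIS**: vector-normalize each column (rᵢⱼ = xᵢⱼ/√Σᵢxᵢⱼ²), weight
(vᵢⱼ = rᵢⱼwⱼ, Σwⱼ = 1), take per-column ideal/anti-ideal points (for these
cost criteria the ideal is the minimum), compute Euclidean separations S_ib
and S_iw from them, and score each genotype by the closeness coefficient

Cᵢ = S_iw / (S_iw + S_ib) ∈ [0, 1].

Cᵢ = 1 means the genotype coincides with the ideal (smallest distances in
both stresses); genotypes are ranked by descending Cᵢ, and a weight sweep
over (w_s, w_d) pairs probes how robust the selection is to the
saline-vs-drought trade-off.

The package also contains the osmotic-potential calibration used to design
such trials: the Michel–Kaufmann polynomial for PEG-6000 (inverted in
closed form) and the van't Hoff relation for NaCl, both as forward and
inverse maps.

## Worked example

```python
import stabselect as ss

cfg = ss.SyntheticConfig(n_genotypes=10, seed=7)   # known sensitivities
table = ss.simulate_phenotypes(cfg)                # 10 x 3 envs x 4 reps
res = ss.GenotypeStabilityModel(table).fit(weights=(0.5, 0.5))
print(res.summary(top=5))
```

```
Genotype stability selection (Minkowski distance + TOPSIS)
==============================================================
genotypes: 10   environments: 3   replicates: 4
control: 'control'   stresses: ('saline', 'drought')
distance order p: 1.0   criterion weights (ds, dd): (0.5, 0.5)
--------------------------------------------------------------
              ds      dd     Siw     Sib      Ci  rank
genotype
G02       0.3193  0.1177  0.3691  0.0000  1.0000     1
G09       1.6480  1.0157  0.2568  0.1137  0.6932     2
G08       1.3266  2.3216  0.2304  0.1632  0.5853     3
G06       2.1750  1.5214  0.2059  0.1641  0.5564     4
G03       0.8215  3.2218  0.2518  0.2085  0.5471     5
--------------------------------------------------------------
Ci: closeness to the ideal (stable) genotype; higher is better.
```

`ds` and `dd` are each genotype's Manhattan distances from its own control
mean under saline and drought stress; `Ci` is the fused stability score.
Here G02 — the genotype the generator made least stress-sensitive — attains
Cᵢ = 1.0, and the fitted top-5 (G02, G09, G08, G06, G03) exactly matches
the generator's true sensitivity ordering
(`ss.ground_truth_ranking(cfg)[:5]`). A robustness sweep,

```python
sw = res.weight_sweep(k=3)
sw.selection_frequency.sort_values(ascending=False).head(3)
```

```
genotype
G02    1.0
G09    0.6
G01    0.4
```

shows G02 entering the top-3 at every weight pair — a selection insensitive
to how the two stresses are weighted.

The same pipeline runs from the shell:

```bash
stabselect simulate --n-genotypes 10 --seed 7 --out phenotypes.csv
stabselect select --in phenotypes.csv --weights 0.5,0.5 --out-dir results/
stabselect sweep --in phenotypes.csv --grid default --topk 10 --out sweep.csv
stabselect osmotic peg --psi -0.20 --temp 25
# {"psi_mpa": -0.2, "temp_c": 25.0, "peg_g_per_L": 119.57}
```

Real data are read from CSV with
`ss.GenotypeStabilityModel.from_csv("phenotypes.csv")`; the expected long
format is one row per genotype × environment × replicate with columns
`genotype, environment, replicate, GERM, SL, RL, TL, SDM, RDM, TDM`
(column names remappable, trait list configurable).

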