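# ricascade

Sequential quantification of reproductive-isolation barriers between
co-occurring plant species, from raw field observations to a full
barrier-cascade decomposition.

Speciation studies in flowering plants routinely ask which mechanisms —
flowering-time divergence, pollinator behaviour, pollen–pistil
incompatibility, fruit abortion, embryo failure — actually keep two
sympatric species from hybridising, and how much each contributes.
`ricascade` is a Python library and CLI for ecologists running such
studies: it ingests the three standard field-data types (per-individual
flowering schedules, pollinator foraging bouts in two-species choice
arrays, and hand-pollination cross outcomes), computes the strength of
each barrier as a reproductive-isolation (RI) index, and assembles the
barriers into the sequential cascade that yields total isolation and
each barrier's absolute contribution. A synthetic-data module generates
statistically faithful datasets so the whole pipeline can be exercised
and validated end to end.

## The indices

For any barrier, with conspecific success $C$ and heterospecific
success $H$ (counts, rates or proportions — the index is
scale-invariant):

$$\mathrm{RI} = 1 - \frac{2H}{H + C}$$

RI = 1 is complete isolation, 0 no isolation, negative values a
heterospecific advantage. Temporal (phenological) isolation uses the
one-sided form $\mathrm{RI}_\text{pheno} = 1 - S/(S+U)$, where $S$ and
$U$ are the shared and unshared proportions of the focal species'
flowering time. Pollinator fidelity per foraging bout is measured by
the constancy index

$$\mathrm{CI} = \frac{c - e}{c + e - 2ce}, \qquad e = p^2 + (1-p)^2,$$

with $c$ the observed proportion of conspecific floral transitions and
$p$ the proportion of visits to one of the two species; intra- vs
interspecific transition totals are compared with a likelihood-ratio
G-test. Barriers combine sequentially — each acts only on the gene flow
that survived earlier stages:

$$\mathrm{RI}_{1,i} = \mathrm{RI}_{1,i-1} + \mathrm{RI}_i\,(1 - \mathrm{RI}_{1,i-1}),
\qquad \mathrm{AC}_i = \mathrm{RI}_{1,i} - \mathrm{RI}_{1,i-1},$$

in the life-cycle order phenology → ethological → style → ovary →
fruit → seed. A flowering-weighted total (heterospecific success
down-weighted by the shared flowering proportion) is reported alongside
the recurrence total, and per-barrier asymmetry between reciprocal
cross directions as $|\mathrm{RI}_{ab} - \mathrm{RI}_{ba}|$.
Nonparametric bootstrap intervals over the raw observations are
available for every barrier and the total.

## Worked example

The package ships the choice-array observations from a field study of
three sympatric *Habenaria* orchids (*H. limprichtii* "lim",
*H. davidii* "dav", *H. delavayi* "del") pollinated by nocturnal moths:

```python
from ricascade import ethological_ri, g_test_transitions
from ricascade import reference_transition_tables

table = reference_transition_tables()["lim_dav"]
print(ethological_ri(table, "lim"))                 # 0.8823529411764706
print(ethological_ri(table, "dav"))                 # 0.6470588235294117
print(g_test_transitions(table.intraspecific, table.interspecific))
# (22.503690392865757, 1, 2.097402660266763e-06)
```

Of the pooled floral transitions in the lim/dav array, only 4 of 34
were interspecific (G = 22.50, p < 0.001): moths foraging on
*H. limprichtii* almost never arrive from a *H. davidii* flower
(RI = 0.882), giving strong ethological isolation in both directions.

The same analysis runs end to end on synthetic data from the shell:

```
ricascade simulate -o data --seed 42
ricascade report -d data -o out
```

which writes per-barrier tables and `out/cascade.json`; for the
simulated dav♀ × lim♂ direction (seed 42):

```
barriers    {phenology: 0.0, ethological: 0.889, style: 0.013,
             ovary: 0.017, fruit: -0.011, seed: 0.0}
cumulative  {phenology: 0.0, ethological: 0.889, style: 0.890,
             ovary: 0.892, fruit: 0.891, seed: 0.891}
AC          {phenology: 0.0, ethological: 0.889, style: 0.001,
             ovary: 0.002, fruit: -0.001, seed: 0.0}
total_recurrence 0.891    total_weighted 0.893
```

Nearly all isolation between the two freely inter-fertile simulated
species comes from pollinator preference (AC = 0.889); the
post-pollination stages contribute almost nothing, and the absolute
contributions sum exactly to the total.

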