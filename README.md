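# nucmut

Tools for asking whether **nucleosome translational-positioning stability
modulates local germline mutation rates**, built for computational
genomicists who have MNase-seq nucleosome maps, de novo / somatic variant
sets and genome-wide functional tracks, and want the whole analysis —
positioning metrics, enrichment, covariate-controlled regression, mutation
spectra, repair escape profiles — as a tested, scriptable pipeline.

## The quantities at the core

For a focal genomic position, collect the absolute distances `d_i` of all
MNase-seq fragment midpoints within ±95 bp (half a nucleosome repeat length
of ~191.4 bp) and summarize translational positioning as

```
d_mean = Σ d_i / n                      0 ≤ d ≤ 95
d_var  = Σ (d_i − d_mean)² / (n − 1)
```

Low `d_var` means nearby nucleosomes sit in nearly the same place across
cells (a translationally stable, "strong" nucleosome); `d_mean` locates the
base relative to the dyad. Sites need ≥10 midpoints in the window and
mappability ≥90 to enter the analysis.

Whether these variables predict mutation independently of known covariates
(sequence context, methylation, replication timing, ...) is tested with a
binary logistic model `logit Pr(y=1) = Xβ` fitted as a MAP estimate under
weakly-informative Cauchy priors (scale 2.5 on standardized coefficients,
10 on the intercept) — the heavy-tailed prior keeps estimates finite under
the complete separation that rare-event data routinely produce. Each
variable is assessed by a likelihood-ratio test against the reduced model
without it, BH-corrected, with McFadden's pseudo-R² quantifying explained
variation.

Mutational processes are read out from the 96-type spectrum after
trinucleotide background correction `F'_i = F_i / N_tri(i) × N_tri,genome(i)`,
per-type Fisher exact tests, and non-negative least-squares refitting
against a signature matrix. Differential repair around dyads is quantified
by the escape ratio per 10-bp bin,

```
R_i = (m_i^A / m_i^B) / (m̄^A / m̄^B)
```

comparing a repair-proficient cohort A with a repair-deficient cohort B,
background-normalized by densities in random 1600-bp windows; `R_i > 1`
means replication errors disproportionately escape repair in bin `i`.

Every input class can be simulated with known ground truth
(`nucmut.simulate`): genomes, dyad landscapes with tunable translational
jitter, mutations from a known logistic model, paired cohorts with a known
escape profile, signature mixtures, and smooth signal tracks.

## Worked example

```python
import numpy as np, pandas as pd
from nucmut import simulate, nucstats, regression

cfg = simulate.SimConfig(chrom_lengths={"chr1": 1_000_000}, seed=11)
genome = simulate.gen_genome(cfg)
dyads, midpoints, strong, rotational = simulate.gen_nucleosome_landscape(genome, cfg)

# per-base positioning statistics
st = nucstats.batch_positioning_stats(
    np.arange(100, 999_900), midpoints.positions["chr1"])
st = st[st.usable & st.d_var.notna()]

# simulate mutations whose rate falls with log d_var (true effect −0.5)
feats = pd.DataFrame({"chrom": "chr1", "pos0": st.pos0,
                      "log_d_var": np.log(st.d_var + 1.0)})
variants, truth = simulate.gen_mutations_from_model(
    genome, feats, {"log_d_var": -0.5}, n_target=5000, seed=12)

# fit the penalized logistic model and recover the effect
y = feats.pos0.isin({v.pos0 for v in variants}).to_numpy(float)
fit = regression.fit_penalized_logistic(
    regression.build_design(feats, ["log_d_var"]), y)
print(round(fit.params["log_d_var"], 3))
```

This prints `-0.515`: the fitted log-d_var coefficient recovers the
generative value −0.5 — mutation probability falls as positioning becomes
less stable, i.e. translational stability is associated with *elevated*
mutation rates once the model's other terms are controlled.

The same stages are exposed as a CLI (`nucmut simulate | nucstats |
occupancy | enrich | profile | regress | spectrum | signatures | escape`);
every subcommand writes TSV output plus a JSON run-manifest, and reruns
with the same `--seed` are byte-identical.

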