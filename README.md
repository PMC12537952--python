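# mitomotor

Quantitative analyses for mouse studies of gut-microbiome effects on
alpha-synuclein-driven motor deficits and striatal mitochondrial
bioenergetics: a right-censored lognormal mixture model for motor-test
latencies, rank-based group inference, composite mitochondrial health
indices from plate enzymology and qPCR, and respiration-state extraction
from Seahorse-style oxygen-consumption traces. Seeded synthetic-data
generators emulate every input, so the full pipeline runs and is tested
without animal data.

## Who this is for

Researchers analyzing motor behavior scored with a time ceiling (beam
traversal, pole descent), together with striatal mitochondrial assays,
in 2x2 genotype x microbiome (or treatment) designs — and anyone who
needs a tested, scriptable implementation of the statistics below.

## The models

**Censored latency mixture.** A trial either fails outright or is
completed in a lognormally distributed time, censored at the 60-s
ceiling:

```
y' ~ omega * LogNormal(mu, sigma) + (1 - omega) * delta_60
y  = y'  if y' < 60, else 60
```

`omega` is the probability of completing the task. Parameters are
estimated by maximum likelihood (logit/log reparameterization,
deterministic multi-start quasi-Newton); confidence intervals come from
a parametric bootstrap (percentile method, 10,000 replicates by
default); model fit is assessed graphically via predictive-ECDF
envelopes and Q-Q plots. Group comparisons use per-animal median
latencies with Kruskal-Wallis followed by Conover's (or Dunn's)
post-hoc test and Benjamini-Hochberg adjustment.

**Mitochondrial indices.** From duplicate enzymatic activities
(Complexes I, II, IV and citrate synthase; plate effects removed via
five on-plate reference samples) and triplicate qPCR (COX1 vs B2M):

```
MHI = (CI + CII + CIV) / (CS + mtDNA density + 1) * 100      (mean-centered features)
MRC = mean(sqrt(CI) + sqrt(CII) + sqrt(CIV)) / mean(cbrt(mtDNA density) + cbrt(CS)) * 100
mtDNAcn = 2^(dCt) * 2,   dCt = mean Ct_B2M - mean Ct_COX1
```

An animal at the cohort average on all five features scores MHI = 100.

**Respirometry.** Injection-phased OCR traces (substrate, ADP,
oligomycin, FCCP, rotenone + antimycin A) yield States 2/3/4o/3u as
phase means minus non-mitochondrial OCR, per microgram protein, with
RCR = State 3 / State 4o, averaged over quintuplicate wells per mouse.

Endpoint group effects use the linear model
`value ~ genotype + condition + genotype:condition` with BH-adjusted
pairwise cell contrasts.

## Worked example

```python
from mitomotor import SyntheticConfig, fit_mle, parametric_bootstrap
from mitomotor.simulate import simulate_trials

trials = simulate_trials(SyntheticConfig(seed=1))
pole = trials[trials["test"] == "pole"]
for (gen, cond), sub in pole.groupby(["genotype", "condition"]):
    fit = fit_mle(sub["latency_s"].to_numpy())
    ci = {b.parameter: (b.lower, b.upper) for b in
          parametric_bootstrap(fit, n_replicates=1000, level=0.95, seed=1)}
    lo, hi = ci["omega"]
    print(f"{gen}-{cond}: omega = {fit.params.omega:.3f} "
          f"[{lo:.3f}, {hi:.3f}], n = {fit.n_obs} trials "
          f"({fit.n_censored} censored)")
```

prints

```
ASO-GF: omega = 0.896 [0.812, 0.979], n = 48 trials (5 censored)
ASO-SPF: omega = 0.681 [0.530, 0.833], n = 48 trials (16 censored)
WT-GF: omega = 0.979 [0.937, 1.000], n = 48 trials (1 censored)
WT-SPF: omega = 0.979 [0.937, 1.000], n = 48 trials (1 censored)
```

The alpha-synuclein-overexpressing mice with a conventional microbiome
(ASO-SPF) have a markedly lower estimated probability of descending the
pole within 60 s, with a bootstrap CI excluding the wild-type groups' —
the qualitative pattern the synthetic generator encodes.

The same analyses are available from the shell:

```sh
mitomotor simulate --seed 1 --out data/
mitomotor fit-latency --input data/trials.csv --test pole --bootstrap 10000 --seed 1 --out fits/
mitomotor run-all --simulate --seed 1 --out run/
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
pushes a constructed all-average animal through the full feature
pipeline (specific activity, plate normalization, qPCR-derived mtDNA
density, cohort mean-centering) and reports the resulting Mitochondrial
Health Index as JSON.

See `docs/methods.md` for model assumptions, parameter defaults,
numerical choices, and known limitations.
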