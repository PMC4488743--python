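# paleombd

Forward simulation and diagnostics for **MBD enrichment of ancient DNA**.

Methyl-CpG-binding-domain (MBD2–Fc) capture separates a DNA extract into a
bound fraction (MBD+), enriched for molecules carrying methylated CpGs, and a
supernatant (MBD−). Applied to ancient DNA it promises probe-free enrichment
of endogenous methylomes away from microbial background — but it interacts
strongly with post-mortem chemistry: fragmentation removes the long,
CpG-rich templates that bind best, and hydrolytic deamination converts
methylated CpGs into TpGs, which are no longer capture targets.

`paleombd` models this interaction end to end so that the diagnostics used to
characterise such experiments can be validated against known ground truth.
It is aimed at palaeogenomicists and methods developers who want to reason
quantitatively about capture biases before (or instead of) sequencing.

## The model

**Damage.** Each double-stranded fragment carries geometric single-stranded
5′ overhangs with termination parameter λ (mean length (1−λ)/λ). Cytosines
deaminate with probability δ_s in single-stranded and δ_d in double-stranded
context (observed as C→T at 5′ read starts and G→A at 3′ read ends);
methylated CpG cytosines deaminate ρ-fold faster. The positional C→T
frequency follows the closed form

```
p(d) = δ_s (1−λ)^d + δ_d (1 − (1−λ)^d),   d = 1-based distance from the 5′ end
```

which the package both simulates and inverts (bounded maximum-likelihood fit
of δ_s, δ_d, λ from misincorporation tables).

**Capture.** A molecule with k intact (methylated, non-deaminated) CpGs is
captured with probability

```
P(capture | k) = c + (1−c)(1−e)(1 − (1−β)^k)
```

— per-target binding β saturating in k, nonspecific carryover c (the route by
which microbial and mitochondrial DNA enters MBD+), and wash/elution escape e.

**Diagnostics.** From the sequenced fractions (PCR resampling with Gamma
amplification weights; duplicates flagged) the package computes endogenous
content under MQ0/MQ25-style placement filters, clonality, mtDNA share,
insert sizes, GC/CpG/dinucleotide composition, CpG-island and
transposable-element coverage ratios, depth histograms, the CpG-vs-CpN
deamination ratio, the regional methylation proxy Ms (terminal CpG→TpG
frequency per 100-bp window), Shannon diversity of the microbial background,
and a random-intercept mixed model (ML + likelihood-ratio test) plus Welch
t-tests for MBD+/MBD− comparisons across samples.

## Worked example

```python
from paleombd import RunConfig
from paleombd.pipeline import simulate_run

res = simulate_run(RunConfig(seed=11826))
for name in ("MBD_plus", "MBD_minus"):
    fit = res["fits"][name]
    print(name, round(fit.delta_s_hat, 3), round(fit.delta_d_hat, 4),
          round(res["ratios"][name], 2), round(res["ms"][name], 3))
```

prints

```
MBD_plus 0.373 0.0219 3.05 0.534
MBD_minus 0.364 0.0203 2.79 0.423
```

i.e. per fraction: the fitted single- and double-strand deamination rates,
the CpG/CpN deamination ratio, and mean Ms. The simulation truth was
δ_s=0.25, δ_d=0.015 with ρ=4: the *apparent* rates exceed the unmethylated
truth because fast-deaminating methylated CpGs are pooled into the global
profile, and the captured fraction — which overlaps more methylated
templates — shows the higher CpG-context ratio and Ms, together with longer
inserts, higher CpG density, strong mtDNA and CpG-island depletion, TE
over-representation and roughly doubled clonality (see
`res["report"].fold_changes`).

The `examples/` directory walks through each capability: reference-world
construction, damage simulation vs the closed form, capture partitioning,
damage/methylation inference, the full enrichment report, and a multi-sample
mixed-model study. A thin CLI mirrors the pipeline stages
(`paleombd run --seed 1 --out runs/demo`).

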