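# Methods

## The forward model

### Reference world

`genome.build_reference` generates i.i.d. base sequences at configurable GC
content for one nuclear contig, one mitochondrial contig and several
microbial contigs. Three annotation strata give the nuclear genome the
methylation structure that matters for MBD capture:

* **CpG islands (CGIs)** — GC-rich (default 0.65) and explicitly CpG-dense
  (CG dimers emitted at an elevated per-step rate of 0.06): many CpG
  targets, essentially none methylated (default 0.05).
* **Transposable elements (TEs)** — families of ≥2 byte-identical copies
  placed at disjoint loci, so reads from them are genuinely ambiguous
  (MAPQ-0 analogue); silenced by methylation (default 0.95).
* **Background** — globally methylated, as in vertebrate genomes
  (default 0.78).

Mitochondrial CpGs are forced to methylation 0; microbial contigs carry no
CpG-methylation entries at all (bacterial methylation is mostly non-CpG and
invisible to MBD). On stratum overlap the precedence is TE > CGI >
background: TE silencing is the mechanism behind TE over-representation in
the captured fraction, so it wins.

Coordinates are 0-based half-open throughout; a CpG is indexed by the
forward-strand position of its C. Methylation is realised **per molecule**
as independent Bernoulli draws from the track (epialleles), so
coverage-level methylation converges to the track value.

A deliberate simplification: i.i.d. sequences are *not* CpG-depleted the way
real vertebrate genomes are (observed/expected CpG ≈ 0.2–0.25 in mammals).
Synthetic fragments therefore carry several-fold more CpGs per bp than real
reads of the same length and GC. This strengthens capture saturation and is
accounted for in the default capture parameters; consequences for what the
defaults can and cannot show are discussed under *Limitations*.

### Damage

Fragment lengths are lognormal by default (median 80 bp, σ_log = 0.4),
matching the right-skewed size spectra of ancient extracts; a per-base
breakage (geometric) alternative exists for sensitivity analyses. Each end
receives an independent geometric 5′ overhang, P(L=l) = λ(1−λ)^l, so the
mean overhang is (1−λ)/λ.

Deamination is Bernoulli per cytosine: probability min(1, ρ·δ_s) in
single-stranded context (forward-strand Cs within the 5′ overhang;
reference Gs — reverse-strand Cs — within the 3′ overhang) and min(1, ρ·δ_d)
elsewhere, with ρ = `rho_meth` when the site is a methylated CpG on that
molecule and 1 otherwise. Events are observed as C→T / G→A; sequencing is
otherwise error-free, because platform error would confound the deamination
signal the package is designed to study. The closed-form positional profile
`expected_ct_profile` (see README) is the oracle for all estimator checks.

Default damage parameters and why:

| parameter | default | rationale |
| --- | --- | --- |
| δ_s | 0.25 | mid-range single-strand deamination for Pleistocene-age material |
| δ_d | 0.015 | typical double-strand plateau, an order of magnitude below δ_s |
| λ | 0.35 | mean overhang ≈ 1.9 bp, inside the 0.9–2.8 bp range seen in ancient libraries |
| ρ (rho_meth) | 4 | hydrolytic deamination of 5-methylcytosine is ~2–4× faster than C in dsDNA |
| insert median | 80 bp | between well-preserved (~100 bp) and degraded (~60 bp) extract scenarios |

### Capture, PCR and sequencing

Capture probability is `carryover + (1−carryover)(1−escape)(1−(1−β)^k)`
with k the number of **intact** methylated CpGs (a deaminated methyl-C has
become TpG and no longer binds). Hemimethylation is ignored: a CpG is intact
iff the forward-strand methyl-C survived — a single-parameter model.
Defaults: β = 0.6 (commercial MBD2–Fc kits are designed to saturate on
multi-mCpG templates), carryover = 0.02 (observed microbial/organellar
leakage into MBD+), escape = 0.05 (wash/elution loss). Binding failure and
wash stringency are not separable experimentally, so both collapse into
`escape`/`carryover`.

Sequencing draws reads with replacement from the pool with per-molecule
Gamma(1/dispersion, mean 1) amplification weights (dispersion 0.3) and an
optional exponential GC-bias; the first draw of a molecule is the
non-duplicate representative, later draws are flagged duplicates. Reads are
full-length molecules (collapsed-read convention). Smaller pools therefore
show higher clonality at fixed sequencing effort, which is exactly the
library-complexity penalty of capture.

Default run size: 150,000 fragments, endogenous fraction 0.35 (a
well-preserved permafrost-bone scenario), mitochondrial weight boost 3
(calibrated to give a percent-level mtDNA share of endogenous reads on the
1-Mb-scale nuclear contig, standing in for organellar copy number on a
3-Gb genome), 60,000 reads per fraction. These sizes keep the full pipeline
under ~30 s on one CPU while leaving every diagnostic thousands of
informative observations.

## Inference layer

* **Misincorporation tables** count C sites and C→T events by 1-based
  distance from the 5′ end (G/G→A mirrored from the 3′ end), stratified by
  CpN context with the reverse strand handled by complement. Duplicates are
  always excluded; defaults also exclude repetitive (MQ0-analogue) and
  non-endogenous reads, mirroring quality-filtered alignments.
* **Damage fit**: bounded ML on the 5′ profile over [0,1]³ from a fixed
  start grid (L-BFGS-B; deterministic). The 3′ side serves as a consistency
  check. Flat profiles (δ_s ≈ δ_d or λ ≈ 1) are non-identifiable in λ and
  flagged `degenerate`; all-zero tables return zeros with the flag. The
  plateau estimate δ̂_d equals p(∞) of the fitted curve.
* **CpG-context ratio**: per-site C→T rate at CpG sites over the pooled
  CpA/CpC/CpT rate. Normalising by context site counts separates chemistry
  from composition — the fractions differ in how many CpGs they carry, not
  only in how fast those deaminate. Zero non-CpG events yield a flagged
  infinity, never a silent division.
* **Ms**: for every reference CpG covered by a read's 5′-terminal base
  (reverse-strand molecules contribute through terminal G→A on the CpG's G),
  the fraction of terminal observations reading TpG, in tiling 100-bp
  windows (configurable step; the restriction to d = 1 maximises the
  deamination signal). Windows below a coverage threshold are omitted.
  The operation's default threshold is 50 observations per window
  (publication-scale); at desk-scale depths the pipeline instead aggregates
  terminal observations genome-wide (coverage-weighted mean Ms, threshold
  1), which estimates the same quantity without requiring per-window depth
  that only billions of reads can supply.

## Comparison layer

The mixed model y = μ + τ·fraction + ν_sample + ε is fitted by **maximum
likelihood** (not REML) so the τ = 0 null is testable by likelihood ratio
against χ²₁. The implementation profiles the likelihood over the variance
ratio θ = σ²_ν/σ² — for fixed θ the GLS solution is closed-form per sample
block (Woodbury) — maximising θ on a deterministic log grid with
golden-section refinement: no random starts, bitwise-reproducible fits. A
single sample drops the random intercept (plain linear model, warned).
Damage parameters are compared with Welch (unequal-variance) two-sample
t-tests, applied only to groups with ≥3 samples per fraction. No
multiple-testing correction is applied. Fold changes are reported only when
both fractions pass the minimum-data gates (2,000 nuclear / 20 mitochondrial
reads).

## Numerical choices

* Binomial likelihoods clip probabilities to [1e-12, 1−1e-12].
* Interval placement retries up to `max_placement_tries` before raising.
* Fragments longer than their contig are resampled; lengths are floored at
  `min_length` (25 bp).
* Size bins are left-closed right-open; "<30 bp" means [2, 30). Empty bins
  report missing, not zero.
* Shannon diversity discards taxa below 1% and renormalises before
  −Σ p ln p.
* Every stage of the pipeline draws from a seed spawned deterministically
  from the run seed; rerunning a configuration reproduces all artifacts
  byte-for-byte (SHA-256 manifest).
* Statistical calibration checks compare the closed-form profile against
  the Rao-Blackwellised empirical frequency (per-molecule conditional event
  probability given the drawn overhangs), whose Monte-Carlo variance is
  strictly below the binomial variance, alongside a pooled chi-square
  goodness-of-fit on the raw events; this keeps fixed-seed checks sharp
  without loosening any tolerance.

## What passing tests do and do not show

The synthetic world reproduces the *structure* that drives MBD biases —
methylation strata, multi-copy repeats, unmethylated organellar and
microbial DNA, size-dependent CpG content, capture saturation, complexity
loss — and the test suite verifies that every diagnostic recovers its
ground-truth signal in the right direction and, where a closed form exists,
at the right value. It does not emulate: real genome composition (CpG
depletion, isochores, repeat taxonomy), nucleosome-protection periodicity,
polymorphism between sample and reference, platform sequencing error,
adapter artifacts, or taxonomic structure of the microbial background
(contigs stand in for genera; only abundances and Shannon diversity are
meaningful). Quantitative fold changes at the defaults are therefore
scenario-specific; directional signatures are the robust output.

One directional caveat is intrinsic to the model rather than the defaults:
with per-site independent deamination, the captured fraction's *global*
C→T profile is necessarily enriched by its higher methylated-CpG content
whenever ρ > 1, so fitted δ̂ values in MBD+ are equal or slightly higher
than in MBD−, even though the capture step does select against deaminated
targets (visible as the lower per-event capture weight and the slightly
shorter MBD+ overhangs). Reproducing a *lower* apparent δ in the captured
fraction additionally requires molecule-level damage-rate heterogeneity
(extracts mixing well- and poorly-preserved templates), which this model
deliberately omits.
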