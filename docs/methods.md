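# Methods

`methbench` implements and cross-compares five strategies for measuring
the fraction of methylated DNA molecules at a CpG-island promoter locus
(the p14^ARF^ tumour-suppressor promoter is the motivating target), at
template amounts representative of circulating cell-free DNA
(~1500 haploid genome equivalents, i.e. 5 ng, per reaction).  All
methods are referenced to a common panel of standards mixed from fully
methylated and fully unmethylated genomic DNA at
100/90/75/50/25/10/0% methylated.

## Quantification models

### Restriction-enzyme digestion PCR (MSRE/MDRE)

Methylation-sensitive enzymes (MSRE) cleave their recognition sites only
when unmethylated; methylation-dependent enzymes (MDRE) only when
methylated.  Digested template is compared with a mock digest of the
same sample.  For qPCR,

    dCq  = mean Cq(mock) − mean Cq(digest)
    ddCq = dCq(sample) − dCq(control)
    MSRE:  % methylation = 100 · 2^ddCq       (control = 100% standard)
    MDRE:  % methylation = 100 · (1 − 2^ddCq) (control = 0% standard)

The amplification base is fixed at 2; per-assay efficiency correction is
out of scope.  An undetected digest is interpreted as complete digestion
(0% for MSRE, 100% for MDRE); an undetected mock or control leaves the
chain undefined and raises.  Replicate wells are summarised over
detected wells only, carrying `n_detected` for downstream weighting.

For digital PCR the same chain runs on Poisson-corrected molecule
counts.  A panel of `n` chambers with `k` positives gives

    λ = −ln(1 − k/n),   estimated targets = n·λ,

with a normal-approximation 95% CI from the binomial variance of
p = k/n propagated through the correction, var(λ̂) = p/((1−p)·n),
truncated at zero.  Counts from the four panels a restriction-digestion
reaction is loaded across are pooled (Σk, Σn) before correction.
Saturated panels (k = n) raise instead of clamping: the assays operate
at λ < 0.2, so saturation signals a corrupt input, not a high
concentration.  The relative quantity %RQ = 100·(digest/mock)/control
is reported directly for MSRE and as 100 − %RQ for MDRE.

Each enzyme class is quantitatively informative only where its digested
template differs measurably from the control: MSRE in the 0–50% range,
MDRE in 50–100%, endpoints inclusive (the 50% standard belongs to both).
A 10-point methylation difference near 100% maps to a Cq difference of
only |log2 0.9| ≈ 0.15 cycles, below the ~0.2-cycle technical noise of
replicate Cq measurements — the quantitative reason these assays cannot
resolve small differences near their control end.

### MethyLight (methylation-specific PCR on bisulfite-converted DNA)

The methylation-specific p14 assay is quantified against a standard
curve (five 1-in-5 dilutions from 7575 haploid genome copies; ordinary
least squares of per-level mean Cq on log10 copies), normalised to the
methylation-independent COL2A1 assay measured on the same sample, and
rescaled to the 100% standard:

    % methylation = 100 · (p14/COL2A1) / (p14/COL2A1 of the 100% standard)

The COL2A1 normalisation makes the estimate invariant to uniform sample
loss.  The dPCR variant replaces interpolated copies with estimated
targets and needs no calibration curve.

### Duplex strand-resolved MethyLight dPCR

Bisulfite conversion leaves the two strands of a duplex
non-complementary, so they separate into different chambers.  A second
assay targeting the opposite strand allows both strands to be counted in
one duplexed reaction; the two target estimates are summed (variances
add) for absolute quantification.  The co-occupancy diagnostic is the
double-positive rate |A∧B| / |A∨B| over chambers positive in at least
one channel: for independent single strands it equals
(1−e^−λA)(1−e^−λB)/P(any positive) — a few percent or less in the
operating regime — whereas double-stranded template drives it toward 1
because both strands of a molecule share a chamber.  The package
normalises combined duplex targets to a COL2A1 estimate measured on the
same sample in a separate assay, since duplexing of the reference locus
is not assumed.

### Bisulfite amplicon sequencing

Reads are aligned to the amplicon reference with all cytosines masked
(C and T in the read both match a reference C), which removes the
alignment bias between converted and unconverted molecules.  The
aligner is a Gotoh local affine-gap dynamic program (match +5,
mismatch −4, gap open −12, gap extend −2; JIT-compiled) with full
traceback; reverse-orientation reads are reverse-complemented into the
reference frame, which maps their G→A conversion pattern back to C→T so
one masking rule serves both strands.  The forward orientation is tried
first and accepted when it already clears the filter; otherwise the
higher-scoring orientation wins.

Quality filtering is strict: > 90% identity over aligned
non-bisulfite-modifiable reference positions (deletions count against
identity) AND > 90% reference coverage; exactly 90% fails.  Passed
alignments are projected onto reference coordinates — read insertions
are dropped, deletions yield gap calls — giving a reference-anchored
call matrix.

Two estimators summarise the call matrix over the 19 methylation-
informative sites (the C of each CpG):

* **SBE** (site-based): mean over covered sites of the per-site
  non-conversion fraction Ccount/(Ccount+Tcount); zero-depth sites are
  excluded, not imputed.
* **RBE** (read-based): each read's converted-site fraction classifies
  it as methylated (≤ 20%), unmethylated (≥ 80%) or indeterminate;
  RBE = 100·M/(M+U) ignoring indeterminate reads.  Reads with a C/T
  call at fewer than half of the informative sites are excluded from
  classification entirely (a conservative floor; the field has no
  agreed threshold).

SBE and RBE agree on clean single-molecule amplicons; PCR chimeras
(crossovers between methylated and unmethylated molecules) leave
per-site counts — and hence SBE — unchanged but swell the indeterminate
class and pull RBE away, so SBE/RBE divergence and the indeterminate
fraction are chimerism diagnostics.

## Evaluation battery

Observed-vs-expected accuracy is summarised by the squared Pearson
correlation (per-sample means and individual points), an OLS regression
of observed on expected (the intercept measures constant
over-estimation; residuals are returned for structure inspection),
per-level fold-bias mean(observed)/expected, and a two-sample t-test of
a candidate barcode's replicates against all others (α = 0.05) for
MID-bias detection.  Discrimination limits come from one-way ANOVA with
Tukey HSD (scipy's studentized-range implementation); the minimum
resolvable difference is the smallest expected-level gap among
significant pairs.  Normality is checked with a one-sample
Kolmogorov–Smirnov test against a fitted normal; constant input is
flagged degenerate rather than tested.

The package ships a 20-row transcription of the two-run bisulfite
amplicon benchmark over the panel
(`methbench/data/ngs_panel_table.csv`).  Re-analysis reproduces
r² = 0.976 (per-sample means, biased barcode excluded), r² = 0.961
(individual points), intercept +8.0, fold-bias 2.03 at 10% and 1.06 at
90%, and the 50%-sample barcode split of 84.9% (MID9) vs 65.1%
(others).  The MID9 exclusion is a flag on input rows, never hard-coded.
The "1.32-fold average over-estimation" sometimes quoted for such data
is not reproduced here: no averaging scheme over the table yields it
exactly (candidates give 1.36–1.38), so it is not asserted anywhere.

## Synthetic data

The generator's defaults are the study conditions: 1515 copies/reaction
(5 ng at 3.3 pg per haploid genome), Cq noise σ = 0.2 cycles, 3
replicate digestions/conversions with triplicate wells, 770-chamber
panels (4 pooled for RE-dPCR, 1 for MethyLight), 13% of the reaction
volume partitioned (0.65 of 5 ng) with MethyLight loading a quarter of
the RE template (1.25 of 5 µL) — together keeping λ < 0.2 everywhere —
500 reads/sample, 99.5% conversion, 1% sequencing error, 0.2%
homopolymer indel rate, no chimeras and no PCR bias.  MSRE digestion is
complete by default; MDRE is 98% efficient, a placeholder for the
observed incomplete digestion of fully methylated template (no
quantitative value exists to anchor it).

Molecules are all-or-none methylated, as in standards mixed from fully
methylated and unmethylated genomic DNA; mosaic methylation patterns,
454 flowgram artefacts, quality scores and primer thermodynamics are
deliberately not modelled, so passing recovery tests says nothing about
those error modes in real data.  Methylation-dependent PCR bias is a
multiplicative read-sampling weight β on methylated templates
(P(methylated read) = fβ/(fβ+1−f)) — the simplest mechanism producing
the monotone inflation seen in practice — optionally modulated per MID
barcode.  Chimeras are single uniform crossovers between two source
molecules.  Every generator is a pure function of (inputs, seed); the
panel experiment spawns one child PRNG stream per assay family so
adding an assay never perturbs another's draws.

`SimulationConfig.unbiased()` switches off every systematic distortion
(enzyme inefficiency, conversion failure, sequencing error, indels,
loss, β, barcode bias, chimeras) while keeping the measurement
architecture's own noise (Cq σ, Poisson partitioning, finite read
sampling).  This is the configuration under which each estimator is
required to recover panel truth within 3 standard errors over 20 seeded
experiments; the 99.5%-conversion default is excluded there because
conversion failure is a ~0.5-point systematic shift of the site-based
estimator, not noise.

## Numerical choices and test scale

Estimated targets use the exact `log1p` form of the Poisson correction;
CI z-values are exact normal quantiles.  The standard-curve fit rejects
non-negative slopes as degenerate.  The aligner's brute-force oracle in
the test suite enumerates affine-gap alignments recursively on ≤ 9-nt
cases.  Recovery and discrimination checks run at desk scale chosen to
keep the whole suite a few minutes long: 20 seeds × 7 samples × 500
reads for the recovery battery, 200 Monte-Carlo replicates for the
ANOVA/Tukey discrimination rates, 10³–10⁴ replicates for the Poisson
and variance oracles.  These sizes give standard errors comfortably
below the asserted tolerances.

## Known limitations

* Identity is computed against the projected reference positions only;
  a read whose best alignment is badly misplaced simply fails the
  filter rather than being flagged.
* The duplex COL2A1 normalisation assumes the reference assay is run on
  the same sample but not in the same duplex; if it were duplexed, the
  co-occupancy diagnostic would need a third channel.
* The qPCR model treats amplification efficiency as exactly 2 per
  cycle; efficiency miscalibration folds into the ddCq chain as a
  multiplicative bias the package does not correct.
* The per-MID bias model acts on read sampling, not on per-cycle PCR
  kinetics, so it reproduces mean shifts but not bias-variance coupling
  across cycles.
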