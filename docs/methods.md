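# Methods

orscreen implements the computational chain of a receptor-deorphanization
study: a heterologous cAMP-luminescence screen of a human odorant-receptor
(OR) library identifies the receptor for the fly pheromone (Z)-4-undecenal
(Z4-11Al); concentration-response assays quantify potency; GC-MS with an
internal standard quantifies what the flies actually emit; and a sensory
panel with receptor genotyping links the receptor's functional haplotype to
human detection of the pheromone. Every stage consumes plain CSV tables and
every input can be generated synthetically, so the full chain runs and is
tested end to end without the deposited raw data.

## Library screening

Each 96-well plate carries receptor-transfected test wells, mock-transfected
negative controls (empty vector) and an OR1A1 + 30 μmol/L R-(−)-carvone
positive control. Luminescence is read three times before odorant
application and three times after; the well summary is
Δ = mean(post) − mean(basal). Per plate, every Δ is divided by the plate's
positive-control Δ, removing plate-to-plate scale (transfection efficiency,
reagent batches, reader gain); normalized duplicate wells of a receptor are
then averaged. A receptor is a hit when its normalized signal strictly
exceeds the screen-wide threshold mean + 2·SD computed over all
test-receptor values; hits that later fail concentration-response validation
are false positives.

Declared conventions (the published description leaves them open):

* The 2σ statistics are computed over test-receptor values only — mock and
  positive control are excluded, and the mock signal is reported alongside.
* Statistics are computed after duplicate averaging.
* SD is the sample SD (n−1) by default; population SD is available.
* Negative normalized values are retained, not clipped.
* Unpaired singleton wells are averaged as-is with a logged warning.

Null behaviour: for an approximately Gaussian null screen the expected
fraction of receptors above mean + 2·SD is ≈2.3% regardless of the noise
magnitude; the suite checks that null screens sit at this level. In a real
screen the planted/true responder inflates the screen SD, pushing the
threshold several null-SDs out, which is why screens with a genuine hit show
essentially no false positives while a fully null screen flags ~2.3%.

## Concentration-response analysis

Per well, Δ-signal as above; the mean mock Δ at the same
(odorant, concentration) is subtracted from each test Δ (the published
description subtracts "the corresponding mock" without stating replicate
pairing; the mean-mock convention is this package's choice). Responses are
normalized either to the plate positive control or to the curve's maximum.
Each replicate is fitted with the four-parameter Hill function

    f(x) = (min − max) / (1 + (x / EC50)^Hillslope) + max

by bounded least squares with EC50 optimized in log10 space. Initialization:
min/max from the data extremes, EC50 at the geometric-mean concentration,
slope 1. Bounds: EC50 within [min conc/100, max conc·100], slope within
[0.1, 10], min/max free; parameter tolerances 1e-12; a fit that ends on the
EC50 bound is marked unconverged. Zero concentrations are excluded from the
log-space fit. EC50s are summarized across replicates as arithmetic mean ±
sample SD (per-replicate fitting, not a pooled fit, matching the published
"mean ± SD, n = 3" reporting).

Nonresponder (ND) rule: a replicate is non-responding when its fit failed,
its EC50 exceeds the highest tested concentration, or its *observable*
amplitude — the fitted response span across the tested window — does not
exceed 3× the SD of mock-subtracted mock responses. The span is used rather
than the asymptotic max − min because an unconstrained 4-parameter fit on
flat noisy data pushes its asymptotes beyond the data range: the asymptotic
amplitude then sits near 3–4 noise SDs and misses about half of truly flat
replicates, while the span stays at noise level (flat curves are called ND
in ≈94% of simulated runs, genuine responders are mis-called in ≤3%). The
receptor is ND when at least two replicates (or all, if fewer) are
non-responding. The rule is statistical: a flat curve can occasionally
produce a spurious "responder" summary, visible in the analysis drivers.

Amplitude contrasts between receptors use a classic paired two-tailed
t-test on replicate-matched mock-subtracted raw amplitudes; identical
samples return (t = 0, p = 1) rather than the 0/0 indeterminate form.

## Headspace quantification

Batches of 60 female flies condition a vial for 24 h; the hexane rinse is
spiked with 100 ng decanal. With a unit response factor (no per-analyte
calibration curve is available; the factor is configurable),
amount = 100 ng · area(analyte)/area(IS). The strain statistic is the
arithmetic mean ± sample SD of *per-sample* Z4-9Al/Z4-11Al ratios — not the
ratio of mean amounts — because the published "2.6 ± 0.7-fold (n = 10)"
reports per-batch variability. The internal standard cancels from the
ratio, so it is invariant to rescaling a sample's areas.

## Sensory panel and the genotype-expectation model

Triangle tests (three vials, two identical) have chance probability 1/3;
binary resemblance comparisons 1/2; the chance level is stored per trial.
Observed correct counts are tested with a 1-df Pearson chi-square
goodness-of-fit against chance; no continuity correction by default, Yates
available by flag.

With c functional-haplotype carriers among n panelists, carriers detecting
with probability p_detect and the rest guessing at p_chance, the number of
correct answers is Binomial(c, p_detect) + Binomial(n − c, p_chance)
(exact pmf by convolution) with expectation c·p_detect + (n − c)·p_chance;
14 always-detecting carriers plus 15 guessers among 29 panelists give 19.

Molarity conversion uses formula-derived molar masses from IUPAC 2021
abridged standard atomic weights (Z4-11Al, C11H20O: 168.28 g/mol, so
1 ng/mL = 0.006 μmol/L at 3-decimal rounding).

## Genotyping

Unphased diploid calls at five coding SNPs (three in OR10A6, two in OR2W1)
are matched against a shipped, versioned haplotype-definition table
(labels, rs sites, two population-frequency columns, functional flags). All
consistent haplotype pairs are enumerated; under phase ambiguity the pair
with the largest product of population frequencies wins and an ambiguity
flag is set — a Sanger workflow cannot phase heterozygous sites either, and
the population frequencies are the only available prior. Allele letters in
the shipped table are nominal placeholders (the public record names the
sites only by rs number); assignment depends only on ref/alt identity.

Two carriage notions are exposed: *site* carriage (either haplotype
contains the variant's site — the composite A117V/V140G/L287P haplotype
carries L287P) and *functional* carriage (the carrying haplotype must also
be functional). Detection phenotypes condition on functional carriage: at
the tabulated frequencies ~95% of individuals carry the L287P site but only
~60% carry the functional single-substitution haplotype, and only the
latter confers receptor function.

In the frequency table, the OR10A6 V140G row carries a minor-allele
frequency (41.3%) but no population haplotype frequency; haplotypes without
a population frequency get zero weight in simulation draws and in the
phasing prior (with it, per-gene frequencies sum to ≤100%, as required).

## Synthetic-data generator

The generator's defaults are the study's conditions: 616 receptor variants
in duplicate (~46 variants per plate plus controls), screening at
30 μmol/L Z4-11Al with OR10A6 L287P planted (EC50 28.21 μmol/L);
triplicate dose-response transfections; 10 headspace batches; triangle
trials at 1 and 10 ng.

* **Noise model.** Reads carry multiplicative Gaussian noise,
  read = true·(1 + ε), ε ~ N(0, cv²), cv = 0.05 — luminescence noise scales
  with signal. Each plate has a multiplicative scale factor
  N(1, 0.10²) that normalization removes. No published noise magnitudes
  exist; these are calibrated choices, fixed once.
* **Signal scale.** Basal 1000 LU, positive-control Δ 4000 LU. Responder
  wells add amplitude · 4000 · Hill(conc) to the post reads.
* **Amplitudes and slopes.** Saturating amplitudes (fraction of positive
  control) are not published; they are set from figure-level statements —
  OR10A6 L287P at 1.0; OR2W1's Z4-11Al amplitude 0.21 (≈six-fold lower raw
  amplitude at 100 μmol/L); comparable Z4-9Al amplitudes. Hill slopes
  default to 1.
* **Headspace presets.** Zimbabwe: per-batch ratio lognormal, calibrated by
  method of moments so the arithmetic mean is 2.6 and SD 0.7 (matching the
  published mean ± SD; a median-2.6 parameterization would bias the
  recovered mean to ≈2.69). Cosmopolitan: Z4-9Al identically zero. Total
  emission per batch: lognormal around 10 ng Z4-11Al (log-SD 0.3) — a
  plausible per-batch scale; the ratio statistic does not depend on it.
* **Panel.** Diplotypes drawn independently per gene at the tabulated
  frequencies (no linkage; no joint frequencies exist). Carrier detection
  probabilities: 1.0 at 10 ng, 0.9 at 1 ng, chance at 0.1 ng — consistent
  with the reported significance pattern across amounts; no psychometric
  function is published.

What the generator does *not* emulate: luminescence kinetics beyond the
3+3 read design, receptor surface-expression differences, chromatogram
waveforms (peak areas only), panelist-level response biases, linkage
between OR10A6 and OR2W1, and the panel's observed enrichment of carriers
relative to population frequencies. Passing tests therefore demonstrate
the correctness and calibration of the analysis chain under these stated
assumptions, not the behaviour of the wet-lab assays.

## Problem sizes and determinism

Monte-Carlo checks use 100 seeds for full 616-variant screens, 50 seeds for
noisy EC50 recovery, 10,000 draws for the panel-model comparison and 10,000
simulated genotypes for frequency recovery — sizes at which the whole suite
runs in well under a minute per module. All randomness flows through
`numpy.random.default_rng` seeded from each config's mandatory seed; fixed
seeds reproduce byte-identical tables.
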