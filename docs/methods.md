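# Methods

This note documents the statistical model behind `mirscreen`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that affect results.

## Plate model and B-score

A screen consists of 96-well plates (rows A–H, columns 1–12). Wells
inside the exclusion mask — by default rows A and B and columns 1 and
12, leaving a 6×10 block of 60 usable wells — carry no samples; the
asymmetric default (A/B rather than A/H) mirrors the layout of the
screen this package emulates and is configurable rather than silently
"corrected". Masks are applied on read, so files with inconsistent
role labels are normalized to one convention.

Each plate is summarized by its median and its **unscaled** MAD (median
of |X − median|; no 1.4826 normal-consistency factor), both over all
usable wells, and every construct-bearing well receives
B = (X − median)/MAD. Even-length medians use the midpoint of the two
central order statistics, for both the location and the deviations;
this is the standard convention but changes the MAD on small plates
(e.g. MAD{1,1,1,9} = 0 either way, but midpoint and lower-interpolation
medians differ on many even-sized sets), so it is fixed here
explicitly. A plate whose MAD is 0 has no usable scale; its scores are
flagged undefined (NaN) rather than propagated as infinities.

B-scores are computed per plate first and then averaged across
replicate plates per construct; raw values are never pooled across
plates, because plate scale and offset effects are exactly what the
per-plate normalization removes (the score is invariant under any
positive affine transform of a whole plate).

Row/column bias diagnostics report each lane's median deviation from
the plate median in plate-MAD units. They are diagnostic only — no
median-polish or row/column correction is applied, matching the
practice of screens where no intraplate bias is observed. Note that a
genuinely biased lane contaminates the plate MAD itself, so a lane
shifted by +3 MAD reports a deviation somewhat below 3; the report is
a flag, not an unbiased effect estimate.

## Normal-null FDR

The empirical FDR at cutoff t is expected/observed hit counts, capped
at 1 and reported as not-applicable when nothing is observed. The null
reference treats well readouts as standard normal: a single B-score is
then approximately Z/c with c = Φ⁻¹(3/4) = 0.67449 (the MAD of a
standard normal), so the mean of k independent replicate scores falls
below t with probability Φ(t·c·√k). The package uses the fixed
constant rather than re-estimating the null from the screen, because
the comparison is to an ideal normal, not to the empirical score
distribution; k defaults to the modal replicate count (2 for a
duplicate screen), with k = 1 exposed for per-replicate curves.

**Finite-plate accuracy.** The Φ(t·c·√k) null is exact only in the
large-plate limit where the plate median and MAD are known. On
60-well plates both are estimated, which fattens the B-score tails:
direct simulation of no-inhibitor duplicate screens (1,072 constructs,
Gaussian well noise) yields on average ≈3.5 constructs per screen with
mean B ≤ −3 against the ideal expectation of 2.26 — a ≈1.5× inflation
with a per-screen Monte-Carlo spread of about ±2. The calibration
tests therefore assert agreement at the scale of a single screen's
Monte-Carlo variability, and the planted-screen tests allow the
empirical FDR up to twice the ideal-null estimate. Users comparing
observed and expected curves on real 60-well data should expect the
same mild excess of "observed" over "expected" even for a completely
null screen. With the default log-normal well noise the effect is
partly offset, because a log-normal left tail is thinner than normal.

## Hit selection

Three branches, evaluated on mean B-scores:

* **A** — mean viability B ≤ −3 (reaching the threshold counts, i.e.
  inclusive);
* **B** — mean viability B < −2 and mean cell-count B < −3 (both
  strict, as conventionally printed);
* **C** — mean viability B < −2 and an externally supplied low-titer
  flag (no numeric titer cutoff exists; a low-titer preparation can
  mimic a viability effect, so such constructs are kept visible at a
  milder score).

All cutoffs are configurable; every satisfied branch is recorded per
hit. Relaxing any cutoff can only grow the hit set (monotonicity is
property-tested).

## Confirmation gating

Candidates are summarized by the mean of their replicates, then gated
against the individual values of the neutral-miRNA control population:
the 95% gate requires the mean to lie below at least ⌈0.95·n⌉ of the n
controls (a counting rule, deliberately not an interpolated quantile —
with n = 28 the 5th percentile is estimator-dependent, the count is
not), and the stringent gate requires it to lie below all of them, with
strict inequality so ties fail. For n = 28 the 95% gate needs 27
controls undercut.

The within-stringent-set FDR uses ranks: a null readout exchangeable
with n controls falls below their minimum with probability 1/(n+1), so
expected null passes = n_candidates/(n+1) and
FDR = expected/|stringent set|, capped at 1. Two conservatisms are
inherent and documented rather than corrected: every candidate is
counted as potentially null (inflating the estimate by roughly the
candidates/null ratio), and candidates averaged over r replicates have
a smaller variance than single-value controls, making them less likely
than 1/(n+1) to undercut the control minimum under the null. On the
reference confirmation counts (55 candidates, 28 controls, 20 stringent
hits) the estimator gives (55/29)/20 ≈ 9.5%.

Group comparisons between candidates (as per-candidate means),
empty vectors and control miRNAs use the two-sided Wilcoxon rank-sum
test (exact for small tie-free groups, normal approximation otherwise);
the choice of test is a documented default, since reports of
this kind rarely name theirs.

## Competition, dose-response, combinations

The GFP−/GFP+ ratio trajectory of a condition is divided by the
empty-vector trajectory and — by default — rescaled to 1 at the first
shared timepoint, which removes the (approximately 1:1 but unknown)
initial mixing ratio; normalization to EV only is exposed via a flag.
The result is invariant to the absolute number of cells analyzed per
timepoint. Empty-vector measurements on different days are linearly
interpolated on the log-ratio scale, with a warning. The fitness
deficit is the least-squares slope of −ln(relative cell number) on
days, with the regression standard error; at least three defined
timepoints are required.

Dose-response readouts are divided by the mock-control value, carrying
the replicate standard deviation on the same scale. The minimal
effective concentration is the smallest tested concentration at which a
series undercuts the scrambled reference by a margin, default 0.10
(ten percentage points of relative viability) — large enough to clear
typical replicate noise; no IC50/4-parameter fit is attempted because
the summaries of interest are threshold-style, not curve parameters.
The combination effect is min(single A, single B) − combination, with
the standard deviation propagated from the combination and the better
single.

## Expression quantification

qPCR levels are 2^−(Ct_target − Ct_U6), with replicate Cts averaged on
the Ct scale before the difference (standard ΔCt practice). Fold
overexpression is ectopic/endogenous, kept at full precision internally
and rounded half-to-even to two significant figures only at reporting;
a zero endogenous level is flagged as infinite fold rather than a
number. Small-RNA abundance is reads·10⁶/total mapped reads. RNA-seq
relative expression is (treated reads/treated total)/(control
reads/control total); genes below a control-read floor are flagged
unquantifiable instead of divided by ~zero.

Target-site enrichment builds the 2×2 table {downregulated vs not} ×
{target site vs not} over quantifiable genes and reports the one-sided
hypergeometric tail for over-representation plus an odds ratio with the
Haldane 0.5 correction when a cell is empty. The downregulation
definition (relative expression < 0.5 with ≥ 10 control reads) is a
configurable default, since enrichment reports rarely state
their cutoff; the conclusion is robust to it in the planted-data tests.

## Synthetic-data generators

`generate_screen` emulates a 1,072-construct duplicate screen (650
annotated + 422 candidate miRNAs' worth of constructs) with two
correlated readouts. Well signal is

    value = base · (plate_scale · (1 − δ) · effect · noise + plate_offset)

with per-plate log-normal scale (sd 0.10) and normal offset (sd 0.01),
mean-1 log-normal well noise (CV 0.10; log-normal keeps positive
absorbances/counts and is CV-parameterized — a Gaussian option exists
for calibrating against normal-theory nulls), and a construct-level
mean-1 log-normal effect (CV 0.05) shared between viability and cell
count with correlation 0.8, which reproduces the strong positive
correlation between the two assays seen in real screens. Inhibitors
(default 50, fractional reductions δ uniform on [0.4, 0.8]) are chosen
uniformly at random so they scatter across plates; base signal is 1.0
(arbitrary — every downstream statistic is scale-free by construction)
for viability and 1,000 rounded to integers for cell counts.
Constructs fill plates in id order, 57 sample plus 3 empty-vector wells
per 60-well plate; duplicates land on distinct physical plates. The
noise magnitudes are calibration knobs, not estimates — the original
screen reports none — chosen as typical of arrayed viability screens.

The generator does **not** emulate spatial edge gradients inside the
usable block, infection-efficiency or selection kinetics, virus titer
(low_titer is a planted flag only), or plate-order drift. Passing
tests on this generator therefore demonstrate the statistics behave
correctly under plate effects, multiplicative noise and planted signal
— not that any particular real screen satisfies those assumptions.

`generate_competition` produces condition/EV series whose expected
GFP−/GFP+ ratio decays as exp(−r·t) with multiplicative log-normal
noise; `generate_expression_table` draws negative-binomial counts
(var = μ + φμ², dispersion φ = 0.05 by default) over log-normal gene
abundances with target genes repressed by a configurable factor;
`generate_confirmation` and `generate_qpcr` produce the corresponding
follow-up inputs. All generators are deterministic given their seed,
and the pipeline fans one global seed out to per-stage child seeds via
`numpy.random.SeedSequence` so stages are reproducible in isolation.

## Problem sizes used in tests and the acceptance script

The self-checks simulate at the sizes the workflow describes: 200
no-inhibitor screens of 1,072 constructs for null calibration, 10
planted screens (50 inhibitors each) for recovery and FDR calibration,
100 noisy competition trajectories (9 timepoints, 5% noise) for
fitness-deficit recovery, 200 planted confirmation screens for the
gate-FDR calibration, and 5,000-gene expression tables at 2M-read
depth for enrichment. The full test suite runs in well under a minute
on one CPU.

## Known limitations

* The normal-null FDR curve inherits the finite-plate bias quantified
  above; it is a property of the B-score method at 60 wells per plate,
  not of the implementation.
* The rank-based confirmation FDR is conservative by design (see
  above); it brackets the true false-positive fraction from above in
  calibration, it does not estimate it unbiasedly.
* Readouts are modelled as independent across wells given plate and
  construct effects; spatially correlated artifacts inside the usable
  block would violate both the generator and the B-score's assumptions.
* No pharmacological curve fitting, no read mapping or target-site
  prediction (target flags are inputs), and no in-vivo statistics.
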