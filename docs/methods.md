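# Methods

## Mass arithmetic and catalog validation

Monoisotopic masses use the most-abundant-isotope atomic masses
(C = 12 exactly, H = 1.00782503207, N = 14.0030740048, O = 15.9949146196 Da).
Negative-mode adducts follow the proton-mass convention:
m/z([M−H]⁻) = M − 1.00727646 and m/z([M−H+FA]⁻) = M + 46.00548 − 1.00727646,
with the ~0.55 mDa electron mass neglected — at 800 Da that is < 0.7 ppm
and reproduces the catalog's printed error column to its one printed
decimal, which a strict ion-mass convention would not. Mass error is the
signed relative deviation 10⁶ (observed − theoretical)/theoretical,
rounded half-away-from-zero to one decimal to match how instrument
software prints it.

Validation tries [M−H]⁻ first and [M−H+FA]⁻ second inside a 20 ppm search
window: a handful of catalog rows (lobetyol, syringin-type glycosides)
print the formate-adduct mass in the detected-m/z column, and preferring
deprotonation ensures a mass matching [M−H]⁻ is never re-explained as a
formate adduct. A row verifies when the recomputed, rounded error is
within 0.05 ppm of the printed value; 69 of 71 packaged rows verify. The
two failures — one row whose printed error disagrees with its own formula
and detected mass by ~1.8 ppm, and one whose detected mass is ~0.35 Da
from any adduct of its printed formula — are recorded in
`data/known_discrepancies.csv` together with rows whose *name* and
printed formula conflict chemically; the table is shipped as printed
rather than silently corrected.

Fragment annotation explains a fragment m/z as the precursor [M−H]⁻ minus
a multiset of neutral losses from a small glycoside-oriented library
(Glc 162.05282, Rha 146.05791, Xyl/Api 132.04226, H₂O 18.01056,
CO₂ 43.98983, CH₂O 30.01057, FA 46.00548 Da). The search returns the
smallest-cardinality multiset within an absolute 0.02 Da tolerance, ties
broken by smallest residual. The tolerance is absolute rather than ppm
because printed fragment masses in MS/MS columns wander by up to ~10 ppm
from exact loss arithmetic. Xylose and apiose are isomers, so annotation
reports the shared mass class ("Xyl/Api"), never the sugar identity.

## Synthetic heart videos

A recording is a dark 8-bit 128×128 background (level 10, chosen as a
typical camera pedestal) plus a bright filled ellipse (level 200, aspect
ratio 1.4) whose **area** is modulated analytically:

    A(t) = A₀ (1 + f · cos φ(t)),   A₀ = 600 px,  f = 0.35,

with diastole (maximal area) at cycle boundaries. Modulating in area
space, and deriving the ellipse axes as √(A/π·ar), keeps the ground-truth
area analytic. Per-cycle periods are drawn as (1/beat_hz)·max(0.2, 1 + cv·z)
with z standard normal, so the inter-beat-interval CV is configurable; a
*dropped* cycle (probability per cycle) holds the diastolic state for its
full duration — a single-chamber stand-in for an AV-block skipped
ventricular contraction. The recording opens mid-cycle so the first
diastolic peak falls strictly inside the trace: a 5-s, 3 Hz stack
contains exactly 15 peaks. Gaussian intensity noise (sd 6 by default) is
added per pixel and clipped to the dtype range.

Presets encode the screen's group conditions: `control-larva` 3.0 Hz
(180 beats/min, regular), `model-larva` 1.5 Hz with IBI CV 0.2 and 5%
dropped cycles (the terfenadine phenotype: 80–100 beats/min, irregular,
occasional block), `adult-normal` 100/60 Hz and `adult-terfenadine`
1.2 Hz with CV 0.25 for the ECG generator. The model group's quantitative
irregularity is not published; CV 0.2 was fixed once as a value that
makes the irregular/regular contrast detectable in a 5-s window, and the
drop probability 0.05 reflects that block appears in *some* model larvae
only. `true_bpm` in the ground truth is the nominal 60·beat_hz.

The ECG generator sums a stylised PQRST template (Gaussian P, Q, R, S, T
lobes; R dominant) at jittered beat times on a 500 Hz grid plus Gaussian
noise. It emulates rate and rhythm only — no QT modelling, no chamber
dissociation.

## Beat detection

The area trace is the per-frame pixel count of the segmented heart:
Otsu threshold, then the largest 8-connected component, which makes the
rate invariant to uniform intensity rescaling and to isolated noise
pixels. Detection then (1) subtracts a 1-s running median (removes drift
slower than any physiological beat at both supported frame rates),
(2) smooths with a 0.1-s moving average, (3) finds local maxima with
prominence ≥ 0.3 × the 5th–95th percentile spread of the detrended signal
and ≥ 0.15 s separation (a 400 beats/min ceiling, far above larval
rates), and (4) refines each peak time by parabolic interpolation through
its three surrounding samples, which recovers the apex of a sampled
cosine to well under one frame period — this is what lets a 20 fps stack
report 180.0 rather than 178–182.

Rate is 60(n−1)/(t_last − t_first) over detected peaks, unbiased for
partial cycles at the stack edges. Rhythm metrics: IBI CV (sample SD over
mean; irregular above 0.15) and a dropped-beat count of intervals longer
than 1.75× the median. Fewer than two peaks yields rate 0 plus a
`no_rhythm` flag instead of an exception so batch runs never abort.

ECG detection reuses the same contract with a 0.02-s smoothing window
(QRS complexes are an order of magnitude narrower than diastolic area
peaks) and a 0.3-s separation so T waves trailing each R are suppressed
in favour of the taller R peak.

Known limitation: a held-diastole plateau is detected at its centre, so a
single dropped cycle appears as two ~1.5× intervals rather than one
doubled interval; the 1.75× dropped-beat counter therefore undercounts
plateau-merged blocks (it reliably catches genuinely missed detections).
The irregularity CV still responds. A second limitation: on a genuinely
flat trace with noise the relative prominence threshold is relative to
the noise itself, so a zero-pulsation recording should be screened by
amplitude before trusting peak counts.

## Bioassay statistics

Survival% = 100·OD_tested/OD_control and protection% =
100·(OD_model − OD_tested)/(OD_model − OD_control) from MTT plate group
means; recovery R_i = 100·(B_i − B_M)/(B_C − B_M) from group-mean beat
rates, matching the scalar form of the defining formula (per-larva R
distributions are a diagnostic only). Neither protection nor R is clamped
to [0, 100]: fractions that depress the rate below the model must come
out negative. Group comparisons use one-way ANOVA (scipy) with a
textbook-formula cross-check in the tests; summaries are mean ± sample SD
(n − 1). Significance is read at α = 0.05 with no multiple-testing
correction — the single-comparison convention of this assay family — so
borderline p-values across many fractions should be treated cautiously.
Fraction concentrations (50 µg/mL default, lower for toxic fractions) are
carried as metadata; R deliberately applies no dose normalization, and an
explicit dose correction is left to the caller.

## Activity indexes

Normalization is per compound across fractions (column-stochastic),
exactly the printed-formula orientation; raw areas are used without log
transform. Compounds absent from every fraction are *excluded with a
warning* rather than scored 0, because 0 would masquerade as "neutral".
AI_j = Σ_i R_i·a_{i,j} is a weighted mean, hence bounded by [min R,
max R]; ranking is descending AI with ties broken lexicographically by
compound id for determinism. The bio-active map is the entrywise product
R_i·a_{i,j}, whose column sums reproduce the AIs. The dual-score plot
reuses the same AI machinery with the cell-protection rate as the
fraction coefficient on the x axis (protection, not survival, since it is
the model-referenced quantity; a caller can pass survival instead), and
the zebrafish AI on the y axis — the upper-right quadrant marks compounds
active in both assays. No significance is attached to AI values: no null
model is defined for them.

## Fraction-assay simulation

Inactive compounds draw independent log-normal areas (σ = 0.5) in every
fraction; each planted active has 90% of its total area concentrated in
its assigned fraction(s) (default: the single highest-R fraction), the
rest spread log-normally over the others. The default recovery profile
declines linearly from +75% to −25% over 10 fractions, mimicking a
separation where early fractions rescue and late ones depress the rate.
Under these conditions a single planted active among 71 compounds is
recovered in the AI top 3 in ≥ 95% of seeded runs. What this does *not*
establish: performance when actives are split across correlated
fractions, when the abundance matrix has fraction-level (row) effects, or
when recovery estimates are noisy at realistic group sizes — real
LC-MS integration noise is also not modelled (the peak-area matrix is an
input in practice).

## Demo screen and problem sizes

`run_demo_screen` chains every stage on synthetic data: 8 larvae per
group (the screen's n ≥ 8 floor), 100-frame 20 fps videos, 10 fractions,
a 71-compound matrix with one planted active, and a 6-well MTT plate per
fraction. Treated-group beat rates interpolate between the model and
control presets in proportion to the true recovery profile, with jitter
and drop probability damped by the same factor (rescue steadies the
rhythm), so the measured R_i track the profile the assay simulator used
to place actives. All randomness flows from one root seed through
`numpy.random.default_rng`, making repeated runs byte-identical; the run
manifest records the config, derived seeds, package version, and a
SHA-256 per output file. The test and acceptance workloads use these
sizes (and 20 replicates per cell in the rate-recovery sweep, 200 seeds
in the planted-active study) as a deliberate desk-scale choice: large
enough for the stated pass fractions to be meaningful, small enough to
run interactively.
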