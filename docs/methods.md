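# Methods

## Scope and model

`mdvflux` processes matrices of measured ion intensities — rows are
(analyte, nominal mass) pairs, columns are chromatograms — into corrected,
replicate-aggregated mass isotopomer distribution vectors (MDVs). The
measurement model for one fragment with `numC` backbone tracer atoms is

```
measured = P_alpha( C · [ (1−f)·x + f·e0 ] ) · scale · noise
```

where `x` is the true labeling distribution (length `numC+1`, simplex),
`e0` the point mass at M+0, `f` the unlabeled original-biomass (OBM)
fraction, `C` the natural-abundance (NA) correction matrix of the full
elemental formula, `P_alpha` the proton loss/gain operator moving a fraction
α of every species one mass unit, and `noise` multiplicative Gaussian
detector noise. Correction inverts these factors in the user-configured
order; the order `[proton, na, obm]` inverts the model exactly on noise-free
data (see "Correction order" below).

## Isotope tables

Per element only the mass shifts +0/+1/+2 are tracked; heavier isotopes are
truncated, the standard practice for MDV correction since multi-heavy-atom
probabilities at natural abundance are negligible at the precision of MS
intensities. Built-in heavy abundances (fraction per atom):

| element | +1 | +2 |
|---|---|---|
| C | 0.011 | — |
| H | 0.000115 | — |
| N | 0.00366 | — |
| O | 0.00038 (¹⁷O) | 0.002 (¹⁸O) |
| S | 0.0075 (³³S) | 0.042 (³⁴S) |
| Si | 0.047 (²⁹Si) | 0.031 (³⁰Si) |

The light isotope takes the remainder. ³³S is a judgment call (sources often
quote only ³⁴S); it can be zeroed — and any value replaced, e.g. ¹³C 1.07 % —
through the isotope-table override TSV (`element, shift, abundance`), because
small disagreements between published abundance sets are the dominant source
of inter-tool variation in corrected values.

## NA correction matrix

Column `j` of the `(numC+1)²` matrix is the NA mass-shift distribution of
the fragment formula with `j` tracer atoms removed from the tracer element's
count (those positions are occupied by tracer label and cannot also carry a
natural heavy isotope), shifted down by `j` rows and truncated at M+numC.
This position-dependent construction avoids double-counting label; the
cruder alternative (all tracer atoms always at natural abundance in every
column) is rejected for that reason. Column 0 therefore equals the NA
distribution of the full formula.

The solve uses non-negative least squares (`scipy.optimize.nnls`) rather
than matrix inversion: on noisy data plain inversion returns negative
fractions, while on noise-free data both coincide (asserted in the tests).
A condition number above 1e12 raises an error naming the fragment; with
realistic abundance tables the matrix is well-conditioned (triangular,
diagonal ≈ 0.8–1).

## Proton shift

The loss equations for a 2-carbon fragment with the M−1 boundary measured:

```
M−1_meas = (1−α)·M−1' + α·M0'
M0_meas  = (1−α)·M0'  + α·M1'
M1_meas  = (1−α)·M1'  + α·M2'
M2_meas  = (1−α)·M2'
```

Gain is the mirror image and requires the M+numC+1 boundary. Assuming the
true boundary signal M−1' is negligible, α is found by fixed-point
iteration: start at `boundary / adjacent-measured`, invert the triangular
system with the current α, update `α = boundary / adjacent-unshifted`, stop
when the change is below 1e-9 (cap 1000 iterations — the fixed point can be
only weakly attracting, with contraction factors around 0.9 observed on
plausible MDVs, so a small cap truncates convergent runs). Failures (no
convergence, α outside [0, 1), non-positive intermediates) leave the MDV
uncorrected, with a message in the run report.

**Known limitation — identifiability.** The system above (numC+2
measurements, numC+2 unknowns, boundary-true assumed 0) is nonlinear in α
and can admit several fully admissible solutions: two different (α, true
MDV) pairs, both with non-negative intensities and α in range, generate
byte-identical data. This happens for a few percent of random
(MDV, α ≤ 0.3) draws, typically when M+1 dominates M+0. No estimator can
resolve such cases from one MDV; the iteration converges to the smallest
root. In practice, corroborate α across fragments of the same analyte class
and treat outliers with suspicion.

## OBM correction and correction order

OBM subtraction computes `(mdv − f·na_dist)/(1−f)`, clamps negatives to
zero and renormalizes. The distribution `na_dist` used to spread the
unlabeled biomass over the masses depends on position in the correction
order: before NA correction it is the fragment's full-formula NA
distribution (truncated at M+numC); after NA correction it degenerates to a
point mass at M+0. Both orders are honored, but they are not equivalent:
the measurement window cuts NA shifts beyond M+numC, and heavily labeled
molecules lose more signal to that cut than unlabeled OBM does, so after
normalization the OBM admixture no longer equals `f` times the truncated NA
vector. With silylated fragments at f = 0.2 the order `[proton, obm, na]`
leaves residual errors of order 1e-2, whereas `[proton, na, obm]` is exact
(machine precision on noise-free data) because NA correction maps the OBM
admixture exactly onto `f·e0`. The exact order is the default in all
examples.

Every correction is followed by renormalization to the simplex. All three
corrections are scale-equivariant, so per-step normalization versus one
final scaling makes no difference to the result (asserted by a test);
boundary vectors are scaled by the same factor as the MDV so that the
boundary/adjacent ratios driving α survive normalization.

## Quality checks

* **Missing values:** empty or non-numeric cells. Non-numeric text (`n.d.`)
  counts as missing, never as zero.
* **Intensity bounds:** configurable `[min, max]` linear detector range,
  applied to every row including boundary masses.
* **Retention times:** per fragment row, mean and sample SD across all
  chromatograms; a cell is flagged when `|rt − mean| > k·SD` (default
  k = 3). The SD includes the candidate outlier, which caps the attainable
  z-score at `(n−1)/√n`; with fewer than ~12 chromatograms a k of 3 can
  never fire and a smaller k is appropriate. A pooled variant (one mean/SD
  over the whole table) is available via `rt_pooled = true` but mixes
  analytes with different retention times and is not the default.

Any flag terminates the run before correction unless forced; feedback is
written as a TSV mask with the input's layout so it can be overlaid in a
spreadsheet. Under `--force`, MDVs containing non-numeric cells are carried
through as NaN and reported, not guessed.

## Fragment assembly

Rows are grouped into runs of consecutive masses per analyte. A run is
matched to a library fragment by (analyte id, M+0 mass), taking the
configured leading/trailing boundary counts into account. A mass missing in
the middle of an MDV is never assumed zero: the fragment is marked
incomplete, excluded from correction and reported, and the orphaned trailing
rows are reported as unknown. Every input row ends up in an MDV, a boundary
vector, or a feedback message (property-tested).

## Replicate statistics and export

Replicates occupy consecutive columns in configuration order. Per group and
mass the arithmetic mean and sample (n−1) standard deviation of the
corrected fractions are computed; a single-replicate group reports the
default deviation 0.05 at every mass. Writers: 13CFLUX FTBL
`MASS_SPECTROMETRY` (columns META_NAME, FRAGMENT, WEIGHT, VALUE, DEVIATION;
tab-indented, continuation rows blank) and `LABEL_MEASUREMENTS` sections,
either standalone per group or injected at the end of an existing section of
a model file (all other lines preserved byte-for-byte); an OpenFLUX-style
CSV (`fragment,weight,mean,stdev`, fractions); and a human-readable summary
TSV in percent. The FTBL column layout is pinned by golden-file tests and
easy to adjust. Fractions (0–1) go to machine formats, percent only to
human-readable output.

## Simulator (the stated test world)

The default simulated experiment: 2 analytes / 3 silylated amino-acid
fragments, 6 chromatograms in two replicate groups of 3, proton loss
α = 0.05, OBM 20 %, intensity scale 1e6 ion counts, noise-free unless asked
(multiplicative Gaussian noise models detector behavior; 1 % is a realistic
setting). The benchmark-shaped variant generates 128 chromatograms, 65
fragments, 412 mass rows. Retention times are one base value per fragment
plus normal jitter — no drift model.

The simulator applies the proton shift to the full signal *including* the
OBM admixture, because every molecule in the ion source is equally likely
to lose or gain the proton; this also makes the forward model exactly
invertible by the `[proton, na, obm]` correction order. What a green
round-trip test establishes: the algebra of the three corrections and their
composition is inverted exactly on data generated by this model. What it
does not establish: robustness to real-world deviations — non-Gaussian
noise, baseline/integration errors, retention-time drift, isotopic impurity
of the tracer substrate, multi-proton artifacts — none of which the
generator emulates.

## Numerical choices

* NA solve: NNLS; condition-number guard 1e12.
* α iteration: tolerance 1e-9 on the α update, cap 1000 iterations,
  initial guess boundary/adjacent-measured.
* Negative intensities after proton or OBM inversion are clamped to zero
  before renormalization; an all-zero residual is an error, not a silent
  zero vector.
* Normalization rejects all-zero vectors.
* Masses are integer nominal m/z; cells are tab-separated, decimal point,
  empty cell = missing.
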