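# mdvflux

Preprocessing of stable-isotope-labeling mass-spectrometric data for
¹³C metabolic flux analysis (MFA): quality checks, isotope correction, and
export of corrected mass isotopomer distributions in the measurement formats
of downstream flux software (13CFLUX FTBL sections, OpenFLUX CSV).

## Who this is for

Labs running ¹³C (or other tracer) labeling experiments who extract per-mass
ion intensities from GC-MS/LC-MS chromatograms (with TagFinder, MZmine,
vendor software, ...) and need the tedious middle step automated: checking the
raw intensities, correcting them for everything that is *not* tracer label,
averaging replicates, and writing files MFA software can ingest.

## The data model and corrections

A fragment with `numC` backbone tracer atoms is measured at the nominal
masses M+0 … M+numC; the vector of those intensities is the **mass isotopomer
distribution vector (MDV)**. Optional boundary masses (M−n below, M+numC+n
above) ride along for quality control and proton-shift estimation. Measured
MDVs are biased by

1. **Natural abundance (NA).** Every atom of the full analyte formula —
   derivatization atoms such as Si included — carries heavy isotopes at
   natural abundance (¹³C 1.1 %, ²⁹Si 4.7 %, ³⁰Si 3.1 %, ...). The probability
   that N atoms with isotopes Iᵢ (per-atom probability p(Iᵢ), occurring f(Iᵢ)
   times) produce a given assignment is the multinomial term
   `N!·Π p(Iᵢ)^f(Iᵢ)/f(Iᵢ)!`; per element only the shifts +0/+1/+2 are kept.
   Convolving all atoms gives a lower-triangular correction matrix **C** with
   `C[i,j] = P(natural shift i−j | j tracer labels)`; the measured MDV is
   `C·x` and the true distribution `x` is recovered by a non-negative least
   squares solve.
2. **Proton loss/gain.** Ionization can move a fixed fraction α of every
   species one mass unit down (loss) or up (gain; the McLafferty ion of fatty
   acid methyl esters). α is estimated from the adjacent boundary mass by
   fixed-point iteration and the shift inverted.
3. **Original biomass (OBM).** Unlabeled biomass present before tracer
   feeding contributes a known fraction f of the signal, distributed as the
   fragment's NA pattern; it is subtracted and the remainder rescaled.

Corrections are applied per MDV, in the order listed in the configuration
file, each followed by renormalization to fractions summing to 1 (percent is
applied only in human-readable output). Average labeling
`Σᵢ i·mᵢ / (numC·Σᵢ mᵢ)` is reported per MDV / chromatogram / replicate group
as a contamination check. Replicate groups get per-mass means and sample
standard deviations; a single-replicate group reports the default deviation
0.05 so error-requiring flux software still runs.

## Worked example

Generate a small simulated experiment (2 analytes, 3 fragments, 6
chromatograms in two replicate groups, proton loss α = 0.05, 20 % OBM, 1 %
detector noise) and push it through the full pipeline:

```sh
mdvflux simulate --seed 42 --noise 0.01 --out demo
```

then point a configuration file `config.txt` at the simulated files. The OBM
table is written by hand (`chrom001<TAB>0.2`, one line per chromatogram), as
is the group-name list (`wildtype`, `mutant`, one per line):

```
data_file = demo/measurements.tsv
rt_file = demo/retention_times.tsv
obm_file = obm.tsv
group_names_file = names.txt
checks = missing, intensity, retention_time
intensity_min = 0
corrections = proton-loss, na, obm
leading_boundary = 1
replicate_groups = 3, 3
output_formats = tsv, ftbl_ms, openflux
```

```sh
mdvflux run --config config.txt --out out
```

The run prints the files it wrote and `out/replicate_summary.tsv` starts:

```
group      fragment  mass  mean_percent  deviation_percent  n
wildtype   Ala_m57   M+0   32.3621       0.4077             3
wildtype   Ala_m57   M+1   31.5773       0.4245             3
wildtype   Ala_m57   M+2   32.4655       0.1966             3
wildtype   Ala_m57   M+3   3.5952        0.1742             3
```

i.e. after removing natural abundance (the silylated alanine fragment carries
11 C, 2 Si, ...), the proton-loss artifact and the 20 % unlabeled biomass,
32.36 % of the alanine is unlabeled, 31.58 % singly labeled, and so on — the
generating ground truth was (32.47, 31.55, 32.20, 3.78) %, recovered to
within the 1 % noise. The matching FTBL measurement section
(`out/wildtype_ms.ftbl`) is ready to paste into a 13CFLUX model:

```
MASS_SPECTROMETRY
	META_NAME	FRAGMENT	WEIGHT	VALUE	DEVIATION
	Ala	1,2,3	0	0.323621	0.004077
		 	1	0.315773	0.004245
```

Any flagged cell in the pre-correction checks (missing values, detector
range, retention-time outliers) terminates the run before correction and
writes a feedback mask TSV that overlays the input layout; `--force`
overrides.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch:
it simulates a full-scale dataset (128 chromatograms, 65 fragments, 412 mass
rows), runs checks, natural-abundance correction, the labeling summary,
replicate statistics and all export writers, and writes the results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
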