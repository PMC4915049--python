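# scml — spike-in calibration of amplicon counts to microbial load

16S rRNA gene profiling yields *relative* abundances: each specimen's reads
are a compositional snapshot, blind to how much bacterial material the
specimen actually contained. When total microbial load varies — antibiotic
treatment, disease, dilution — relative shifts can invert the true
direction of change: an OTU at 5 % of a load-rich community may hold twice
as many bacteria as the same OTU at 10 % of a depleted one.

`scml` implements **spike-in-based calibration to microbial load (SCML)**:
exogenous bacteria (*Salinibacter ruber*, *Rhizobium radiobacter*,
*Alicyclobacillus acidiphilus* — absent from mammalian gut communities,
with 1, 4 and 6 16S copies per genome) are added to crude specimens at
known 16S rDNA copy numbers before lysis. Let s̄ be the mean read count of
the reference spike over all samples; each sample *i* is rescaled by a size
factor

```
s_i = s̄ / (reference spike count in sample i)
```

so the spike-in count equals s̄ everywhere. After calibration, the ratio of
the same taxon between two samples estimates the ratio of its *absolute*
abundance — species-specific read yields cancel within a taxon. Ratios
*between* taxa remain uncalibrated. A combined mode adjusts each
non-reference spike's counts by its designed concentration difference to
the reference, sums all spikes into one artificial entity and calibrates
to that sum, which damps spike-count noise.

The package also provides the surrounding machinery to *validate* such an
experiment: design-expected log2 ratios from a dilution/spike design table,
all-pairs observed log2 ratios under four normalizations (relative
abundance, qPCR total-16S scaling, single- and combined-spike SCML),
per-method error summaries, and a synthetic dilution-experiment generator
with known ground truth.

## Worked example

Simulate a spiked dilution series (6 two-fold dilution levels × 6
replicates, 3 spikes, 40 background taxa, ~20 000 reads/sample) and
benchmark every normalization against the design:

```bash
scml demo --seed 1 --out demo/
```

prints

```
Validation of calibration methods against the design
====================================================
samples: 36   background taxa: 40   spikes: 3 (reference S.ruber)

basis                  method          n_pairs      bias  variance  pearson_r
----------------------------------------------------------------------------
background-dilution    relative          49532    -0.000     3.945      0.585
background-dilution    qpcr              49532     0.000     3.002      0.814
background-dilution    scml-single       49532    -0.000     1.989      0.889
background-dilution    scml-combined     49532    -0.000     1.472      0.911
spike-concentration    relative           2520     0.000     4.574      0.743
spike-concentration    qpcr               2520     0.000     3.405      0.790
spike-concentration    scml-single        2520     0.000     1.963      0.861
spike-concentration    scml-combined      2520    -0.000     1.080      0.916
```

Each row summarizes the error (observed − expected log2 ratio) over all
ordered sample pairs: `background-dilution` rows compare background taxa
against the load ratios implied by the dilution factors; the
`spike-concentration` rows compare the two variable spikes against their
designed copy ratios. Relative abundances cannot see load changes (largest
error variance, weakest correlation); qPCR total-copy scaling helps but
carries quantification noise; calibrating to the reference spike roughly
halves the error variance, and combining all three spikes reduces it
further — the ranking the method predicts.

From Python, the same analysis in the model/results style:

```python
from scml import SimulationParams, simulate_experiment, SpikeCalibration
from scml.validation import ValidationExperiment

counts, design, qpcr, truth = simulate_experiment(SimulationParams(seed=1))

res = SpikeCalibration(counts, design, mode="single", reference="S.ruber").fit()
res.factors            # per-sample size factors s_i
res.calibrated.values  # SCML-calibrated table (reference row == s_bar)

val = ValidationExperiment(counts, design, qpcr).fit()
print(val.summary())
val.error_variances()  # per-method background error variance
```

Real data enters through plain TSV tables: a count table (taxa as rows,
classic `#OTU ID` dialect accepted), a design table
(`sample_id, dilution_factor, <species...>` with designed 16S copies), an
optional qPCR table (`sample_id, total_copies`), and a
`species → taxon_id` spike map. See `scml --help` for the `calibrate`,
`relabund`, `qpcr-calibrate`, `ratios` and `validate` subcommands.

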