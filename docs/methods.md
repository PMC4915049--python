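# Methods

## The calibration model

A 16S amplicon library is a multinomial draw from the lysed, amplified
pool: the count of taxon *t* in sample *i* is, in expectation,

```
count(i,t) ≈ N_i · y_t · c_t(i) / Σ_t' y_t' · c_t'(i)
```

where `N_i` is the library size, `c_t(i)` the absolute 16S rDNA copies of
taxon *t* in the specimen and `y_t` a species-specific *read yield*
(lysis × PCR × sequencing efficiency per copy). Neither `N_i` nor the
denominator is biologically meaningful, so raw counts and relative
abundances only identify composition.

Adding a reference spike at known copies `c_ref` in every sample provides
an internal scale. SCML rescales sample *i* by
`s_i = s̄ / count(i, ref)` with `s̄` the across-sample mean of the
reference-spike count (the anchor; any positive constant gives the same
ratios, the mean keeps calibrated values on a read-count-like scale).
Substituting the model, the calibrated value of taxon *t* is
`s̄ · (y_t / y_ref) · c_t(i) / c_ref(i)`: between-sample ratios of the same
taxon estimate absolute-abundance ratios exactly — the yields cancel —
while between-taxon ratios retain the unknown factor `y_t / y_t'` and are
*not* calibrated. This is calibration of ratios, not absolute
quantification: unit-bearing quantities (bacteria per gram) remain out of
reach because yields and copy numbers per genome vary across species.

**Combined mode.** Each non-reference spike *j* is first adjusted for its
designed concentration difference to the reference,
`adjusted(i,j) = count(i,j) · c_ref(i)/c_j(i)` (a spike added at half the
reference concentration has its counts doubled), then all spikes are
summed into one artificial entity and that sum is calibrated to its mean
exactly like a single spike. Averaging over spikes damps the
spike-count noise that the size factor propagates into every taxon. When
all spikes are added at sample-constant equal concentrations the
adjustment is the identity and can be skipped.

**qPCR total-copy scaling.** The comparison method measures each sample's
total 16S copies `T_i` by qPCR and puts read fractions on the copy scale:
`value(i,t) = count(i,t)/N_i · T_i`, so each sample's values sum to its
measured total. Counts are compositional — a library carries no scale —
so the external total must multiply the read *fractions*; scaling raw
counts by a total-copy factor directly would compound the library-size
arbitrariness with the load and invert the signal. Between-sample ratios
become (relative ratio) × `T_a/T_b`.

**Zero handling.** A zero reference-spike count is a hard error: such a
sample carries no load information (`--drop-uncalibratable` excludes it
instead). In ratio estimation, records where either value is zero are
dropped by default; a `--pseudocount` is available for exploration.
Calibrated values are kept real-valued — downstream use is log-ratio
estimation, so re-rounding would only discard information.

## Validation against a dilution/spike design

A validation experiment controls truth at two levels: background taxa
change only through the dilution factor (expected log2 ratio between
samples *a, b* is `log2(load_a/load_b)` with load = 1/dilution factor),
and each variable spike changes only through its designed copies
(expected ratio `log2(c_a/c_b)`). For every taxon, ordered sample pair and
normalization method we record `observed_log2 − expected_log2` and
summarize per method: mean error (bias), sample variance (n−1
denominator), and the Pearson correlation of expected vs observed pooled
across taxa. Ordered pairs are materialized in both directions —
antisymmetry makes this redundant but keeps `n_pairs` interpretable and
the signed mean trivially near zero; the variance is unaffected. When the
expected values in a group are constant the correlation is undefined and
reported as not applicable.

Expected background loads are framed purely by the dilution factor and the
designed copies; the small volume change from adding the spike suspension
is ignored, as are bench-level pipetting plans (only the cells ↔ OD600 ↔
16S-copies conversions are provided, with the panel constants 1/4/6
copies per genome and 4.6e9/1.4e9/1.2e9 cells·ml⁻¹·OD600⁻¹).

## The synthetic generator

`simulate_experiment` emulates an OTU table downstream of closed-reference
picking for a spiked dilution series; it is the package's test bed, not a
read-level simulator (no FASTQ, chimeras or homopolymer errors, and no
taxonomic realism in the background community).

Defaults (one choice each, made on first principles and kept):

| parameter | default | rationale |
| --- | --- | --- |
| background taxa | 40 | desk-scale community; enough taxa for stable pooled summaries |
| base abundances | lognormal, median 1e8 copies, σ=1.5 | right-skewed communities typical of stool |
| dilution ladder | 1,2,4,8,16,32 × 6 replicates | 36 samples; two-fold steps span a 32-fold load range |
| reference spike | S. ruber, 3.0e8 copies, constant | measures load in every sample |
| variable spikes | R. radiobacter 1.0e8, A. acidiphilus 5.0e7, opposing 2-fold ladders ×1/8…×4 over replicates | within-species expected ratios span ±5 log2 units; totals stay a few percent of the undiluted background so the spikes remain a minor constituent of the specimen (an external total-copy measurement must track the background, and the design expectations ignore spike mass) |
| read yields | background 1.0; S. ruber 1.5; R. radiobacter 0.8; A. acidiphilus 0.4 | species-specific yields differing several-fold, reference highest |
| library size | lognormal, median 2e4 reads, σ=0.25 | pyrosequencing-era depths |
| overdispersion | 0.2 (gamma weights, Dirichlet-multinomial-like) | biological/technical extra-multinomial noise; 0 gives pure multinomial |
| qPCR noise | lognormal, σ=0.7 | a ~2-fold typical quantification error for universal-primer total-16S assays; reproduces the observed spacing between qPCR scaling and SCML |

The designed copies in the default table are illustrative — a plausible
design of this shape, not a reconstruction of any particular experiment.

Generation: background copies are drawn once and scaled per dilution
level (`GroundTruth` records them); read probabilities are
`yield × copies`, optionally perturbed per (taxon, sample) by unit-mean
gamma weights of variance `overdispersion`; counts are multinomial at a
lognormal library size; qPCR totals are the true totals under independent
lognormal noise. RNG streams are spawned per component (abundances,
depths, counts, qPCR) from one seed, so turning one noise source on or off
leaves the others' draws unchanged, and a fixed seed reproduces every
table byte for byte. The `expected=True` mode replaces all sampling by
expectations (real-valued counts, exact totals), which makes the
calibration identities hold to machine precision and anchors the exact
tests.

What passing on synthetic data does and does not show: the generator
realizes exactly the mechanism SCML assumes (a common multinomial channel
with per-species yields), so it validates the estimator's algebra, its
noise propagation and the relative ranking of normalizations — not
robustness to phenomena it omits (taxon-specific PCR interactions,
chimeras, OTU-picking artifacts, spike reads bleeding across OTUs).

## Numerical conventions

- Size factors and calibrated values are exact floating-point ratios; the
  reference-spike fixed point holds to ≲1e−15 relative and is asserted at
  1e−9.
- Sample variance uses ddof=1 throughout; Pearson correlations come from
  `scipy.stats.pearsonr` on the pooled (expected, observed) pairs.
- Reports serialize floats with 10 significant digits and a fixed row
  order (taxon, sample pair, method), making repeated runs byte-identical;
  design/qPCR tables therefore round-trip to 1e−9 relative, count tables
  exactly.
- The classic `#OTU ID` header dialect is detected by the first header
  cell only; spike roles always come from an explicit species → taxon map,
  never from taxonomy strings.

## Problem sizes

The shipped validation and the reproduction script use the default
36-sample × 43-taxon design, ~50 000 background pairs per method, and 25
replicate experiments for the ordering fraction — sizes at which the
pooled summaries are stable (the ordering held in 25/25 replicates at the
development seeds) and a full run completes in seconds.

## Known limitations

- Inter-species ratios are intentionally left uncalibrated; no attempt is
  made to estimate or correct per-species yields.
- Absolute quantification (copies per gram) is out of scope by design.
- The qPCR comparison assumes the measured total covers the same material
  the reads come from; systematic primer-coverage bias is not modelled.
- BIOM/HDF5, FASTQ and taxonomy parsing are out of scope; inputs are
  plain TSV.
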