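# Methods

## Measurement model

A multiplex amplicon kit quantifies each locus as a fluorescence peak area
after capillary electrophoresis. Demultiplexing is purely length-keyed: every
amplicon has a unique designed fragment length, and a sized peak is assigned
to the amplicon whose expected length is nearest within the panel's
`length_tolerance` (default 0.5 bp — since lengths are unique by design and
spaced by several bp, the nearest match within half a base pair is
unambiguous). When two peaks of one sample map to the same amplicon the
larger area is kept: the dominant peak is the amplicon product, minor peaks
are stutter. Failed amplicons are *absent* from a sample's area map rather
than zero; a zero would silently destroy the downstream ratios, whereas an
absent value propagates as "no data".

## Dosage quotients

The copy-number signal is the double ratio

    DQ = [TarA(s)/RefA(s)] / [TarA(ctr)/RefA(ctr)]

which cancels both per-amplicon efficiency (constant across samples of a run)
and per-sample input amount, leaving DQ = copies/2 in the noise-free limit.
The final DQ of a target is the arithmetic mean over the full Cartesian
product of reference amplicons × control samples, with the sample standard
deviation (n−1; defined as 0 for a single combination) as a stability
measure. Combinations with a missing or non-positive area are excluded, not
imputed — imputation would fabricate signal. Averaging over the flat
Cartesian product rather than nested means (references first, controls
second) is a deliberate choice; the two coincide exactly when no combination
is missing, and the flat mean weights every valid measurement equally when
some are.

Two controls per experiment is the default for MAQ-style runs and three for
MLPA-style runs, but the engine accepts any N ≥ 1. Kits are analyzed
independently and DQs are never pooled across kits before scoring; in
particular the MYCN kit is separate because high-level amplification
interferes with co-amplified targets in the same multiplex reaction.

## Scoring rules

All "at least" thresholds are inclusive; "more than 75%" and "more than
half" are strict. Numeric choices per clause:

* **Segmental (consecutive clause).** ≥ 2 adjacent loci, position-sorted
  within one arm region, all deviating by ≥ 0.2 (MAQ) or ≥ 0.25 (MLPA) in
  the *same* direction. A no-data locus breaks adjacency (conservative: no
  call bridges a failed amplicon), as does a direction flip. The scan is
  positional — the first completed run along the arm determines the call —
  which matters only in the pathological case of a loss run and a gain run
  in one region. Fewer than 2 numeric loci → no_data.
* **Segmental (fraction clause, MLPA only).** More than 75% of the region's
  numeric loci deviating ≥ 0.15 in the same direction. Applied per arm
  region (not per chromosome); with typical 4–6-locus regions the per-arm
  reading is the stricter and more local one.
* **Whole-chromosome.** ≥ 75% of the p-arm DQs *and* ≥ 75% of the q-arm DQs
  on the same side of 1, and more than half of the union of both arms' DQs
  deviating by ≥ 0.1. The majority clause is applied jointly to both arms.
  Evaluated only when the sample has no segmental call anywhere (global
  segmental precedence: the clinically decisive question is whether any
  segmental aberration exists).
* **MYCN.** Amplified when all designated MYCN loci (3 under MAQ rules, 2
  under MLPA rules) reach DQ ≥ 1 + 3 = 4.0 — "increase by at least 3" read
  relative to the normal baseline of 1. The alternative reading DQ ≥ 3.0 is
  available by overriding `mycn_delta` in a rule-set YAML. MYCN status is
  scored independently of the sample category, and when amplified the MYCN
  loci are excluded from chromosome-2 whole-chromosome evaluation, where
  they would trivially mimic a gain and mask the ploidy assessment.

Rule sets are plain frozen dataclasses serializable to YAML; the two
published presets are bundled and any threshold can be overridden.

## Evaluation

Calls are binarized against the gold standard direction-specifically: loss
for 1p/3p/11q, gain for 17q, amplification for MYCN, either direction for
whole chromosomes. No-data on either side excludes the pair. Ratios with a
zero denominator are reported as not-available, never as 0 or 100.

Two AUCs are exposed. `binary_auc` is the two-point ROC through the single
operating point of a rule-based caller, (sensitivity + specificity)/2.
`continuous_auc` sweeps a threshold over a per-region score — the maximum DQ
deviation toward the region's expected direction — and equals the
Mann-Whitney pairwise probability (ties at half weight); it is computed via
scikit-learn and cross-checked in the tests against a brute-force pairwise
oracle. Macro-average AUC is the unweighted mean over regions; pooled
false-positive/negative rates sum confusion counts over all evaluable
(sample, region) pairs.

Repeatability follows Bland-Altman: for paired replicate DQs the bias (mean
difference) and limits of agreement (1.96 × SD of differences) are reported
separately, plus a single coefficient of repeatability |bias| + 1.96·SD,
because the single-number phrasing common in assay validation conflates the
two. Comparisons against scoring thresholds use the 1.96·SD component.

## Synthetic cohorts

The generator produces peak tables, a sample sheet and a gold-standard table
for the three bundled kits. Its defaults mirror a realistic validation
series: 35 segmental tumors (15 of them on a near-triploid background, 22
MYCN-amplified with 15–40 copies), 17 numerical-only near-triploid tumors,
two diploid controls. Segmental samples draw events from {1p −1, 3p −1,
11q −1, 17q +1} with frequencies 0.5/0.35/0.45/0.7 (redrawn until at least
one event is present), roughly the relative frequencies seen in unfavorable
neuroblastoma.

Peak areas follow

    area = baseline × efficiency(amplicon) × (copies/2) × exp(N(0, σ²))

with lognormal multiplicative noise (areas are positive and errors scale
with signal) at σ = 0.05 by default — chosen so the per-locus DQ scatter
(≈ 0.06 SD, ≈ 0.12 at 1.96 SD) stays within the repeatability coefficient a
well-run assay achieves (~0.1). Per-amplicon efficiencies are drawn once per
run and held constant across samples, so they cancel in the DQ exactly as
the double ratio intends; run-to-run drift can be probed by drawing fresh
efficiencies.

**Near-triploid masking.** Numerical-only samples are simulated as uniformly
near-triploid: every chromosome, including the four reference chromosomes,
sits at the modal ploidy of 3. The double ratio then cancels the shared
ploidy and every DQ is centred on 1 — the co-aberrant-reference confound
that makes whole-chromosome changes intrinsically hard for ratio-normalized
panel assays. This is a deliberate modelling choice, not a limitation of the
scorer: with exact area ∝ copies proportionality and integer copy states, a
whole-chromosome change that deviates from the modal ploidy produces DQ
ratios of 4/3 or 2/3, which land beyond the segmental windows (the 0.8–1.2
window spans exactly a 3/2 ratio), so any "detectable" numerical event would
be indistinguishable from a segmental one. Real near-triploid profiles sit
in the compressed, mostly-masked regime, and the simulator reproduces that
regime. Consequently the default numerical cohort tests the specificity
claim that matters clinically — no false segmental calls in numerical
tumors — while the whole-chromosome scoring path itself is exercised by
direct DQ-profile unit tests (e.g. chromosomes 1/2/17 at 1.15 and 3/11 at
0.85). Gold entries for the numerical samples record deviations from the
modal ploidy and are therefore negative; the generator does not model tumor
cell-content dilution, intra-tumor heterogeneity or electrophoretic stutter.

What passing simulation tests therefore show: the caller is exact under the
stated measurement model and robust at realistic noise. What they do not
show: performance on partially masked real profiles with intermediate DNA
indices, contaminating normal cells, or PCR ratio compression.

## Numerical and testing choices

* Oracle equivalence of the DQ engine is checked on 1,000 random instances
  (1–9 references, 1–3 controls, 15% missing areas) against a plain double
  loop; agreement is required to < 1e−12 (observed: exact).
* The scoring engine is scanned against a word-for-word transcription of the
  rule text over the DQ grid {0.70, 0.75, 0.78, 0.80, 0.85, 1.0, 1.15, 1.2,
  1.25, 1.3}: exhaustively for 2–4 loci (11,100 combinations) plus a seeded
  uniform sample of 6,000 combinations of 5–8 loci, for both rule sets
  (34,200 checks in total) — sizes chosen to keep the scan well under a
  minute while covering every boundary value on both sides.
* The default simulated cohort is run at its natural size (52 samples, 3
  kits, ~2,800 peaks); the whole suite runs in a few seconds.
* Determinism: all randomness flows from one integer seed through numpy's
  `default_rng`; cohort outputs are byte-identical across reruns, and every
  emitted file carries the seed in a header comment or manifest.

## Known limitations

* The whole-chromosome majority clause is arm-joint and the MLPA fraction
  clause arm-local; both are documented readings of ambiguous prose, and
  both are configurable only by editing the scorer, not the rule YAML.
* Confidence intervals for AUC are not implemented.
* Ploidy estimation, breakpoint localization within an arm, and calling
  outside the panel are out of scope.
* The simulator's integer copy states cannot produce the partially
  compressed near-triploid profiles discussed above; users who need them
  should feed measured DQ tables directly into the scorer.
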