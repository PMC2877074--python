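# Methods

## The screening problem

`dpnscreen` implements a coherence-based screen for differential gene
expression in a two-genotype developmental time course measured on bead
arrays, one chip per (tissue, genotype, postnatal day) with no chip
replicates. The reference design has eight time-points (P20, P24, P28,
P32, P36, P40, P48, P56) in two tissues (DRG and sciatic nerve
endoneurium) for a diabetic mutant (*Ins2*^Akita/+^, "Akita") against
wild-type littermates. Without replicates, per-time-point test statistics
are unavailable; the screen instead demands *temporal coherence*: a real
genotype effect should persist across neighbouring, closely spaced
time-points, while hybridization noise — especially on weakly expressed
probes — produces "zigzagging" single-time-point excursions.

## Pipeline

1. **Chip QC.** Per-chip mean intensity and fraction of present calls are
   summarized; chips are clustered by average-linkage hierarchical
   clustering on `1 − Pearson(log2(raw + 1))` and the tree is cut into as
   many clusters as tissues. A chip whose cluster's majority tissue
   differs from its manifest tissue is flagged and excluded (the
   mislabeled/swapped-chip scenario). A tissue vote that ties flags every
   member of the cluster — never a silent pass. Constant chips, whose
   correlation is undefined, are flagged as degenerate (log-intensity
   standard deviation < 1e−12) and left out of the clustering. Manual
   exclusion lists are honored in addition.
2. **Per-tissue normalization.** Quantile normalization applied within
   each tissue only (chips of a tissue end with identical value
   multisets; ranks are resolved by stable sort). The scanner software's
   proprietary cubic-spline option is a rank-based distribution-matching
   procedure of the same family; quantile normalization is the
   reproducible stand-in and is cross-checked against
   `limma::normalizeBetweenArrays` in the test suite. `none` disables
   normalization for raw-scale replication runs. A single-chip tissue is
   passed through with a warning.
3. **Detection filter.** A probe is retained only if some genotype's call
   series contains at least `min_present_run = 2` consecutive "present"
   calls; "marginal" never counts as present. By default a qualifying run
   in *either* genotype retains the probe (`present_rule="either"`, the
   most inclusive reading of "eliminate single-stage artifacts");
   `"both"` is available. A QC-masked day breaks a presence run
   (`mask_rule="break"`, conservative: no call evidence exists there);
   `"bridge"` treats the flanking days as adjacent.
4. **Fold-change windows.** Intensities below the floor (10 raw units,
   the absent-call level) are raised to it, then the per-day genotype
   ratio r_t = Akita/WT is formed. A probe is **accepted** iff
   - exactly one maximal direction-uniform run of time-points exceeds
     the fold threshold (`r > f` or `r < 1/f`, strict),
   - the run has ≥ `min_run = 2` unmasked time-points, and
   - every unmasked out-of-run ratio lies strictly inside the open
     escape band `(1/1.5, 1.5)`.
   With the lenient setting (f = 1.5, escape = 1.5) this reduces to: the
   out-of-band time-points form a single contiguous direction-uniform
   block of length ≥ 2. The stringent setting is f = 3 with the escape
   band unchanged. The down threshold is the exact reciprocal `1/f`, not
   a rounded display value such as 0.66 (`down_threshold` overrides it
   for bit-faithful replication attempts). Masked days break runs and are
   exempt from the escape constraint — the only reading under which a
   tissue with an eliminated chip can still yield acceptances.
5. **Low-expressor classification.** An accepted probe whose median raw
   intensity across the tissue's retained chips is strictly below 100 is
   flagged as a low expressor (mean available via config); such probes
   pass the filter but are known to be unreliable.
6. **Reporting.** The run-length summary counts accepted probes with run
   length ≥ k for k ∈ {2..6} (cumulative, so the k = 2 row contains every
   accepted probe; an exact-length mode exists). Candidate-gene panel
   profiles divide each probe's intensities by its median over the
   tissue's retained chips and report whether any probe of a panel gene
   passes the lenient filter.

### Numerical choices

Exceedance is strict and the escape band open: boundary-exact ratios are
measure-zero in floating data, and the open band makes "exceeds the
threshold" and "escapes the band" complementary at f = escape. Two
disjoint qualifying runs reject the probe (the escape constraint forbids
any exceedance outside "the" window). A contiguous exceedance block that
mixes directions is treated as two runs and hence rejected. Probe order,
result order (run length descending, then probe id) and the clustering
are deterministic; the pipeline is bit-identical under re-run, and
outlier flagging is invariant under chip permutation (tested).

The window classifier is verified against `brute_force_oracle`, an
independent literal enumeration of every contiguous window checking all
three clauses, on > 10,000 random ratio series (lengths 4–12, masked and
unmasked, both threshold settings) with ratios concentrated near the
decision boundaries.

## Synthetic data generator

The generator emulates the screen's data regime, not its biology: probe
classes `stable`, `developmental_trend` (smooth shared trend, ratio 1),
`planted_window` (ratio equal to the planted fold over a contiguous
window, 1 elsewhere), `zigzag_low` (low expressor with sign-alternating
ratios) and `absent` (called absent at all but ≤ 1 time-point). Default
class fractions are 0.55/0.15/0.05/0.10/0.15; planted folds default to
2.0 and 1.8 over runs of 2–4.

Intensities are log-uniform per-probe baselines with bounded per-tissue
log factors in [0.5, 2], multiplicative log-normal measurement noise of
coefficient of variation `noise_cv` (default 0.1) per chip measurement,
and per-chip log-normal scale factors (`chip_scale_spread`, default
0.05). Present-class values are clipped to the stated intensity range
(10–40,000). The baseline windows per class are chosen so that **at zero
noise no clipping or flooring can distort a planted ratio**: present
baselines sit in [210, high/(2.2·max fold)], making zero-noise recovery
an exact identity (precision = recall = 1, tested). Zigzag baselines sit
just under the low-expressor cutoff; their down-excursions may hit the
intensity floor, which only flattens them into the escape band — the
remaining alternating up-excursions still reject the probe. Detection
calls are gated directly on the true noise-free level (absent < 10,
marginal < 20) because the scanner's detection p-values are not
specified; the paper-facing behaviour (absent probes eliminated, low
expressors retained) is what matters. The optional outlier chip is
redrawn using another tissue's probe factors — a tissue swap — so the
clustering QC must find exactly it.

What the generator does *not* emulate: bead-level replicates and their
summarization, spatial artefacts, intensity-dependent (heteroskedastic
beyond log-normal) noise, probe cross-hybridization, and real covariance
between neighbouring time-points. Passing recovery tests therefore
demonstrates correctness of the *selection logic* under the stated noise
model, not performance on real arrays.

### Noise and the recall bound

With independent CV-0.1 log-normal noise on each genotype's chip, the
log-ratio has standard deviation √(2·ln 1.01) ≈ 0.141. For a planted
fold of 2.0 against the 1.5 threshold, each in-window point exceeds with
probability ≈ 0.979 and each of the out-of-window points stays in the
escape band with probability ≈ 0.996, giving an expected per-probe
acceptance of ≈ 0.94 for a run-2 window (measured: ≈ 0.95 over 600
planted probes × 20 replicates). The recovery test therefore asserts
recall ≥ 0.90, the analytic expectation with sampling margin; a bound of
0.95 would presume noise on the ratio itself rather than on the two
measurements that form it.

## Problem sizes

Tests and the acceptance script use 100–400 probes per dataset, 32 chips
(2 tissues × 2 genotypes × 8 days), ~10,000 series for oracle
equivalence and 20 replicates for the noisy-recall estimate — sizes at
which every stage's behaviour is exact or statistically stable while the
whole suite runs in well under a minute. The pipeline itself is
vectorized over probes and handles full-platform matrices (~48k probes)
without modification.

## Known limitations

- The clustering QC reproduces the *decision* (a swapped chip is
  eliminated), not any particular scanner/analysis software's dendrogram;
  metric and linkage are configurable.
- Detection calls are taken as input for real data; the package never
  recomputes them from intensities.
- Whether published elimination counts used the either- or both-genotype
  presence rule, and whether a masked day was bridged, is not derivable
  from the screen's description; both behaviours are implemented as
  config switches so either convention can be replicated.
- No statistical significance is attached to accepted probes — the
  screen is a coherence filter, and its published validation (qPCR)
  suggests the lenient 1.5-fold setting is enriched for false positives
  among low expressors. The low-expressor flag exists to make that
  caveat visible in the output.
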