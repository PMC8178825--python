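# Methods

## Model

The haploidy metric treats the per-base read-depth histogram of an
assembly as a mixture of up to three coverage components:

- **collapsed** bases, represented once in the assembly, receive reads
  from both haplotypes and sit near the full sequencing depth;
- **uncollapsed** bases, where the two haplotypes were assembled
  separately, split their reads between the two copies and sit near half
  depth;
- **contaminant** bases (co-sequenced foreign organisms) form a
  low-coverage mode.

The method is nonparametric: no mixture model is fitted. The histogram is
filtered and smoothed, its modes are found as local maxima, the coverage
axis is partitioned into one region per mode, and the base counts of the
raw histogram within each region give the component areas. With `C` the
collapsed area and `U` the uncollapsed area (both in bases),

    haploidy = C / (C + U/2).

A perfectly collapsed assembly of `C + U/2` bases would contain all of `C`
and half of `U`, so the score is the properly collapsed fraction of that
ideal. It is 1.0 with no uncollapsed peak, 0.0 with no collapsed peak,
invariant to uniform scaling of the histogram and to contaminant area, and
strictly monotonic in both `C` and `U`. Hemizygous deletions and haploid
chromosomes (e.g. a Y chromosome) genuinely produce half-coverage signal,
so a perfect score is not always attainable; no correction is attempted.

## Pipeline stages and parameters

1. **Tail filter** (`quantile`, default 0.99). Scanning coverage bins in
   ascending order, bins are kept until the cumulative base count first
   reaches `quantile` × total; strictly higher bins are dropped. This
   removes sparse repeat-driven high-coverage bins that otherwise seed
   spurious peaks. The bin at which the threshold is crossed is kept, so
   at least 99% of the base mass always survives and the filter is
   idempotent.
2. **Smoothing** (`window_length` 41 bins, `poly_degree` 3). The histogram
   is densified over 0..max retained coverage (absent bins = 0), because
   the Savitzky–Golay filter assumes equally spaced samples, then
   smoothed. The filter reproduces polynomials up to the chosen degree
   exactly, preserving peak positions and shapes. If the dense curve is
   shorter than the window, the window shrinks to the largest odd integer
   ≤ the length (degree reduced below it if needed) instead of failing.
   Negative filtered values are clamped to 0.
3. **Peak detection** (`min_height_frac` and `min_prominence_frac`, both
   0.05; relative to the curve's global maximum so the defaults are
   scale-free). A peak is a strict local maximum — a sample whose
   neighbours are smaller; plateau maxima report the plateau midpoint
   (rounded down). Minor maxima are rejected by the height and prominence
   thresholds, prominence being the height above the lowest contour line
   connecting the peak to higher terrain or the array edge.
4. **Width measurement** (`rel_height` 0.5). Each peak's width interval is
   the pair of x positions where the curve crosses
   `height − rel_height × prominence` on either side, linearly
   interpolated between samples and clipped to the curve domain.
5. **Region attribution.** The retained coverage axis is partitioned: the
   boundary between consecutive peaks is the midpoint of the gap between
   the left peak's right width-edge and the right peak's left width-edge;
   when the width intervals overlap, it falls back to the coverage of the
   minimum of the smoothed curve between the two modes (lowest coverage on
   ties). The first region starts at the lowest retained bin, the last
   ends at the highest, so regions are disjoint, contiguous, and their
   areas — sums of the **raw** tail-filtered counts, since areas are base
   counts — always total exactly the filtered histogram mass.
6. **Classification** (`contaminant_max`, `uncollapsed_max`, no defaults).
   Each peak is labeled purely by its mode position against the two
   user-supplied coverage limits (boundary positions belong to the lower
   range). Limits are a user decision because they depend on the
   sequencing depth of the dataset; `suggest_limits` proposes values from
   the curve minima between the detected peaks as a starting point. If
   several peaks share a label their areas are merged (conserving bases)
   with a warning; an advisory warning also flags an "uncollapsed" peak
   whose position is not within 0.35–0.65 of the collapsed mode.

Depth-0 positions are excluded from the histogram by default: they are
unmapped or uncalled bases and would create a spurious low-coverage mode
(`include_zero` keeps them). When no peak lands in either the collapsed or
the uncollapsed range the score is undefined; the library reports this as
a `None` result with an explanatory warning and the CLI exits non-zero
while still writing the report.

## Scorecard

Four per-assembly scores, each on a 0–1 scale:

- **size** `S = 1 − |s − G| / G`, with `s` the assembly size and `G` the
  estimated haploid genome size (default 102 Mb, the genome the metric was
  developed on). Raw values can be negative (s > 2G); the display value is
  clamped to [0, 1] and the raw value kept alongside.
- **N50**: the length of the largest contig for which contigs of equal or
  greater length contain at least half the assembly size (a cumulative sum
  reaching exactly half counts). Reported raw; optionally min–max
  normalized like the other metrics so it fits a 0–1 scorecard axis.
- **completeness** `Comp = (B_norm + K_norm)/2`, where `B_norm` is the
  single-copy BUSCO count and `K_norm` the k-mer score
  `K = 1 − |k_obs − k_exp| / k_exp` (`k_exp` = 50%), each min–max
  normalized as `(x − x_min)/(x_max − x_min)` over a user-declared
  comparison set of assemblies. Completeness is therefore a within-set
  ranking; on an all-equal set the normalization returns 1.0 with a
  warning rather than dividing by zero. BUSCO and KAT are run externally;
  their outputs enter as scalars.
- **haploidy**, from the pipeline above.

## Synthetic data generator

`simulate_depths` emulates the three-component structure directly: each
position is assigned a component by a multinomial draw over the base
fractions, and its depth is drawn from a negative binomial with the
component's mean `m` and variance `m·(1 + dispersion)` — real long-read
depth is overdispersed relative to Poisson, and `dispersion = 0` recovers
a Poisson exactly. The default dispersion is 0.5, a mild overdispersion
typical of long-read mapping; the default collapsed depth is 100X with
the uncollapsed component at half that, matching the depth regime the
metric targets. The realized (not nominal) component base counts are
returned as ground truth, so `C/(C + U/2)` on the truth is an analytic
reference for the pipeline's estimate.

Positions are exchangeable — no along-genome autocorrelation, GC bias,
mappability structure or read-length effects are simulated, and no
heterozygous sequence or k-mer spectra exist behind the depths. The
haploidy metric consumes only the histogram, so these simplifications do
not affect what the tests can show about the metric itself; they do mean
that passing tests say nothing about upstream mapping artifacts in real
data (e.g. depth troughs at contig edges, collapsed repeats).
`simulate_contig_lengths` draws random compositions (distinct uniform cut
points) for N50 fixtures, conserving the total exactly.

## Numerical choices and verification scale

Ties and degenerate inputs are resolved deterministically: plateau maxima
to their midpoint, boundary minima to the lowest coverage, single-bin
histograms refuse smoothing, empty peak lists are errors for attribution
and classification. Reports round haploidy to 3 decimals for display but
retain full precision internally; identical inputs give byte-identical
JSON reports.

The test suite verifies peak detection and prominence against a
brute-force scan of their definitions (1,000 random arrays of ≤ 200
bins), N50 against a definitional scan (1,000 random length lists), and
end-to-end haploidy recovery within ±0.02 of the analytic truth on
million-base simulated profiles with uncollapsed fractions 0.1–0.5 (five
seeds each). One million positions keeps every end-to-end check in the
sub-second range while leaving Monte-Carlo error in the realized areas far
below the ±0.02 acceptance band.

## Limitations

- Coverage limits are user-supplied; a grossly wrong `uncollapsed_max`
  silently misclassifies peaks (the half-depth advisory warning is the
  only guard).
- Overlapping or heavily skewed peaks make the region boundary (a
  width-edge midpoint or curve minimum) a convention, not an inference;
  areas near the boundary are attributed approximately.
- The score ignores indels: inserted sequence has no homologous
  counterpart and yields half coverage, capping the attainable score
  below 1 for indel-rich genomes.
- Windowed coverage summaries, BAM parsing and plotting are out of scope;
  depth must be precomputed (e.g. with `samtools depth`).
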