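# Methods

This note documents the models, defaults, numerical choices and
limitations behind `circapa`.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The estimation problem

A tandem-UTR gene expresses a short isoform ending at the proximal
poly(A) site and a long isoform ending at the distal site.  The 3′UTR
splits into a *common* region of length $L_c$ (present in both
isoforms) and an *extension* of length $L_e$ (long isoform only).
Under uniform read sampling across the expressed mixture, a 3′UTR read
falls in the extension with probability
$p_\text{ext}(\theta) = \theta L_e/(L_c + \theta L_e)$, where $\theta$
is the long-isoform fraction.  Counting $c_\text{common}$ and
$c_\text{ext}$ reads at one time point gives a Binomial($n$,
$p_\text{ext}(\theta)$) likelihood whose maximizer is the closed form
$\hat\theta = fL_c/(L_e(1-f))$, $f = c_\text{ext}/n$.  This is the
tandem-two-isoform special case of mixture-of-isoforms quantification:
point estimates only, no read-position model, no posterior intervals.
The estimator is the exact inverse of the synthetic noise model, which
makes consistency provable and testable; the grid-search maximizer of
the same likelihood (`estimate_psi_grid_oracle`) exists purely as an
independent oracle and is never called by the pipeline.

Boundary behavior: $f \ge L_e/(L_c+L_e)$ drives $\hat\theta$ past 1;
the estimate is clamped and flagged rather than rejected, because the
downstream zero-time-point filter needs to count such degenerate fits.
Zero-read time points yield missing values, not ψ = 0: imputing zero
would spuriously trigger the zero-time-point rule.

## Filtering cascade

Rules and thresholds (all configurable):

1. **Coverage** — ≥ 20 reads in the 3′UTR. Applied *per time point* by
   default: ψ must be estimable at every time point for the rhythm fit.
   A pooled mode (≥ 20 summed over time points) is available; the
   per-time-point reading is the stricter of the two interpretations.
2. **Mean ψ** — each isoform needs mean ψ ≥ 0.1 over all time points
   (strictly below removes).
3. **Zeros** — an isoform with ψ = 0 at ≥ 2 time points (two-cycle
   designs) or ≥ 1 (one-cycle) is removed.  The comparison is exact,
   not a tolerance: in this implementation ψ = 0 arises only from
   $c_\text{ext}=0$ or boundary clamping, both exact events.
4. **Expression** — genes with mean TPM < 1 are removed.  The filter is
   gene-level because isoform-level TPM is not computable from segment
   counts alone.

TPM uses gene-level total reads over the long-isoform UTR length as the
effective length.  Any fixed per-gene length produces the same ordering
under a TPM threshold for the generator's expression model; the choice
is recorded in the manifest and configurable through the reader
interface.

A gene survives only if both isoforms of its pair survive.  Pair
selection takes the two isoforms with the highest mean ψ; every isoform
tied at the second-highest value forms an independent pair (distinct
`pair_id`s).  With exactly two isoforms per gene this is the identity,
but the operation implements the general contract as the extension
point for multi-isoform annotations (ties at the top rank are broken by
isoform id before second-place ties expand).

## Rhythm detection

The detector is a fully specified cosinor-plus-permutation procedure,
not a re-implementation of any meta-algorithm: deterministic given a
seed, exactly calibrated, with the same decision thresholds commonly
used for circadian screens (p < 0.05; amplitude > 0.1 for the APA
index, > 0.01 for abundance; relaxed preset 0.06/0.09).  Consequences:

- **Fit.** $y(t) = m + a\cos\omega t + b\sin\omega t$ solved by exact
  least squares per candidate period; rank deficiency (period aliasing
  with the sampling grid) raises a named error.
- **Period grid.** 20–28 h in 0.5 h steps.  Residual ties break toward
  the period nearest 24 h, then toward the smaller period, making the
  constant-series case deterministic.
- **Acrophase.** $(T/2\pi)\operatorname{atan2}(b,a) \bmod T$ — the time
  of the fitted peak, matching the generator's
  $\cos(2\pi(t-\phi)/T)$ parameterization so that phase recovery is
  directly comparable.  Float noise at the wrap point ($\phi \to T$) is
  folded to 0.
- **Amplitude.** The absolute fitted cosine amplitude.  A *relative*
  amplitude (amplitude/mesor) is ill-defined for the signed, near-zero
  APA index; for abundance series the absolute amplitude is still used
  by default, with the thresholds interpreted on that scale.
- **p-value.** Values are permuted across time points; the statistic is
  the best-period $R^2$ (the period scan is repeated inside every
  permutation, so the maximum over periods is nulled correctly).
  $p = (1 + \#\{\text{perm} \ge \text{obs}\})/(n_\text{perm}+1)$;
  a constant series returns p = 1 by convention.  With
  $n_\text{perm} = 999$ the smallest attainable p is 1/1000.
- **Multiplicity.** No multiple-testing correction by default,
  matching the raw-p screening convention; the batch output contains
  everything needed to apply one downstream.

Because the permutation statistic is computed from orthonormal design
bases shared across permutations, batch detection over ~1,000 series
with 999 permutations each takes seconds.

## PAS scanning

The scan window is the 40 nt of *transcript* sequence immediately 5′ of
the cleavage site (genomic-window scanning is not provided).  Priority
is canonical (AAUAAA) > variant (default set {AUUAAA}, extensible) >
none; within the winning class the occurrence closest to the 3′ end is
reported, matching the positional bias of functional signals.  Windows
truncated by the sequence start are scanned as far as possible and
flagged.  When the two cleavage sites are closer than 40 nt, a motif
lying in both windows is counted for both sites and flagged
`double_counted`; a shared motif also replaces a strictly
lower-priority call at the other site.

Rank-sum comparisons use the Mann–Whitney–Wilcoxon test with the
standard automatic switch: exact null distribution for small tie-free
samples, tie-corrected continuity-corrected normal approximation
otherwise.  The pure normal approximation misorders borderline
decisions at tiny group sizes (e.g. sizes 3 vs 6 at U = 1: exact
p = 0.048, normal approximation p = 0.053), which is why the switch is
not optional.

## Synthetic data generator

The generator reproduces the *statistical structure* of circadian liver
3′-end datasets at the counts level.  What it emulates, and the
defaults:

| parameter | default | rationale |
|---|---|---|
| `frac_multi_pas` | 0.574 | observed multi-PAS gene fraction in liver 3′-end annotation |
| `frac_rhythmic` | 0.05 of multi-PAS genes | yields ~2.9% of all genes rhythmic, the observed order of magnitude |
| `design` | 2-cycle/4h | 12 samples over 48 h; 1-cycle/3h and 2-cycle/6h also supported |
| `common_len_median` / `total_long_len_median` | 768 / 1800 nt | observed short/long isoform 3′UTR medians; log-normal with σ = 0.45 |
| `reads_per_gene_mean` | 200 | ~10–30M usable reads spread over ~8,000 genes and 8–12 samples |
| `expr_sigma` | 2.0 | log-normal expression spread; leaves a ~2% sub-1-TPM tail so the expression filter is exercised |
| PAS class probabilities | distal 0.55/0.18, proximal 0.35/0.25, single 0.64/0.18 (canonical/variant) | canonical enrichment at distal and single sites, variants enriched proximally |
| `amplitude_range` | (0.1, 0.3) ψ units | APA-index amplitudes 0.2–0.6, straddling realistic effect sizes above the 0.1 calling threshold |
| `period_true` | 24 h | circadian |

Mechanics chosen for testability:

- Multi-PAS and rhythmic assignments use **deterministic rounding**
  (`round(n·frac)` genes, selected by seeded draw), so fixture counts
  are exact rather than Bernoulli-noisy.
- Counts follow **Poisson totals + binomial segment splits** — the
  minimal noise model consistent with uniform read sampling, and the
  matched inverse of the ψ estimator.  Gene-level totals for TPM come
  from an independent log-normal expression profile scaled to the
  library size (UTR segment depth and overall expression are decoupled;
  see limitations).
- Rhythmic ψ trajectories are
  $\text{clip}(b + A\cos(2\pi(t-\phi)/T),\,0,\,1)$ with baselines
  uniform on [0.2, 0.8] and phases uniform on [0, 24) (no global phase
  enrichment is imposed).  An amplitude incompatible with its baseline
  is shrunk with a logged warning rather than redrawn.
- Sequences are uniform random with **all** AATAAA/ATTAAA occurrences
  scrubbed by re-randomization before hexamers are planted 10–30 nt
  upstream of their cleavage site; junction artifacts created by
  planting are scrubbed again with the planted spans protected.
  Segments are at least 46 nt so the two scan windows are disjoint and
  every planted motif is unambiguous ground truth.
- Strands are assigned ± with probability ½; the GFF3/FASTA round trip
  restores transcript-orientation sequences identically on both
  strands.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-position and fragment-length
effects (3′ bias, mappability), overdispersion beyond Poisson–binomial,
correlated noise across time points, shared 3′ ends between genes,
alternative-last-exon structures, more than two poly(A) sites per gene,
non-sinusoidal waveforms, and any coupling between expression level and
3′UTR read depth.  Detector operating characteristics measured here are
upper bounds for messier real libraries.

## Coordinates and file formats

Internal coordinates are 0-based half-open; GFF3 I/O is 1-based closed
per the GFF3 specification, converted only at the file boundary.  The
annotation layout is one `gene` feature with child
`three_prime_UTR_segment` features carrying `segment=common|extension`
and `site=proximal|distal` attributes.  On the minus strand the distal
site has the smaller contig coordinate but is always 3′-most in
transcript orientation, and stored sequences are always transcript
5′→3′.  Genes annotated with more than one extension segment are
collapsed onto the pair of sites flanking the longest extension (the
analysis only ever consumes the top-two pair) with a logged warning.
Counts and truth tables are TSV; truth floats are written as `%.17g`
and parsed in round-trip mode so `read(write(x)) == x` holds bitwise.

## Evaluation conventions

Detection metrics are computed against the generator truth restricted
to filter-surviving genes — a rhythmic gene removed by the coverage or
expression filter is a pipeline loss, not a detector miss — with the
unrestricted sensitivity reported alongside.  Phase error is the
minimal circular distance in hours; the fitted APA-index amplitude is
compared against twice the planted ψ amplitude, since
$\psi_\text{prox}-\psi_\text{dist} = 2\psi_\text{prox}-1$.

## Problem sizes

The shipped test suite and the acceptance script run the generator at
500–2,000 genes, 199–999 permutations per series, and 10⁴ background
scan windows; a full 2,000-gene end-to-end run (simulation through
characterization, 999 permutations per pair) completes in roughly ten
seconds on one CPU, so all reported operating characteristics are
recomputed from scratch on every run.

## Known limitations

- Two isoforms per gene; the tie-expansion contract is the designed
  extension point for >2 sites, but quantification itself is binary.
- ψ point estimates carry no uncertainty; downstream tests treat them
  as data.
- The permutation null assumes exchangeability of time points (no
  autocorrelation under the null).
- The TPM effective-length convention matters only up to monotone
  reordering under the generator's expression model; with real
  isoform-resolved expression data a ψ-weighted effective length would
  be preferable.
- The detector's amplitude threshold is on the absolute cosine
  amplitude; screens tuned to relative-amplitude thresholds will select
  differently on abundance series.
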