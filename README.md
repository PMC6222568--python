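# circapa

Detection and characterization of **circadian alternative polyadenylation
(APA)** from time-course RNA-seq 3′UTR read counts.

Many genes carry two tandem poly(A) sites in one 3′UTR: cleavage at the
*proximal* site yields a short isoform, cleavage at the *distal* site a
long isoform carrying an extension region rich in regulatory elements.
In tissues with a strong circadian clock (the motivating system is mouse
liver sampled every 3–6 h over one or two circadian cycles), a minority
of genes switches between the two sites with a ~24 h rhythm.  `circapa`
implements the full desk-scale analysis for this question, for
computational biologists who have per-gene segment counts (reads in the
common region shared by both isoforms vs. reads in the distal-only
extension) and want calibrated rhythmicity calls with known operating
characteristics.

## Model and statistics

**Isoform usage (ψ).**  For a gene with common-region length $L_c$ and
extension length $L_e$, reads sampled uniformly from the isoform mixture
land in the extension with probability

$$p_\text{ext}(\theta) = \frac{\theta L_e}{L_c + \theta L_e},$$

where $\theta$ is the long-isoform (distal) fraction.  With $n = c_\text{common} + c_\text{ext}$
reads and $f = c_\text{ext}/n$, the binomial likelihood is maximized in
closed form by $\hat\theta = f L_c / (L_e(1-f))$, clamped to $[0,1]$.
Then $\psi_\text{dist} = \hat\theta$ and $\psi_\text{prox} = 1-\hat\theta$
sum to one exactly.  A grid-search likelihood maximizer is shipped as an
independent test oracle.

**APA index.**  Per time point, $\text{APA index}(t) = \psi_\text{prox}(t) - \psi_\text{dist}(t) \in [-1, 1]$;
positive values mean short-isoform (proximal) dominance.

**Filtering cascade.**  Genes with <20 3′UTR reads (per time point by
default), isoforms with mean ψ < 0.1 or with ψ = 0 at ≥2 time points
(two-cycle designs; ≥1 for one-cycle), and genes with mean TPM < 1 are
removed; the two isoforms with the highest mean ψ form the tested pair,
with ties at second place expanding into independent pairs.

**Rhythm detection.**  Single-harmonic cosinor fits
$y(t) = m + a\cos(2\pi t/T) + b\sin(2\pi t/T)$ over a 20–28 h period
grid (0.5 h step, ties toward 24 h); amplitude $\sqrt{a^2+b^2}$,
acrophase $(T/2\pi)\,\mathrm{atan2}(b,a) \bmod T$.  Significance is a
permutation p-value on the best-period $R^2$ (values shuffled across
time points, add-one rule).  A series is rhythmic when $p < 0.05$ and
amplitude > 0.1 (APA index) or > 0.01 (abundance); a relaxed preset
(0.06 / 0.09) is available.

**Characterization.**  Poly(A) signal hexamers (canonical AAUAAA,
variant AUUAAA, U/T-equivalent) are scanned in the 40 nt upstream of
each cleavage site, with canonical > variant priority, closest-to-3′-end
within a class, and a double-count rule for sites closer than 40 nt.
3′UTR lengths, site strengths (mean ψ), APA-index distributions and
acrophase histograms are compared between all and rhythmic pairs with
Mann–Whitney–Wilcoxon tests.

**Synthetic ground truth.**  A generator emulates the statistical
structure of circadian liver datasets — 57.4% multi-PAS genes, ~3% of
genes rhythmic, log-normal UTR lengths (medians 768 / 1800 nt), Poisson
totals with binomial segment splits, planted PAS hexamers on a
motif-free background — so every stage is testable against known truth.

## Worked example

```python
from circapa import RunConfig, SimConfig, run_end_to_end

config = RunConfig(
    sim=SimConfig(n_genes=500, frac_rhythmic=0.1, seed=42),
    out_dir="scratch/demo_run",
    n_perm=999,
    seed=42,
)
result = run_end_to_end(config)

m = result.manifest
print(f"tandem-UTR genes analysed : {m['n_tandem_genes']}")
print(f"pairs surviving filters   : {m['n_pairs_tested']}")
print(f"rhythmic APA pairs        : {m['n_rhythmic_pairs']}")

ev = result.evaluation
print(f"sensitivity               : {ev.sensitivity:.3f}")
print(f"specificity               : {ev.specificity:.3f}")
print(f"median phase error (h)    : {ev.phase_error_hours_median:.2f}")

rep = result.report
print(f"median APA index (all)    : {rep['apa_index']['median_all']:.3f}")
print(f"median 3'UTR diff (nt)    : {rep['utr_lengths']['all']['median_length_difference_nt']:.0f}")
```

prints

```
tandem-UTR genes analysed : 287
pairs surviving filters   : 276
rhythmic APA pairs        : 31
sensitivity               : 0.929
specificity               : 0.980
median phase error (h)    : 0.38
median APA index (all)    : 0.052
median 3'UTR diff (nt)    : 1148
```

Of 500 simulated genes, 287 carry a tandem site pair; 276 pairs survive
the cascade.  The detector recovers 92.9% of the planted oscillations
with a median acrophase error of 0.38 h while calling 2.0% of
non-rhythmic survivors.  The run directory contains `psi.tsv`,
`pairs.tsv`, `apa_index.tsv`, `rhythm.tsv`, the characterization
`report.json`, the `filter_report.json` cascade bookkeeping, and a
`manifest.json` that makes the run byte-reproducible.

The same pipeline is scriptable from the shell:

```bash
circapa simulate --config sim.yaml --out data --seed 5
circapa psi --annotation data/annotation.gff3 --fasta data/contigs.fa \
            --counts data/counts.tsv --out psi.tsv
circapa filter --psi psi.tsv --counts data/counts.tsv --tpm tpm.tsv \
               --n-cycles 2 --out pairs.tsv --report freport.json
circapa rhythm --series pairs.tsv --kind apa_index --n-perm 999 --seed 7 \
               --out rhythm.tsv
circapa characterize --annotation data/annotation.gff3 --fasta data/contigs.fa \
                     --pairs pairs.tsv --psi psi.tsv --rhythm rhythm.tsv \
                     --out report.json
circapa run --config run.yaml        # everything in one step
```

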