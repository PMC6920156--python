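# Methods

This note documents the models, the defaults and the reasoning behind
the open design choices in `hetqtl`, in pipeline order.

## Meiosis and population simulation (`simdata`)

Each gamete is a mosaic of the two parental haplotypes. Crossover
counts are Poisson with mean equal to the chromosome's genetic length
in Morgans, breakpoints are uniform on the genetic axis, and the
starting origin is a fair coin — the Haldane model, with no chiasma
interference. Kosambi-style interference would thin close double
crossovers, but the mapping function used downstream (`genmap`,
Haldane by default, Kosambi behind a flag) is chosen to match the
simulator, so map-length recovery is internally consistent either way.
An F2 individual is two independent gametes per chromosome; genotypes
are coded by the count of male-parent (M) alleles (FF=0, MF=1, MM=2).

The default genome is maize-like: 10 chromosomes with physical sizes
near the reference assembly (2.1 Gb total) and genetic lengths
distributing a 1588.8 cM genome total proportionally to physical size
(per-chromosome genetic lengths are not separately published for this
cross, so proportionality is the neutral choice). Physical and genetic
coordinates are related linearly within a chromosome; local
recombination suppression (e.g. peri-centromeric cold regions or
inversions) can be emulated by adjusting a chromosome's genetic length
or masking SNP emission over an interval, but is not on by default.

Parents are modelled as fully homozygous inbred lines, informative at
every simulated SNP (default density 100 informative SNPs/Mb);
residual parental heterozygosity is ignored. Identity-by-state
segments between parents — real crosses can share long haplotypes —
are emulated by `noninformative_intervals`, which simply emits no SNPs
there. The F1 is heterozygous genome-wide.

Phenotypes follow the classical biometrical model: for each QTL the
homozygote carrying the advantageous allele contributes `+a`, the
other homozygote `−a`, and the heterozygote `d` measured from the
mid-homozygote point; loci act additively across the genome on top of
a trait `baseline`, plus Gaussian residual noise. `a` is stored as a
magnitude with the direction carried by the advantageous-parent label,
which keeps `d/a` well-defined as effects shrink. Parental-line and F1
"means" are the genotypic values of the all-homozygous and
all-heterozygous genomes (no separate plot-level noise model). A
second environment re-draws phenotypes after jittering each locus:
`a ← a·exp(ε)`, `d ← d·(1+ε′)` with `ε, ε′ ~ N(0, s)` — multiplicative
so `a` stays non-negative and large effects shift proportionally, the
qualitative behaviour expected from genotype-by-environment
interaction.

Skim sequencing is reduced to its informative content: per individual
and SNP the number of allele observations is Poisson(coverage), each
observation samples one of the two haplotypes uniformly and reports
that parental allele, flipped with probability `obs_error_rate`
(default 1%). Read-level artifacts (quality, mapping, duplicates) are
deliberately out of scope; the error rate is the net post-filter
miscall probability. Every stochastic routine takes an explicit seed
and is byte-reproducible.

The one real-data fixture is the embedded 17-locus two-location
replication table (`table1_fixture`), stored verbatim as printed,
including its two not-evaluable rows and two unstable-ratio footnotes.

## Window genotype calling (`skimgeno`)

At 0.2× most SNPs have 0–1 observations, so calling pools consecutive
observations into windows of fixed observation count (default
`window_size=15`, advancing by full windows). With
`p = n_M/(n_M+n_F)`, a window is MM when `p ≥ 0.85`, FF when
`p ≤ 0.15`, MF otherwise, and missing below `min_obs=10`
observations. The window advances by observation count rather than bp
so call confidence is homogeneous; physical spans (1-based inclusive)
are recorded.

The defaults are a deliberate trade-off. Heterozygote detection is a
binomial problem: an error-free MF window of w observations still
lands outside the (0.15, 0.85) band with probability ~0.7% at w=15
(and ~1e−6 at w=40), while an MM window with 1% observation error
crosses into the band with probability ~1e−4. Pooling fewer than ~10
observations cannot separate MF from the homozygotes (the documented
heterozygote-deficit bias when `min_obs` is too low); pooling many
more costs physical resolution (~0.75 Mb per window at 0.2× and 100
SNPs/Mb). Consequences: (i) isolated miscalled windows are smoothed
(a single window discordant with two equal flanking calls is rewritten
to the flank); (ii) exact mosaic recovery in the noiseless limit holds
for deep windows (w≈40), while at w=15 rare isolated het miscalls
remain at the call level and are almost always removed by smoothing.

Breakpoints are placed at the bp midpoint between the last window of
one segment and the first of the next — unbiased under locally uniform
SNP density. Resolution limits worth keeping in mind: a crossover
closer than one window span to a chromosome end, or a double-crossover
pair closer together than about two window spans, produces a genotype
segment below the caller's resolution element and is invisible to any
windowed method (~2% and ~3% of crossovers respectively at the default
design). Away from those cases, ~97% of crossovers are recovered
within 1.5 median window spans at 0.2×/1% error.

Bin maps take the union of all individuals' breakpoints as bin
boundaries; each individual's code per bin is read off its mosaic, and
individuals with no callable window on a chromosome are missing there.
Bins called in fewer than 80% of individuals are dropped before map
estimation and scanning (`filter_bins`): sparse bins contribute mostly
noise to adjacent-bin recombination fractions and to cofactor columns.
`thin_bins` subsamples bins to a minimum cM spacing for scan marker
grids — in large populations breakpoint-union bins are far denser than
any scan step resolves.

## Genetic map (`genmap`)

Bin order is fixed by physical position (reference-anchored design; no
de novo ordering). The map therefore reduces to adjacent-bin
recombination fractions. For F2 co-dominant markers the likelihood has
no closed-form maximum (the double-heterozygote class mixes 0- and
2-recombinant gamete pairs), so r is estimated by EM over the latent
gamete phase, with E-step weights derived from the 16 ordered
gamete-pair configurations; the implementation is vectorized over all
adjacent pairs at once. Tests pin the EM to a brute-force grid
maximizer of the explicit class-probability likelihood.

Distances come from the Haldane mapping function
`d = −50·ln(1−2r)` (Kosambi optional). Pairs with fewer than 30
complete observations are interpolated from physical distance at the
chromosome's average cM/Mb and flagged; estimates hitting r = 0.5 are
capped at 50 cM and flagged. On simulated truth-derived bin maps the
summed map length equals the realized crossover count to within EM
tolerance, and recovers the simulated 1588.8 cM genome total to well
within 2% at n=2567 (sampling SD of the realized total is ~0.35%).

## QTL scan (`cimscan`)

Composite interval mapping by Haley–Knott regression. At each test
position (union of a 2 cM step grid and the marker positions), the F2
conditional genotype probabilities given the flanking bins are
computed from the per-gamete origin Markov chain under Haldane; the
trait is regressed on `x_a = P(MM) − P(FF)` and `x_d = P(MF)` plus
cofactor columns, and `LOD = (n/2)·log10(RSS_reduced/RSS_full)` with
the reduced model dropping `(a, d)` but keeping cofactors. The
classical n (not n−p) form is used. Haley–Knott regression was chosen
over a full EM mixture fit: at these sample sizes the two are
practically indistinguishable, and correctness is anchored by exact
equivalence to the two-degree-of-freedom single-marker regression at
marker positions (tested to 1e−8 relative) plus recovery experiments.

Missing flanking calls are marginalized out of the conditional (both
flanks missing gives the 1:2:1 prior) rather than searching for the
nearest informative marker per individual; after the 80% call-rate
filter the information loss is negligible. Cofactor columns use prior
expectations (0, 0.5) for missing codes.

Cofactors are chosen by forward stepwise selection on `(x_a, x_d)`
pairs, entering at a 2-df F-test p < 0.01, at most 5 (both
configurable); once a bin enters, candidates within the 10 cM
cofactor window of it are removed to avoid near-collinear stacks.
During the scan, cofactors within 10 cM of the test position are
excluded. With `max_cofactors=0` the scan is simple interval mapping —
note that even a single strong QTL then leaves linked "shoulder"
maxima above threshold tens of cM away, which is exactly what
cofactors absorb.

Peaks are local maxima with LOD above 3.5 (the conventional fixed
threshold for these designs, applied per scan; no permutation
thresholds). Maxima within 20 cM of a higher maximum are absorbed —
the consolidation radius is this package's choice, matched to the
mapping resolution of an F2 at these sizes. Each peak record carries
the effect estimates at the peak, `d/a = d̂/|â|` oriented by the
trait's polarity, its heterotic class and the advantageous parent
(from the sign of `â`).

## Heterotic classification and indices (`heterosis`)

Effects at a called locus are re-estimated from genotype-class means
(each class needs ≥ 30 individuals by default). `a` is the absolute
half-difference of homozygote means — dividing by a signed near-zero
`a` is what produces the occasional huge `|d/a|` at loci whose
homozygotes nearly coincide, and such loci are flagged
`unstable_ratio` instead of being classified silently (if `d ≠ 0` the
over/underdominance candidate implied by the sign of d is reported
with the flag). Classification uses the five half-open `d/a` intervals
listed in the README, evaluated on unrounded values.

The locus-level mid-parent heterosis is `100·d / mid-homozygote mean`.
The denominator choice is genuinely open — the population mean is a
defensible alternative — and the mid-homozygote genotypic mean was
adopted because it is the locus-level analogue of the trait-level
mid-parent point; treat cross-study comparisons of locus MPH
magnitudes with care. Trait-level MPH/BPH are percentages of the
mid-parent and better-parent values, with the better parent chosen by
an explicit per-trait polarity registry (bigger-is-better for yield
and size; late flowering registered as the advantage direction for
flowering time), not hard-coded.

For genome-wide summaries, `d/a` values are clipped to ±3 in the
display output only (stored values are never clipped), and QTLs are
stratified by LOD to expose the overdominance-inflation mechanism:
among weak loci the sampling error of `d/a` pushes many truly dominant
loci (`d/a` in (0.25, 1.25]) over the 1.25 boundary, so the apparent
overdominance fraction falls sharply as LOD rises. The package
demonstrates this on simulations where no truly overdominant locus
exists. Relatedly, true overdominance cannot be distinguished from
pseudo-overdominance (tight repulsion-phase linkage of two dominant
loci) at F2 mapping resolution; the simulator can generate such
repulsion pairs, and no deconvolution is claimed.

## Replication (`replication`)

Second-location evidence per locus is a one-way fixed-effects ANOVA
across MM/MF/FF (scipy), with no multiple-testing correction at
α = 0.05 by default (a Bonferroni flag exists); loci with P ≥ 0.05 are
"not evaluable" and excluded from concordance, as are loci with
`d/a ≤ −1` (where `log(d/a+1)` is undefined) — exclusion is by those
rules only, never by effect magnitude, so evaluable outlier ratios
stay in. Concordance is the Pearson correlation of `log(d/a + 1)`
between locations; natural log by default, and provably base-invariant
(asserted by test). On the embedded 17-locus table this yields 15
significant loci and r = 0.556 (rounding to 0.6) over the 15 evaluable
loci.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to the
smallest designs that measure each property cleanly: full n=2567 /
10-chromosome populations for segregation and map-length recovery
(truth-derived bin maps, no observation layer needed), n≈2500
single-chromosome designs for scan power and class recovery, n≈400–500
for caller and null-scan calibration. EM for r runs to |Δr| < 1e−12
(max 200 iterations) with r clipped to [1e−12, 0.5−1e−12]; LOD
computations guard against zero residual sums of squares by skipping
degenerate positions with a warning; `estimate_rf` requires ≥ 30
informative individuals and map construction falls back to physical
interpolation below that.

## Known limitations

- No crossover interference in the simulator; realized map expansion
  under Kosambi-type interference is not modelled.
- Individuals are genotyped independently; no cross-individual
  imputation, so very low coverage inflates missingness rather than
  borrowing information.
- The scan's conditional probabilities use the immediate flanking bins
  per position, not per-individual nearest informative markers.
- Epistasis is not scanned; phenotypes are strictly additive across
  loci in the simulator.
- Trait polarity must be declared; the package does not infer it.
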