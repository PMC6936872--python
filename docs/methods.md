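# Methods

## Scope and model overview

`poolsweep` implements the desk-scale core of a pooled-resequencing
selection scan in a pigmentation-genetics setting: detection of selective
sweeps from pooled allele counts (−ZHp and windowed FST), read-depth plus
junction-based reconstruction of copy-number-variant (CNV) alleles, and
TMM-normalized expression comparison between differently pigmented skin
samples. Everything upstream of allele counts — read cleaning, mapping,
duplicate marking, variant calling — is out of scope; the package starts
at sync files, depth tables, junction tables and count matrices.

## Pooled heterozygosity scan

For each sliding window the statistic is

    Hp = 2 · ΣnMAJ · ΣnMIN / (ΣnMAJ + ΣnMIN)²

with nMAJ/nMIN the major/minor allele read counts of each SNV in the
window, summed before forming the product. Hp ∈ [0, 0.5]; a sweep that
removes diversity drives it toward 0. Window values are Z-transformed,
ZHp = (Hp − μ) / σ, and significance is one-sided on −ZHp at a
conservative default threshold of 4. Adjacent or overlapping significant
windows are merged into selection signatures and annotated with
overlapping genes.

Choices that were genuinely open:

* **Window geometry.** Defaults are 150 kb windows with a 75 kb step
  (50 % overlap). Enumeration emits a window start while
  `start + step ≤ chromosome length`, i.e. a window must contribute at
  least one full step of new sequence; the terminal window is truncated
  at the chromosome end and scored like any other (Hp is count-ratio
  based, not length-normalized). A chromosome shorter than one step gets
  a single truncated window so its SNVs are not dropped.
* **SNV-free windows.** Windows with zero SNVs get no Hp and are
  excluded from μ/σ. Scoring them as Hp = 0 would fabricate the
  strongest possible sweep signal out of missing data (which may equally
  reflect assembly gaps or coverage filters).
* **Population σ.** The Z-transform uses population (ddof = 0) standard
  deviation: at tens of thousands of windows the sample/population
  difference is negligible, and it matches the plain Z-score formula.
* **Ties.** When nMAJ = nMIN both alleles are kept and the major is
  chosen by fixed base order A<C<G<T; Hp is symmetric in the labels, so
  nothing downstream depends on the choice.

SNV filters default to minimum coverage 15, maximum coverage 50 (to
suppress collapsed-repeat artifacts — this is also why amplified loci
can paradoxically lack a sweep signal: their coverage exceeds the cap
and SNVs are not called) and minor-allele support ≥ 3 reads.
Individual-cohort genotype tables are converted to the same major/minor
counts (homozygote = 2, heterozygote = 1 per allele; sites with any
no-call dropped by default), then flow through the identical machinery.

## Windowed FST

Per site, with major-allele read frequencies p_a, p_b and
p̄ = (p_a + p_b)/2:

    HT = 2·p̄·(1 − p̄),  HS = (2p_a(1−p_a) + 2p_b(1−p_b))/2,
    FST = (HT − HS)/HT   (0 when HT = 0)

HT − HS = 2·Var(p) ≥ 0, so FST ∈ [0, 1] by construction and no clamping
is needed. This is a plain read-frequency estimator without pool-size or
coverage unbiasedness correction; pool sizes are recorded on `PoolSpec`
should a corrected estimator be added. Defaults: coverage 4–50 per pool,
combined minor count ≥ 2. Window values are means of per-site FST
weighted by min(coverage_a, coverage_b) — a site is never trusted beyond
its thinner pool — with an unweighted mean available for sensitivity
checks. Z-transformation and signature merging reuse the Hp machinery,
one-sided on +ZFST.

## CNV calling and allele reconstruction

Relative coverage r = per-base depth / genome-wide mean depth estimates
copies per haplotype for a pool fixed for an allele (the genome-wide
mean is the diploid one-copy baseline; a tandem triplication runs at
r ≈ 3). Defaults: 1 kb bins, 5-bin median smoothing, 5 kb minimum
segment — the CNV units of interest span 13–155 kb, so this resolution
separates them while absorbing single-bin mapping noise. Each bin gets
round(smoothed r); equal-CN runs are merged, sub-minimum runs absorbed
into the neighbor with the closer copy number, and segments with CN ≠ 1
reported (CN 0 = deletion). Heterozygous alleles would produce
fractional r; the raw mean r is kept alongside the rounded call for
inspection.

Junctions are consumed as pre-extracted records — (chrom, pos, side,
chrom, pos, side, support) — rather than from alignment files, keeping
the module testable without BAM data while preserving the read-pair
orientation logic. Classification, reading a junction as
right_of(e) → left_of(s): different chromosomes or ends ≥ 1 Mb apart →
distant insertion (precedence matters: a 19 Mb forward skip must not
classify as a deletion); s = e+1 → reference-colinear; s < e (walking
back into passed sequence) → head-to-tail tandem; s > e+1 → deletion of
the skipped bases. The 1 Mb threshold is unambiguous at this locus
scale, where the one observed donor sits 19 Mb away.

Reconstruction walks the reference chromosome, consuming junctions:
tandem joins are traversed (copy number − 1) extra times, with the copy
number taken from the depth segment maximally overlapping the unit;
deletion joins skip sequence; distant-insertion joins are paired
(splice-in with splice-back bracketing one donor locus) and taken on
every pass, so a splice inside a tandem unit appears in every copy. The
resulting walk is validated against the depth calls: the modal per-base
source multiplicity over each called segment must equal its copy number
(modal, not per-base, because binning blurs segment edges by a bin or
two). Inconsistency raises an error naming the violated segment.

The six published alleles are built with their printed unit lengths
(100,000 ≈ "~100 kb"; 16,280 bp deletion; 22,702 bp donor; 154,677 bp
×3; 13,433 bp ×8; 45,680 bp ×5 and ×4 with 27,996/41,807 bp triplicated
flanks) on synthetic chromosomes, since the real assembly coordinates
live in supplementary material not consumed here. The internally deleted
and donor-spliced unit of the Barbari allele carries the splice in both
tandem copies: the shared breakpoints indicate a common origin, and only
that architecture yields the observed donor-locus depth of ≈ 3× (one
native plus two spliced copies). Synthetic chromosomes are ≥ 10 Mb so
the amplifications inflate the genome-wide mean by < 3 % and round(r)
still recovers the true copy number.

## TMM expression normalization

TMM factors follow the published method's defaults: reference sample =
the one whose upper-quartile count fraction is closest to the mean;
per-sample M (log2 ratio of library-scaled counts vs reference) and A
(mean log2 abundance) over genes expressed in both; double trim of 30 %
(M) and 5 % (A) by ranks; factor = 2^(precision-weighted mean of
retained M); factors rescaled to geometric mean 1. Precision weighting
uses the asymptotic inverse variance of M and therefore depends on
absolute counts — factors are exactly invariant to rescaling a sample
only with `precision_weights=False` (plain trimmed mean), and invariant
to within ~1 % with weighting on. Normalized expression is reported per
million on TMM-effective library sizes (the scale is stated explicitly
because "TMM values" alone does not fix one). Paired comparisons report
the plain ratio pheomelanistic / eumelanistic for the gene of interest,
with an infinite-ratio flag when the denominator is zero; no
differential-expression test is fitted.

## Synthetic-data generator

What it emulates, and what it does not:

* **Pooled counts.** Population minor-allele frequencies follow the
  neutral site-frequency shape (weight ∝ 1/x on the grid {1/2N … 0.5});
  sampling is two-stage, mirroring pool-seq's double sampling —
  chromosomes Binomial(2n, f), then reads Binomial(depth, pool
  frequency) at Poisson(λ) depth (default λ = 30, matching the ~30×
  design; densities default to 1 SNV/kb). Not modelled: linkage
  disequilibrium, demography, base-calling error.
* **Sweeps.** A sweep region scales every site's minor frequency by
  (1 − reduction). No separate site-removal step is applied: at strong
  reductions the binomial pool-sampling stage already floors most swept
  sites to zero minor copies (P ≈ (1−f′)^2n ≈ the reduction itself), so
  swept windows thin out *and* the surviving SNVs run at low frequency —
  which is what gives the scan its contrast. An explicit additional
  removal step would leave swept windows with no called SNVs at all
  under the default filters; such windows are excluded from the
  Z-transform and would paradoxically make strong sweeps undetectable.
  This is a frequency-scaling knob, not a coalescent simulation: it
  produces controlled reduced diversity, nothing more. Consequently,
  passing sweep-power tests show the scan detects reduced diversity at
  the simulated sharpness, not that it matches the power of the scan on
  real demographic histories.
* **Truth tables.** Every simulated site's post-sweep population
  frequency and sweep membership is recorded; heterozygosity-reduction
  checks are made on these truth frequencies, because the minor-count ≥ 3
  read filter censors called minor read fractions below ≈ 0.1 and puts a
  floor of ≈ 0.17 on called-SNV window Hp regardless of the true
  reduction.
* **CNV evidence.** Per-base depth is Poisson(λ × walk multiplicity) for
  a pool fixed (homozygous) for the allele; each unique non-reference
  adjacency in the walk yields one junction record with support
  ~ Poisson(λ/2), min 1. Segregating CNVs and split-read breakpoint
  refinement are not simulated.
* **Expression.** Gamma-Poisson (negative binomial) counts with
  group-dependent means, dispersion default 0.1, library sizes jittered
  ±20 %. Dispersion 0 degenerates to Poisson.

All outputs are bit-reproducible from the configured seed.

## Numerical and testing choices

* Z-transform requires ≥ 2 finite values with nonzero spread; degenerate
  input (e.g. identical pools genome-wide in the FST scan) raises an
  explicit error rather than emitting NaN scores.
* Sync and depth positions are 1-based on disk (their formats'
  conventions); all internal windows, segments and exported BED
  intervals are 0-based half-open. Signature/gene overlap requires ≥ 1 bp
  (abutting intervals do not annotate).
* Test problem sizes: the oracle-equivalence fixture uses ~10⁴ sites on
  3 Mb; sweep power uses a 75.75 Mb chromosome (1,010 overlapping
  windows: 1,000 neutral + 10 swept at 95 % reduction); the end-to-end
  recovery run uses 60 Mb with three sweeps. These sizes give stable
  Z-score baselines while keeping the whole suite around a minute.
* The TMM implementation is cross-checked against an independent
  reference implementation (edgeR via Rscript) to 10⁻⁶ on a 2,000-gene
  negative-binomial fixture with 5 % asymmetrically inflated genes.
* Statistical test bands are derived from the sampling distribution they
  test (e.g. the equal-means fold-change check bounds a single draw at
  3σ of its NB sampling error and the across-seed geometric mean at a
  tight band), not chosen ad hoc.

## Known limitations

* The FST estimator is the classical heterozygosity partition on read
  frequencies; it is biased at low coverage and small pool sizes
  (no Karlsson- or Weir–Cockerham-type correction).
* Copy numbers are called for fixed (homozygous) alleles; segregating
  CNVs yield fractional relative coverage and are only reported with
  their raw r.
* Junction reconstruction assumes head-to-tail tandems and simple
  deletion/insertion splices in direct orientation; inversions are not
  modelled.
* Genome-wide counts reported in the motivating study (thousands of
  signatures across 21 pools) require the full ~30× whole-genome data
  and are not reproducible at desk scale; the package's validation is
  property-based plus parameter recovery against the published CNV
  architectures.
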