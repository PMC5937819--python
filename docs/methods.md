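# Methods

## Gene-order model

A genome is reduced to the 5'→3' order of its genes.  Within each
chromosome genes are ranked by start coordinate (GFF3-style 1-based
inclusive; ties broken by end, then gene id), and strand is ignored:
the divergence statistic depends only on ordering, and strand-flipping
rearrangements surface downstream as order changes.  The coordination
number `L = chromosome_index · offset + 10000 + rank` encodes adjacency
as `|ΔL| = 1`; the per-chromosome offset (default 100000, widened
automatically for very large simulated chromosomes) guarantees genes on
different chromosomes can never appear adjacent.  Ortholog maps are
normalised to one-to-one; the default `drop_ambiguous` policy discards
every pair touching a duplicated id, because the pair statistic needs
an unambiguous correspondence (a `strict_one_to_one` mode turns
ambiguity into an error instead).  How a co-ortholog clustering is
reduced to pairs upstream is deliberately left to the caller.

## pGOD

`pGOD = 1 − Σc / ((N1 + N2 − n1 − n2)/2)`.  A neighborhood is conserved
(`c = 1`) when both orthologs exist, share a chromosome in the other
genome, and differ in coordination by at most the threshold (default 1;
1–5 exposed, results are insensitive in that range).  `Σc` is the
average of the two directional conserved counts: the denominator is
already the average neighborhood count of the two genomes, and
averaging the numerator keeps the statistic exactly symmetric when
`N1 − n1 ≠ N2 − n2`.  A missing ortholog is a valid non-conserved
outcome, not an error; genomes whose chromosomes all carry a single
gene have no neighborhoods and are rejected.

## Window profiles and the gamma shape

Regional heterogeneity is measured by tiling each chromosome of the
reference genome of a pair with windows of 50 genes stepped by 25
(defaults).  A window's pGOD is the fraction of its internal
neighborhoods not conserved in the A→B direction.  A trailing window is
kept only when it holds strictly more than half a window of genes —
shorter stubs are dropped to bound their variance, which also means a
100-gene chromosome yields exactly the windows starting at ranks 1, 26
and 51.

The gamma shape `α` is the MLE of a gamma distribution (location fixed
at zero, shape and scale free) over the positive window values; zeros
are excluded because gamma support is `x > 0` and observed profiles at
the divergences where the correction matters are strictly positive.
Fewer than 10 positive windows or a constant profile is an error
(pool windows across chromosomes or comparisons instead); if the MLE
fails to converge the method-of-moments estimate `mean²/variance` is
used.  Per-pair fitting (`alpha="auto"`) and fixed shapes are both
supported; the representative-species medians 2.83 / 2.69 / 3.10
(N. crassa, S. cerevisiae, Sch. pombe) ship as a lineage table for runs
that prefer one shape per subphylum.

## dGOD, rates and group statistics

`dGOD = α[(1 − pGOD)^(−1/α) − 1]` corrects for repeated breakage of
the same neighborhood under gamma-distributed regional rates and tends
to `−ln(1 − pGOD)` as `α → ∞`; it is undefined at `pGOD = 1`.  Rates
are `dGOD / seq_distance`, with pairs at distance ≥ 0.6 excluded
(strict inequality) because the variance of dGOD explodes near
saturation.  Divergence-versus-distance trends use OLS on `ln x`
(logarithmic) or `x` (linear); half-lives solve the fitted model at
pGOD = 0.5 (`exp((0.5 − b)/a)` or `(0.5 − b)/a`).  Natural logarithms
throughout.  Lineage comparisons use one-way ANOVA with Tukey HSD
(studentized range, via statsmodels) and the equal-variance Student's
t-test for two-sample contrasts; no further multiplicity correction is
layered on top of Tukey.  The richness correlation is the Pearson r of
described-species counts against median lineage rates.

Loss classification applies the precedence DELETION > TRANSLOCATION >
OTHERS: absence of an ortholog is checked first, so a neighborhood that
lost one gene *and* moved chromosomes counts as a deletion.  The
gene-loss rate is defined as the symmetric unshared-gene fraction
`((N1 − |map|) + (N2 − |map|)) / (N1 + N2)` per unit distance — a
per-gene quantity, deliberately independent of the per-neighborhood
deletion count.

## SV filtering and validation

Coordinates are 1-based inclusive on input (VCF convention) and
half-open internally; BED tracks are taken as-is.  A call is rejected
if ANY hard filter fires — size < 100 bp, quality < 1000, either end
unassembled, a breakpoint within 30 kbp (inclusive) of a
telomere/centromere interval, or ≥ 90% reciprocal overlap with a
transposable element (DEL/INS/INV/DUP only; reciprocal overlap is the
smaller of the two mutual fractions).  The first firing rule labels the
rejection but the passing set is order-independent.  Split-alignment
validation measures signed gaps between the inner edges of consecutive
contig segments on the contig and on the reference: DEL needs the
reference gap to exceed the contig gap by ≥ 100 bp, INS the reverse,
DUP needs ≥ 100 bp more *overlap* on the reference (negative gaps),
INV a reverse-orientation segment of ≥ 100 bp, TRA segments on two
reference chromosomes.  Consecutive segments may overlap by at most 75%
of either segment on the contig.  Breakpoint concordance is ± 100 bp
inclusive; translocations additionally require the partner breakpoint
to sit on the mate's chromosome.  Rates normalise breakpoints (2 per
SV uniformly — the choice for insertions is not canonical, so the
count per SV is a parameter) per Mbp per unit genetic distance.

## Simulator

The simulator evolves ordered gene lists away from a shared ancestor.
Defaults emulate a typical ascomycete genome: 5000 genes on 8
chromosomes, regional rate multipliers `Gamma(2.8, 1/2.8)` (mean 1,
shape in the middle of fitted fungal profiles) over 50-gene blocks,
geometric segment lengths with mean 4 genes, and a deletion-heavy event
mix (100 deletions, 40 inversions, 20 transpositions, 10 reciprocal
translocations, 10 tandem duplications) mirroring the observed
dominance of imbalanced rearrangements.  The mean tract length of 4
also makes one deletion and one interior inversion contribute equally
many lost neighborhoods (5 + 1 versus 4, pooled over directions), so a
50/50 deletion/inversion mix yields a ~50/50 loss composition.
Multipliers attach to genes, not positions — fragility travels with
the sequence.  Events are placed in chromosome interiors so the
per-event breakage bookkeeping (tabulated in `simulate.py`) is exact:
inversions and reciprocal translocations account for 2 lost
neighborhoods, transpositions 3, a deletion of `L` genes `L + 1`
deletion-type plus 1 balanced loss, a tandem duplication 1 plus `L + 1`
(the copies carry no orthologs).  `expected_pgod` turns this table into
an analytic expectation with a product-form multiple-hit correction,
valid for homogeneous rates while collisions between events are rare.
`proxy_distance = events / n_genes` is only claimed to be monotone in
divergence, not calibrated to substitutions/site.

What the simulator does **not** model: sequence evolution, realistic
TE insertion dynamics, whole-genome duplication, chromosome fusion or
fission, and gene-family expansion.  Tests passing on simulated data
therefore demonstrate the estimators' internal consistency under the
stated breakage model, not performance on real annotation noise
(fragmented assemblies, mis-annotated gene models, ortholog errors).

## Validation designs and numerical choices

* *Shape recovery.*  Fitting a gamma to raw window pGOD values is
  biased in two opposing ways: window-level counting noise (binomial,
  plus the pairing of each event's two breakpoints) inflates the
  variance and drags the fitted shape down, while multiple-hit
  saturation compresses the upper tail and pushes it up.  The recovery
  experiment therefore uses non-overlapping windows of 800 genes
  aligned with the simulator's rate blocks and a mean window divergence
  of ~0.08, where a pilot bias study showed the estimator is close to
  unbiased (|bias| ≲ 0.1 across shapes 2.3–3.9) with seed-to-seed
  spread ~0.15–0.3 at 1000 windows.  The production default (50-gene
  windows) matches practice for real genomes, where profiles pool many
  chromosomes and only the order of magnitude of `α` matters.
* *Rate-ratio recovery.*  The two-lineage study uses balanced
  rearrangements only and branch distances ≤ 0.11: deletions remove
  genes and add a second saturation channel that the gamma correction
  does not model, visibly flattening slopes for fast lineages at high
  divergence.  With the balanced mix the recovered slope ratio sits
  within a few percent of the simulated 3× contrast.
* *Problem sizes.*  Test simulations use 0.4–800 k genes chosen so
  each check's sampling error is comfortably below its tolerance; the
  brute-force pGOD oracle runs on ≤ 20-gene genomes where exhaustive
  scanning is exact and cheap.
* Ties and degenerate inputs: overlapping genes order by (start, end,
  id); constant regressions return slope 0 with r² = 0; identical
  constant groups give ANOVA p = 1; a composition with no lost
  neighborhood is flagged undefined rather than invented.

## Known limitations

* pGOD treats the ortholog map as truth; ortholog errors inflate
  apparent divergence, deletions and duplications indistinguishably.
* The gamma correction assumes one shape per comparison; lineage-
  specific fragile sites that move over time violate the fixed-rates
  assumption.
* The simulator's event-count-to-distance proxy is linear by
  construction; real divergence times would require external
  calibration.
* Gene-content loss is corrected neither by dGOD nor by the rate
  normalisation — rate comparisons between lineages with very
  different deletion loads should be read with that in mind.
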