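# Methods

This note documents the models, defaults and numerical choices behind
`splice-rescue`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Junction-read PSI

The percent-spliced-in of an internal exon *n* is computed from junction
reads only:

    PSI(n) = J(n−1, n) / ( J(n−1, n) + J(n−1, n+1) )

with `J(a, b)` the number of primary, non-duplicate spliced alignments
whose CIGAR N operation spans exactly the interval between the end of
exon *a* and the start of exon *b* (0-based half-open genomic
coordinates). Only the upstream-anchored junctions enter the ratio; this
asymmetric definition is the default because it is the form the ratio is
usually quoted in for cassette-exon screens. A symmetric mode
(`compute_psi(..., symmetric=True)`) averages the upstream and
downstream inclusion junctions and is offered for general use.

Extraction details that the data do not dictate and are therefore fixed
as documented defaults:

* matched anchors of ≥ 8 nt (CIGAR M/=/X immediately flanking the gap)
  on both sides of an N operation; one observation per N, so a
  doubly-spliced read contributes two junctions;
* no mapping-quality floor; secondary, supplementary, duplicate and
  unmapped records are ignored;
* junctions are matched to gene models by exact coordinates; strand is
  carried in the key but not used for matching. Reads from unannotated
  junctions remain in the counts (they contribute to the rpm
  denominator) and are tallied in a diagnostics counter.

PSI is *undefined* (not 0) when `J_incl + J_skip = 0`. Coverage is
expressed in reads per million junction reads:
`rpm = (J_incl + J_skip) × 10⁶ / total junction reads`.

## Differential-splicing screen

Per-condition PSI is the arithmetic mean over replicates, ignoring
samples where PSI is undefined (an exon is undefined in a condition only
when all its samples are). ΔPSI = mean PSI(treated) − mean PSI(control).
The coverage filter keeps exons with pooled condition coverage strictly
greater than 15 rpm — pooled meaning the condition's summed
`J_incl + J_skip` per million summed junction reads — in *either*
condition ("and/or" read as OR; an AND rule is configurable). Ranking is
by |ΔPSI| descending with deterministic ties (gene id, then exon
ordinal, ascending); events are counted at an inclusive |ΔPSI| ≥ 0.1.
No p-values are attached: the screen ranks by effect size only.

## Read preprocessing

Reads are split into consecutive 60-nt fragments from the 5′ end; the
terminal remainder is kept only if ≥ 25 nt (an alignability floor — the
sub-60 tail is otherwise too short to map reliably; both behaviours are
available via `terminal_min_length`). Fragments with arithmetic-mean
Phred score < 17 (Sanger offset 33 by default) are eliminated; the
comparison is strict, so a mean of exactly 17 is kept. "Average Phred"
is the plain arithmetic mean of per-base scores, not an
error-probability-weighted mean. The post-alignment blacklist accepts
any BED of intervals (rRNA/tRNA/snRNA/snoRNA/repeat annotations in
practice); an alignment is removed when its reference span overlaps a
region by ≥ 1 nt under half-open conventions.

## Donor/U1 register

The donor window is the nine nucleotides at −3..+6 (−1 = last exonic,
+1 = first intronic; there is no position 0). It is paired antiparallel
against the 5′-terminal single-stranded end of U1 snRNA,
5′-AUACUUACCUG-3′ (nucleotides 1–11), with donor +6 pairing template
nucleotide 3 and donor −3 pairing nucleotide 11. The template and map
are pinned constants, overridable in `U1Register`. G:U wobble counts as
pairing by default (`wc_plus_gu`), standard for U1 duplexes; the
bundled IKBKAP contexts give identical mismatch sets under both
policies, which the tests assert.

## Enhancer-motif scanning

Candidate SR-protein binding sites are scored with the ESEfinder 3.0
SELEX weight matrices, shipped as TSV resources with provenance headers
(SRSF1/SF2-ASF, SRSF2/SC35, SRSF5/SRp40, SRSF6/SRp55; thresholds 1.956,
2.383, 2.67, 2.676). A motif's score is the sum of per-position matrix
entries; score = threshold counts as a hit. Starts are reported in
splice-site-relative coordinates, the start being the first nucleotide
of the L-mer. L-mers must lie fully inside the covered sequence; the
scanner warns when the window is entirely uncovered. The scanner
reports *all* above-threshold starts, including overlapping ones.

On the oligo-tiled mutant region (exonic −8..−1 plus intron +1..+75 —
the only span reconstructible from the published oligos), the SRSF6
matrix yields above-threshold hits at +4, +45 and +58, with the site-b
hexamer UGUGUG at +45..+50 the strongest intronic hit. The +4 site is
created by the IVS20+6 T>C substitution itself (AGUGCC → AGCGCC). Note
that the hexamer at +21 (UGCGAC), described in the experimental
literature as a candidate SRSF6 site, scores 2.11 with this matrix —
below the 2.676 default threshold; web-tool runs at lowered display
thresholds, with curation, can produce different candidate lists.
Variant comparison (`compare_variant_motifs`) aligns two equal-length
regions position-by-position, lists substitutions, and classifies a
reference hit as "lost" when its score in the variant falls below the
threshold.

## Potency

Dose–response readouts are modelled with the four-parameter logistic

    y(d) = bottom + (top − bottom) / (1 + (EC50/d)^hill),

fitted by unconstrained least squares on log10 dose
(`scipy.optimize.curve_fit`) with multi-start initialisation over
hill ∈ {±0.5, ±1, ±2} and EC50 over dose quantiles; the start with the
smallest residual norm wins and the convergence flag is honest
(parameters are withheld when no start converges). Bottom/top
constraints are off by default and exposed in configuration. Vehicle
(dose 0) rows are excluded from the log-dose fit. Reporter tables are
normalized so the mean response at a designated reference
(compound, dose) equals 100%; `ec_at(fit, level)` then inverts the
fitted curve at `level × 100%` on that normalized scale (EC25 at 0.25).
CT50 is the same inversion at 50% applied to a falling viability curve
normalized to vehicle = 100%. A level the curve cannot attain, or whose
crossing lies outside the tested concentration range × [1/10, 10], is
reported as "not reached".

Group comparisons default to Student's unpaired pooled-variance t test
(df = n_a + n_b − 2), one- or two-tailed; Welch's unequal-variance form
is behind a flag. Two zero-variance groups with equal means return
p = 1 with a flag.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *counting statistics* of a cassette-exon
screen, not the sequence biology. For each simulated exon (one
three-exon gene per exon: 100-nt exons, 200-nt introns, plus strand),
the inclusion junction count is Binomial(depth, PSI_true) and the
skipping count the remainder, so inclusion + skipping always equals the
allocated depth. Defaults mirror a small fibroblast study: 2 conditions
× 2 replicates. Binomial sampling (no overdispersion) is the default
since no noise model beyond counting is implied by the design; a
beta-binomial option (`dispersion`) exists but defaults off. Spliced
reads are emitted one per junction observation with anchors of
read_length/2 on each side, so the round trip
simulate → extract → count is an identity — by construction, which is
exactly what makes it an oracle for the extraction arithmetic.
`simulate_spliced_sam` therefore consumes the simulated counts rather
than re-drawing them. Reporter tables are 4PL values plus i.i.d.
Gaussian noise with σ expressed as a fraction of |top − bottom|.

Not emulated: read sequence content and quality structure, alignment
error, multi-mapping, fragment-length or GC bias, overdispersion from
library preparation, intron retention or alternative 5′/3′ splice
sites. Passing the synthetic tests demonstrates the correctness of the
counting, filtering, ranking and fitting arithmetic; it does not
validate aligner behaviour or biological noise models.

Estimator-recovery problem size: the recovery test uses 500 exons,
2 replicates per condition and junction depth 500 per exon per sample.
The depth was set by a pre-run power calculation: with binomial
counting noise, E|ΔPSI_hat − ΔPSI| ≈ 0.8·√(E[p(1−p)]/D) per exon
(≈ 0.015 at D = 500 for uniform PSI), comfortably inside the 0.02
acceptance band, whereas D = 200 would sit on the boundary.

## Determinism and orchestration

All generators take explicit seeds (`numpy.random.default_rng`); the
pipeline records the seed in every output header and writes a MANIFEST
with SHA-256 content hashes, and reruns with the same config and seed
are byte-identical (asserted in tests). Configuration is one YAML
document with a strict schema — unknown keys are violations — and
validation reports every violation at once. CLI exit codes: 0 success,
2 config error, 3 stage failure.

## Known limitations

* Only cassette-exon skipping is modelled; intron retention and
  alternative splice-site events are out of scope.
* Junction-to-model matching requires exact coordinates; no tolerance
  for soft-clipped or shifted junctions.
* The oligo-tiled region covers intron +1..+75 (plus 8 exonic nt) only;
  scans requesting −100..+100 silently cover the available span.
* EC estimates carry no confidence intervals; the fit reports residual
  norm and convergence only.
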