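# Methods

This note documents the models, conventions and design choices behind
`lilimir`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Read triage

A raw read is processed as: 3′-adapter trim → length gates → poly-N
filter → mean-quality filter → ncRNA/repeat annotation.  The trim
removes the suffix starting at the *leftmost* position where a prefix of
the adapter of ≥ `adapter_min_overlap` (6) nt matches with ≤ 1 mismatch;
a read starting with the adapter is `adapter_only`.  Inserts outside
18–25 nt are `too_short`/`too_long`; inserts with > 10 % N are `junk`;
mean Phred < 20 is `low_quality`.  The quality and poly-N thresholds are
our defaults (the upstream convention names no values); both are
`FilterParams` fields.  ncRNA/repeat annotation is exact substring
matching on both strands against the reference sets, with precedence
rRNA > tRNA > snoRNA > snRNA > other, then repeats — an indexed aligner
would add a dependency without changing results at desk scale, and exact
matching is bit-reproducible.  Every read receives exactly one label, so
the statistics table's class rows always sum to the raw totals; this
partition is asserted in the pipeline tests.

## Hairpin criteria and stem delimitation

Novel-precursor candidates are folded at 37 °C (temperature
configurable) with ViennaRNA's MFE algorithm.  The **stem** is the helix
chain containing the mature arm: starting from the first paired mature
nucleotide, the walk follows directly nested pairs inward until the
terminal loop or a multiloop, and outward until the exterior loop, a
multiloop, an interior loop whose unpaired run exceeds `stem_walk_break`
(20 nt), or a stem span beyond `max_stem_span` (250 nt).  The last two
stops delimit the precursor inside a transcript excision window: random
flanking sequence often pairs loosely *around* a genuine hairpin, and
without a boundary its interior loops would be charged to the hairpin's
stem.  The break threshold (20) deliberately exceeds the stem-bulge
criterion (12) so that a genuinely oversized bulge inside a precursor is
still traversed and counted; the span cap is above the longest plant
pre-miRNAs worth considering.  Measured statistics:

* **stem bulge** — largest contiguous unpaired run on either side of any
  interior loop in the stem (criterion: ≤ 12 nt);
* **mature bulge** — the same, restricted to loops touching the mature
  interval (≤ 4 nt);
* **stem pairs** — number of base pairs in the walk (≥ 16);
* **mature errors** — unpaired nucleotides inside the mature (≤ 2);
* **biased errors** — the asymmetric part |left − right| of a single
  mature-region interior loop (≤ 2).  The original criterion's wording is
  ambiguous; this reading is isolated in `evaluate_hairpin` so it can be
  revised in one place.

A candidate whose mature overlaps the terminal loop, pairs with itself,
or is entirely unpaired is rejected with a reason rather than scored.
Candidates are excised as tag ± 150 nt windows; the window covers any
plausible precursor (longest reported plant novel hairpins are < 200 nt)
and overlapping windows merge, with the most abundant tag as the mature.
The reported "hairpin length" and MFE of an accepted candidate refer to
the stem-loop spanned by the outermost stem pair, re-folded on its own —
not to the excision window.

## Catalogue matching and groups

BLAST-style search is replaced by exact substring matching: a tag hits a
precursor when it occurs verbatim with its start within ± 4 nt of the
annotated mature start.  Matched miRNAs are grouped by transcriptome
evidence: group 1 (tag and precursor both in the transcriptome), group 2
(tag only), group 3 (neither).  Families come from the catalogue; novel
records are numbered `miRn1, miRn2, …` in discovery order.  IsomiR
handling is limited to 0–2 nt of 3′ trimming, which keeps tag→miRNA
assignment unambiguous.

## Normalization and differential expression

The reference profile is the per-sequence median copy number over the
sequences nonzero in *every* sample.  For each sample, ordinary least
squares fits log₂(sample) = a + b·log₂(reference) over the subset with
|ΔLog₂| < 2, and every sequence is corrected as (log₂(obs) − a)/b — the
"arithmetic correction factor" interpreted as inverting the fitted line;
a mean-offset-only variant (b ≡ 1) is available for sensitivity
analysis.  If the subset is empty (e.g. a uniform shift of exactly 2),
the fit falls back to all common sequences with a warning; a
zero-variance reference falls back to the identity with a warning.  A
pseudocount of 1 is added before log₂ (configurable; the exactness
checks use 0 with strictly positive counts).  Differential expression is
a per-miRNA one-way fixed-effects ANOVA across stages on the expected
log₂ scale — the omnibus test, not per-pair post-hocs — with raw
p ≤ 0.05 as the significance rule and BH q-values reported alongside.
Zero between- and within-group variance yields p = 1 by convention.
Significant profiles are clustered by average linkage under correlation
distance on z-scored stage means, cut into 3 classes by default.

The 2^−ΔΔCt utility takes a gene × sample Ct table: ΔCt subtracts the
mean Ct of the reference genes per sample (two references are averaged
on the Ct scale, equivalent to a geometric-mean normalizer on the linear
scale); ΔΔCt subtracts the calibrator sample's (or stage's mean) ΔCt, so
the calibrator column is exactly 1.

## Degradome scoring and categories

Duplex penalty: mismatch 1, G:U wobble 0.5, single-nucleotide bulge 1,
all doubled at miRNA positions 2–13; sites with penalty ≤ 4 are
candidates.  Scoring is a small DP over ≤ 1 bulge per strand (both knobs
configurable), verified against exhaustive alignment enumeration.  The
expected cleavage position is the transcript nucleotide opposite miRNA
position 10 from the 5′ end; degradome tags are sense-strand 5′ ends,
and evidence is accepted within ± 1 nt (configurable).  Categories
follow the standard degradome convention, isolated in one function:
4 = single tag; 0 = unique transcript maximum; 1 = tied maximum;
2 = above the median of nonzero positions but below the maximum;
3 = otherwise.  The median excludes zero positions.  Multi-mapping tags
count once per locus (a fractional mode splits them).

One stated invariant was weakened knowingly: "reverse-complementing both
strands leaves the penalty unchanged" cannot hold for a wobble-aware
scorer, because the complements of a G·U pair (C and A) do not pair.
The tests assert the properties that do hold: role-swap symmetry under
uniform position weights, and reverse-complement invariance on
wobble-free duplexes.

## Coexpression network

Unsigned adjacency a_ij = |cor(x_i, x_j)|^β.  β defaults to 12; the
scan picks the smallest candidate whose signed scale-free fit R² (from
the log₁₀ p(k) vs log₁₀ k regression over 10 connectivity bins) reaches
0.8, falling back to the default with a warning, and a degenerate
point-mass connectivity (exact block-diagonal correlation) counts as a
maximal fit.  TOM uses the standard formula with connectivity k as the
diagonal-free row sums.  Modules: average-linkage clustering of 1 − TOM,
a static cut (height 0.98) rather than dynamic hybrid cutting — simpler
and reproducible at this scale — minimum module size 10, grey for
unassigned, colours assigned by descending size from the conventional
palette.  Eigengenes are the first principal component of the module's
z-scored expression, signed to track the mean profile; modules whose
eigengenes correlate above 1 − 0.25 merge.  Note that in an *unsigned*
network, decreasing and increasing trajectories are maximally similar
and will share a module — the expected behaviour, visible in the
round-trip tests.  Enrichment is the exact hypergeometric upper tail per
term against a local annotation table (no live database), BH-adjusted.

## The synthetic study generator

The generator emulates the structure such a study assumes, and its
defaults are the study conditions used throughout the tests:

* **Design** — 5 stages (VJ_I, VJ_II, FI_I, FI_II, FD) × 3 replicates,
  20 000 reads per library, 80 transcripts (600–1500 nt), 40 catalogue
  miRNAs in weighted families (miR156 largest), 10 catalogue-hidden
  novel precursors, 10 decoys, 12 ncRNA references, 15 planted target
  sites.  Raw reads are 50 nt with 3′-adapter read-through (TruSeq
  small-RNA adapter); the raw read length is our choice, as the upstream
  protocol names none.
* **Precursors** are designed as reverse-complement stems (≥ 16 pairs)
  around the mature with an 8-nt loop and *verified with the same
  evaluator the discovery module uses*; decoys are engineered to violate
  exactly one criterion (14-nt stem bulge, 3 mature mismatches, or a
  3-nt asymmetric mature-region bulge) and verified likewise.  Two of
  the five thresholds (mature bulge, stem pairs) cannot be violated in
  isolation under these definitions, so decoys cycle the three isolable
  violations.  Precursors are embedded between 40-nt A/C spacers
  (A and C cannot pair with each other), and hairpin-predicted loci are
  re-verified in their actual excision-window context at generation
  time; real transcripts have structured flanking context, so passing
  these tests shows correctness of the machinery, not robustness to
  arbitrary mRNA secondary structure.
* **Abundance** — per-miRNA negative-binomial counts (dispersion 0.1,
  Poisson available) around stage expectations.  Only the lead members
  (a/b) of the shaped families move; trajectories swing ~50-fold with
  every non-central stage ≥ 2.2 log₂ units from the profile median, and
  DE base abundance is capped an order below the flat ceiling.  This
  keeps stage totals dominated by stable sequences — the regime the
  median-reference normalization assumes (in the real study, 84 DE of
  ~400 miRNAs).  With DE sequences dominating total abundance instead,
  compositional coupling makes flat miRNAs appear stage-dependent and
  no per-sample line can correct it; the generator's defaults therefore
  encode the method's stated applicability conditions.  Mature-length
  masses are rescaled so the aggregate valid-read length distribution
  follows the configured weights (mode 24 nt, then 21 nt) by design
  rather than by lottery over heavy-tailed abundances.
* **Degradome** — per planted site, the tag 5′ ends fall exactly on the
  cleavage coordinate; signal abundance and decoy peaks are chosen per
  intended category (40 tags for 0; 20+tied 20 for 1; 8 under a 25 peak
  for 2; 2 at/below a median of 3s for 3; a singleton for 4), plus
  uniform background at 0.1× signal.
* **Determinism** — every stream derives from `(seed, label…)` via
  `SeedSequence`, so bundles and libraries are byte-identical across
  runs and machines for a fixed seed.

What the generator does **not** emulate: sequencing-error profiles,
5′ isomiRs and editing, genomic (vs transcriptomic) context, structured
UTR/mRNA folding around target sites, adapter dimers beyond the pure
adapter read, and library-size imbalance beyond the negative-binomial
noise.  Passing tests demonstrate the pipeline's internal correctness
and calibration under these controlled conditions, not performance on
real libraries.

## Problem sizes and tolerances

Tests and the acceptance script run the default bundle (15 libraries ×
20 000 reads), a 100 000-read library for length-distribution checks,
2 000 null and 500 effect miRNAs for ANOVA calibration, exhaustive
category enumeration up to length-6/count-3 profiles, 10-node TOM
brute-force comparisons (10⁻¹²), and 3 × 20-node planted modules — sizes
chosen so the full suite completes in minutes on one core while keeping
every Monte-Carlo check's standard error well inside its asserted band.
Numerical comparisons use exact equality only where the arithmetic is
exact (ΔΔCt closed forms, duplex hand scores); otherwise stated absolute
tolerances (10⁻⁹ for normalization exactness, 10⁻¹² for TOM/enrichment
oracles, 10⁻¹⁰ for the ANOVA cross-check).

## Known limitations

* Exact-substring matching (catalogue, transcriptome, ncRNA) tolerates
  no variants; real pipelines allow mismatched BLAST hits.
* The stem walk handles one anchor helix; maturas spanning a multiloop
  arm are rejected rather than scored.
* The unsigned network cannot separate anti-correlated modules; a signed
  variant would, but is not what the original analysis used.
* p ≤ 0.05 on raw p-values is the upstream rule and is kept as the
  significance flag; q-values are emitted for readers who want control
  of the false discovery rate.
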