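# lilimir

Small-RNA miRNA discovery, differential expression, degradome target
validation and coexpression-module mining for a multi-stage plant
development study — with a synthetic-data generator that makes the whole
pipeline testable end to end.

## The problem

Plant developmental transitions (juvenile → adult → flowering) are
steered by small regulatory RNAs: miR156 silences *SPL* transcription
factors and fades with age, while miR172 rises and silences *AP2*-like
floral repressors.  A typical study sequences small-RNA libraries across
developmental stages, identifies conserved and novel miRNAs, calls
stage-dependent expression, confirms targets by degradome (PARE)
sequencing, and mines coexpression modules.  `lilimir` implements that
computational chain for species without a reference genome, working from
a transcriptome assembly:

1. **Read triage** — 3′-adapter trimming (leftmost ≥6-nt prefix match,
   ≤1 mismatch), poly-N and quality filters, 18–25 nt length gates, and
   exact-substring rRNA/tRNA/snoRNA/snRNA/repeat annotation; every read
   lands in exactly one class, and class totals always sum to the raw
   read count.
2. **miRNA identification** — tags matching catalogue precursors near
   the annotated mature position are classified into group 1 (tag and
   precursor in the transcriptome), group 2 (tag only) or group 3
   (catalogue only).  Unannotated transcriptome-mapped tags seed novel
   precursor candidates (±150 nt windows), which are folded (ViennaRNA)
   and accepted when the stem-loop satisfies the standard criteria: a
   single stem bulge ≤ 12 nt (≤ 4 nt in the mature region), ≥ 16 base
   pairs in the mature-bearing stem, ≤ 2 unpaired mature nucleotides,
   ≤ 2 asymmetric ("biased") nucleotides per mature-region bulge, and a
   mature clear of the terminal loop.
3. **Differential expression** — counts are normalized by the
   median-reference regression scheme: each sample's log₂ counts are
   regressed on the reference (per-sequence median over samples) using
   only sequences with |ΔLog₂| < 2, and the fitted line is inverted to
   give "expected Log₂(copy#)".  A per-miRNA one-way ANOVA across stages
   flags p ≤ 0.05 (BH q-values reported alongside); significant profiles
   are clustered (average linkage, correlation distance).  A 2^−ΔΔCt
   utility covers qPCR validation tables.
4. **Degradome validation** — candidate binding sites are scored with
   the classic plant penalty scheme (mismatch 1, G:U wobble 0.5, 1-nt
   bulge 1, doubled at miRNA positions 2–13, threshold ≤ 4); a site is
   validated when degradome tag 5′ ends pile up on the transcript
   nucleotide opposite miRNA position 10, and classified into evidence
   categories 0–4 by the signal's rank against the transcript's maximum
   and median.
5. **Coexpression network** — unsigned WGCNA-style adjacency
   (|cor|^β, β = 12 by default, scale-free scan included), topological
   overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
   average-linkage module detection with eigengene merging, subnetwork
   export around DE miRNAs, miRNA–target anticorrelation, and exact
   hypergeometric term enrichment.

Real studies of this kind rest on raw sequencing archives and unpublished
transcriptome assemblies, so the package ships a first-class
**synthetic study generator**
(`lilimir.simulate`): 5 stages × 3 replicates, miR156-like decreasing and
miR172-like increasing trajectories over flat nulls, hairpin precursors
planted in transcripts (verified with the same evaluator used for
discovery), single-violation decoy hairpins, contaminants, junk and
low-quality reads, degradome tags with category-controlled signal, and
truth tables for every planted effect.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/02_preprocess_libraries.py
python analysis/03_identify_mirnas.py
python analysis/04_differential_expression.py
python analysis/05_degradome_targets.py
python analysis/06_coexpression_network.py
```

Output from a run at seed 1:

```
307100 raw reads -> 252208 valid (82.1%); 18913 unique tags
modal valid-read length: 24 nt
40 catalogue miRNAs in 15 families; groups: {1: 30, 2: 5, 3: 5}
10 novel miRNAs: mature 19-24 nt, hairpins 70-80 nt, MFE -75.2 to -56.4 kcal/mol
11 significant miRNAs (p <= 0.05); 11/11 planted effects found
15 validated cleavage sites; categories: {0: 3, 1: 3, 2: 3, 3: 3, 4: 3}
15/15 planted sites recovered at the exact position with the intended category
modules: {'grey': 39, 'turquoise': 11}
DE subnetwork: 56 edges; top hub: miR156a
15/15 miRNA-target pairs negatively correlated
top enriched term: GO:0009409 (p=1.51e-16, q=2.11e-15)
```

Reading this: 82% of simulated reads survive triage with the modal valid
length at 24 nt (as in real plant sRNA libraries); all planted known,
novel and differentially expressed miRNAs are recovered with no decoy
passing the hairpin filter; every planted cleavage site is confirmed at
the exact coordinate with its intended evidence category; the ageing-
pathway miRNAs form the single non-grey coexpression module with miR156a
as the best-connected hub; and the cold-response term planted on the
target transcripts tops the enrichment table.

The same stages are exposed as a CLI (`lilimir simulate / preprocess /
identify / de / ddct / degradome / network / enrich`) over files on
disk; `analysis/` drives them as a library.

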