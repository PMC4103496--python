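# Methods

## Scope and model

`flanklift` translates heterozygous SNV coordinates between two diverged
genome assemblies by local alignment of variant-centred flank queries,
and corroborates genotypes at the translated positions. It consumes
genotypes as single-sample VCF; read mapping and variant calling are
upstream of the package. The procedure assumes the two assemblies are
diverged but alignable in conserved regions (on the order of 1–5% local
divergence); outside such regions flank queries simply fail the identity
filter and the site is reported untranslated rather than mistranslated.

Coordinates are 0-based half-open internally; 1-based VCF positions are
converted at I/O boundaries only.

## Flank queries

For a variant at 1-based position *x* with flank width *f* (default
100), the query is `s[x−1−f : x+f]`, nominally `2f+1 = 201` bases with
the variant at offset *f*. At contig ends the window is truncated, never
padded, and the truncation is recorded; the coverage filter below keeps
the fixed 201-base denominator regardless, so a truncated flank must
align nearly end-to-end to survive. N bases are retained and never match
anything during alignment.

## Alignment

Two routes share one affine-gap Smith–Waterman cell engine (a
numba-compiled kernel; its best local score is cross-checked against
Biopython's `PairwiseAligner` in the test suite):

- **Exhaustive route** (`smith_waterman`): fills the full DP matrix over
  the whole target for both strands and reports every distinct local
  alignment with score ≥ `min_score` by Waterman–Eggert iteration (emit
  the best alignment, mask its target span so masked bases match
  nothing, repeat). Intended for modest targets; the matrix is
  materialised in memory.
- **Seeded route** (`find_hsps`): indexes the target's exact k-mers
  (default k = 11), looks up seeds of the query and of its reverse
  complement, merges hits into candidate windows (window = hit position
  ± query length + 50 bp, overlapping windows merged), and runs the same
  masking iteration inside each window. An index can be prebuilt once
  per target genome and reused across a whole VCF.

Scoring defaults: match +1, mismatch −1, gap of length *L* costs
`gap_open + L·gap_extend` with open = extend = 1. The penalties are
deliberately mild: with a length-1 gap costing 3 or more, a gapped
alignment whose prefix score dips to zero is truncated by the
Smith–Waterman zero-reset, and short flank alignments spanning a single
indel break in two. All scoring parameters are exposed on `AlignParams`.

Determinism and tie-breaks: within a DP cell, diagonal moves are
preferred over vertical over horizontal (fewer gap columns); among
equal-score end cells the longer alignment (larger i+j) wins, then
row-major order; among equal-score alignments across strands, plus
strand first, then leftmost target start. Minus-strand alignments are
computed on the reverse-complemented query and reported in forward
target coordinates with a strand flag; a minus-strand block maps query
position `q+i` to target `t + (len−1−i)`.

## HSP acceptance and uniqueness

An HSP survives iff

1. it contains the variant offset within its aligned query span;
2. its aligned query span covers ≥ `min_query_cover` (default 0.50) of
   the **nominal** 201 bases — so ≥ 101 aligned query positions;
3. its gap-inclusive identity `matches / (matches + mismatches +
   gap_columns)` is ≥ `min_identity` (default 0.90, inclusive).

Containment is tested on the aligned query span; whether the exact
variant column is aligned is resolved at projection time, where a
variant falling between blocks (a target-side gap) yields the distinct
`gap_at_variant` status instead of a coordinate. A site is translated
only when **exactly one** HSP survives; zero and multiple survivors are
terminal statuses (`no_hsp`, `multiple_hsp`). Multi-mapping flanks are
the signature of paralogous target regions, which would otherwise
manufacture false heterozygotes. A unique HSP landing on an excluded
target contig (default `{chrX, X}`, configurable — assemblies differ in
naming) gives `target_excluded_contig`.

Repeat filtering applies to the source side only (tested at the
variant's anchor position against BED or UCSC `nestedRepeats`
annotations); target-side repeat filtering is not applied, matching the
study design the package automates, but the same machinery can be run on
the lifted VCF if wanted. Indel records are read and classified but not
lifted: the procedure centres a single variant base in the flank query,
and projecting an allele span through a gapped alignment is
underdetermined. Only heterozygous SNVs are lifted by default;
`het_only=False` lifts homozygous sites too, e.g. for interspecies
catalogues.

## Corroboration and concordance

A translated site is corroborated when the target-assembly genotype is
heterozygous with exactly the strand-adjusted allele pair (alleles are
complemented, as an unordered pair, on minus-strand mappings). The
looser reading — any heterozygous call corroborates — is available as
`het_only`; both modes are tested, and homozygous or missing target
calls never corroborate in either. The corroboration rate is
`corroborated / translated`, reported to one decimal, and undefined
(absent) when nothing translated.

Array concordance normalises both call tables to the Illumina top
strand: C/T → A/G and G/T → A/C; A/C and A/G are unchanged. The
complement-invariant sets A/T and C/G cannot be oriented from the
genotype alone and are routed to no-call, as are missing genotypes;
homozygous calls are left as-is (against a heterozygous pipeline call
they are discordant under either orientation, so orientation cannot
change the verdict). Concordance is allele-set equality over the
remaining shared sites, reported to two decimals. The minimal PED/MAP
reader accepts one individual, 3- or 4-column MAP rows, and `0` as the
missing-allele marker.

## Synthetic data generator

The simulator emulates the study design: one i.i.d. ancestor (default
200 kb, GC 0.42) evolved down two independent branches — not one genome
mutated into the other — so that pairwise divergence at orthologous
columns is `1 − (1 − p)²` for per-branch substitution rate *p*. Defaults
are the validation conditions used throughout: p = 0.0075 (≈1.5%
pairwise, representative of conserved regions between species diverged
tens of millions of years), indel rate 0.0005 per base with geometric
lengths of mean 2, 5% inserted repeat content (300 bp motif copies at 2%
within-family divergence, recorded in a truth BED), optional block
inversions, and 500 planted heterozygotes with zero genotype error.
Every transformation carries an exact base-level coordinate map, and the
composed A↔B orthology map (positions plus relative strand) is the
ground truth the pipeline is scored against; its self-consistency is
checked by recomputing the observed mismatch fraction from the map.

Paralog duplications — the artifact that produces false heterozygotes in
real cross-species mappings — are applied to the target branch only:
segments (default 2 kb at 2% divergence) are duplicated and appended at
the end of the target contig, which leaves the orthology map untouched
and, because paralog draws come last in the branch's random stream,
keeps a paralog run otherwise byte-identical to its baseline. That makes
the paralog stress test a site-for-site comparison.

Het sites are sampled without replacement from mapped positions whose
±100 bp window is gap-free and collinear (the guard is configurable and
can be disabled to stress projection through gaps); inserted repeats are
unmapped by construction, so planted sites are automatically outside
repeats. The target-side genotype VCF reports the strand-adjusted allele
pair at the true coordinate; a configurable error rate corrupts calls to
homozygotes or no-calls, half each in expectation.

What the generator does **not** model: read-level noise (coverage,
mapping quality, genotype likelihoods), context-dependent substitution
matrices, large-scale rearrangements other than inversions, and
assembly gaps. Passing tests therefore demonstrate the correctness of
coordinate translation and genotype bookkeeping under clean calls — not
the error profile of a real cross-species mapping, where corroboration
rates are much lower for reasons upstream of this package.

## Validation and problem sizes

The test suite validates each stage against independent references:
brute-force interval scans, Biopython alignment scores, binomial bounds
on simulator statistics, and the exhaustive aligner as reference for
the seeded search (200 random instances ≤ 2 kb with 1–3 diverged copies
on both strands, compared after identical filtering). Pipeline-level
checks use a 100 kb self-liftover (every unique-flank het must map to
itself on the plus strand), the 200 kb / 500-het recovery run (≥90%
of sites must translate to the exact true coordinate; corroboration
over correctly translated sites must be 100% at zero genotype error),
and a 60 kb paralog stress pair. These sizes keep the whole suite to a
few minutes on one CPU while leaving hundreds of base-level events per
property; all seeds are fixed in the tests, and `scripts/acceptance.py`
derives every sub-seed from its `--seed` argument.

## Known limitations

- Uniqueness is judged after filtering; two passing HSPs always drop a
  site even when one scores far higher (faithful to the "exactly one"
  rule, with the strictness documented rather than configurable away).
- The seeded route can only find HSPs containing at least one exact
  k-mer match; at the default k = 11 this is guaranteed only for flanks
  within a few percent divergence of their ortholog — the regime the
  identity filter accepts anyway — but adversarially spaced mismatches
  could evade seeding while passing 90% identity.
- Indel projection, multi-sample VCFs, phased genotypes, and chain-file
  interchange are out of scope.
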