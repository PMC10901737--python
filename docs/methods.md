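# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open (the BED convention).
Coordinates printed in the genomics literature as 1-based fully closed
intervals are converted at the I/O boundary
(`GenomicInterval.from_one_based_closed`); e.g. the printed insertion
interval chr17:8,439,335–8,439,554 converts to [8439334, 8439554), width
220 bp. MAF `s` lines natively carry start + size and are stored as parsed;
negative-strand rows are kept as written (already reverse-complemented by
the aligner), and every reported variant coordinate is on the reference
assembly's forward strand. The MAF reader is a small hand-written parser:
it must report the offending line number on malformed input and round-trip
byte-stably, and no installed library offers both. A species appearing twice
in one block is a format error, not a merge.

## Ingroup consensus and variant-calling rules

The species panel is a six-assembly hominoid ingroup (hg38 is the reference)
and two tailed outgroups. "Consensus" is defined as unanimity over a
complete ingroup: a column yields a base only when every ingroup species is
present and agrees; any absence, N, or disagreement yields N. A majority
mode exists behind a flag but is not used by the calling rules, which all
require the full ingroup to share the allele anyway.

Column verdicts:

* SNV — ingroup unanimous base differing from ≥1 outgroup base
  (`any-differs`; `both-differ` optional). "Absent in either outgroup" for
  insertions is read as *at least one* (`any-absent`), mirroring the SNV
  rule's "any"; `both-absent` is the strict alternative. Deletions always
  require both outgroups present.
* Columns with N in any decisive species are never called (no imputation).
* When the two outgroups disagree with each other the call is kept but
  flagged `ambiguous_outgroup`: it may be an outgroup-branch change rather
  than an ingroup-specific one.

Indel runs merge maximally: consecutive insertion columns merge only while
the per-outgroup absence pattern is identical, and a single interrupting
column breaks the run (no gap-tolerant merging — the simplest faithful
reading of "DNA sequences present/absent"). Deletions are reported as
width-0 anchors between the two flanking reference bases, with the outgroup
segment recorded, because the deleted sequence has no reference coordinates.
Gene regions are widened by `flank_bp` (default 10,000 bp) on both sides;
overlapping widened regions are de-duplicated before global counting, so a
variant counts once globally and once per gene in the per-gene table.

## Transcript selection and consequences

"Longest transcript with the most exons" is resolved with exon count as the
primary key, spliced length secondary, and transcript id as a deterministic
tie-break. Consequences are computed inversely to ordinary variant calling —
the hominoid reference base is the reference allele and the outgroup base
the alternate — because no ancestral genome is available. When the two
outgroups disagree, the first outgroup base differing from the ingroup
allele serves as the alternate (such sites already carry the ambiguity
flag).

The splice-region window is fixed at 2 intronic bp from each exon boundary
(the canonical donor/acceptor dinucleotides) and takes precedence over any
coding class. CDS SNVs are translated strand-aware with the standard genetic
code; CDS indels are in-frame iff the length hitting coding sequence is
divisible by 3 (deletions use the lost outgroup-segment length; multi-exon
deletions sum their CDS overlap). SIFT and PolyPhen are consumed as input
annotations with strict thresholds (SIFT < 0.05, PolyPhen > 0.446);
re-deriving those predictors is out of scope. Protein-altering indels pass
the damaging filter unconditionally. Triage applies the three recurring
false-positive categories in a fixed order, first match wins:
outgroup-specific change → consequence only on a minor transcript → amino
acid shared with at least one tailed species → otherwise candidate. The
underlying manual inspection across a 241-species alignment is human
judgement; only its output categories are encoded.

## Stem-pair scanning

Candidate pairs are two repeats annotated on opposite strands, each fully
contained in an intron of the transcript, with the upstream member's intron
strictly 5′ (transcript orientation) of the downstream member's. Orientation
comes from the annotation (RepeatMasker-style BED), not from sequence
inference. Pairs across non-adjacent introns are allowed, so more than one
exon can be trapped.

*Inner distance* is the gap from the end of the genomically earlier repeat
to the start of the later one — the only convention that gives 0 for
abutting repeats. *Stem identity* globally aligns the upstream repeat
against the reverse complement of the downstream repeat (match +1,
mismatch −1, gap −2) and reports the **maximum number of identical aligned
positions achievable by any optimal-score alignment** over the shorter
sequence's length. The lexicographic (score, identities) dynamic programme
makes the quantity well defined despite co-optimal alignments, so an
independent oracle can check it exactly. A `gapless=True` mode reports the
plain position-wise match count, under which a 297-bp stem with exactly 69
substituted positions scores exactly 228/297; with gaps permitted,
score-tied alignments can trade two mismatches plus two gaps for two
matches, and the same construction reports 230.

Numerical caveat: under the gapped definition, *unrelated* ~200–300-bp
sequences plateau near 0.59–0.70 identity, so the default
`min_identity_fraction = 0.6` admits essentially any opposite-strand pair
within range. Scans meant to report only genuine stems should raise the
threshold to ≥ 0.8 (Alu–Alu pairs and planted pairs sit well above it); the
recovery tests do exactly that.

The ranking score, identity_fraction × exp(−inner_distance/λ) with
λ = 2,000 bp, is an invented, configurable heuristic encoding only the
qualitative kinetic argument that a proximal stem can fold during
transcription before a distal one exists. No minimum-free-energy folding is
performed — the stem identity stands in for it by design. Frame effect:
skipping is in-frame iff the trapped exons' summed CDS length is divisible
by 3; trapped exons with no CDS contribute zero and a wholly non-coding
skip is reported in-frame with a flag.

## Cross statistics

"Affected" = any of {no tail, short tail, kinked tail}; long-tailed animals
are unaffected. Penetrance intervals are exact two-sided Clopper–Pearson at
95% (scipy's `binomtest(...).proportion_ci(method="exact")`) because several
observed cells sit at 0% or 100%, where the normal approximation collapses;
zero-total rows return an undefined marker with the vacuous [0, 1] interval.
Expected offspring proportions come from the Punnett square of two biallelic
parents, computed before viability selection — deviation from them (missing
homozygotes, under-represented compound heterozygotes) is precisely what the
chi-square ratio test (Σ(O−E)²/E, df = k−1) measures. Runt/death
annotations are carried in a supplementary column and never added to
phenotype totals, since the published tables count those animals inside the
no-tail cells. The published count tables ship with the package as TSVs
(genotype labels ASCII-ized: `dexon6` for the exon-6 deletion allele).

## Synthetic data

`simulate_alignment` plants ingroup-specific variants on a uniformly random
ancestral sequence: SNVs alter the outgroup base(s) per an outgroup pattern
(`both`, or one outgroup only — which the screen then calls as ambiguous),
insertions gap the outgroups over the run, deletions insert extra alignment
columns gapped across the whole ingroup. Background divergence, when
enabled, applies independently per outgroup branch only, and never inside a
planted footprint, so planted hominoid-specific features remain the only
ingroup-shared signal and calls are a superset of the planted truth.
Planted variants keep ≥ 2 bp of clearance so independently planted indel
runs cannot merge. There is no substitution-model realism (no
transition/transversion bias, no rate variation) and no indel length
distribution beyond the planted lengths — recovery results on this
generator demonstrate correctness of the calling logic, not performance on
real alignments with alignment error, paralogy, or missing rows.

`simulate_locus` defaults to a five-exon gene whose 117-bp middle exon makes
the single-exon skip frame-preserving (and a 117+91 double skip not), with a
planted 297-bp pair at 1,448 bp inner distance — the geometry of the studied
locus. The downstream repeat is written as the reverse complement of the
upstream one with the requested number of substitutions, forcing the gapless
stem identity to length − substitutions. Placement is deterministic given
the spec; only sequence content and substitution positions are random.
Substitution positions are sampled uniformly without replacement.

`simulate_cross` draws offspring genotypes from the Punnett proportions and
phenotypes from per-genotype penetrance and category mix. Every generator
uses a single `numpy.random.default_rng(seed)` stream; identical seeds give
byte-identical outputs.

## Problem sizes and verification

The test suite verifies each operation against an independent oracle:
column classification against a brute-force restatement on 10,000+ random
columns; stem identity against exhaustive alignment enumeration (lengths
≤ 6) and an independent memoized recursion (lengths ≤ 12); consequence
classes against a rebuild-and-translate oracle exhaustively over a toy CDS;
Clopper–Pearson bounds against statsmodels' beta-method intervals; the
chi-square examples against hand computation. Screen recovery is checked at
120 kb with 210 planted variants of each class (exact set equality between
calls and truth), and cross-simulation coverage with 100 replicates of
n = 10,000 offspring. These sizes were chosen to characterize the methods
well while keeping the full suite under ten seconds.

## Known limitations

* Published full-scale screen counts require the Multiz30way alignment of
  27 primates and are not recomputed here.
* The stem-identity proxy ignores RNA thermodynamics (G·U pairs, bulge
  energetics, co-transcriptional folding kinetics).
* The triage of residues across tailed species encodes the decision rule
  only; building the cross-species residue table is up to the caller.
* Splicing efficiency is not modelled; frame prediction says what the
  skipped transcript would encode, not how much of it is made.
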