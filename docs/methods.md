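# Methods

This note documents the models, parameter choices and numerical
conventions behind `apa3seq`, and what the synthetic-data tests do and do
not demonstrate about real 3'-Seq libraries.

## Coordinate and orientation conventions

All in-memory coordinates are 0-based, half-open, on the genome forward
strand; conversions to 1-based formats (SAM, WIG) happen only at file
boundaries. Read sequences are always handled in *transcript-sense*
orientation: the 3' terminus of the stored sequence is the poly(A)-proximal
end regardless of genomic strand, which keeps tail detection strand-agnostic.
For minus-strand reads the writer reverse-complements into genome
orientation when emitting SAM, and the reader undoes it. A cleavage
position is the genomic coordinate of the *first untemplated base*; on the
minus strand this is the base immediately left (genomically) of the aligned
templated span.

## Tail detection and the internal-priming filter

A read yields cleavage evidence iff its maximal terminal A-run is ≥ 8 nt
long and ≥ 5 of the run's first 8 bases mismatch the reference at the
corresponding transcript-sense positions. Choices within that rule:

- Only the *terminal* maximal A-run is considered; interior A-runs are
  ignored, since the library chemistry places the tail at the 3' terminus.
- The run may extend backwards into the aligned span (genomic As adjacent
  to the cleavage point join the run); the mismatch test then naturally
  discounts them, which is exactly how internal-priming artifacts — whose
  run is entirely templated — fail with 0 mismatches.
- A reference `N` counts as a mismatch. This is conservative in the
  direction of *accepting* tails over unsequenced reference, and never
  converts a templated run into an artifact call.

## Site calling

The per-sample profiles (position → evidence count) are pooled over all
samples before site identification; per-sample quantification happens at
the peak stage. Site calling has three deliberately pinned-down rules
where prose leaves room:

- **Local maximum**: a position whose pooled count is ≥ every neighbour
  within ± 50 nt; on plateaus (equal counts) only the 5'-most position
  (strand-aware) survives. This makes the candidate set deterministic.
- **Spacing conflicts** (< 50 nt) are resolved greedily in descending
  support order, ties again 5'-most first.
- **Support**: each evidence record is assigned to the nearest surviving
  candidate within ± 25 nt (half the minimum spacing), and candidates with
  pooled support < 10 reads are dropped. Counting only reads at the exact
  modal position would systematically undercount sites whose cleavage
  scatters over a few nucleotides — the observed behaviour of real
  libraries the generator emulates — so support means "reads assigned to
  this site", not "reads at this exact base". Evidence farther than 25 nt
  from every surviving candidate stays unassigned; consequently the sum of
  per-sample supports never exceeds the evidence count.

Region annotation extends each annotated 3' UTR by 1,000 nt downstream in
transcript orientation, and resolves overlaps by priority
utr3 > intron > cds > intergenic — maximizing sensitivity for the two
region classes the downstream statistics use.

## Peaks and quantification

Bins are 5 nt wide and anchored at genomic coordinate 0, so bin boundaries
are identical across runs and samples. Peak candidates are maximal runs of
*non-empty* bins, kept when the run's maximum (across-sample max) bin count
is ≥ 3; this reading keeps weak shoulders attached to strong sites rather
than fragmenting them. Merging of peaks closer than 60 nt is transitive.

Peak levels count *inferred cleavage positions* (from tail evidence) inside
the half-open peak interval, not raw alignment starts; cleavage positions
are the quantity whose usage the statistics test, and this makes E_j
directly interpretable as CS usage. Binning raw alignment starts instead is
available behind `quantify_mode="start"` for comparison. Levels are raw
counts — the chi-square contingency design absorbs library-size differences
through its column margins, and no additional scaling is applied.

Sites link to the peak containing them, or the nearest within 30 nt;
unlinked sites are excluded from transcript tests (and logged). Ordinals
j = 1..N run 5'→3' in transcript orientation over a transcript's 3'-UTR
peaks.

## Statistics

- **Chi-square**: Pearson, no continuity correction, expected cells from
  row/column margins. Tables with an empty margin are untestable and
  skipped with a diagnostic rather than patched. Cutoff p < 0.001 on raw
  p-values (no multiple-testing correction by default, matching the
  protocol; Benjamini–Hochberg can be applied downstream by the caller).
- **Weighted CS index** ⟨CS_J⟩ = Σ w_j·j with w_j normalized to sum 1;
  a significant test with strictly lower ⟨CS_J⟩ in the proliferative
  condition is "shortened". Equal indices under significance yield
  direction "none" with a warning.
- **PUI**: PUI_j = log2(E_j/⟨E⟩) with ⟨E⟩ the geometric mean after adding
  a pseudocount (default 1) to every level — required whenever a peak has
  zero reads in one condition. ΣPUI_j = 0 to machine precision by
  construction. The *proximal* PUI is the value at ordinal j = 1.
- **Binomial direction tails** are one-sided upper tails P(X ≥ k) at
  p = 1/2, accumulated by `logsumexp` over log-pmf terms so tails far
  below 1e-300 keep a finite log10 p instead of underflowing.
- **Rank-sum tests** are exact (enumeration) for pooled n ≤ 25 without
  ties, otherwise normal approximation with continuity and tie correction;
  an all-equal pooled sample returns p = 1 directly.
- **Cross-system core set**: transcripts significant in both systems with
  agreeing direction; enrichment is the upper binomial tail of the
  consistent-shortened count against the larger single-system shortened
  fraction.
- **Quantile normalization** replaces each column by the mean-of-sorted
  profile at its within-column rank, with average-rank interpolation for
  ties (default). With ties present the sorted columns agree only up to
  the interpolation — the same trade-off as `limma::normalizeQuantiles`;
  `ties="first"` restores exact column identity at the cost of arbitrary
  tie ordering. The expression floor of 5 reads is applied *after*
  normalization: its purpose is to protect later ratios from division by
  zero, so it must bind last.

## The synthetic generator

The generator emulates the features of a 3'-Seq library the pipeline must
survive; its defaults are the standard study conditions used throughout
the tests:

| parameter | default | meaning |
|---|---|---|
| `n_transcripts` | 300 | transcripts, 50 per chromosome, both strands |
| `depth_per_transcript` | 200 | reads per transcript per condition |
| `n_cs_per_transcript` | 2 | 3'-UTR CS loci per transcript (1–3 supported) |
| `jitter_sd` | 2 nt | truncated-normal (±3σ), rounded cleavage scatter |
| `tail_length` | 8 + Poisson(4) | untemplated tail, always ≥ the 8-A floor |
| `internal_priming_rate` | 0.1 | artifact reads in bait-carrying transcripts |
| `internal_priming_bait_fraction` | 0.3 | transcripts carrying a 12-A tract |
| `body_read_fraction` | 0.2 | tail-less transcript-body reads |
| `error_rate` | 0.005 | per-base substitutions on templated sequence |
| `shifted_fraction` | 1/3 | transcripts with proximal weight 0.7 vs 0.3 |
| `proximal_weight_null` | 0.5 | proximal weight of unshifted transcripts |
| `intronic_fraction` | 0.15 | transcripts with an intronic CS locus |
| `intronic_weight` | (0.25, 0.10) | intronic usage per condition |
| `extension_fraction` | 0.1 | distal CS placed 300 nt past the annotated end |
| `cell_cycle_fraction` / boost | 0.10 / 4× | expression boost in condition 1 |
| `processing_fraction` / boost | 0.05 / 2× | 3'-end-machinery gene set |

Every transcript occupies a fixed 6-kb slot with a uniform local layout
(two exons flanking one intron, 3' UTR at the 3' end of the second exon),
which keeps read simulation splice-free: all simulated reads are
contiguous on the genome, so a minimal all-match SAM representation is
exact. The cleavage scatter width is not an empirically known constant;
2 nt is the package's choice and is exposed in the config.

Two deliberate cleanups make ground-truth scoring exact rather than
probabilistic: random A/T homopolymers in background sequence are capped
at 6 nt (so the only templated pseudo-tails are the planted baits), and
the 24 nt around each planted cleavage locus contain no As (so a genuine
tail there can never be mistaken for a templated run, even after jitter).
Sequencing errors are applied to templated sequence only; errors inside
the homopolymer tail are not modelled.

What passing tests therefore show: the pipeline's rules are implemented
correctly and recover a *clean but noisy* ground truth (jitter, sampling
noise, substitution errors, artifact and body reads, both strands,
intronic and annotation-extended sites). What they do not show: behaviour
on spliced alignments, multimappers, A-rich *untemplated-looking* genomic
context near real CSs, sequencing-quality artifacts, adapter read-through,
or real annotation complexity (overlapping genes, many isoforms per gene).
Dataset-scale counts from deep libraries (tens of thousands of sites) are
likewise out of reach at the bundled problem sizes.

## Problem sizes and determinism

The standard validation run uses 300 transcripts × 2 conditions × 200
reads (~140k reads, ~1.8 Mb of genome across 6 chromosomes) and completes
in seconds; the monotonicity check uses ten 30-transcript runs. All
randomness flows from a single integer seed through independent
`numpy` `default_rng` streams per stage (planning, sequence, reads);
identical config + seed reproduces every artifact byte for byte.

## Known limitations

- One sample per condition; replicate columns in the contingency design
  are supported by the statistics (C ≥ 2 columns) but not by the
  orchestration layer's config schema.
- The generator's transcript architecture is deliberately uniform; it is
  ground truth for rule verification, not a realistic genome model.
- Peak levels are raw counts; strongly unequal library sizes shift the
  chi-square's power between conditions (the test stays valid, the effect
  size estimate ⟨CS_J⟩ per condition is unaffected since it normalizes
  within condition).
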