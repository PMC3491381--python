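# apa3seq

Cleavage-site calling and differential alternative-polyadenylation (APA)
analysis for 3'-end sequencing (3'-Seq) data.

Most mammalian genes carry several poly(A) cleavage sites (CSs), so the
same gene can produce mRNA isoforms with longer or shorter 3' UTRs — or
truncated, intronic-CS isoforms. Because 3' UTRs hold most miRNA and
RBP regulatory elements, a global shift toward proximal CSs (3' UTR
shortening) changes post-transcriptional regulation genome-wide, and is a
hallmark of proliferating and transformed cells. `apa3seq` is for
computational biologists who have 3'-Seq libraries (oligo-dT-anchored
reads spanning the cleavage site) aligned to a genome and want to:

1. call poly(A) CSs from reads carrying untemplated poly(A) tails, while
   rejecting internal-priming artifacts from genomically A-rich tracts;
2. quantify per-sample CS usage as binned read peaks;
3. test each multi-CS transcript for condition-dependent usage shifts and
   summarize global 3'-UTR shortening and proliferation statistics.

A fully seeded synthetic 3'-Seq generator with ground truth is part of the
package, so the entire pipeline is testable without external data.

## Method

**Tail detection / internal-priming filter.** A read supports a cleavage
call iff its transcript-sense 3' terminus ends in a maximal A-run of
length ≥ 8 with at least 5 of the first 8 As mismatching the reference.
The cleavage position is the genomic position of the run's first base.
Templated A-runs (internal oligo-dT priming) match the reference and are
rejected.

**Site calling.** Per-position tallies of tail evidence form CS profiles;
sites are profile local maxima with a minimum spacing of 50 nt (the
stronger candidate wins a conflict) and pooled support ≥ 10 reads.
Sites are annotated utr3 / intron / cds / intergenic against transcript
models whose 3' UTRs are extended 1,000 nt downstream.

**Peaks.** Chromosomes are split into 5-nt bins; per-bin counts are
reduced to the maximum over samples, runs of non-empty bins with max ≥ 3
reads become peaks, and peaks closer than 60 nt are merged. Peak levels
E_j (per-sample counts within the peak) are the usage quantities.

**Statistics.** For each transcript with ≥ 2 3'-UTR CSs, the peaks ×
conditions count table is tested by Pearson chi-square (cutoff
p < 0.001). Shift direction uses the coverage-weighted mean CS ordinal

    ⟨CS_J⟩ = Σ_j w_j · j,   w_j = E_j / Σ_k E_k,

which decreases under 3'-UTR shortening. Per-site relative usage is the
poly(A) site usage index

    PUI_j = log2(E_j / ⟨E⟩),   ⟨E⟩ = geometric mean of E_1..E_N,

whose proximal (j = 1) median over transcripts is the global shortening
measure. Direction imbalances get an upper binomial tail at p = 1/2;
gene expression is 3'-UTR read counts, quantile-normalized and floored at
5 reads; the proliferation index is log2(median cell-cycle-gene
expression / overall median); gene-set expression shifts use a two-sample
rank-sum test.

## Worked example

```python
from apa3seq import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    outdir="demo_run", seed=7,
    simulate={"n_transcripts": 60},   # 60 transcripts, 200 reads/cond each
))
```

The summary (also written to `demo_run/summary.json`, next to the BED /
TSV / SAM / FASTA artifacts of every stage) contains:

```
sites_by_region       total 129  (utr3 120, intron 9)
proximal_pui_median   proliferating +0.065   arrested -0.037
apa_shift             60 multi-CS transcripts tested, 20 significant,
                      k_shortened 20, binomial_p 9.5e-07
intronic_shift        9 tested, 6 significant, 6 toward intronic (p 0.016)
proliferation_index   proliferating +1.38    arrested -0.008
geneset_shift         processing_vs_background_p 0.023
```

Reading: of the 60 simulated transcripts, the 20 programmed to raise
proximal usage from 0.3 to 0.7 in the proliferating condition are all
flagged at p < 0.001 with direction "shortened"; the one-in-a-million
binomial tail says such a 20/20 imbalance cannot be a coin flip. The
median proximal PUI is higher in the proliferating condition (global
shortening), the planted cell-cycle expression boost yields a positive
proliferation index there, and the 3'-end-processing gene set shows a
significant expression shift against the background.

The same stages are available as a console tool:

```sh
apa3seq simulate --out sim --seed 7 --n-transcripts 60
apa3seq call-sites --reads-tsv sim/reads.tsv --genome sim/genome.fa \
    --models sim/models.tsv --out sites.bed
apa3seq run --config run.yaml
```

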