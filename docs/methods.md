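# Methods

`longamp` reconstructs near full-length (~1.4 kb) 16S rRNA gene sequences
from Illumina 2×250 paired-end reads of amplicons that were dual-tagged with
random 10-nt molecular tags (UMIs) before PCR. This note documents the model
each stage implements, the parameters that matter, what the simulator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## The tagging model

Each template molecule is extended once from each of two primers
(27F `AGAGTTTGATCMTGGCTCAG`, 1391R `GACGGGCGGTGTGTRCA`), attaching to each
end a synthetic construct:

```
[Illumina adapter][phaser 0–3 nt][sample barcode 8 nt][random tag 10 nt][gene primer][16S …]
```

With 4^10 ≈ 10^6 possible tags per end (~10^12 ordered pairs), each template
in a pool of a few thousand receives an essentially unique (tag_f, tag_r)
label before any amplification. Every read descending from that template
carries one of the two tags, which makes three things possible:

1. **grouping** all reads of one progenitor molecule for per-template
   assembly and consensus (errors arising after tagging average out);
2. **chimera detection**: a PCR template switch joins the 5′ part of one
   template to the 3′ part of another, producing a *novel* tag pair whose
   individual tags belong to other, more abundant groups;
3. **bias measurement**: every tagged template starts as one copy, so the
   spread of per-tag-pair read counts measures amplification bias directly.

Two fragment populations are sequenced together: full-length amplicons
(**end+end**, both tags readable, mates read the two synthetic ends) and
tagmentation products (**end+internal**, one tagged end plus a transposase
breakpoint inside the gene), pooled at ~7:1 so the interior of the gene is
covered.

## Stage-by-stage

### Demultiplexing (`demux`)

Each mate is tested against both end layouts. Phaser lengths are scanned
ascending (0→3); at each offset the 8-nt window must match **exactly one**
known barcode within 1 mismatch *and* the gene-primer annealing sequence
must follow the tag with ≤ 2 mismatches (IUPAC-aware, so the degenerate
M/R positions match their expansions; an `N` in a read never matches
anything). The primer screen exists because internal 16S sequence can
spuriously match a barcode. The same screen is applied to the single tagged
end of end+internal candidates.

Barcode sets must have minimum pairwise Hamming distance 3, which makes
1-mismatch decoding provably unambiguous; the sheet loader rejects sets
that violate this.

Pairs with one forward and one reverse parse are end+end; their ordered
barcode pair either names a sample or is an **invalid combination** — the
demux-level signal of in-vitro recombination (cross-sample template
switches during post-pooling PCR). Exactly one parse → end+internal;
two same-label parses are counted as anomalies and excluded, not guessed.

### Dual-tag clustering (`tag_cluster`)

Valid end+end pairs are reduced to a 64-nt composite
(tag_f + tag_r + bc_f + bc_r + 14 nt of gene sequence after each primer)
and clustered greedily at ≥ 0.89 Hamming identity (≤ 7/64 mismatches).
Unique composites are processed in canonical order (duplicate count
descending, then lexicographic), founding centroids greedily; consensus
(per-position plurality, ties broken A<C<G<T, `N` wins only strict
majorities) is then recomputed and every composite reassigned once against
the consensus list. The canonical order makes the result invariant to input
order; identity is alignment-free because all components are fixed-length
synthetic sequence. The threshold is applied to the composite (not each
10-nt tag separately): the clustered strings *are* the composites, and the
gene-prefix positions let true templates that collided in one tag still
separate. Both the threshold and the interpretation are configurable.

### Recombinant elimination (`chimera_filter`)

A cluster is discarded iff another cluster with **strictly** greater
abundance shares its consensus tag_f or tag_r (exact 10-mer match;
sequencing-error divergence was already absorbed by clustering).
Equal-abundance sharers are all kept — with no strictly more abundant
parent the direction of the switch cannot be inferred. Singleton clusters
are not auto-discarded; they fall only to the tag rule. The read-level
recombination rate is the discarded abundance over the end+end pool, and a
combined estimate adds the invalid-combination reads, since cross-sample
switches never reach clustering (their barcode pair is invalid).

### Binning (`binning`)

All reads — end+end and end+internal — are matched against the kept
consensus tags with unique-best-match semantics at a 1-mismatch budget
(mirroring the clustering radius): exact hits beat distance-1 hits, and two
equally close candidates leave the read unassigned rather than guessed.
End+end pairs must resolve both tags to the same cluster. Reads matching
only discarded clusters are dropped, not reassigned. End+internal reads
from chimeric fragments that inherited a kept tag are accepted here by
construction — they are indistinguishable — and handled by coverage-based
cleanup during assembly.

### Per-bin assembly (`assembly`)

Reads are first stripped of synthetic sequence (the parsed
phaser/barcode/tag/primer prefix; configured adapter stubs at the 3′ end,
exact then 1-mismatch, never discarding a read), quality-trimmed from the
3′ end by the BWA running-sum rule at Q20, oriented to the 27F→1391R strand
using the parsed ends as anchors (so the graph is single-stranded), and
dropped if shorter than 2k.

Error correction is spectrum-based: a base all of whose covering 31-mers
are weak (count < 3) is corrected iff exactly one substitution makes them
all solid, with at most 2 edits per read; ambiguous cases stay untouched.

Assembly is a forward-strand de Bruijn graph at k = 31 (the ~1.4 kb
amplicon has essentially no repeats at that k). Two solid-k-mer floors are
tried — the base floor (2; 1 for bins under 10 reads) and a depth-adaptive
floor of one tenth of the count-weighted median k-mer count — and the
attempt producing fewer contigs (ties: longer total reconstruction) wins.
The two floors exist because per-bin coverage is U-shaped (the tagged ends
appear in every end+end pair and every tagged fragment): deep bins need a
high floor to suppress coincident-error k-mers, while the mid-template dip
of shallow bins would be erased by it. Graph cleanup runs at most three
deterministic rounds: unconditional pruning of tips shorter than 2k;
pruning of read-length-scale tips when a ≥ 3× better-supported continuation
leaves their junction (the signature of contaminating chimeric fragments,
which form dead-end branches up to one read long); and popping of the
lower-coverage arm of short parallel bubbles (coincident identical
sequencing errors). Maximal unambiguous paths become contigs, with
per-base coverage from the k-mer counts.

Finally, contigs with mean coverage more than 10-fold below the
best-covered contig in the bin are removed (strictly: exactly 10-fold lower
is kept). This is the second line of defence against chimera-derived
sequence, which — riding on a minority of a bin's fragments — cannot reach
the dominant contig's coverage.

### Consensus and quality (`consensus_quality`)

Bin reads are mapped back to the kept contigs by best shared 15-mer offset
voting plus a substitutions-only comparison (band 0 — bins are
single-template, so true indels are absent); reads under 90% identity over
their overlap stay unmapped. The consensus base is the quality-weighted
plurality, and its PHRED score is

```
Q = min(93, max(0, Σ qualities agreeing − Σ qualities disagreeing))
```

capped at the FASTQ `~` limit. This additive model is declared, not derived
from any external tool: it is monotone in concordant coverage and yields
the qualitative behaviour reported for such data (scores far above raw read
quality, higher at the deeply covered ends). No claim of numerical
equivalence with any mpileup-based caller is made. Positions with no mapped
read fall back to the contig base at Q0.

### Run statistics (`run_stats`)

"Relative mean error" of amplification — the nonstandard term is read as
the coefficient of variation — is the sample (n−1) SD of kept end+end
cluster abundances over their mean (population SD via `ddof=0`), reported
with and without singleton clusters (possible residual recombinants).
Length summaries use a strict `> 1300 nt` full-length rule.

## The simulator

The generator emulates the protocol: random templates with concrete
primer-compatible termini (degeneracies resolved per template); one sample
barcode pair and two independent uniform-random tags per template
(collisions allowed — `unique_tags=True` draws without replacement);
lognormal per-template copy number `max(1, round(depth · LogNormal(0, σ)))`;
per-copy template switching at rate `r` with a uniform interior breakpoint
and tag/barcode inheritance from both parents; one end+end read pair per
molecule plus a size-selected (400–1,500 bp) tagmentation pool at a 7:1
read-pair ratio; substitution errors at a constant per-base rate; and a
position-decaying quality curve with integer jitter (clipped to 2–40).
Same config and seed give byte-identical output.

Defaults are the study conditions: σ = 1.27 (the CV ≈ 2 implied by the
reported relative mean error, giving the observed ~0.06–32× abundance
spread), r = 0.10, mean cluster abundance ≈ 9 (depth 4), 12 samples drawn
diagonally from two 25-barcode sets, 2×250 reads, 0.5% per-base error.

What it does **not** emulate — and therefore what green tests do not prove
about real data: indels and quality-correlated error placement; PCR errors
accumulating before/during tagging (flagged in the source protocol as
unmeasurable); primer-binding and GC bias (bias is a single lognormal
factor); tagmentation sequence preferences; cross-contamination of barcoded
primers. Real runs will also contain taxa whose 16S sequences are nearly
identical, which the simulator's independent random templates do not model.

## Numerical choices and degenerate inputs

* Ambiguity is never resolved arbitrarily: ambiguous barcode windows,
  equidistant tag matches, two-way correction candidates and
  equal-abundance tag sharers are all left as-is/unassigned/kept.
* Ties in consensus calling break by fixed base order A<C<G<T; `N` never
  wins a tie it is part of; `N` never counts as a match in any comparison.
* The clustering identity test uses `matches ≥ ceil(0.89·64) = 57`,
  avoiding float-boundary surprises.
* Coverage-filter boundary is strict: `cov × 10 < max` drops, equality
  keeps.
* Empty inputs: empty FASTQ pairs yield empty valid outputs; empty bins
  assemble to nothing; bias estimation requires ≥ 2 clusters and errors
  otherwise; rate denominators of zero raise.
* Exact reconstruction is defined as: one kept contig that is an exact
  substring of the true template and covers at least the complete
  inter-primer insert. Template position 0 is covered by no read under the
  trimming rule (tagged reads are trimmed through the primer; tagmentation
  breakpoints start at 1), so whole-template byte equality is impossible
  for any method; how far a contig reaches into the primer termini depends
  on the breakpoints sampled in that bin.

## Problem sizes used in tests and acceptance

The verification suite runs at desk scale, chosen so that each property is
a sharp statistical test rather than a capacity benchmark: the error-free
round trip uses 200 templates at ~150× tiling coverage (gap probability
< 10⁻⁵ per bin, so exact reconstruction of *every* bin is the expected
outcome, not a lucky one); chimera-rate recovery uses 1,000 templates at
the study-like σ = 1.27 and r = 0.10, compared against the 99% binomial
interval of r; bias recovery uses 1,000 clusters at σ = 0.5, where the
sample-CV estimator's relative standard error is ≈ 4.5%, making the 15%
acceptance band a ≈ 3-sigma check. At the study-like σ = 1.27 the CV
estimator is dominated by the lognormal's fourth moment (relative SE ≈ 50%
at n = 1,000), so no implementation could pass a 15% band there; the
smaller σ tests the estimator, not the tail. Round-trip and recovery runs
draw tags without replacement: exact tag collisions (birthday expectation
~1 per end at 1,000 templates) are a documented limitation of the tagging
scheme itself, exercised separately by the collision-statistics test.

## Known limitations

* Tag collisions merge or cross-contaminate bins; with uniform tags the
  effect grows quadratically in pool size. Distinguishing collisions from
  tag sequencing errors is out of scope.
* Same-sample chimeras whose parents are at equal or lower abundance are
  undetectable by the tag rule (~1% of chimeras under default conditions).
* The assembler handles single-template bins only; it is not a general
  metagenome assembler, and bins contaminated above ~30% foreign reads can
  still fragment.
* Consensus qualities are calibrated only in the ordinal sense; they are
  not probabilities validated against a mock community.
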