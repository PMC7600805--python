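# Methods

This note documents the models and procedures implemented in `numt_atlas`,
the parameters that matter, and the choices made where the underlying
methods left details open.

## Problem setting

Nuclear mitochondrial DNA sequences (NUMTs) arise when fragments of the
mitochondrial genome integrate into nuclear chromosomes, presumably at
double-strand breaks repaired by non-homologous end joining. After
integration a NUMT can be duplicated together with its flanking nuclear DNA
("duplicate type"), or fragmented by subsequent insertions — typically
transposable elements (TEs) — leaving a chain of co-oriented, syntenic
fragments ("complex NUMTs"). The toolkit detects NUMTs in an assembly,
classifies them by these post-insertion fates, characterises the genomic
neighbourhoods they occupy, and runs the cross-species comparative
statistics used to relate NUMT content to genome properties.

## Homology search

The scanner is a seed-and-extend local aligner in the blastn/megablast
tradition:

- **Seeding.** Exact `word_size`-mers (default k = 11) shared between the
  mitochondrial query and a nuclear scaffold, found on both strands via a
  2-bit k-mer index of the mitochondrial sequence. Any window containing an
  ambiguous base (N) is excluded from seeding.
- **Extension.** Affine-gap x-drop dynamic programming (match +1, mismatch
  −2, gap of length L costs 5 + 2L, x-drop 20), extended independently left
  and right of the seed. Cells whose score falls more than `xdrop` below
  the running maximum are pruned, so the explored band tracks the best
  diagonal. An N scores as a mismatch, which means a run of ≥ 10 Ns
  exhausts the default x-drop by itself and extension never crosses it.
- **Hit statistics.** Each hit's final rectangle is re-aligned with a
  banded affine global DP with traceback to obtain the exact
  match/mismatch/gap decomposition (identity, alignment length) and the
  diagonal span of the optimal path; the raw score is the maximum of the
  extension score and this banded score.
- **Significance.** Karlin–Altschul: E = K·m·n·e^(−λS) with λ = 1.28,
  K = 0.46 (the standard gapped values for +1/−2 scoring), m the
  mitochondrial length and n the total nuclear length. The raw product m·n
  is used with no edge correction — simpler than BLAST's length adjustment,
  so E-values near a threshold can differ from blastn's. Bit score is
  (λS − ln K)/ln 2.
- **Reporting.** A seed falling inside an already-extended alignment (same
  rectangle, diagonal within the path's span) is skipped. Hits are reported
  once; among hits overlapping by more than half on *both* the nuclear and
  the mitochondrial axis only the best-scoring one is kept.
  Non-overlapping hits are never merged. A default reporting cap of E ≤ 10
  (as in blastn) suppresses chance seed extensions; the analysis filters
  are stricter.
- **Filters.** Following standard NUMT-survey practice the pipeline keeps
  hits with E < 10⁻⁴ and nuclear segment length ≥ 50 bp.
- Hits touching either end of the (linearised) mitochondrial sequence are
  flagged `mito_terminal`: the mito genome is treated as linear, so a NUMT
  spanning the circular origin would appear as two terminal hits.

Hits can equivalently be loaded from BLAST `-outfmt 6` tabular output
(1-based inclusive coordinates converted to 0-based half-open; subject
start > end encodes the minus strand), so downstream stages run identically
on real blastn output.

The optimality of reported scores is validated against Biopython's
`PairwiseAligner` (an independent full Smith–Waterman implementation under
the identical scoring scheme) on hundreds of random pairs.

## Classification

**Complex NUMTs.** Filtered hits are chained greedily left-to-right per
scaffold. The next NUMT extends the current chain iff (1) it starts less
than `max_gap` = 10 kb of non-mitochondrial DNA after the previous member,
(2) it lies on the same strand, and (3) synteny holds — mitochondrial
coordinates advance strictly with the scaffold (increasing for `+` chains,
decreasing for `-`). Chains of ≥ 2 members become clusters. Because local
alignments routinely over-extend one or two bases into the inserted DNA at
a fragment boundary (chance matches), mito intervals of consecutive members
may overlap by up to `synteny_slop` = 20 bp; substantially overlapping
(re-duplicated) fragments still break the chain. Greedy chaining is
deterministic and linear; nothing in the criteria requires an all-subsets
optimisation. Note that the criteria are purely positional: two independent
insertions that happen to land within 10 kb with compatible orientation and
mito order will be chained — on dense NUMT landscapes some detected
clusters are such coincidences, which is inherent to distance-based
clustering, not an implementation artifact.

**Duplicate-type NUMTs.** If one NUMT arose from another by nuclear
duplication, homology must extend into the flanking nuclear DNA, and flank
divergence must match NUMT divergence. For every candidate pair (gated on
mitochondrial intervals overlapping by ≥ 50% of the shorter — copies
necessarily descend from the same mito segment), the two NUMT sequences are
locally aligned (strand-aware: the minus-strand member is
reverse-complemented and its flanks swapped). A pair is duplication-linked
iff:

1. NUMT–NUMT local alignment identity ≥ `dup_min_numt_similarity` (0.80)
   over at least half of the shorter NUMT, and
2. at least one pair of corresponding 1 kb flanks shows a homologous
   segment ≥ `min_flank_homology` (100 bp) whose aligned ends lie within
   `boundary_slop` (20 bp) of the NUMT boundary in both sequences, and
3. |flank identity − NUMT identity| ≤ `similarity_tolerance` (0.05).

"Similarity" is identities per alignment column throughout; the thresholds
are configurable and reported in output metadata, since the underlying
principle fixes no numbers. Families are connected components of the link
graph. Within each family the member most similar to the mitochondrial
genome (ties: lower E-value, then smaller coordinate) is labelled the
putative original (`insertion`); the rest are `duplicate`. Whether the
original should instead be counted with its family is genuinely ambiguous,
so `label_types(..., originals_as_insertion=False)` labels whole families
duplicate. Either way insertion + duplicate = total.

*Known confound:* two unrelated NUMTs inserted immediately adjacent to
copies of the same TE family exhibit genuine flank homology contiguous with
their boundaries, and when their divergences happen to agree the rule links
them. This is a limitation of the flank-homology principle itself (observed
in synthetic full-pipeline runs between fragments of different
TE-fragmented insertions flanked by the same Gypsy element); the pairwise
evidence table exposes the flank identities so such links can be audited.

## Genomic context

- **AT profiles.** Mean AT content in 5 bp sliding windows (step 1) across
  the 250 bp flanks and the first/last 50 bp of each NUMT. Windows are
  taken on the genome itself so they slide across the NUMT boundary;
  scaffold-edge-truncated flanks contribute only defined windows, and NUMTs
  shorter than 100 bp contribute a truncated interior.
- **Flank AT test.** One-sided Wilcoxon signed-rank test that the pooled
  10 bp flanks of NUMTs are AT-richer than the host scaffold's average.
  The naive design — each NUMT's flank AT minus the scaffold-wide mean — is
  *not* calibrated: flank AT lies on a lattice (k/20), and the large tied
  group at the lattice value nearest the mean flips sign as a block with
  the mean-estimation error, overdispersing the statistic (measured
  Kolmogorov–Smirnov statistics of 0.15–0.34 against uniformity under a
  null of random placement). The default design therefore pairs each NUMT
  with one random control window of the same width from the same scaffold:
  under random placement the paired difference is sign-symmetric by
  construction and the test is exactly calibrated (verified by simulation),
  while retaining full power at realistic site bias. The literal
  scaffold-mean comparison remains available via
  `reference="scaffold_mean"`. Differences are computed in exact rational
  arithmetic in both modes because float rounding breaks lattice mirror
  ties in a systematically signed way. Exact null for n ≤ 25 without ties;
  otherwise normal approximation with continuity and tie correction. The
  two flanks are pooled into one 20 bp measurement per NUMT (testing them
  separately would double-count insertions).
- **Position classes.** A NUMT overlapping any CDS interval by ≥ 1 bp is
  `coding`; else overlapping any gene interval, `intronic`; else
  `intergenic` (precedence CDS > intron > intergenic; overlapping gene
  models resolved by longest-gene precedence). Genes with ≥ 1 intronic NUMT
  are counted once each.
- **Density tracks.** NUMT and TE coverage in 50 kb windows over every
  scaffold containing ≥ 1 NUMT. Windows are non-overlapping tiles (the
  step is configurable; the original sliding-window script is unpublished,
  and tiles make coverages independent), the last window of a scaffold is
  truncated, and annotations are flattened before computing coverage so
  every value lies in [0, 1].
- **TE vicinity.** For each unit — a single NUMT, or a complex cluster
  taken as one unit spanning its outermost members — TEs overlapping the
  5 kb flanks are counted; for clusters, interior TEs count as well (the
  fragmenting element itself). A TE whose edge lies exactly 5,000 bp away
  is outside the window. The nearest TE is chosen by minimum edge distance,
  ties broken by larger overlap with the searched regions, then by
  coordinate; summaries report the proportion of units with any TE and the
  superfamily spectrum of nearest TEs.

## Comparative statistics

- **PGLS.** Generalized least squares under Brownian motion:
  ŷ = Xβ̂ with β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y, where C[i,j] is the shared
  root-to-MRCA path length computed from the tree's branch lengths in a
  single traversal. Residuals are whitened by the Cholesky factor of C;
  R² = 1 − RSS/TSS on whitened residuals with TSS about the GLS mean; the
  slope p-value is a t-test with n − 2 df; σ² (the BM rate) is RSS/(n−2).
  λ is fixed at 1 (pure BM) by default; `estimate_lambda=True` profiles
  Pagel's λ on [0, 1] by maximum likelihood, and the fit records the λ
  used. On a star tree C ∝ I and the fit reduces to OLS exactly.
- **Spearman.** ρ is the Pearson correlation of average ranks. For n ≤ 9
  the two-sided p-value is exact (full enumeration of rank permutations);
  otherwise the t approximation with n − 2 df.
- **Rank tests.** Signed-rank (paired) and rank-sum (two-sample) with exact
  small-sample nulls when there are no ties (n ≤ 25 paired, total ≤ 30
  two-sample), otherwise normal approximation with continuity and tie
  correction (via scipy).
- **Binned tables.** Length bins (default 0, 500, 1000, 2000, 5000, ∞ bp)
  and identity bins (default 0.70–1.00 in 0.05 steps) are left-closed,
  right-open, last bin closed; a value equal to an interior edge falls in
  the right bin. Per-length-bin proportions and per-identity-bin mean
  lengths are reported; percentages in species summaries are printed to 3
  decimals.

## Synthetic genomes

The generator (`synthetic_data`) emulates the statistical structure the
analyses assume, with every planted feature recorded in a truth table:

- **Sequences.** An AT-rich linear mitochondrial genome (default 15.8 kb at
  78% AT — mito genomes of small insects are strongly AT-biased) and
  multi-scaffold nuclear backgrounds (default 65% AT). The mito genome is
  simulated linear, and origin-spanning NUMTs are not planted.
- **Genes.** Placed uniformly and non-overlapping, 2–5 exons of 100–400 bp
  separated by 200–1500 bp introns; CDS equals the exons. Planted NUMTs
  never land inside exons by default (`allow_exon_insertion` overrides for
  negative controls), so intronic insertions arise naturally and coding
  insertions do not — matching the empirical pattern that coding
  insertions are purged.
- **TEs.** A small library dominated by Gypsy (plus Jockey, Mariner, RTE)
  with random consensus sequences; background copies are painted onto the
  background with 0–15% divergence, and the RepeatMasker-style annotation
  records the query interval, superfamily and divergence.
- **Insertion sites.** Candidate splice points are weighted by
  (local AT fraction of the surrounding 20 bp)^`at_site_bias` — the
  observed pattern is AT-enrichment at insertion sites, but no generative
  model exists, so a power law is the modelling choice. The exponent 0
  means uniform placement (the calibration null); the default 5 produces
  enrichment comparable to the observed effect. Points keep a minimum
  separation (default 2.5 kb) and avoid exons and TE intervals.
- **Mutations.** Substitutions only by default (each mutated site changes
  base), keeping truth intervals exact; an indel-rate option exists and
  defaults to 0. Per-NUMT substitution rates are drawn from
  `divergence_dist` (default uniform on [0, 0.2] — the real divergence
  distribution is not published beyond coarse bins, so this is a
  modelling choice, not an observation).
- **Duplications.** A duplicate event copies an existing planted NUMT
  *plus* `dup_flank_carry` = 1 kb of its nuclear flanks, applies
  `dup_extra_divergence` = 2% additional substitutions to the whole block,
  optionally reverse-complements it, and re-inserts it elsewhere. The truth
  table records the family linking copies to their source.
- **Complex events.** One mito segment (1.5–6 kb) is split into 2–4
  fragments (≥ 300 bp) and re-assembled with TE-library copies between
  fragments; the whole block is inserted at one point, so fragments keep
  order and strand and inter-fragment gaps equal the TE insert lengths.
  Fragments share a truth cluster id.

Everything derives from a single seed; identical configurations produce
byte-identical FASTA/GFF3/RepeatMasker/truth outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic mito gene content and codon structure;
compositional heterogeneity (isochores, satellite arrays) and
low-complexity sequence, which inflate chance homology in real genomes;
indel-dominated divergence of old NUMTs; nested or tandem TE structures;
assembly artifacts (collapsed repeats, gaps). Recovery rates measured here
are therefore upper bounds for assemblies of comparable quality.

## Validation experiments (tests and `scripts/acceptance.py`)

Problem sizes were chosen as the smallest at which the measured quantities
are stable: scanner optimality on 200 pairs ≤ 2 kb against the Biopython
Smith–Waterman oracle; recovery of 200 NUMTs (divergence ≤ 0.10, length
100–3000 bp) planted in 5 Mb, with no-plant 1 Mb genomes for specificity;
30 TE-fragmented insertions for exact cluster reconstruction (with events
spaced > 10 kb apart, since events closer than the chaining distance with
compatible geometry are by definition one cluster to the chainer, making
exact membership recovery ill-posed); 100 insertions + 20 duplications for
family recovery (no background TEs — the TE-adjacency confound above is a
separate, documented phenomenon); 100–200 simulated genomes for flank-test
calibration and power (the null uses a mito genome composition-matched to
the nuclear background so that insert content does not shift the scaffold
average, isolating the placement effect under test); 100–200 BM
simulations on 50-tip trees for PGLS slope recovery; exhaustive
enumeration for rank statistics at n ≤ 10.

## Numerical choices

- Internal coordinates are 0-based half-open everywhere; writers emit
  1-based inclusive where a format demands it (GFF3, RepeatMasker `.out`,
  BLAST tabular, classified-NUMT TSV).
- Alignment scores are integers; no floating point enters the DP.
- The flank AT test uses exact rational arithmetic for its paired
  differences (see above).
- Ties in the duplicate-family "original" choice break by identity, then
  E-value, then coordinate — deterministic across runs.
- Degenerate inputs: an all-zero difference vector in the flank test
  reports p = 1 with a `degenerate` flag; a zero-length tree (singular C)
  and n < 3 are errors in PGLS; constant vectors are errors in Spearman.

## Known limitations

- E-values are not bit-compatible with blastn (no edge correction, fixed
  λ/K), so hit sets can differ near the 10⁻⁴ threshold.
- The duplicate detector's flank rule cannot distinguish duplication from
  shared TE-adjacency (see above) and quadratic pair comparison limits it
  to a few thousand NUMTs per genome.
- The greedy chainer assigns each NUMT to at most one cluster and does not
  revisit choices; pathological interleavings of two fragmented insertions
  could be split differently by an optimal chainer.
- PGLS assumes pure BM by default; an Ornstein–Uhlenbeck covariance is out
  of scope.
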