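# Methods

`stasis_scan` compares the intraspecific conservation of the secreted
proteome (SP, signal-peptide-bearing proteins) against the cytoplasmic
proteome (CP) in bacterial species clusters built from draft genomes, and
ships a forward simulator whose planted truth validates every analysis
stage. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not show.

## The analysis model

**MAG bookkeeping.** Completeness and contamination are consumed as
externally estimated percentages (CheckM-style); genomes with completeness
≥ 40% and contamination ≤ 5% are retained and tiered (high ≥ 90%, medium
70–89%, partial 40–69%). Estimated genome size is
`length / (completeness/100) × ((100 − contamination)/100)`; sizes
≤ 2.1 Mbp are classed *small*, the rest *large*. Post-binning curation
assigns each bin the modal class over its contig protein-taxonomy labels
and discards a contig when (a) more than 30% of its own labels fall outside
that class, (b) it carries no labels, or (c) its GC deviates from the bin
median by more than 15% *of that median*. The GC rule could also be read as
±15 percentage points; the relative reading was chosen because an absolute
band of that width would essentially never trigger across bacterial GC
ranges. Ties for the modal class break lexicographically so curation is
deterministic.

**Fragment ANI and species clustering.** Genomes are cut into consecutive
1200-bp fragments (terminal remainders ≥ 100 bp kept). Each fragment is
aligned against the other genome with edlib's glocal (infix) mode, and the
alignment path is then clipped to its maximum-scoring local segment under
BLASTN-like column scores (match +2, mismatch −3, gap open −5, extend −2),
which restores the local behaviour of a BLAST search: spurious or partial
hits shrink below the acceptance cutoffs instead of being padded to full
length. A hit is accepted at identity ≥ 30% over ≥ 70% of the fragment with
no internal indel run > 150 nt, and must map reciprocally: the matched
target region, re-aligned against the source genome, has to overlap the
originating fragment by ≥ 50%. ANI is the mean percent identity of accepted
fragments from both directions; the conserved-DNA fraction is the accepted
share of the total fragmented length. Species clusters are connected
components of the graph whose edges pass ANI ≥ 95% *and* conserved DNA
≥ 0.70 (single linkage; no linkage rule is canonical for this criterion),
and clusters with ≥ 9 members are flagged eligible for intraspecific
analyses. Note that for two partial genomes the conserved-DNA fraction is
bounded by their completeness overlap, so very incomplete assemblies may
fail the 0.70 gate against every partner; this is a property of the
criterion itself, not of the implementation.

**Compartment partition.** A protein belongs to the SP iff its topology
contains a signal peptide. Topologies come from parsed Phobius `-long`
output; for synthetic data a deterministic heuristic stands in: K/R within
the first 5 residues, an 8-residue window of mean Kyte–Doolittle hydropathy
≥ 1.6 (extended residue-wise), and an A-x-A cleavage site within 6 residues
after the hydrophobic core, all inside the first 45 residues. The heuristic
is a test double co-designed with the generator's motif grammar, not a
general predictor; real analyses must supply Phobius output. Lipoprotein
and TAT signals are not treated distinctly. Topology-segment lengths are
summed per class over cytoplasmic, non-cytoplasmic and transmembrane spans;
the signal peptide is excluded from the three classes.

**Compartment AAI and the SP/CP index.** AAI between two (compartment-
filtered) proteomes is the mean percent identity over reciprocal best hits
from local BLOSUM62 alignments (gap open 11, extend 1), admitted at
identity ≥ 30% over ≥ 70% of the shorter protein. The cutoffs follow common
AAI practice; the source criterion names the method but prints none.
`fraction_compared` divides RBH count by the *larger* proteome so
genome-specific proteins lower it. Per species, AAI aggregates as mean
identity per pair, then median over the C(n,2) member pairs per
compartment; the SP/CP similarity index is `median(SP-AAI)/median(CP-AAI)`
— above 1, the secreted proteome is the more conserved one. ANI
normalization defaults to the identity ratio AAI/ANI (an "SP/ANI" axis); a
dissimilarity variant `(100−AAI)/(100−ANI)` is available behind
`normalize="distance"` because the criterion can be read either way. The
index–coding-density relationship is tested with Spearman's rank
correlation (rho, S = Σd², two-sided p); group contrasts use two-sided
Wilcoxon rank-sum tests (exact for small tie-free samples, matching R's
`wilcox.test`), Kruskal–Wallis for ≥ 3 groups, and Holm-adjusted p-values
alongside raw ones.

**Redundancy and selection summaries.** The functional redundancy ratio of
an annotated gene set is `1 − unique KO count / total KO count` (0 = every
function unique); unannotated genes are excluded first and annotation
coverage is reported alongside so the ratio stays interpretable. Site-level
selection calls (FEL-style) and per-species recombination estimates
(ClonalFrameML-style) are parsed from documented TSV schemas and only
aggregated: a gene is *positive* if any positively selected site is
significant at α = 0.05 (positive takes precedence over negative, so any
adaptive site marks the gene adaptive), *negative* if any negative site is,
*invariant* when the caller flags a zero-polymorphism alignment, else
*none*. Per size class, a 2 (compartment) × 3 (positive/negative/other)
Pearson chi-square (df = 2, no continuity correction) tests homogeneity.
Recombination summaries report medians of r/m, ν and δ by size class and
compartment with Kruskal–Wallis contrasts and a flag for r/m > 1. The
upstream tooling uses ν for import divergence and δ for import length while
the summaries' vocabulary sometimes conflates them, so both columns are
carried verbatim.

## The simulator

The generator emulates the data regime the analysis was designed for:
species clusters of ≥ 9 partial genomes, within-species nucleotide
divergence < 5%, a tunable SP-vs-CP divergence ratio, tunable coding
density and KO-level duplication, completeness 40–100% and contamination
0–5%. No generative model is canonical here; all choices below are
stand-ins calibrated to reproduce those qualitative regimes.

Per species, an ancestor is built as `n_genes` genes laid head-to-tail with
intergenic spacers sized so realized coding density matches the target
(multinomial split, within 0.02 by construction). Proteins are i.i.d. amino
acid sequences; SP-truth proteins begin with the motif grammar (M, K/R in
the n-region, 8–11 hydrophobic residues, short polar spacer, A-x-A), with
segment lengths constrained so the predictor's search windows always reach
the motif; CP-truth proteins are rejection-sampled against the predictor so
the two agree by construction. Reverse translation draws synonymous codons
from an i.i.d. base model at the GC target. KO labels are planted per
compartment with `round((1−d)·n)` distinct labels so the redundancy ratio
recovers the duplication rate `d` exactly up to rounding; SP and CP draw
from disjoint label pools.

Members evolve by uniform nucleotide substitution — no codon model, since
every downstream statistic is identity-based — at per-site rate `mu_cp`
(CP genes, intergenic) or `mu_cp × sp_rate_multiplier` (SP genes), plus
`recomb_events_per_genome` imports whose segments are diverged at
`donor_divergence` (geometric lengths, mean `import_length_mean`). Start
and stop codons and the signal-peptide-encoding region are frozen so ORFs
and compartment labels survive evolution (biologically: short targeting
signals under strong purifying selection); the rate on a gene's remaining
sites is scaled up by `length/mutable_length` so the expected per-gene
substitution count still matches the nominal rate — without this the frozen
~25% of an SP gene would bias the equal-rates SP/CP index above 1.
Substitutions that would create an internal stop codon advance to the next
non-stop base deterministically.

Degradation fragments each genome at intergenic cut points into ≥ 20
contigs (target length 30 kb ± 10 kb, shrunk for small test genomes); cut
positions are drawn once per species so homologous contigs tile identical
coordinates across members. Contigs are then dropped in random order until
the planted completeness (uniform in `completeness_range`) is best
approximated — realized completeness differs from planted only by contig
granularity — and contamination is added as contigs copied from a member of
the next species, tagged in the truth table. The planted values are
recorded as the "estimated" completeness/contamination the QC layer
consumes; completeness estimation itself is out of scope. All randomness
derives from one top-level seed through fixed `(species, member)` spawn
keys, so outputs are byte-reproducible and adding members never reshuffles
earlier ones.

**What the synthetic data does not show.** Genes are i.i.d. sequences with
no homology structure beyond planted duplication, no gene gain/loss, no
phage or plasmid content, no codon-usage or growth-rate signal, no strain
microheterogeneity, and contamination is whole-contig and fully foreign.
Passing tests therefore demonstrate that the statistics recover *planted*
effects at realistic magnitudes, not that real MAG data are free of the
confounders (assembly chimerism, partial contamination, annotation error)
the simulator omits.

## Problem sizes and numerical choices

Tests and the reproduction script run on deliberately small genomes
(20–40 genes of ~60–90 aa, 3–10 members per species) so the full stack —
including all-vs-all fragment ANI and per-pair RBH AAI — completes in
minutes on one CPU; all thresholds are scale-free, so these sizes exercise
the same code paths as full-size genomes. Protein best hits are selected by
alignment score (score-only pass) with tracebacks computed only for RBH
pairs; identity is matches over alignment columns, gap columns included.
edlib alignment identity is `(columns − edit distance)/columns` on the
clipped segment. Degenerate inputs are handled explicitly: empty
compartments exclude a pair from medians, zero RBHs make AAI missing rather
than zero, all-contig discards warn rather than raise, and constant vectors
make rank correlations an error rather than NaN.

## Known limitations

- The conserved-DNA gate (≥ 0.70) interacts with completeness as noted
  above; clustering very incomplete MAG sets needs either the taxonomic
  pre-grouping path or a relaxed gate.
- No low-complexity masking is performed before fragment alignment, which
  can inflate conserved-DNA fractions on artificially repetitive toy
  inputs.
- The heuristic signal predictor is deliberately matched to the generator;
  its accuracy on synthetic data says nothing about Phobius accuracy on
  real proteomes.
- The FEL/ClonalFrameML adapters read simplified TSV schemas, not the
  tools' native output dialects; converting native output is a one-line
  column mapping documented in the parsers.
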