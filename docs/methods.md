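# Methods

This note documents the models, numerical choices and limitations behind
`gbtax`, in the order the pipeline runs: synthetic data → alignment kernel
→ relatedness indices → marker phylogenomics → taxonomic decisions →
pipeline plumbing.

## Synthetic genomes with planted divergence

The generator exists so that every downstream stage can be tested against
known truth. One `PairSpec` describes a genome pair diverged from a common
ancestor:

| parameter | units | default | role |
|---|---|---|---|
| `n_genes` | count | 300 | proteome/CDS size |
| `gene_length_mean` | amino acids | 220 | protein length, Normal(μ, 0.2 μ), min 30 |
| `shared_fraction` | fraction | 1.0 | fraction of genes orthologous between the lineages |
| `target_protein_identity` | fraction | 0.7 | expected pairwise amino-acid identity among orthologs |
| `target_nucleotide_identity` | fraction | 0.8 | expected genome-sequence identity |
| `indel_rate` | events/aa site/lineage | 0.0 | single-residue protein indels |
| `seed` | int | 0 | all randomness |

The defaults are sized like a small thermophilic bacterial genome reduced
~6-fold: 300 genes of mean 220 aa give a ~200 kb genome, large enough that
index estimates have sub-point sampling error yet a full all-vs-all run
stays interactive.

**Two-lineage mutation accounting.** To plant a pairwise identity *p*,
each lineage substitutes sites independently at rate *q* under uniform
replacement over an alphabet of size *A*; two descendant sites then match
with probability (1−q)² + q²/(A−1). Inverting,

    q = (A−1)/A · (1 − √(1 − A(1−p)/(A−1))),

valid for p > 1/A. Proteins use A = 20, genome nucleotides A = 4. The
inversion is exact, so the recorded `PlantedTruth` is analytically
checkable: the mean Hamming identity over the recorded ortholog map is an
unbiased estimator of *p* (test tolerance 0.02 matches its sampling error
at the test sizes).

**The three sequence views are deliberately decoupled.** Proteins are
mutated at the amino-acid level; CDSs keep the ancestral codon at
unsubstituted positions and draw a uniform synonymous codon at substituted
positions, so translation consistency holds exactly and ortholog CDS
identity tracks (but exceeds) protein identity. The *genome* sequence is
the ancestral CDS+spacer concatenation mutated directly at
`target_nucleotide_identity`, because the whole-genome indices (ANI, dDDH)
read only that view; the genome therefore does not literally contain the
lineage CDSs. Non-shared genes are fresh random sequences from the same
length distribution, so they fail any sensible RBH cutoff — this is what
makes POCP/AF ground truth clean.

**Markers on a tree.** `evolve_markers_on_tree` walks a Newick tree
(branch lengths in substitutions/site) and mutates each marker
independently; the per-branch substitution probability is the uniform-model
saturation curve p(t) = (19/20)(1 − e^(−20t/19)). Evolution is
substitution-only, so per-taxon marker sets are concatenation-ready without
realignment.

**What the generator does not emulate:** operon structure, GC skew, codon
bias, mobile elements, rearrangements, gene duplication/paralogy, and —
for genome sequences — indels. Consequently, passing tests demonstrate
correctness of the *method* under its stated model (collinear,
substitution-divergent genomes with uniform composition), not robustness
to repeats, paralogs or structural variation in real assemblies.

## Alignment kernel

**Protein search** is exact affine-gap Smith–Waterman (biotite's C
kernel, BLOSUM62, gap open 11 / extend 1 in the BLAST convention: a gap of
length L costs open + L·extend) on candidates nominated by a shared 4-mer
prefilter. Candidates are ranked by shared-k-mer count (ties by subject
id) and the top 5 are aligned; nomination and the final best-hit choice
are invariant to gene order. Tie-breaking everywhere is (score desc,
identity desc, subject id asc). The prefilter's sensitivity is tested, not
assumed: at ≥40 % identity on ~100-aa-or-longer proteins the expected
number of conserved 4-mers is ≥5 and the tests verify no planted ortholog
is lost down to 55 % identity; a random unrelated pair shares < 1 four-mer
in expectation, which is what makes the filter effective. The cost of the
guarantee's edge: a query whose only exhaustive-SW "best hit" is a
spurious ~10-residue micro-alignment may go hitless — such hits carry no
homology signal and no index uses them.

**E-values** use the Karlin–Altschul form E = K·m·n·e^(−λS) with the
published gapped BLOSUM62(11,1) constants λ = 0.267, K = 0.041. They are
exposed but OFF by default; only the POCP conserved-protein criterion
(e < 10⁻⁵) consumes them.

**Genome-fragment mapping** (the ANI/dDDH substrate) is a seed-and-verify
mapper rather than local alignment, for a measured reason: at ≤60 %
identity a positive-score-only local alignment retreats to short
high-identity islands, and a free-end edit-distance alignment inflates
identity through gap abuse (~0.55 apparent identity for *unrelated*
sequence). The mapper seeds 6-mers on both strands, votes on
16-wide diagonal buckets (votes smeared across the bucket boundary),
evaluates the top 80 buckets by an exact gapless sliding scan, and reports
identity = matches/1020 at the best shift. 6-mers are short enough that a
fragment at 50 % identity still yields ~16 conserved seeds against a
per-bucket background of ~8 — the separation that makes the lowest tested
identity reliably mappable. A placement is accepted only above a
significance floor of 0.35 identity: the best spurious placement of an
unrelated fragment measures ~0.30 (best of ~5·10³ evaluated shifts over a
0.25 background), so anything below 0.35 is indistinguishable from noise
and is rejected rather than reported. Known limitation: the scan is
gapless, so a fragment spanning a genuine indel reports understated
identity; under the generator's substitution-only genome model the
reported identity is exact.

**Gene-vs-gene search** (the gANI/AF substrate) aligns 11-mer-nominated
candidate CDS pairs globally with edlib (bit-parallel, exact edit path)
and scores hits by identity. Global alignment of two *unrelated* genes
still yields ~50–56 % nucleotide identity (gap abuse again), so
bidirectional best-hit pairs below 60 % identity are discarded as
background; measured ortholog identity at the lowest planted protein
identity (0.5) is ≥63 %, so the cutoff separates cleanly.

## Relatedness indices

All indices return an explicit undefined flag (`value=None`) when no
qualifying alignment exists — never 0, because 0 is a meaningful value.
Symmetric-mean indices are invariant to argument order; matrices fill the
diagonal analytically (100 %, AF 1.0).

- **AAI**: unweighted mean of RBH pair identities (each pair's identity =
  mean of its two directed hits), cutoffs identity ≥ 20 % and query
  coverage ≥ 70 % in both directions.
- **POCP**: (C₁+C₂)/(T₁+T₂) × 100 with the conserved-protein criteria
  e-value < 10⁻⁵, identity > 40 %, aligned region > 50 % of query length.
- **ANI**: consecutive non-overlapping 1020-nt fragments (tails ≥ 100 nt
  kept), keep-rule identity ≥ 30 % and coverage ≥ 70 % applied on top of
  the mapper's significance floor; per-direction unweighted mean identity,
  headline = mean of the two directions.
- **gANI/AF**: over qualifying BBH gene pairs, per direction
  gANI = Σ(identityᵢ·alnlenᵢ)/Σ alnlenᵢ and AF = Σ alnlenᵢ / Σ gene length
  of the query genome; both directions retained, headline = their mean
  (published values in the field are printed as single numbers; the mean
  keeps the matrix symmetric).
- **dDDH formula 2**: HSPs are the fragment placements passing the ANI
  keep-rule, pooled over both directions; the raw statistic is
  Σ matches / Σ aligned columns. The logistic map to a DDH percentage,
  100/(1 + e^((d − d₀)/s)) with d = 1 − raw, is configuration: the
  defaults d₀ = 0.042, s = 0.0075 are calibrated to two anchors
  (self-comparison ≈ 99.6 %, and 70 % DDH ↔ raw ≈ 0.964, consistent with
  the conventional DDH-70/ANI≈96 correspondence). Every result carries
  the raw statistic, and tests assert only on it.
- **16S identity**: best local alignment (match +2 / mismatch −3, gap
  5,2), percent identity over aligned columns; inputs must be ≥ 200 nt.

## Marker phylogenomics

Marker extraction searches seed (exemplar) proteins against a proteome and
keeps the best hit passing identity ≥ 30 % and seed coverage ≥ 70 %;
absence is reported, never fabricated. Multiple alignment is biotite's
guide-tree progressive aligner (two sequences reduce to the optimal global
pairwise alignment). Codon-aware gap stripping removes every codon
column-triple containing a gap in any taxon — the operation is idempotent
and leaves a gap-free multiple-of-3 alignment. Concatenation follows a
declared marker order (default: sorted ids), fills missing taxa with gap
blocks and records partitions.

Distances support p-distance, Poisson, JC69 and K2P with *pairwise*
deletion (sites gapped in either member of a pair are ignored for that
pair only — the common default of desktop phylogenetics tools; the
alternative, complete deletion, is a one-line switch away in
`_pair_distance` but not exposed because nothing in the test battery
needs it). Saturated corrections (log of a non-positive argument) are
flagged infinite and capped at 10 substitutions/site inside NJ.

Neighbor joining is the Saitou–Nei agglomeration with the standard
Q-criterion. Determinism and printability choices: agglomeration ties
break on the lowest (i, j) index pair; negative branch estimates are
clamped to zero with the deficit shifted to the sibling edge (standard
practice, preserves the pair's path length); the result is returned
unrooted (trifurcating root). On exactly additive matrices the
reconstruction is exact to 1e-9 in both topology and path lengths, which
the tests verify against random additive metrics, and the topology is
cross-checked against an independent NJ implementation on noisy matrices.

Bootstrap resamples alignment columns with replacement, rebuilds the tree
per replicate, and reports for each internal edge of the point tree the
percentage of replicates containing its bipartition; supports are written
as internal node labels in Newick (widest parser compatibility).

## Taxonomic decisions

Thresholds (configuration, with the field's customary defaults): species
dDDH 70 % / ANI 95 %; AAI genus band 60–62 % (the refined band inside the
broader 60–80 % literature band); POCP 50 %; gANI above both its published
mean (73.98) and median (73.11) and AF above mean (0.33) and median
(0.345) — "above threshold" requires exceeding both, since the literature
cites both without choosing; 16S genus cutoff 94.5 %.

Voting: dDDH/ANI above threshold vote same-species; AAI votes same-genus
above the band, different-genus below it and *abstains inside it* (band
membership defers to phylogeny — the band endpoints' inclusivity is
unspecified in the field, so the band is treated as abstention territory);
POCP and gANI/AF are supportive same-genus votes only, never vetoes; 16S
below 94.5 % is a veto that overrides genome-index *genus* evidence, sets
an exception flag and records a conflict — it does not override a
species-level call, which in practice cannot co-occur with sub-94.5 % 16S
identity. Consensus is the highest rank with unvetoed support, else
majority among genus votes, else "uncertain — phylogeny required".
Encoding the 16S criterion as a veto rather than an averaged vote keeps
the genome/16S discordance visible in the output instead of washing it
out. The classifier is monotone: raising any index value (rank order
different_genus < uncertain < same_genus < same_species) never demotes the
consensus, a property the suite checks with randomized inputs.

The boundary scan enumerates all labeled pairs, reports the minimum
intra-clade and maximum inter-clade values with their arg-min/arg-max
pairs, per-clade intra distributions, and a nearest-integer rounded band
as context. Excluded clades (e.g. families whose 16S signal contradicts
genome indices) are dropped from both sides of the scan. Single-member
clades contribute no intra pairs; an unlabeled genome is an error, not a
silent skip.

Ortholog clustering builds a graph over all proteins with RBH edges
passing the AAI cutoffs and takes connected components: a core cluster
touches every genome; a singleton has no edge. Connected components
over-merge relative to dedicated orthology pipelines when promiscuous
hits chain clusters, so counts are labeled approximate in reports.

## Pipeline and I/O

Long-format TSV is the canonical inter-stage format; square matrices are
derived views. Index values print with 4 decimals, supports with 2.
Stages cache their outputs keyed by a config-content hash: rerunning an
identical config reloads every stage (the tests assert byte-identical
outputs on a cache hit). A manifest records the config hash, package
version and seed; one seed drives simulation and bootstrap alike. The CLI
accepts `--threads` for interface compatibility; execution is serial, so
results are trivially independent of the thread count.

## Verification problem sizes

The acceptance battery runs at: identity recovery on 300-gene /
~200 kb pairs (5 identity levels × 3 replicates, for AAI and ANI);
shared-fraction recovery on 200-gene pairs at 0.3/0.5/0.7; 10 random
6–10-taxon additive metrics for NJ; 20 random labeled matrices for the
boundary scan; 5 simulated 10-taxon datasets (139 markers) for the
MLSA-vs-SCG concordance. These sizes put sampling error well inside the
stated tolerances (±2 identity points, ±0.05 fraction) while keeping a
full run on one CPU in minutes.

## Known limitations

- Fragment identity is gapless: indel-divergent genomes read low.
- No paralogy model: RBH on real genomes with recent duplications can
  mis-pair; the generator does not exercise this.
- The dDDH *percentage* depends on calibrated logistic coefficients; only
  the raw formula-2 statistic is calibration-free.
- Bit-compatibility with BLAST-based tooling is not attempted; agreement
  is at the level of tolerances, not identical hit tables.
- E-values are a Karlin–Altschul approximation with fixed gapped
  constants, not finite-size-corrected BLAST statistics.
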