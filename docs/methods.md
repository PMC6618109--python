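# Methods

## The problem

The ITS2 rDNA marker used to genotype Symbiodiniaceae (the dinoflagellate
symbionts of corals; clades A–I, corresponding to genera) is multicopy: one
genome carries hundreds of gene copies whose sequences differ slightly.  An
amplicon library from a coral sample therefore mixes *intragenomic*
variation (copies within one symbiont genome) with *intergenomic* variation
(several symbiont taxa co-occurring in one host).  Treating every sequence
as a taxon inflates diversity; collapsing everything at a fixed similarity
threshold (the 97 % OTU convention) destroys it, because distinct
Symbiodiniaceae taxa often differ by fewer bases than the copies within a
single genome.

The package resolves the two sources of variation by exploiting a
statistical signature: the proportions of intragenomic variants in a
genome are stable, so the *same set* of sequences re-occurs, at
characteristic relative abundances, in every sample dominated by that
genotype.  Sequences in a sufficiently re-occurring set are **defining
intragenomic variants (DIVs)**; the ordered set plus each DIV's observed
abundance range is an **ITS2 type profile**, the unit reported to the user.

## Quality control

Per sample, paired reads go through: overlap merging → ambiguity/homopolymer
screen → clade assignment → dereplication → abundance filter → primer
trimming → length screen → entropy-based denoising.  Parameters (defaults
in `Config`):

| parameter | default | meaning |
|---|---|---|
| `min_overlap` | 30 bp | shortest accepted ungapped read overlap |
| `maxambig` / `maxhomop` | 0 / 5 | max ambiguous bases; longest homopolymer |
| `abund_cutoff` | 2 | unique sequences kept only at count > 2 |
| `pdiffs` / `rdiffs` | 2 / 2 | primer mismatches tolerated (5′ / 3′) |
| `minlength` / `maxlength` | 184 / 310 bp | post-trim length window, inclusive |
| `min_collection_size` | 200 | reads needed before a (sample, clade) collection is searched |
| `entropy_threshold` | 0.10 | column entropy below which splitting stops |

Merging slides the reverse-complemented reverse read along the forward
read and keeps the highest-scoring ungapped overlap (match +1, mismatch
−1, ties to the longer overlap); disagreements resolve to the
higher-quality base.  An overlap under 90 % identity is rejected — with
Illumina-scale error rates a genuine amplicon overlap sits far above this,
and accepting near-random overlaps would fabricate chimeric contigs.

Clade assignment screens each unique contig against the nine bundled clade
anchor sequences by infix edit-distance alignment (both orientations); the
best anchor must fit within the contig at ≥ 80 % identity.  Contigs
matching no anchor are discarded as non-symbiont sequence.

The denoising step is a deliberately simplified, configurable
minimum-entropy-style decomposition, not a re-creation of any published
tool: unique sequences are stacked (positionally when equal length,
otherwise via the internal progressive aligner), Shannon entropy of the
count-weighted base frequencies is computed per column, and the stack is
split recursively at the highest-entropy column while that entropy exceeds
`entropy_threshold`.  Children totalling fewer than max(10 reads, 1 % of
the parent) are folded into the nearest sibling by edit distance, which is
what removes recurring sequencing-error variants.  A column already used
for splitting is blocked within its own branch so that fold-backs cannot
re-trigger the same split.

## Profile discovery

Searchable collections (> 200 reads) contribute a **footprint**: the
sequences at ≥ `footprint_rel_cutoff` (1 %) of the collection.  The cutoff
must sit well below ~5 % because genuine DIVs can be that rare; 1 % also
matches the denoiser's minimum node size, so footprints and nodes are
consistent scales.

Discovery is a greedy, deterministic, largest-first search with support
threshold `min_support` (3 collections):

1. Among the still-unexplained portions of all footprints, find the best
   supported candidate set — preferring **whole footprints** over
   intersections of footprints, then larger sets, more supporters, higher
   summed abundance, and finally the lexicographically smaller UID list.
   Whole footprints come first because a supported footprint is a variant
   set some sample actually carries, whereas an intersection of footprints
   from *different* mixtures can describe no genotype at all; intersections
   remain the collapse path when no whole footprint is supported (e.g.
   noisy footprints sharing only a core set).
2. Record the supporters, then *peel* the chosen members off their
   footprints.  A footprint holding two co-occurring genotypes therefore
   supports the second genotype's set with its residue, while a footprint
   wholly explained by a larger set never re-supports that set's subsets.
3. Repeat until nothing is supported.

Each member of a candidate is then tested for a multimodal abundance
distribution across supporters (Gaussian KDE, Silverman bandwidth; two
modes are declared when the deepest valley between surviving peaks falls
below 85 % of the lower peak).  Multimodal candidates are partitioned by
nearest mode and re-tested recursively; partitions that would drop any
part below `min_support` are dissolved.  This is what allows two profiles
with identical DIV sets at different abundances.

A candidate becomes a profile with: DIVs ordered by decreasing mean
abundance, per-DIV [min, max] abundance ranges across supporters
(optionally widened by `range_tolerance`, default 0), and a majority set —
every DIV observed as some supporter's most abundant sequence.  Profile
names join majority DIVs with `/` and the remainder with `-`, in abundance
order; unnamed sequences appear as their registry UID.

**Abundance normalization.**  DIV abundances used for characterization and
matching are normalized within the profile's own DIV set.  This makes the
signature mixture-invariant: a genotype mixed 50:50 with another taxon of
the same clade keeps its internal DIV proportions even though every
collection-relative abundance halves.  Collection-relative abundances are
still used for footprint membership, for single-DIV profiles (whose
within-set abundance is degenerately 1), and when competing profiles are
compared.

## Assignment

A profile matches a collection when all its DIVs are present and each
falls inside its range (a 10⁻⁹ epsilon absorbs floating-point differences
at exact range endpoints).  Among matches:

* a profile whose DIV set is exactly covered by ≥ 2 disjoint matching
  profiles, each found as the *sole* profile of some sample, is set aside
  as an intergenomic composite in favour of the combination;
* the best remaining match (greatest summed DIV abundance in the
  collection; ties to more DIVs, then lower UID) is always assigned;
* further profiles are added only if disjoint from everything already
  assigned and validated standalone.

Collections matching nothing receive a conservative fallback profile:
their single most abundant sequence.  Fallback profiles only ever match
collections in which that sequence is again the majority.

Within a clade, assigned profiles split the collection in proportion to
their DIV sums; re-merging across clades multiplies by each clade's share
of the sample's post-QC reads, so per-sample abundances sum to exactly 1.
Profiles whose DIV graph (edges at ≤ 3 nt edit distance) has two or more
connected components are flagged as possible "super types" — two taxa's
radiations conflated into one profile — but never split automatically.

## Distances and ordination

Per clade: Bray–Curtis on sequence relative abundances, and normalized
weighted UniFrac, Σ l·|p_A − p_B| / Σ l·(p_A + p_B) over branches, on a
neighbour-joining tree built from uncorrected p-distances (terminal gap
runs excluded, as in `countends=F` conventions) of an internal progressive
alignment, summarised as a 50 % majority-rule consensus over 100 seeded
column-resampling bootstrap replicates.  Negative NJ branch estimates are
clamped to zero with the deficit moved to the sibling edge, preserving the
joined path length.  Classical PCoA (double-centred −D²/2,
eigendecomposition) reports all eigenvalues and drops non-positive axes.
Profile-level distances use DIV range midpoints renormalized to 1 — the
profile-level input vector is not otherwise defined, and midpoints are the
natural point summary of a range-characterized profile.

## OTU baseline

The contrast method clusters p-distances by count-weighted average linkage
(every redundant read contributes to the linkage mean) up to a 3 %
dissimilarity cutoff, across pooled samples or within each sample, and
reports each OTU by its most abundant sequence.  On the benchmark-shaped
survey this collapses all clade-C diversity into a single OTU represented
by C3 — the resolution loss the DIV approach exists to avoid.

## Synthetic data

The bundled reference data are synthetic stand-ins, generated once and
shipped as text: nine random 260-bp clade anchors (mutually ~75 %
divergent) and a named-variant catalogue derived from them by small
substitution sets (e.g. C3gulf is 1 edit from C3; the C15 radiation sits
12 edits away, beyond the 3-nt super-type threshold).  Names follow the
field's nomenclature; the sequences do not reproduce GenBank entries.

A synthetic genotype fixes a proportion vector over a few catalogue (or de
novo) variants — geometric decay by default, emulating the skew of an rDNA
array.  Reads are drawn multinomially from (mixture weight × variant
proportion), carry independent per-base substitution errors (default
0.001), keep their primers, and overlap as 2×250 bp pairs over a ~307 bp
amplicon.  Quality strings are constant Q40 except at simulated errors
(Q2), so merge conflict resolution is deterministic and usually restores
the true base.  Study generators emit the sample sheet + FASTQ + ground
truth consumed by the pipeline:

* `generate_study`: K genotypes × n standalone samples each, plus optional
  same-clade mixtures (preferring variant-disjoint pairs, 0.6/0.4) and
  cross-clade mixtures with a D1/D4 genotype;
* `generate_benchmark_study`: a 42-sample, three-host-species survey
  (13/15/14 samples) in which one sample carries an aberrant genotype
  whose rarest variant sits below the footprint cutoff, forcing the
  conservative single-DIV fallback.

What the simulator does *not* model: chimeras, PCR bias, indel errors,
quality decay along reads, variable amplicon length within a genotype.
Passing tests therefore demonstrate the algorithmic contracts —
recoverability of profiles whose abundance signatures are stable — not
robustness to every artefact of real libraries; on real data the
configurable thresholds (`min_support`, `footprint_rel_cutoff`,
`range_tolerance`, the multimodality criterion) matter and may need
calibration.

## Problem sizes and numerical choices

The shipped studies run at depth 2,000 reads/sample with 30–42 samples,
sizes at which every stage is exercised and multinomial noise is visible
but profile recovery is stable.  Determinism is enforced throughout:
seeded generators everywhere, sorted iteration orders, and explicit
tie-breaks (lower UID, lexicographic labels).  Degenerate inputs raise
rather than guess: empty abundance maps, all-gap alignment rows,
sub-2-point ordinations, unsearchable collections passed to the footprint
extractor.

## Known limitations

* Shared-DIV abundance is not partitioned between co-occurring sibling
  taxa; overlapping matches yield a single winner.
* Super types are flagged, never split.
* The aligner's equal-length fast path assumes positional homology, which
  holds for substitution-only variation but not for length-variant
  radiations; unequal lengths go through the full progressive aligner.
* A single local store replaces any notion of a shared multi-user
  database; analyses re-use prior profiles only through that store.
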