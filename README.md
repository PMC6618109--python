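# its2div

Intragenomic-variant (DIV) profiling of multicopy ITS2 amplicon data from
Symbiodiniaceae, the dinoflagellate symbionts of reef corals.

## Why

The ITS2 marker is multicopy: each symbiont genome carries hundreds of
rRNA gene copies whose sequences differ slightly, so a sample's amplicons
mix *intragenomic* variation (copies within one genome) with
*intergenomic* variation (several symbiont taxa in one host).  Counting
every sequence as a taxon inflates diversity; clustering at the usual 97 %
OTU threshold erases it, because distinct Symbiodiniaceae taxa often
differ by fewer bases than the copies inside one genome.

`its2div` separates the two by searching for **re-occurring sets of ITS2
sequences across samples**.  Because a genome's copy proportions are
stable, the same variant set reappears at characteristic relative
abundances wherever that genotype dominates.  Sequences in a sufficiently
supported set are *defining intragenomic variants* (DIVs); the ordered set
plus each DIV's abundance range is an **ITS2 type profile** — the taxonomic
unit this package reports, e.g. `C3-C3gulf-C3c-C3aq` (DIVs in decreasing
abundance; co-majority DIVs joined by `/`, as in `C3/C3c-C3gulf`).

The package contains the full chain: paired-FASTQ quality control, the
profile-discovery engine, Bray–Curtis / weighted-UniFrac distances with
PCoA, a 97 %-OTU baseline for contrast, count-table/FASTA/newick writers,
a local analysis store, and a synthetic-community simulator with ground
truth for verification.  See `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate a 9-sample study of three clade-C genotypes, run it through the
pipeline, and write all outputs:

```sh
its2div simulate --out study --k 3 --n-per-genotype 3 --depth 500 --seed 5
its2div load     --sheet study/samples.tsv --store store.json
its2div analyse  --store store.json
its2div output   --store store.json --out tables
its2div distances --store store.json --out dists --metric unifrac --level samples
its2div otu-compare --store store.json --out otus
```

`analyse` logs `analysis 1: 3 profiles, 9 assignments`: each simulated
genotype was recovered as one type profile and every sample was assigned
its generating profile.  The profile count table
(`tables/profiles.absolute.tsv`) begins:

```
# analysis_uid	1
profile_uid	clade	majority_its2_sequences	associated_species	abundance_local	abundance_db	profile_name	div_uids
1	C	C3	Cladocopium thermophilum	3	3	C3-C3gulf-C3d-C3i-C115c-C115b	3-2-7-8-9-6
2	C	C3	Cladocopium thermophilum	3	3	C3-C3gulf-C3c-C3aq	3-2-1-4
3	C	C3	Cladocopium thermophilum	3	3	C3-C3gulf-C3c-C3am	3-2-1-5
```

Each row is one profile: its DIVs in decreasing abundance (`profile_name`),
the sequence most abundant in its samples (`majority_its2_sequences`),
species descriptions whose diagnostic variants are all among the DIVs
(`associated_species`), and how many samples carry it in this output
(`abundance_local`) versus the whole store (`abundance_db`); per-sample DIV
read counts follow.  The sequence table lists every post-QC sequence by
registry UID with per-sample counts and QC-retention rows, and
`tables/sequences.fasta` holds the sequences themselves.

The OTU contrast (`otus/otu_across_C.tsv`) collapses the *same* data to a
single 3 %-cutoff OTU represented by the C3 sequence — all three taxa
become indistinguishable, which is precisely the resolution loss the
profile engine avoids.

All of this is also available as a library; `its2div.pipeline.analyse_study`
runs sheet → QC → analysis in one call, and the synthetic generators live
in `its2div.simulate`.

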