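# pareslice

Degradome (PARE) sequencing analysis: from degradome reads plus transcript
and mature-miRNA sets to classified miRNA cleavage-target calls, with
cross-library comparison and a ground-truth simulator.

The pipeline follows the classic plant degradome convention: 20–21 nt
5'-monophosphate signatures are mapped exactly (sense strand) onto
transcripts; miRNA:mRNA duplexes are scored with plant-style penalties
(mismatch 1, G:U 0.5, gap 1, doubled over miRNA positions 2–13) and gated
at a total penalty of 7 with miRNA nt 10 and 11 required to pair; sites
backed by degradome reads are classified into categories 0–4 by the
abundance of the signature at the predicted cleavage coordinate (the
transcript base pairing miRNA nt 10) relative to the maximum and median
abundance on that transcript; abundances are normalized as TP100M (tags
per 100 million transcriptome-matched reads); significance comes from a
composition-preserving miRNA-shuffle null with add-one correction.

## Layout

| module                 | role                                                        |
|------------------------|-------------------------------------------------------------|
| `pareslice.models`     | core record types (Transcript, MatureMiRNA, TargetCall, …)  |
| `pareslice.seqio`      | FASTA/FASTQ/GFF3/TSV readers and writers                    |
| `pareslice.mapping`    | read filtering + exact-match signature profiles             |
| `pareslice.duplex`     | duplex scoring, candidate-site search, cleavage coordinate  |
| `pareslice.calling`    | categories, TP100M, shuffle p-values, t-plots, orchestration|
| `pareslice.compare`    | tissue partitioning and annotation-set comparison           |
| `pareslice.simulate`   | synthetic libraries with planted ground truth               |
| `pareslice.fixtures`   | packaged transcriptions of the published result tables      |

## CLI

```sh
# generate a synthetic library with known truth
pareslice simulate --config sim.yaml --out-dir sim/

# filter + map reads into a signature profile
pareslice map --reads sim/reads.fastq --transcripts sim/transcripts.fasta \
    --out profile.tsv

# dump candidate duplex sites below the score gate
pareslice align --mirnas sim/mirnas.fasta --transcripts sim/transcripts.fasta \
    --max-score 7 --out sites.tsv

# full pipeline: filter, map, align, classify, p-values, t-plots
pareslice call --reads sim/reads.fastq --transcripts sim/transcripts.fasta \
    --mirnas sim/mirnas.fasta --cds cds.tsv --seed 1 --out calls.tsv \
    --tplot-dir tplots/ --png

# shared vs tissue-specific targets across libraries
pareslice compare callsA.tsv callsB.tsv --meta libraries.yaml --out-dir cmp/

# annotation-group comparison between two datasets
pareslice compare-annotations annots_a.txt annots_b.txt --out table.tsv
```

`libraries.yaml` maps library names to tissues (`cotyledon` / `seed_coat`);
tissue is always configuration, never guessed from a library name.  Duplex
penalties are configurable through `--penalties` (YAML with `mismatch`,
`gu`, `gap`, `core_start`, `core_end`, `core_multiplier`).

## Notes

- Coordinates are 1-based inclusive throughout; the cleavage site (C.Site)
  is the 5'-most nucleotide of the 3' cleavage fragment.
- Calls report the region (5'UTR/CDS/3'UTR) only when a CDS interval is
  supplied; otherwise `unknown`.
- Multi-mapping reads count fully at every matching locus; identical read
  sequences are collapsed before matching.
- The category-2/3 median is taken over positions carrying at least one
  read (zeros excluded), site position included.
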