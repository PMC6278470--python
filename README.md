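# plastid-marker

Comparative chloroplast-genome analysis and species-diagnostic barcode
marker discovery, built as a reusable pipeline:

- **Quadripartite structure** — inverted-repeat detection and
  LSC/IRb/SSC/IRa partitioning with per-region length and GC statistics
  (`plastid_marker.structure`).
- **Microsatellites** — a from-scratch perfect-SSR scanner (unit lengths
  1–6, complete-unit counting, default thresholds 8/4/3/3/3/3) with
  strand/phase-invariant motif classes, region and genic-context
  assignment (`plastid_marker.ssr`).
- **Alignment** — affine-gap global alignment, a small progressive MSA for
  amplicon panels, sliding-window identity profiles and variable-region
  ranking (`plastid_marker.align`).
- **Diagnostic markers** — species-diagnostic substitution/indel calling
  from labeled alignments, reference-coordinate mapping, conserved-flank
  primer-pair design with Wallace-rule Tm (`plastid_marker.markers`).
- **Phylogenetics** — p/Poisson-corrected distances with pairwise gap
  deletion, neighbor joining, bootstrap supports, outgroup rooting,
  newick I/O (`plastid_marker.phylo`).
- **Simulation** — seeded generators for plastome-like genomes with
  planted IRs/SSRs and labeled species panels with planted diagnostic
  events plus truth tables (`plastid_marker.synthetic`).

## CLI

All coordinates in reports are 1-based inclusive; BED output is 0-based
half-open. Every output file starts with `#` metadata lines (version,
command line, seed).

```sh
plastid-marker partition --genbank genome.gb --min-ir 1000 --out regions.tsv --bed regions.bed
plastid-marker ssr --genbank genome.gb --thresholds 8,4,3,3,3,3 --min-size 0 --out ssrs.tsv
plastid-marker align --fasta amplicons.fasta --out aligned.fasta
plastid-marker scan --aln aligned.fasta --window 200 --step 50 --out profile.tsv
plastid-marker diagnose --aln aligned.fasta --labels labels.tsv --out-prefix run1
plastid-marker primers --aln aligned.fasta --target 300-360 --out primers.tsv
plastid-marker tree --aln aligned.fasta --model poisson --bootstrap 1000 --seed 1 --outgroup OG --out tree.nwk
plastid-marker simulate --seed 7 --out-dir simdata/
plastid-marker report --genbank a.gb --genbank b.gb --out summary.tsv
```

`labels.tsv` is a two-column TSV (sample id, species name).

## Reference data

The worked examples and the acceptance report use three published *Rheum*
chloroplast genome records: MH572012 (*R. officinale*), MH572013
(*R. tanguticum*), KR816224 (*R. palmatum*). They are not bundled; fetch
them once into `data/` on a machine with network access:

```sh
for acc in MH572012 MH572013 KR816224; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=gbwithparts&retmode=text" \
    -o data/${acc}.gb
done
```

Without these files, the record-specific tests automatically run
property-based surrogates on synthetic planted-truth genomes, and
`scripts/acceptance.py` omits the record-specific targets (with a note on
stderr) rather than substituting values.

## Whole-genome comparisons

Genome-scale analyses (the multi-species whole-genome identity profile
and the whole-plastome phylogeny with ~20 downloaded outgroup genomes)
are supported as a documented workflow, not as part of the offline test
surface: align the genomes externally (e.g. `mafft`), then feed the
aligned FASTA to `plastid-marker scan` and `plastid-marker tree
--bootstrap 1000 --outgroup <name>`. The progressive aligner built into
`plastid-marker align` is intended for amplicon-scale panels (tens of
sequences, a few kb), not 160 kb genomes.
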