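# methconcord

Cross-platform CpG methylation concordance analysis. Given per-CpG
methylation calls from two detection technologies (a long-read pipeline
emitting bedMethyl-like files and a bisulfite pipeline emitting
Bismark-coverage-like files), `methconcord`:

* normalizes both dialects into one 0-based internal record model, with
  optional strand merging of per-strand bisulfite records;
* builds genomic-context catalogs — CpG island/shore(±2 kb)/shelf(2–4 kb)
  partitions, GC density in 5-base tiles, repeat classes
  (tandem/LINE/SINE/other/non-repetitive), gene features (2 kb promoters,
  exons, introns, UTRs, CDS, intergenic), regulatory tracks, chromosomes —
  plus a reference CpG index for normalization;
* classifies methylated CpGs (level ≥ 50 %, depth ≥ 4 by default; 80 %
  alternative cutoff) and decomposes the two platforms' mC sets into
  overlap/unique components with per-site discordance explanations;
* computes per-context normalized mC proportions, mean methylation levels
  and Pearson correlations at overlapping sites, and depth-binned 2D
  concordance;
* performs site-level depth-matched downsampling (hypergeometric, without
  replacement, to the per-site minimum depth, over configurable replicates)
  with per-context and per-depth r distributions;
* produces 140-bin gene-aligned methylation profiles (20 upstream + 100
  body + 20 downstream bins);
* derives sequence statistics: Shannon entropy of CpG-containing 100-bp
  windows by repeat category, CpG/CHG/CHH context classification, and
  bisulfite conversion efficiency (100 − % CHH methylation);
* ships a synthetic two-platform data generator (reference FASTA, UCSC-like
  annotation tables, GTF, paired call files) so the entire pipeline runs and
  is testable without any downloads.

## CLI

```bash
# end-to-end on the built-in synthetic preset
methconcord run --seed 17 --out-dir out/

# or from a YAML config (keys mirror methconcord.pipeline.RunConfig)
methconcord run --config run.yaml

# individual stages
methconcord simulate --seed 17 --preset paper-like --out-dir sim/
methconcord ingest sim/platform_b.bismark.cov --format bismark --out calls_b.bed
methconcord annotate --islands sim/cpgIslandExt.txt --fasta sim/genome.fa \
    --gtf sim/genes.gtf --out-dir anno/
methconcord compare --input-a sim/platform_a.bedmethyl.tsv \
    --input-b sim/platform_b.bismark.cov --min-level 50 --min-depth 4 --out cmp.json
methconcord downsample --input-a ... --input-b ... --replicates 1000 --seed 17 --out ds.json
methconcord metaprofile --input sim/platform_a.bedmethyl.tsv --gtf sim/genes.gtf --out prof.tsv
methconcord seqstats --fasta sim/genome.fa --simple-repeat sim/simpleRepeat.txt \
    --rmsk sim/rmsk.txt --out seq.json
```

Outputs are TSV/JSON/BED; `methconcord run` writes a deterministic report
bundle (same config + seed ⇒ byte-identical files).

## Layout

```
src/methconcord/
  meth_io.py         call-file readers/writers (bedMethyl, Bismark coverage)
  intervals.py       interval algebra (merge/subtract/complement)
  annotation.py      context catalogs + reference CpG index
  mc_sets.py         mC classification and two-platform set decomposition
  context_stats.py   per-context stats, Pearson r, depth-binned concordance
  depth_matching.py  depth-matched hypergeometric downsampling
  metaprofile.py     140-bin gene-aligned profiles
  seqstats.py        entropy, cytosine context, conversion efficiency
  synthetic.py       synthetic genome + paired-platform call generator
  pipeline.py, cli.py  orchestration and command-line interface
tests/               pytest suite (unit, property, acceptance criteria)
scripts/acceptance.py
```
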