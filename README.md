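# chipregulon

A ChIP-Seq regulon-mapping toolkit for bacterial transcription factors that
bind palindromic sites, built around five analysis stages plus a synthetic
data generator:

- **`chipregulon.io`** — FASTA / GFF3 / BED6 / TSV readers and writers.
  Internal coordinates are 1-based inclusive; BED is converted at the
  boundary. Region tables render a `Q` column that underflows to `"0"`
  while `NLQ = -log10(Q)` stays finite.
- **`chipregulon.simulate`** — seeded synthetic datasets: a uniform genome
  with non-overlapping genes, planted degenerate `GTAN8TAC` 14-mers
  (intragenic/intergenic mixture, log-uniform site strengths, optional
  canonical Class II promoter geometry), and fragment-end 5'-tag libraries
  (ChIP pileups flanking each site + uniform background, plus a uniform
  matched input library).
- **`chipregulon.peaks`** — double-strand peak calling. Per-strand local
  maxima of a ±w moving-sum coverage are screened by a continuity-corrected
  one-sided score `z = (a − b − 1)/√(a + b)` against max(flank coverage,
  library-scaled input); forward/reverse peaks are paired into regions,
  rescored on the summed coverage at the two peak locations, and adjusted
  with a Tarone-modified distribution-free Benjamini–Yekutieli procedure.
  All p/Q arithmetic is carried in log10 space.
- **`chipregulon.annotate`** — midpoint-anchored region-to-gene assignment
  (one gene, or two when flanking genes tie), strand-aware positional
  classes (upstream far/close, internal 5'/3', downstream), position and
  functional-category summaries, site-list comparison against external
  predictions, and qPCR fold enrichment `2^(Ct_sample − Ct_control)`.
- **`chipregulon.motif`** — 14-mer scanning scored 0–6 over the six
  constrained consensus positions (G1 T2 A3 … T12 A13 C14; the 8-nt spacer
  is free), best-site-per-region selection, strict-site enrichment against
  length-matched random control subsequences, and position-frequency
  matrices with per-column information content (`2 + Σ f log2 f` bits).
- **`chipregulon.architecture`** — Class II activator / repressor-like /
  site-only promoter classification: a `TAN3T` −10 box at a 20–24-nt
  exclusive spacer downstream of the site, a same-strand TSP 30–40 nt from
  the site 3' end (counting the TSP base), and
  `center_to_tsp = tsp_distance + 6.5`, so the canonical geometry
  (22-nt spacer, 35-nt TSP distance) centers the site 41.5 nt upstream of
  the transcription start.

## Command line

```sh
chipregulon simulate --config sim.json --seed 1 --out-prefix sim
chipregulon callpeaks --chip-tags sim.chip.bed --input-tags sim.input.bed \
    --genome sim.fasta --fdr 0.05 --out-prefix calls
chipregulon annotate --regions calls.regions.tsv --annotation sim.gff3 \
    --genome sim.fasta --out-prefix ann
chipregulon motifs --regions calls.regions.tsv --genome sim.fasta \
    --min-score 5 --controls 100 --seed 7 --out-prefix mot
chipregulon architecture --sites mot.sites.tsv --genome sim.fasta \
    --tsp sim.tsp.tsv --out arch.tsv
chipregulon compare --found found.tsv --predicted predicted.tsv --tolerance 50
```

`simulate` accepts a TOML or JSON file of `SimulationConfig` fields and
writes FASTA, GFF3, two BED tag files, a ground-truth site TSV and a TSP
TSV. `callpeaks` emits a scored region TSV plus a BED companion file.

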