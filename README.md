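# loopamp

Concatemer-aware analysis of LAMP-amplified nanopore sequencing reads.

LAMP (loop-mediated isothermal amplification) produces concatemers:
single molecules carrying multiple alternating-orientation copies of the
amplified unit. Standard long-read aligners pick one primary alignment
per read and discard the rest, losing diagnostically relevant hotspot
information. `loopamp` instead:

1. **marks** every occurrence of the target seed and each LAMP design
   sequence (F3/F2/F1/B1/B2/B3, optional loop primers) on the read by
   local alignment on both strands (identity ≥ 70%, query coverage
   ≥ 80% by default);
2. **chains** design hits to the left and right of every target hit
   under an adjacency grammar describing properly formed concatemers,
   extracting one sub-read per target copy;
3. **aligns** each sub-read back to the amplicon reference and builds a
   per-read pileup over the declared hotspot; the read's call is the
   plurality of the pileup, with seeded random tie-breaking;
4. **classifies** every read as exactly one of TARGET / FRAGMENT /
   SPURIOUS / BACKGROUND / ONT / SHORT / UNKNOWN;
5. **reports** variant allele fraction (VAF) with a proportion
   confidence interval, support-over-time curves from ONT `start_time`
   metadata, time to an N× support target (default 250×), and an exact
   binomial sensitivity/specificity operating point.

The package also ships a **sequencer performance model** (time to reach
a support target from pore/rate/fraction parameters, and the
amplification amount minimising total end-to-end time) and a
**synthetic read simulator** that generates labelled LAMP libraries —
concatemers at a configured VAF, fragments, spurious primer products,
background genomic slices, adapter reads — under a per-base
substitution/insertion/deletion error model with Poisson arrivals, so
the whole pipeline is testable without external data.

## CLI

```bash
# synthetic labelled library (demo assay, true VAF 0.55)
loopamp simulate --assay demo:synthetic --n-reads 1000 --vaf 0.55 \
    --seed 1 --out sim.fastq --truth truth.tsv

# batch classification + VAF report
loopamp classify --assay demo:synthetic --out-dir out --vcf sim.fastq

# follow a directory as FASTQ files appear (real-time mode)
loopamp watch --assay demo:synthetic --idle-timeout 30 fastq_dir/

# sequencer performance model: optimal amplification amount
loopamp model --curve sweep.tsv --per-unit-time 60 --overhead 600

# plain amplicon-mode classification (primary-alignment position)
loopamp amplicon --assay demo:synthetic sim.fastq
```

`classify`/`watch` write `report.json` (class counts, VAF + CI,
time-to-support, seed, config echo), `reads.tsv` (per-read class and
call), `timeline.tsv`, and optionally a minimal single-record VCF
(1-based hotspot position, DP/AF INFO fields).

Exit codes: 0 = report produced (whatever the diagnostic outcome),
2 = input error, 3 = config error.

## Assay definition files

YAML, one design per key; inner primers may be given as FIP/BIP and are
split on their poly-T linker into the F1c+F2 / B1c+B2 halves:

```yaml
name: my-assay
target_ref: ACGT...          # amplicon-region reference (or a .fasta path)
hotspot: 165                 # 0-based position on target_ref
wildtype: A                  # optional cross-check; must equal ref base
mutants: [T]
linker: TTTT
# target_span: [135, 196]    # optional; default: between F1/B1 sites ±5 bp
designs:
  F3: GTTTGGTAGTTGCATATGGTG
  B3: ATACCTGTAACGATGAGGTTTC
  FIP: GCGGGCAGTCTGCTTTGTATTTTATGCTGGTAGGTAAGTAAGGA
  BIP: CGACCGGTGGTAAAGCACCTTTTCACCCCTCCAGTAGAG
  FLP: CGAGCCATGGTACAGAGAC
  BLP: CAGGAAGCAACTGGCTACA
```

Orientation convention: F-side sequences are given in the forward
orientation of `target_ref`; B-side sequences and FLP are
reverse-strand; BLP is forward-strand. `demo:synthetic`, `demo:h3f3a`
and `demo:hist1h3b` name built-in demo assays (the latter two embed the
published K27M primer sets in synthetic genomic filler).

## Notes

- All coordinates are 0-based half-open internally; only VCF output is
  1-based.
- The alignment scoring scheme is match +2, mismatch −4, gap open −4,
  gap extend −2 (a gap of length L costs open + (L−1)·extend); identity
  counts matches over aligned columns including internal gaps.
- Background classification uses a k-mer diagonal-voting index over a
  supplied FASTA; without `--background` those reads degrade to
  UNKNOWN.
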