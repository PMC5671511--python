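# codonlab

Detect codon-usage bias in highly expressed genes, recode coding sequences
toward or away from the preferred-codon profile without touching the protein,
and normalize dual-reporter (GFP/mCherry) plate-reader measurements for
transfection efficiency. A seeded synthetic-data module generates every input
the pipeline needs, with ground-truth tables, so the whole analysis is
testable offline.

## Modules

| Module | What it does |
| --- | --- |
| `codonlab.codon_core` | Genetic-code tables, validated coding sequences, codon counting, global/within-family frequency tables, GC and GC3, Wright's effective number of codons (ENC) |
| `codonlab.bias_detection` | Expression stratification (intensity thresholds or top-n), per-codon two-sided Fisher exact tests (within-family or vs-all contingency), Benjamini–Hochberg/Holm FDR, rank-scan of detection depth |
| `codonlab.recoding` | Preferred/avoided codon maps from bias results, deterministic protein-neutral recoding with an auditable change ledger, codon-level diffs |
| `codonlab.fluor_norm` | Plate model (sample/blank/background wells), blank subtraction, per-well GFP/mCherry ratios with background exclusion, replicate aggregation, reference scaling, c.v. and Student's t statistics |
| `codonlab.synthetic_data` | Seeded generators for CDS sets with planted codon-preference shifts, log-normal expression tables, and dual-channel plates with per-well efficiency factors |
| `codonlab.cli_io` | `codonlab` CLI plus FASTA/TSV/CSV readers and writers (all formats round-trip exactly; writes are atomic) |

## CLI

```sh
# synthetic inputs (seed required; truth tables written alongside)
codonlab simulate cds --seed 1 --n-genes 220 --biased 20 --out-dir sim/
codonlab simulate plate --seed 1 --out-dir sim/

# per-gene GC/GC3/ENC report and codon counts
codonlab enc --fasta sim/genes.fasta --out stats.tsv
codonlab count --fasta sim/genes.fasta --pooled --out counts.tsv

# codon bias in highly expressed genes (cutoff 450000 or --top-n N)
codonlab bias --fasta sim/genes.fasta --expr sim/expression.tsv \
    --top-n 20 --alpha 0.05 --out bias.tsv

# detection depth over expression rank
codonlab scan --fasta sim/genes.fasta --expr sim/expression.tsv \
    --grid 20,50,100,220 --out scan.tsv

# protein-neutral recoding with a change ledger
codonlab recode --fasta gene.fasta --map sim/truth_map.tsv --mode high \
    --out recoded.fasta --ledger changes.tsv

# dual-reporter normalization (blank-correct, ratio, reference scaling)
codonlab normalize --plate sim/plate.csv --reference ref --scale 1 --out summary.tsv
```

Library use mirrors the CLI; see the module docstrings. A minimal example:

```python
from codonlab import (CdsSimConfig, count_codons, detect_bias, pool_counts,
                      simulate_cds_set)

records, truth = simulate_cds_set(CdsSimConfig(seed=1))
counts = [count_codons(r) for r in records]
result = detect_bias(pool_counts(counts[:20]), pool_counts(counts), alpha=0.05)
print(sorted(result.biased_amino_acids))
```

## Conventions

- Codons are frame-0 3-mers over `{A,C,G,T}`; codon and sequence coordinates
  are 1-based. Internal stop codons are validation errors by default
  (`strict=False` to tolerate them).
- Stop codons and single-codon families (Met, Trp) are excluded from
  frequency tables, ENC and bias testing; the FDR test count m covers
  testable codons only.
- The bias background is inclusive (the group is part of "all genes");
  exclusive background is available via a flag.
- ENC follows Wright's estimator with six-fold families as their own
  degeneracy class and mean-of-defined-classes fallback, clamped to [20, 61].
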