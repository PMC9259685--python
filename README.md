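# paralocus

Paralog-aware copy-number and recombinant-allele calling for gene/pseudogene
pairs — built around the GBA/GBAP1 locus — from short-read alignments, with
companion tools for long-read amplicon panels, cohort association statistics,
and a fully synthetic mini-genome simulator for end-to-end validation.

Highly similar pseudogenes defeat standard variant callers: reads misalign
between the paralogs, and pathogenic alleles frequently arise from structural
exchange between them (gene conversion, fusion deletions, duplications) rather
than from isolated point mutations.  `paralocus` calls these alleles by
combining three signals:

1. **Aggregate depth** over a region unique to one paralog — total copy
   number of the pair (`coverage_cn`).
2. **Base ratios** at the paralog-differentiating sites, pooled across both
   alignment positions so misalignment cancels out — per-site gene copy
   number and copy-number transition breakpoints (`site_cn`).
3. **Read-level linkage** across the ten phasing sites of the homology
   region — haplotype assembly, per-haplotype copy number, and the
   one-vs-two-wild-type-copies scenario test that yields carrier genotypes
   (`recombinant_phaser`).

Known variants outside the homology region are genotyped directly
(`targeted_variant_caller`).  The `amplicon_tools` module covers long-read
amplicon workflows: primer-pair allele classification, sentinel-site
breakpoint localization, and a leave-one-out depth-anomaly detector for
homopolymer variants.  `cohort_stats` implements carrier-exclusion odds
ratios, prevalences and proportion tests for case/control cohorts.
`synthetic_data` builds a deterministic ~52 kb mini-genome with a
gene/pseudogene pair at realistic identity and simulates aligned reads for
any allele class, providing ground truth for the whole stack.

## Quick start (library)

```python
from paralocus import synthetic_data as sd
from paralocus.pipeline import call_sample

# simulate a RecNciI fusion-deletion carrier at 30x
import numpy as np
rng = np.random.default_rng(1)
ref = sd.build_mini_reference(seed=7)
fasta = ref.write_fasta("mini.fa")
specs = sd.class_allele_specs(ref, "RecNciI_CNL", rng)
bam, truth = sd.simulate_sample(ref, specs, sd.SimulationConfig(seed=2), "sample")

report = call_sample(bam, ref.model, fasta, sample_id="demo")
print(report.to_dict()["cnv_class"])           # "CNL"
print(report.to_dict()["recombinant_calls"])   # RecNciI, mechanism CNL
```

A bundled GBA/GBAP1 hg38 region model is available via
`paralocus.load_bundled_model()`; region models are plain JSON and can be
authored for any paralog pair (`paralocus.region_model`).

## Quick start (CLI)

```sh
paralocus simulate --seed 11 --sample-class RecNciI_CNL --out-prefix demo
paralocus call --bam demo.bam --model demo.model.json --fasta demo.fa
paralocus cohort-stats --table cohort.tsv --exclude p.N409S --exposure any_variant
```

## Layout

- `src/paralocus/` — the library; each module is importable on its own.
- `tests/` — unit tests with independent numerical oracles, plus
  `tests/test_acceptance.py`, one test per release criterion.
- `scripts/acceptance.py` — recomputes the headline quantities and writes
  them as JSON (`--seed`, `--out`).
- `examples/` — short narrative scripts for each workflow.
- `docs/methods.md` — the statistical methods, end to end.
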