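# somatrio

Somatic single-nucleotide variant discovery for a matched tumor trio — a
normal sample plus two tumor biopsies from the same patient (for example a
drug-sensitive baseline tumor and a tumor re-biopsied after resistance
emerged) — with a synthetic-trio simulator that provides ground truth for
every stage.

The pipeline answers the question *which mutations appeared between the two
biopsies?* Each tumor is called against the shared normal, calls are vetted
by a seven-criterion statistical false-positive cascade, annotated at codon
level against a gene model, and the two call sets are partitioned into
shared / baseline-only / resistance-only sites. The resistance-only,
protein-altering calls form the emergent-mutation report — the candidates
for acquired drug resistance. A depth-ratio segmenter detects copy-number
changes from the same data.

Everything runs at desk scale: kilobase reference sequences, pileup-level
read evidence in plain TSV, seconds of runtime, exact statistics.

## What's inside

| module | purpose |
| --- | --- |
| `somatrio.simulate` | synthetic trio generator: reference, germline/somatic/artifact truth set, per-read evidence, depth windows |
| `somatrio.evidence` | pileup-level evidence model, TSV round-trip, SAM/BAM ingestion |
| `somatrio.stats` | exact Fisher (point-probability rule), one-sided rank-sum, signed-rank vs. constant; exact enumeration with a normal-approximation fallback |
| `somatrio.caller` | tumor-vs-normal candidate detection (depth, alt-read, VAF and Fisher gates) |
| `somatrio.filters` | the seven-criterion false-positive cascade (adjacency, MAPQ, base quality, allele-frequency change, gap regions, read-end bias, simple repeats) |
| `somatrio.cnv` | depth-ratio binning, change-point segmentation, gain/loss calling, segment-set comparison |
| `somatrio.annotate` | codon-level effect classification from a GTF subset; six-class mutation spectrum |
| `somatrio.compare` | pre/post call-set partition, measured private-site VAFs, emergent-mutation report |
| `somatrio.casestudy` | a bundled worked example: 9 resistance variants across 8 genes inside a 46 = 22+12+12 somatic landscape |

## Worked example 1: the bundled case study

The package ships a deterministic micro-fixture: a seven-contig reference,
a matching gene model, and trio evidence for 46 somatic sites of which 22
are shared between the biopsies, 12 are baseline-only and 12 are
resistance-only. Nine of the resistance-only sites are protein-altering.

```text
$ somatrio case-study --outdir case_out
{"total": 46, "shared": 22, "pre_only": 12, "post_only": 12}
    gene genomic_change aa_change     mutation_type  vaf_baseline_pct  vaf_resistance_pct
   ACAP2    chr3:310C>T  Met->Ile nonsynonymous SNV               0.0               11.36
  CARD10   chr22:310C>G  Glu->Asp nonsynonymous SNV               0.0                6.60
  CARD10   chr22:342C>G  Asp->His nonsynonymous SNV               0.0                6.60
KIAA0556   chr16:304G>T  Gly->Cys nonsynonymous SNV               0.0                5.26
   PAQR7    chr1:310G>T  Phe->Leu nonsynonymous SNV               0.0               28.37
 PPP1R39    chr5:305G>A  Arg->Gln nonsynonymous SNV               0.0                8.50
   SAFB2   chr19:312C>T  Gly->Ser nonsynonymous SNV               0.0               15.79
  STARD9   chr15:305G>A  Gly->Glu nonsynonymous SNV               0.0               46.81
  ZFYVE9    chr1:619G>T     Glu->      stopgain SNV               0.0                9.89
```

An empty destination amino acid (`Glu->`) marks a stop gained. Baseline
VAFs are measured from the baseline tumor's reads at each site — they are
verified to be 0, not assumed.

## Worked example 2: simulate, call, filter, compare

```text
$ somatrio simulate --seed 7 --outdir demo
simulated trio with seed 7: 46 somatic sites -> demo

$ somatrio call --evidence demo/evidence.tsv --reference demo/reference.fa \
    --tumor-sample post --out demo/candidates_post.vcf
46 candidates (post); skipped: {'no_alt_reads': 292, 'normal_not_hom_ref': 101, 'few_alt_reads': 20}

$ somatrio filter --candidates demo/candidates_post.vcf --evidence demo/evidence.tsv \
    --reference demo/reference.fa --tumor-sample post --out demo/calls_post.vcf
32/46 calls PASS all seven criteria
```

The filtered VCF carries each call's verdicts: `FILTER` is `PASS` or the
semicolon-joined ids of the failed criteria, and `CRIT_P` in `INFO` records
every criterion's statistic and p-value:

```text
chr1  896  .  T  G  .  PASS  TUMOR_AD=48,36;NORMAL_AD=72,0;VAF_T=42.86;VAF_N=0.0;FISHER_P=2.512e-12;...
```

After calling and filtering the baseline sample the same way:

```text
$ somatrio compare --pre demo/calls_pre.vcf --post demo/calls_post.vcf \
    --evidence demo/evidence.tsv --outdir demo/cmp
{"total": 41, "shared": 18, "pre_only": 9, "post_only": 14}

$ head -5 demo/cmp/vaf_scatter.tsv
chrom   pos     ref     alt     vaf_pre vaf_post        category
chr1    896     T       G       0.3684  0.4286  shared
chr1    3429    A       G       0.1389  0.1525  shared
chr1    7417    A       C       0.3553  0.1475  shared
chr1    10256   G       A       0.0     0.425   post_only
```

With the default simulator settings somatic VAFs reach down to 5%, below
the power of a ~68x depth design, so the recovered partition (41 of 46
sites here) deliberately differs from the implanted truth; the truth set is
in `demo/truth_variants.tsv` for exactly this comparison.
`somatrio run-all` performs the whole sequence in one command; `somatrio
cnv` / `cnv-compare` segment the depth windows written by `simulate`.

## Python API

```python
from somatrio.simulate import SimConfig, simulate_trio
from somatrio.pipeline import run_trio

reference, truth, evidence = simulate_trio(SimConfig(seed=7))
result = run_trio(reference, evidence)
print(result.comparison.totals)
print(result.callsets["post"].calls)  # passing calls keyed by (chrom, pos, ref, alt)
```

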