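# modaudit

**Audit sequence-context bias in direct RNA sequencing modification calls.**

Nanopore direct RNA sequencing lets single-sample algorithms call base
modifications such as 5-methylcytosine (m⁵C) from raw current signal.  Some
widely used callers, however, systematically over-call m⁵C at cytosines in a
particular sequence context — most notoriously the 3-mer **GCU** — and they
do so even in in-vitro-transcribed (IVT) RNA that verifiably contains no
modified bases.  A "conserved GCU methylation motif" reported from such
calls is therefore likely an algorithmic artifact.

`modaudit` is a library (plus a thin CLI) for epitranscriptomics analysts
who want to test their own call sets for this failure mode.  It implements
the complete audit chain:

1. **Per-site fractions** — collapse per-read calls into the methylated
   fraction *f = mod_count / depth* at every cytosine; strict coverage
   filters (depth > 100, or > 10 for shallow samples).
2. **Top-N ranking** — rank sites by fraction and keep the top N (default
   1,000), recording the minimum selected fraction.
3. **Motif discovery** — extract ±5 nt context windows around the top
   sites, census the central 3-mer, and learn up to five PWM motifs of
   width 3–6 with a ZOOPS (zero-or-one-occurrence-per-sequence) EM on the
   given strand against a 0-order background, with significance from a
   mononucleotide-shuffle permutation null.
4. **Context comparison** — stratify all sites by central 3-mer
   (depth > 10, fraction > 0), and compare GCU vs all other central-C
   contexts: median fold change, two-tailed Welch z, and Cohen's *d*
   (pooled SD).
5. **Native/IVT verdict** — run the comparison on a native sample and its
   IVT counterpart; a GCU elevation significant in *both* — including the
   unmodified IVT RNA — is flagged **artifact-consistent**.
6. **Synthetic data** — a seeded generator of transcriptomes and per-read
   calls with a planted context-specific false-call probability and
   optional true modification sites, for end-to-end validation.

The statistics, in the usual notation: for groups A (GCU) and B (other),

- Welch z: `z = (x̄_A − x̄_B) / √(s²_A/n_A + s²_B/n_B)`, `p = 2(1 − Φ(|z|))`
- Cohen's d: `d = (x̄_A − x̄_B) / s_pooled`,
  `s_pooled = √(((n_A−1)s²_A + (n_B−1)s²_B)/(n_A+n_B−2))`
- median fold: `median(f_A) / median(f_B)`

## Worked example

```python
from modaudit import (RunConfig, SimulationConfig, compare_gcu,
                      generate_transcriptome, run_audit, simulate_site_table)

cfg = SimulationConfig(seed=1)          # ~30 kb, depth ~ Poisson(100),
ref = generate_transcriptome(cfg)       # per-read false-call rate 0.10,
sites, truth = simulate_site_table(ref, cfg)   # 0.25 in GCU context

result = run_audit(ref, sites, RunConfig(nmotifs=2, n_shuffles=49, seed=1))
census = result.kmer_counts
print(census.top, census.top_to_runner_up_ratio)
c = compare_gcu(sites, ref, min_depth=100)
print(c.median_fold, c.z, c.cohens_d)
```

prints (seed 1):

```
GCU 2.8
2.50 52.0 4.92
```

GCU is the most frequent central 3-mer among the top-ranked "modified"
sites (2.8× the runner-up), and GCU-context cytosines show a 2.50-fold
higher median methylated fraction than all other cytosines (Welch z ≈ 52,
Cohen's d ≈ 4.9) — recovering the planted 0.25/0.10 = 2.5 bias.  Running
the same audit on the simulated IVT partner (`examples/03_native_vs_ivt.py`)
gives fold 2.50 in the modification-free sample too, and the paired verdict
is `artifact-consistent`.

The `examples/` directory has one short script per capability (audit,
stratified comparison, native/IVT verdict, motif discovery); each prints
the numbers it computes and what they mean.  The same functionality is
available from the shell:

```bash
modaudit simulate --outdir sim --seed 1
modaudit audit --reference sim/reference.fasta --site-table sim/native_sites.tsv \
    --outdir audit_out
modaudit compare-pair --reference sim/reference.fasta \
    --native-sites sim/native_sites.tsv --ivt-sites sim/ivt_sites.tsv \
    --outdir pair_out
```

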