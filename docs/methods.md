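# Methods

## The audit model

The object of study is the per-site *methylated fraction*: at cytosine
*i* with read depth *d_i*, the upstream caller labels *m_i* reads modified
and reports *f_i = m_i / d_i ∈ [0, 1]*.  The audit asks whether high *f*
concentrates in a sequence context (the central 3-mer around the cytosine)
rather than at biologically coherent sites, and whether that concentration
survives in IVT RNA, which contains no modified bases.  Everything operates
in transcriptome coordinates (0-based, '+' strand only); the internal
alphabet is DNA with `U→T` on input and `T→U` in motif/k-mer reports.

Two analysis modes mirror how the audit is used:

* **Top-N mode** — rank all sites by fraction, keep the top N (default
  1,000; ties broken by depth, then coordinate, so ranking is a
  deterministic function of the site set), extract ±5 nt windows, and ask
  what sequence feature the top set shares.  When the minimum selected
  fraction falls below 0.85 — the floor observed for whole-transcriptome
  top-1,000 selections — the run logs a warning that the reference is
  probably too small for top-N to be informative and the all-3-mer mode
  should be read instead.
* **All-3-mer mode** — stratify every C site by central 3-mer under strict
  filters (depth > 10 and fraction > 0, both strict as conventionally
  printed) and compare GCU against all other central-C sites pooled.

## Filters and histograms

All coverage/fraction filters are strict inequalities (`depth > 100`,
`depth > 10`, `fraction > 0`).  Histograms use bin width 0.025 on [0, 1]
(40 bins), half-open `[low, low + w)` with the final bin closed so that
*f = 1.0* is counted; widths that do not divide 1 produce a final partial
bin.  Bin counts always sum to the stratum size.

## Group statistics

The GCU vs non-GCU comparison treats site-level fractions as independent
observations (sites pooled across transcripts; a documented simplifying
assumption — reads spanning adjacent sites correlate them in real data).
The location test is a two-sample Welch z — group sizes in every intended
use are ≫ 30, so the normal reference is adequate — with two-tailed
p = 2(1 − Φ(|z|)).  Effect size is Cohen's d with the classical pooled SD.
The headline descriptive statistic is the median fold change
median(GCU)/median(other), reported alongside n, medians, z, p and d.
Pooled SD of exactly zero raises a degenerate-variance error rather than
returning an infinite d.  No multiple-testing correction is applied: the
audit runs one pre-specified contrast (GCU vs rest) per sample.

For native/IVT pairs the per-3-mer comparison is descriptive: per-stratum
n, medians, median difference, histograms, and the two-sample KS statistic.
By default only positions passing the filters in *both* samples enter
("position-matched"); unmatched pooling is a switch.  The verdict logic:
the target-context elevation (fold > 1, z > 0, p < α with α = 0.01) present
in both samples — including the unmodified IVT one — is labelled
`artifact-consistent`; anything else `no shared-context artifact detected`.

## Motif discovery

`discover_motifs` is a ZOOPS EM position-weight-matrix learner:

* **Model.** With probability λ a window contains exactly one motif site at
  a uniform offset; letters at the site follow the 4×w PWM, all other
  letters a 0-order background estimated from the input letter frequencies.
  Search is on the given strand only.
* **EM.** The E-step computes each window's posterior over {no site, site
  at offset j}; the M-step re-estimates the PWM (pseudocount 0.1 per cell)
  and λ.  Iteration stops when the relative log-likelihood change is below
  1e-6 (default) or after 200 iterations; the log-likelihood is monotone
  non-decreasing and this is asserted in tests on every recorded history.
* **Initialization.** The PWM seeds from the most frequent width-w word in
  the (availability-weighted) windows — majority letter + 0.1 pseudocounts,
  λ₀ = 0.5 — making every fit deterministic.  Ties in the word census break
  to the lexicographically smallest word.
* **Significance.** Each null replicate mononucleotide-shuffles every
  window independently (per-window composition preserved exactly) and
  re-fits single-motif EM; the score is the log-likelihood ratio against
  the background-only model, and p = (1 + #{null ≥ observed}) /
  (1 + n_shuffles).  Under the i.i.d. null the observed and shuffled window
  sets are exchangeable, so the p-value is exact up to its resolution floor
  1/(n_shuffles + 1).
* **Width selection.** Widths 3–6 compete.  A raw permutation p cannot rank
  two widths that both beat every shuffle (both sit at the floor), so each
  width's observed score is standardized against that width's own null mean
  and SD, the largest standardized score wins (ties → smaller width), and
  the reported p-value is the selection-adjusted permutation p of the
  max-standardized-score statistic (Westfall–Young).  This keeps the
  p-value calibrated across the width search while letting a strong wide
  motif beat its own prefixes.
* **Successive motifs.** After a motif is accepted, each position's
  availability is multiplied by (1 − posterior site coverage) and EM
  re-runs on the damped windows.  Null distributions are computed once per
  width and reused, so later motifs' p-values are conservative (their
  observed scores carry the erasure handicap; the nulls do not).  Motifs
  are reported ordered by (p_empirical, −log-likelihood).

The report annotates motifs at p < 0.05 as enriched; thresholding is left
to the reader, since the empirical p floor depends on n_shuffles.

## Synthetic data

The generator emulates the statistical signature of a context-biased
caller, not the physics of nanopore sequencing.  Transcripts are i.i.d.
letters with P(G) = P(C) = gc/2 and lengths uniform within ±20% of the
mean; each cytosine receives depth ~ Poisson(depth_mean) (negative binomial
offered, since real transcript coverage is overdispersed) and per-read
binary calls: modified with probability `p_context[central 3-mer]` when the
3-mer is configured, else `p_base`; planted true-modification sites use
their own per-read fraction instead.  Edge cytosines without a full 3-mer
use `p_base`.  A truth table records every C site's generating probability.

Defaults are the package's study conditions: 20 transcripts × ~1.5 kb
(≈30 kb, ≈400–500 GCU sites at GC 0.5), depth_mean 100, p_base 0.10,
p_context {GCU: 0.25} — a planted median fold of 2.5, comparable in size to
context elevations reported for real biased callers.  The IVT counterpart
of a native config keeps the context bias (it belongs to the caller) and
drops true sites.  All draws derive from the config seed via independent
named streams, so references, call sets and truth tables reproduce
bit-exactly; the per-read and per-site generation paths consume identical
draws and agree exactly after aggregation.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: signal-level error structure, read-length
and alignment effects, non-uniform base composition and codon structure,
correlated calls from reads spanning neighbouring sites, and any context
effect wider than 3 nt.  A real caller audit should treat the synthetic
results as a validation of the *pipeline*, not of the caller.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately compact instances chosen as
realistic miniatures: ~30 kb simulated transcriptomes (hundreds of GCU
sites) for end-to-end recovery over 20 seeds; 50×15 nt windows for
planted-word recovery; 50×11 nt windows × 20 seeds × 100 shuffles for null
calibration; 19–49 shuffles inside multi-seed loops where only consensus
and effect sizes (not fine p resolution) are read.  Fraction consistency
in site tables is checked to 1e-6 (survives decimal serialization); PWM
columns are normalized to 1 within 1e-9; EM monotonicity is asserted at
1e-9 slack.  `mod_count` from fraction/coverage tracks is `round(f · d)`
(IEEE round-half-even at exact halves).

## Known limitations

* The first learned motif can summarize general C-richness of the top-site
  windows instead of the planted 3-mer when context enrichment in the
  top-N set sits near the recovery margin (observed in roughly 1 in 25–50
  simulated draws at default conditions); the central-3-mer census is the
  robust detector and is always reported alongside.
* ZOOPS only — no multi-occurrence (ANR/TCM) motif model, no reverse
  strand, no Markov background above order 0, and no analytic E-values.
* The Welch z ignores the binomial mean–variance coupling of fractions and
  site-level dependence; with thousands of sites the qualitative verdict is
  insensitive to this, but the z magnitude should not be over-read.
* Wiggle/bedGraph interop treats whichever fraction track is supplied as
  authoritative (callers differ in whether they emit raw or dampened
  fractions); the provenance is the caller's concern.
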