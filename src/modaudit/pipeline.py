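"""High-level analysis runs: the top-N motif audit and the paired comparison.

Two modes mirror how the audit is applied in practice:

* ``run_audit`` — single sample: fractions → strict depth filter → top-N
  ranking → context windows → motif discovery + central-k-mer census, with a
  markdown summary naming the top central 3-mer and the minimum fraction
  among the selected sites.
* ``run_compare_pair`` — native vs IVT: per-k-mer stratified summaries,
  GCU-vs-other comparison in each sample, and a verdict: a GCU elevation
  that is significant in *both* samples (including the unmodified IVT one)
  is "artifact-consistent" — signal in IVT cannot be biological.

Every run writes its fully-resolved configuration next to its outputs, so a
run is reproducible from that file alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import context_compare, motif_discovery, site_stats
from .context_compare import ComparisonResult, PairedStratum
from .errors import InsufficientDataError
from .io_formats import SiteRecord, Transcript, write_site_table
from .motif_discovery import KmerEnrichment, MotifModel
from .site_stats import RankedSites

log = logging.getLogger(__name__)

#: Whole-organism floor of the top-1,000 fraction range; selections dipping
#: below it indicate the reference is too small for a top-N analysis and the
#: all-3-mer stratified mode is the informative one.
TOP_N_FRACTION_FLOOR = 0.85


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one analysis run (defaults are the audit's
    standard settings: depth > 100, top 1,000 sites, 5-nt flanks, five
    motifs of width 3–6, 100 shuffles, 0.025 histogram bins)."""

    min_depth: int = 100
    min_fraction: float = 0.0
    top_n: int = 1000
    flank: int = 5
    k: int = 3
    call_threshold: float = 0.5
    nmotifs: int = 5
    minw: int = 3
    maxw: int = 6
    n_shuffles: int = 100
    bin_width: float = 0.025
    alpha: float = 0.01  # significance level for the artifact verdict
    position_matched: bool = True
    seed: int = 0

    @classmethod
    def low_depth(cls, **kw) -> "RunConfig":
        """Preset for shallow samples (depth > 10), e.g. short viral refs."""
        kw.setdefault("min_depth", 10)
        return cls(**kw)


@dataclass
class AuditResult:
    ranked: RankedSites
    kmer_counts: KmerEnrichment
    motifs: list[MotifModel]
    n_sites_input: int
    n_sites_after_depth: int
    n_windows: int
    n_rejected_edge: int
    summary_markdown: str


@dataclass
class PairCompareResult:
    strata: dict[str, PairedStratum]
    comparison_native: ComparisonResult
    comparison_ivt: ComparisonResult
    verdict: str


def _write_config(config: RunConfig, outdir: Path) -> None:
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def run_audit(
    ref: Sequence[Transcript],
    sites: Sequence[SiteRecord],
    config: RunConfig = RunConfig(),
    outdir: Optional[str | Path] = None,
    discover: bool = True,
) -> AuditResult:
    """Top-N motif audit of one sample's per-site fractions."""
    n_in = len(sites)
    filtered = site_stats.filter_depth(sites, config.min_depth)
    log.info("depth filter >%d: %d -> %d sites", config.min_depth, n_in, len(filtered))
    if not filtered:
        raise InsufficientDataError(
            f"no sites remain after depth > {config.min_depth} filter"
        )
    if config.top_n > len(filtered):
        log.warning(
            "top-N %d exceeds available sites (%d); using all", config.top_n, len(filtered)
        )
    ranked = site_stats.rank_top_n(filtered, config.top_n, min_depth=config.min_depth)
    if ranked.min_fraction_rank < TOP_N_FRACTION_FLOOR:
        log.warning(
            "minimum fraction among top-%d is %.3f (< %.2f): the reference may be "
            "too small for a top-N analysis; consider the all-3-mer stratified mode",
            config.top_n, ranked.min_fraction_rank, TOP_N_FRACTION_FLOOR,
        )
    windows, rejections = site_stats.extract_windows(ref, ranked.sites, config.flank)
    n_edge = sum(1 for r in rejections if r.reason == "edge")
    log.info("windows: %d extracted, %d rejected (edge)", len(windows), n_edge)
    kmers = motif_discovery.count_central_kmers(windows, config.k)
    motifs: list[MotifModel] = []
    if discover and len(windows) >= 10:
        motifs = motif_discovery.discover_motifs(
            windows,
            nmotifs=config.nmotifs,
            minw=config.minw,
            maxw=config.maxw,
            n_shuffles=config.n_shuffles,
            seed=config.seed,
        )
    elif discover:
        log.warning("only %d windows; skipping motif discovery (needs >= 10)", len(windows))

    summary = _audit_markdown(config, ranked, kmers, motifs, n_in, len(filtered), len(windows))
    result = AuditResult(
        ranked=ranked,
        kmer_counts=kmers,
        motifs=motifs,
        n_sites_input=n_in,
        n_sites_after_depth=len(filtered),
        n_windows=len(windows),
        n_rejected_edge=n_edge,
        summary_markdown=summary,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_site_table(ranked.sites, outdir / "ranked_sites.tsv")
        site_stats.windows_to_fasta(windows, outdir / "windows.fasta")
        _kmer_tsv(kmers, outdir / "kmer_counts.tsv")
        pd.DataFrame(motif_discovery.motif_report_rows(motifs)).to_csv(
            outdir / "motif_report.tsv", sep="\t", index=False, lineterminator="\n"
        )
        with open(outdir / "pwms.txt", "w", newline="\n") as fh:
            fh.write("\n\n".join(motif_discovery.format_pwm(m) for m in motifs) + "\n")
        (outdir / "summary.md").write_text(summary)
        _write_config(config, outdir)
    return result


def _kmer_tsv(kmers: KmerEnrichment, path: Path) -> None:
    rows = sorted(kmers.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    pd.DataFrame(rows, columns=["kmer", "count"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def _audit_markdown(config, ranked, kmers, motifs, n_in, n_filt, n_win) -> str:
    lines = [
        "# Modification-call audit summary",
        "",
        f"- sites in: {n_in}; after depth > {config.min_depth}: {n_filt}",
        f"- top-N requested: {config.top_n}; selected: {len(ranked.sites)}",
        f"- minimum fraction among selected sites: {ranked.min_fraction_rank:.4f}",
        f"- context windows (flank {config.flank}): {n_win}",
    ]
    if kmers.total:
        top = kmers.top
        lines.append(
            f"- top central {kmers.k}-mer: **{top}** "
            f"({kmers.counts[top]}/{kmers.total}; "
            f"{kmers.top_to_runner_up_ratio:.2f}x the runner-up)"
        )
    if motifs:
        m = motifs[0]
        lines.append(
            f"- top motif: **{m.consensus}** (width {m.width}, occupancy "
            f"{m.occupancy:.2f}, p_empirical {m.p_empirical:.4g})"
        )
        lines.append("")
        lines.append("| consensus | width | occupancy | n_sites | p_empirical |")
        lines.append("|---|---|---|---|---|")
        for m in motifs:
            sig = " *" if m.p_empirical < 0.05 else ""
            lines.append(
                f"| {m.consensus}{sig} | {m.width} | {m.occupancy:.3f} "
                f"| {m.n_sites} | {m.p_empirical:.4g} |"
            )
    return "\n".join(lines) + "\n"


VERDICT_ARTIFACT = "artifact-consistent"
VERDICT_NO_ARTIFACT = "no shared-context artifact detected"


def run_compare_pair(
    ref: Sequence[Transcript],
    native_sites: Sequence[SiteRecord],
    ivt_sites: Sequence[SiteRecord],
    config: RunConfig = RunConfig(),
    outdir: Optional[str | Path] = None,
    target_kmer: str = context_compare.GCU,
) -> PairCompareResult:
    """Native-vs-IVT stratified comparison with the artifact verdict.

    The target-context elevation (median fold > 1 at p < alpha) observed in
    BOTH samples — crucially including the unmodified IVT one — is flagged
    "artifact-consistent"; anything else is "no shared-context artifact
    detected".
    """
    strata = context_compare.paired_sample_compare(
        native_sites,
        ivt_sites,
        ref,
        k=config.k,
        min_depth=config.min_depth,
        min_fraction=config.min_fraction,
        position_matched=config.position_matched,
        bin_width=config.bin_width,
    )
    cmp_native = context_compare.compare_gcu(
        native_sites, ref, min_depth=config.min_depth, k=config.k, target_kmer=target_kmer
    )
    cmp_ivt = context_compare.compare_gcu(
        ivt_sites, ref, min_depth=config.min_depth, k=config.k, target_kmer=target_kmer
    )

    def elevated(c: ComparisonResult) -> bool:
        return c.median_fold > 1.0 and c.z > 0 and c.p_two_tailed < config.alpha

    verdict = VERDICT_ARTIFACT if elevated(cmp_native) and elevated(cmp_ivt) else VERDICT_NO_ARTIFACT

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _strata_tsv(strata, outdir / "paired_kmer_summary.tsv")
        _comparison_tsv({"native": cmp_native, "ivt": cmp_ivt}, outdir / "gcu_comparison.tsv")
        _histogram_tsv(strata, outdir / "histograms.tsv")
        (outdir / "verdict.md").write_text(
            _pair_markdown(config, strata, cmp_native, cmp_ivt, verdict, target_kmer)
        )
        _write_config(config, outdir)
    return PairCompareResult(
        strata=strata,
        comparison_native=cmp_native,
        comparison_ivt=cmp_ivt,
        verdict=verdict,
    )


def _strata_tsv(strata: dict[str, PairedStratum], path: Path) -> None:
    pd.DataFrame(
        [
            {
                "kmer": s.kmer,
                "n_native": s.n_native,
                "n_ivt": s.n_ivt,
                "median_native": s.median_native,
                "median_ivt": s.median_ivt,
                "median_difference": s.median_difference,
                "ks_statistic": s.ks_statistic,
            }
            for s in strata.values()
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _comparison_tsv(comparisons: dict[str, ComparisonResult], path: Path) -> None:
    pd.DataFrame(
        [{"sample": name, **dataclasses.asdict(c)} for name, c in comparisons.items()]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _histogram_tsv(strata: dict[str, PairedStratum], path: Path) -> None:
    rows = []
    for s in strata.values():
        for sample, hist in (("native", s.histogram_native), ("ivt", s.histogram_ivt)):
            for low, count in hist:
                rows.append({"kmer": s.kmer, "sample": sample, "bin_low": low, "count": count})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _pair_markdown(config, strata, cmp_n, cmp_i, verdict, target) -> str:
    def row(name, c):
        return (
            f"| {name} | {c.n_gcu} | {c.n_other} | {c.median_gcu:.4f} | "
            f"{c.median_other:.4f} | {c.median_fold:.3f} | {c.z:.2f} | "
            f"{c.p_two_tailed:.3g} | {c.cohens_d:.3f} |"
        )

    return "\n".join(
        [
            "# Native vs IVT context comparison",
            "",
            f"Filters: depth > {config.min_depth}, fraction > {config.min_fraction}; "
            f"{len(strata)} shared {config.k}-mer strata.",
            "",
            f"| sample | n_{target} | n_other | median_{target} | median_other "
            "| fold | z | p | d |",
            "|---|---|---|---|---|---|---|---|---|",
            row("native", cmp_n),
            row("IVT", cmp_i),
            "",
            f"**Verdict: {verdict}** — a {target} elevation present in the "
            "unmodified IVT sample cannot be biological.",
        ]
    ) + "\n"
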