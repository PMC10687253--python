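"""Stratified GCU vs non-GCU comparison of methylated fractions.

Sites are stratified by the 3-mer centered on the cytosine; the audit's key
statistic compares the GCU stratum against all other central-C contexts:
median fold change, a two-sample Welch z test and Cohen's d (pooled SD).
For native / in-vitro-transcribed (IVT) pairs, per-k-mer distributions are
compared descriptively (medians, histograms, Kolmogorov–Smirnov statistic) —
a context elevation that persists in the fully unmodified IVT sample is the
signature of a caller artifact rather than of biology.

Filters are strict inequalities exactly as stated: depth > min_depth,
fraction > min_fraction.  Histogram bins are half-open [low, low+w) with the
final bin closed so fraction 1.0 is counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ComparisonError, ConsistencyError, DegenerateVarianceError, InputError
from .io_formats import RefLike, SiteRecord, as_ref_dict
from .site_stats import Rejection, central_kmer

DEFAULT_BIN_WIDTH = 0.025  # histogram bin width used throughout the audit
GCU = "GCU"


@dataclass(frozen=True)
class StratumSummary:
    """Distribution of methylated fractions for one central-C k-mer context."""

    kmer: str  # RNA alphabet
    n: int
    median: float
    mean: float
    sd: float
    histogram: tuple[tuple[float, int], ...]  # (bin_low, count), fixed width


@dataclass(frozen=True)
class ComparisonResult:
    """GCU vs non-GCU group statistics."""

    n_gcu: int
    n_other: int
    median_gcu: float
    median_other: float
    median_fold: float
    z: float
    p_two_tailed: float
    cohens_d: float


@dataclass(frozen=True)
class PairedStratum:
    """One k-mer's native-vs-IVT descriptive comparison."""

    kmer: str
    n_native: int
    n_ivt: int
    median_native: float
    median_ivt: float
    median_difference: float  # native − IVT
    ks_statistic: float
    histogram_native: tuple[tuple[float, int], ...]
    histogram_ivt: tuple[tuple[float, int], ...]


def summarize_density(
    fractions: Sequence[float], bin_width: float = DEFAULT_BIN_WIDTH
) -> list[tuple[float, int]]:
    """Histogram of fractions on [0, 1] at fixed bin width.

    Bins are [i*w, (i+1)*w) with the final bin closed at 1.0; when the width
    does not divide 1 evenly the last bin is partial.  Counts conserve n.
    """
    if not 0 < bin_width <= 1:
        raise InputError("bin_width must be in (0, 1]")
    nbins = math.ceil(round(1.0 / bin_width, 9))
    edges = np.minimum(np.arange(nbins + 1) * bin_width, 1.0)
    edges[-1] = 1.0
    counts, _ = np.histogram(np.asarray(fractions, float), bins=edges)
    return [(float(edges[i]), int(counts[i])) for i in range(nbins)]


def _sd(values: np.ndarray) -> float:
    return float(values.std(ddof=1)) if len(values) > 1 else 0.0


def _group_fractions(
    sites: Iterable[SiteRecord],
    ref: RefLike,
    k: int,
    min_depth: int,
    min_fraction: float,
) -> dict[str, list[SiteRecord]]:
    """Strict-filter sites and bucket them by central k-mer (RNA alphabet).

    Edge sites (full k-mer does not fit) are silently dropped; a site whose
    reference base is not C is a data inconsistency and raises.
    """
    seqs = as_ref_dict(ref)
    groups: dict[str, list[SiteRecord]] = {}
    for s in sites:
        if not (s.depth > min_depth and s.fraction > min_fraction):
            continue
        km = central_kmer(seqs, s.transcript_id, s.pos, k)
        if isinstance(km, Rejection):
            if km.reason == "not-C":
                raise ConsistencyError(
                    f"site {s.transcript_id}:{s.pos} is not a reference cytosine"
                )
            continue  # edge: context unavailable at this k
        groups.setdefault(km, []).append(s)
    return groups


def stratify(
    sites: Iterable[SiteRecord],
    ref: RefLike,
    k: int = 3,
    min_depth: int = 10,
    min_fraction: float = 0.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, StratumSummary]:
    """Per-context distribution summaries after strict depth/fraction filters.

    Defaults mirror the all-k-mer analysis mode: depth > 10 and fraction > 0.
    """
    if k % 2 != 1:
        raise InputError("k must be odd")
    groups = _group_fractions(sites, ref, k, min_depth, min_fraction)
    out = {}
    for km, recs in sorted(groups.items()):
        f = np.array([s.fraction for s in recs])
        out[km] = StratumSummary(
            kmer=km,
            n=len(f),
            median=float(np.median(f)),
            mean=float(f.mean()),
            sd=_sd(f),
            histogram=tuple(summarize_density(f, bin_width)),
        )
    return out


def welch_z(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Welch z statistic and its two-tailed normal p-value."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = math.sqrt(va / len(a) + vb / len(b))
    if se == 0.0:
        raise DegenerateVarianceError("zero standard error; z undefined")
    z = (a.mean() - b.mean()) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the classical pooled standard deviation."""
    na, nb = len(a), len(b)
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0.0:
        raise DegenerateVarianceError("pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)


def compare_gcu(
    sites: Iterable[SiteRecord],
    ref: RefLike,
    min_depth: int = 100,
    k: int = 3,
    target_kmer: str = GCU,
) -> ComparisonResult:
    """GCU vs all-other-central-C comparison of methylated fractions.

    Group A: sites whose central 3-mer is ``target_kmer``; group B: every
    other central-C site passing ``depth > min_depth`` with full context.
    Reports medians, median fold (A/B), Welch z with two-tailed normal p,
    and Cohen's d (pooled SD).
    """
    groups = _group_fractions(sites, ref, k, min_depth, min_fraction=-1.0)
    a = np.array([s.fraction for s in groups.get(target_kmer, [])])
    b = np.array(
        [s.fraction for km, recs in groups.items() if km != target_kmer for s in recs]
    )
    if len(a) == 0 or len(b) == 0:
        raise ComparisonError(
            f"empty group after depth filter: n_{target_kmer}={len(a)}, n_other={len(b)}"
        )
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_b > 0:
        fold = med_a / med_b
    else:
        fold = float("inf") if med_a > 0 else float("nan")
    z, p = welch_z(a, b)
    return ComparisonResult(
        n_gcu=len(a),
        n_other=len(b),
        median_gcu=med_a,
        median_other=med_b,
        median_fold=fold,
        z=z,
        p_two_tailed=p,
        cohens_d=cohens_d(a, b),
    )


def paired_sample_compare(
    native_sites: Iterable[SiteRecord],
    ivt_sites: Iterable[SiteRecord],
    ref: RefLike,
    k: int = 3,
    min_depth: int = 10,
    min_fraction: float = 0.0,
    position_matched: bool = True,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, PairedStratum]:
    """Per-k-mer native vs IVT comparison under identical strict filters.

    With ``position_matched`` (default, mirroring the "filtered in both
    samples" convention) only positions surviving the filters in *both*
    samples enter the comparison.  The KS statistic is descriptive.
    """
    native_sites, ivt_sites = list(native_sites), list(ivt_sites)
    if position_matched:
        keep_n = {(s.transcript_id, s.pos) for s in native_sites
                  if s.depth > min_depth and s.fraction > min_fraction}
        keep_i = {(s.transcript_id, s.pos) for s in ivt_sites
                  if s.depth > min_depth and s.fraction > min_fraction}
        shared = keep_n & keep_i
        native_sites = [s for s in native_sites if (s.transcript_id, s.pos) in shared]
        ivt_sites = [s for s in ivt_sites if (s.transcript_id, s.pos) in shared]
    g_native = _group_fractions(native_sites, ref, k, min_depth, min_fraction)
    g_ivt = _group_fractions(ivt_sites, ref, k, min_depth, min_fraction)
    shared_kmers = sorted(set(g_native) & set(g_ivt))
    if not shared_kmers:
        raise ComparisonError("no k-mer stratum is populated in both samples")
    out = {}
    for km in shared_kmers:
        fn = np.array([s.fraction for s in g_native[km]])
        fi = np.array([s.fraction for s in g_ivt[km]])
        ks = float(stats.ks_2samp(fn, fi, method="asymp").statistic) if len(fn) and len(fi) else 1.0
        out[km] = PairedStratum(
            kmer=km,
            n_native=len(fn),
            n_ivt=len(fi),
            median_native=float(np.median(fn)),
            median_ivt=float(np.median(fi)),
            median_difference=float(np.median(fn) - np.median(fi)),
            ks_statistic=ks,
            histogram_native=tuple(summarize_density(fn, bin_width)),
            histogram_ivt=tuple(summarize_density(fi, bin_width)),
        )
    return out
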