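"""Per-site aggregation, depth filtering, ranking and context extraction.

This is the site-selection chain of the audit: per-read calls are collapsed
into per-cytosine methylated fractions, filtered by coverage, ranked from
highest to lowest fraction, and the sequence context around the top sites is
pulled out of the reference for motif analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import pandas as pd

from .errors import InputError, UnknownTranscriptError
from .io_formats import (
    RefLike,
    SiteRecord,
    Transcript,
    as_ref_dict,
    calls_to_frame,
    to_rna,
)


@dataclass(frozen=True)
class ContextWindow:
    """A (2*flank+1)-nt reference window centered on a candidate cytosine."""

    transcript_id: str
    pos: int
    window: str  # DNA alphabet; window[flank] == 'C'
    flank: int

    def __post_init__(self):
        if len(self.window) != 2 * self.flank + 1:
            raise InputError(
                f"window length {len(self.window)} != 2*flank+1 = {2 * self.flank + 1}"
            )
        if self.window[self.flank] != "C":
            raise InputError(f"central base of {self.window!r} is not C")

    @property
    def fasta_id(self) -> str:
        return f"{self.transcript_id}:{self.pos}"


@dataclass(frozen=True)
class Rejection:
    """A site excluded from context extraction, with the reason.

    ``reason`` is ``"edge"`` (insufficient flanking sequence) or ``"not-C"``
    (reference base at the position is not cytosine).
    """

    transcript_id: str
    pos: int
    reason: str


@dataclass(frozen=True)
class RankedSites:
    """Top-N selection result, ordered by fraction (desc)."""

    sites: tuple[SiteRecord, ...]
    n_requested: int
    min_depth: int
    min_fraction_rank: float  # lowest fraction among selected; nan if empty


def aggregate_fractions(calls, call_threshold: float = 0.5) -> list[SiteRecord]:
    """Collapse per-read calls into one SiteRecord per (transcript, position).

    depth = number of covering calls; mod_count = calls with
    ``p_mod >= call_threshold`` (the boundary counts as modified);
    fraction = mod_count / depth.  Output is sorted by (transcript_id, pos).
    """
    if not 0.0 <= call_threshold <= 1.0:
        raise InputError(f"call_threshold {call_threshold} outside [0,1]")
    df = calls_to_frame(calls)
    if df.empty:
        return []
    grouped = (
        df.assign(modified=(df["p_mod"] >= call_threshold).astype("int64"))
        .groupby(["transcript_id", "pos"], sort=True)
        .agg(depth=("p_mod", "size"), mod_count=("modified", "sum"))
        .reset_index()
    )
    return [
        SiteRecord(str(r.transcript_id), int(r.pos), int(r.depth), int(r.mod_count),
                   int(r.mod_count) / int(r.depth))
        for r in grouped.itertuples(index=False)
    ]


def filter_depth(sites: Iterable[SiteRecord], min_depth: int) -> list[SiteRecord]:
    """Keep sites with ``depth > min_depth`` — strictly greater, as the
    coverage filters are stated ("depth >100", "depth >10"). Order preserved."""
    if min_depth < 0:
        raise InputError("min_depth must be >= 0")
    return [s for s in sites if s.depth > min_depth]


def rank_top_n(sites: Iterable[SiteRecord], n: int, min_depth: int = 0) -> RankedSites:
    """Rank sites by methylated fraction (desc) and keep the top n.

    Ties broken by depth (desc), then (transcript_id, pos) ascending, so the
    ranking is a deterministic function of the site *set*.  Records the lowest
    selected fraction (the "top-1,000 fractions ranged between X and 1.0"
    statistic).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    ordered = sorted(sites, key=lambda s: (-s.fraction, -s.depth, s.transcript_id, s.pos))
    top = tuple(ordered[:n])
    min_frac = min((s.fraction for s in top), default=float("nan"))
    return RankedSites(top, n_requested=n, min_depth=min_depth, min_fraction_rank=min_frac)


def extract_window(
    ref: RefLike, transcript_id: str, pos: int, flank: int
) -> Union[ContextWindow, Rejection]:
    """Extract the (2*flank+1)-nt window centered at ``pos``.

    Returns a :class:`Rejection` (reason "edge" or "not-C") instead of a
    window when the site cannot provide full context or is not a reference C.
    Unknown transcripts raise :class:`UnknownTranscriptError`.
    """
    if flank < 1:
        raise InputError("flank must be >= 1")
    seqs = as_ref_dict(ref)
    if transcript_id not in seqs:
        raise UnknownTranscriptError(f"transcript {transcript_id!r} not in reference")
    seq = seqs[transcript_id]
    if not 0 <= pos < len(seq):
        raise InputError(f"position {pos} outside transcript {transcript_id!r}")
    if seq[pos] != "C":
        return Rejection(transcript_id, pos, "not-C")
    if pos < flank or pos > len(seq) - 1 - flank:
        return Rejection(transcript_id, pos, "edge")
    return ContextWindow(transcript_id, pos, seq[pos - flank : pos + flank + 1], flank)


def extract_windows(
    ref: RefLike, sites: Iterable[SiteRecord], flank: int
) -> tuple[list[ContextWindow], list[Rejection]]:
    """Vector form of :func:`extract_window` over a site list."""
    seqs = as_ref_dict(ref)
    windows: list[ContextWindow] = []
    rejections: list[Rejection] = []
    for s in sites:
        out = extract_window(seqs, s.transcript_id, s.pos, flank)
        (windows if isinstance(out, ContextWindow) else rejections).append(out)
    return windows, rejections


def central_kmer(
    ref: RefLike, transcript_id: str, pos: int, k: int = 3
) -> Union[str, Rejection]:
    """The k-mer centered at ``pos``, reported in the RNA alphabet (T→U).

    Rejection rules as :func:`extract_window` ("edge" when the full k-mer
    does not fit, "not-C" when the reference base is not cytosine).
    """
    if k % 2 != 1:
        raise InputError("k must be odd")
    if k == 1:
        seqs = as_ref_dict(ref)
        if transcript_id not in seqs:
            raise UnknownTranscriptError(f"transcript {transcript_id!r} not in reference")
        base = seqs[transcript_id][pos]
        return "C" if base == "C" else Rejection(transcript_id, pos, "not-C")
    out = extract_window(ref, transcript_id, pos, flank=k // 2)
    if isinstance(out, Rejection):
        return out
    return to_rna(out.window)


def windows_to_fasta(windows: Iterable[ContextWindow], path) -> None:
    """Export windows as FASTA (id "transcript:pos") — the shape fed to motif
    discovery, one record per top site."""
    from .io_formats import write_fasta

    write_fasta([Transcript(w.fasta_id, w.window) for w in windows], path)
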