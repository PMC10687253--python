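"""Readers and writers for every external format the pipeline touches.

Conventions, fixed across the whole package:

* Coordinates are 0-based on the given (transcript) strand, always '+'.
* The internal alphabet is DNA ``{A, C, G, T, N}``; RNA ``U`` is accepted on
  input and mapped to ``T``.  Motif and k-mer *reports* map T back to U so
  that outputs read "GCU" as the RNA community writes them.
* Tables are tab-separated, '.' decimal, LF line endings, with fixed headers.
* ``depth == 0`` rows carry an undefined methylated fraction and are rejected
  (counted, warned) rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import ConsistencyError, DuplicateIdError, FormatError, JoinError

log = logging.getLogger(__name__)

#: Absolute tolerance for a site table's fraction column against
#: mod_count/depth; survives decimal serialization.
FRACTION_ATOL = 1e-6

_DNA = set("ACGTN")
_COMPLETE_DNA = set("ACGT")

SITE_TABLE_COLUMNS = ["transcript_id", "pos", "depth", "mod_count", "fraction"]
CALL_TABLE_COLUMNS = ["read_id", "transcript_id", "pos", "p_mod"]


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA U to DNA T. Idempotent."""
    return seq.upper().replace("U", "T")


def to_rna(kmer: str) -> str:
    """Report a DNA-alphabet k-mer in RNA letters (T→U)."""
    return kmer.replace("T", "U")


@dataclass(frozen=True)
class Transcript:
    """One reference transcriptome entry (the coordinate system for sites)."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SiteRecord:
    """One cytosine with coverage, modified-read count, and methylated fraction."""

    transcript_id: str
    pos: int
    depth: int
    mod_count: int
    fraction: float

    def __post_init__(self):
        if self.pos < 0:
            raise ConsistencyError(f"negative position {self.pos}")
        if self.depth <= 0:
            raise ConsistencyError(
                f"site {self.transcript_id}:{self.pos} has depth {self.depth}; "
                "fraction is undefined at depth 0"
            )
        if self.mod_count < 0 or self.mod_count > self.depth:
            raise ConsistencyError(
                f"site {self.transcript_id}:{self.pos}: mod_count {self.mod_count} "
                f"outside [0, depth={self.depth}]"
            )
        if abs(self.fraction - self.mod_count / self.depth) > FRACTION_ATOL:
            raise ConsistencyError(
                f"site {self.transcript_id}:{self.pos}: fraction {self.fraction} "
                f"inconsistent with mod_count/depth = {self.mod_count}/{self.depth}"
            )


@dataclass(frozen=True)
class PerReadCall:
    """A single per-read modification call (p_mod in [0,1]; 0/1 when binary)."""

    read_id: str
    transcript_id: str
    pos: int
    p_mod: float

    def __post_init__(self):
        if not 0.0 <= self.p_mod <= 1.0:
            raise ConsistencyError(f"p_mod {self.p_mod} outside [0, 1]")
        if self.pos < 0:
            raise ConsistencyError(f"negative position {self.pos}")


RefLike = Union[Iterable[Transcript], Mapping[str, Transcript], Mapping[str, str]]


def as_ref_dict(ref: RefLike) -> dict[str, str]:
    """Coerce any accepted reference representation to ``{id: seq}``."""
    if isinstance(ref, Mapping):
        out = {}
        for k, v in ref.items():
            out[k] = v.seq if isinstance(v, Transcript) else str(v)
        return out
    return {t.id: t.seq for t in ref}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a reference transcriptome FASTA.

    Sequences are uppercased with U mapped to T; record order is preserved.
    Raises :class:`FormatError` (with the offending line number) for malformed
    headers or illegal characters, and :class:`DuplicateIdError` for repeated
    ids.  An empty file yields an empty list.
    """
    path = Path(path)
    records: list[Transcript] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_chunks: list[str] = []

    def flush():
        if cur_id is not None:
            records.append(Transcript(cur_id, "".join(cur_chunks)))

    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError("empty FASTA header", line=lineno, path=str(path))
                cur_id = header.split()[0]
                if cur_id in seen:
                    raise DuplicateIdError(
                        f"duplicate transcript id {cur_id!r}", line=lineno, path=str(path)
                    )
                seen.add(cur_id)
                cur_chunks = []
            else:
                if cur_id is None:
                    raise FormatError(
                        "sequence data before first '>' header", line=lineno, path=str(path)
                    )
                chunk = normalize_seq(line.strip())
                bad = set(chunk) - _DNA
                if bad:
                    raise FormatError(
                        f"illegal sequence character(s) {sorted(bad)!r}",
                        line=lineno,
                        path=str(path),
                    )
                cur_chunks.append(chunk)
    flush()
    return records


def write_fasta(records: Iterable[Transcript], path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Site table TSV
# ---------------------------------------------------------------------------

def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read a per-site fraction table.

    Dialect: header ``transcript_id  pos  depth  mod_count  fraction``,
    tab-separated, 0-based positions.  Rows with depth 0 are rejected with a
    counted warning; inconsistent rows raise :class:`ConsistencyError` naming
    the row, non-integer counts raise :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != SITE_TABLE_COLUMNS:
        raise FormatError(
            f"site table header {list(df.columns)} != {SITE_TABLE_COLUMNS}",
            line=1,
            path=str(path),
        )
    sites: list[SiteRecord] = []
    n_depth0 = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # data starts line 2
        try:
            pos = _parse_int(row.pos, "pos", i, path)
            depth = _parse_int(row.depth, "depth", i, path)
            mod_count = _parse_int(row.mod_count, "mod_count", i, path)
            fraction = float(row.fraction)
        except ValueError as exc:
            raise FormatError(str(exc), line=i, path=str(path)) from exc
        if depth == 0:
            n_depth0 += 1
            continue
        try:
            sites.append(SiteRecord(str(row.transcript_id), pos, depth, mod_count, fraction))
        except ConsistencyError as exc:
            raise ConsistencyError(f"{path}:{i}: {exc}") from exc
    if n_depth0:
        log.warning("%s: rejected %d depth-0 row(s) (fraction undefined)", path, n_depth0)
    return sites


def _parse_int(value: str, field: str, line: int, path: Path) -> int:
    s = str(value)
    try:
        as_float = float(s)
    except ValueError:
        raise ValueError(f"non-numeric {field} {s!r}")
    if as_float != int(as_float) or "." in s or "e" in s.lower():
        raise ValueError(f"non-integer {field} {s!r}")
    return int(as_float)


def write_site_table(sites: Iterable[SiteRecord], path: str | Path) -> None:
    """Write a site table; ``read_site_table`` of the result is the identity.

    Fractions are serialized with ``repr(float)`` so 1.0 stays "1.0".
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(SITE_TABLE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.transcript_id}\t{s.pos}\t{s.depth}\t{s.mod_count}\t{s.fraction!r}\n"
            )


# ---------------------------------------------------------------------------
# Per-read call TSV
# ---------------------------------------------------------------------------

def calls_to_frame(calls) -> pd.DataFrame:
    """Coerce per-read calls (DataFrame or iterable of PerReadCall) to a frame."""
    if isinstance(calls, pd.DataFrame):
        missing = [c for c in CALL_TABLE_COLUMNS if c not in calls.columns]
        if missing:
            raise FormatError(f"call table missing column(s) {missing}")
        return calls[CALL_TABLE_COLUMNS]
    return pd.DataFrame(
        [(c.read_id, c.transcript_id, c.pos, c.p_mod) for c in calls],
        columns=CALL_TABLE_COLUMNS,
    )


def read_call_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"read_id": str, "transcript_id": str, "pos": "int64", "p_mod": float},
    )
    if list(df.columns) != CALL_TABLE_COLUMNS:
        raise FormatError(
            f"call table header {list(df.columns)} != {CALL_TABLE_COLUMNS}",
            line=1,
            path=str(path),
        )
    bad = df[(df["p_mod"] < 0) | (df["p_mod"] > 1)]
    if len(bad):
        raise ConsistencyError(
            f"{path}: p_mod outside [0,1] at data row(s) {list(bad.index[:5] + 2)}"
        )
    if (df["pos"] < 0).any():
        raise ConsistencyError(f"{path}: negative position in call table")
    return df


def write_call_table(calls, path: str | Path) -> None:
    df = calls_to_frame(calls)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Fraction / coverage track interop (wiggle & bedGraph dialects)
# ---------------------------------------------------------------------------

def _parse_track(path: str | Path) -> dict[tuple[str, int], float]:
    """Parse a per-site track: fixed-step wiggle, variable-step wiggle, or
    4-column bedGraph (intervals must be single-base, end == start+1).

    Wiggle coordinates are 1-based (converted to 0-based here); bedGraph is
    already 0-based half-open.
    """
    path = Path(path)
    values: dict[tuple[str, int], float] = {}
    mode: str | None = None  # "fixed" | "variable" | None (bedGraph lines allowed)
    chrom = ""
    start0 = 0
    step = 1
    idx = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = _wig_kv(line, lineno, path)
                chrom = kv.get("chrom", "")
                if not chrom or "start" not in kv:
                    raise FormatError("fixedStep needs chrom= and start=", lineno, str(path))
                start0 = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                if int(kv.get("span", 1)) != 1:
                    raise FormatError("only span=1 tracks are supported", lineno, str(path))
                mode, idx = "fixed", 0
                continue
            if line.startswith("variableStep"):
                kv = _wig_kv(line, lineno, path)
                chrom = kv.get("chrom", "")
                if not chrom:
                    raise FormatError("variableStep needs chrom=", lineno, str(path))
                if int(kv.get("span", 1)) != 1:
                    raise FormatError("only span=1 tracks are supported", lineno, str(path))
                mode = "variable"
                continue
            fields = line.split()
            if mode == "fixed" and len(fields) == 1:
                values[(chrom, start0 + idx * step)] = _track_float(fields[0], lineno, path)
                idx += 1
            elif mode == "variable" and len(fields) == 2:
                pos = int(fields[0]) - 1
                values[(chrom, pos)] = _track_float(fields[1], lineno, path)
            elif len(fields) == 4:  # bedGraph: chrom start end value (0-based)
                c, s, e, v = fields
                s, e = int(s), int(e)
                if e != s + 1:
                    raise FormatError(
                        f"bedGraph interval {c}:{s}-{e} is not single-base "
                        "(end must equal start+1)",
                        lineno,
                        str(path),
                    )
                values[(c, s)] = _track_float(v, lineno, path)
            else:
                raise FormatError(f"unparseable track line {line!r}", lineno, str(path))
    return values


def _wig_kv(line: str, lineno: int, path: Path) -> dict[str, str]:
    out = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise FormatError(f"bad wiggle declaration token {tok!r}", lineno, str(path))
        k, v = tok.split("=", 1)
        out[k] = v
    return out


def _track_float(s: str, lineno: int, path: Path) -> float:
    try:
        return float(s)
    except ValueError:
        raise FormatError(f"non-numeric track value {s!r}", lineno, str(path))


def read_fraction_track(value_path: str | Path, coverage_path: str | Path) -> list[SiteRecord]:
    """Assemble SiteRecords from a per-site fraction track plus a coverage track.

    The two tracks must cover the identical set of (transcript, position)
    keys; ``mod_count = round(fraction * depth)``.  Fractions outside [0,1]
    raise :class:`FormatError`; positions present in only one track raise
    :class:`JoinError` listing them; depth-0 positions are dropped with a
    counted warning.
    """
    fracs = _parse_track(value_path)
    covs = _parse_track(coverage_path)
    only_f = sorted(set(fracs) - set(covs))
    only_c = sorted(set(covs) - set(fracs))
    if only_f or only_c:
        msg = []
        if only_f:
            msg.append(f"positions only in fraction track: {only_f[:10]}")
        if only_c:
            msg.append(f"positions only in coverage track: {only_c[:10]}")
        raise JoinError("; ".join(msg))
    sites = []
    n_depth0 = 0
    for key in sorted(fracs):
        f = fracs[key]
        if not 0.0 <= f <= 1.0:
            raise FormatError(f"fraction {f} outside [0,1] at {key[0]}:{key[1]}")
        depth = int(round(covs[key]))
        if depth == 0:
            n_depth0 += 1
            continue
        mod_count = int(round(f * depth))
        sites.append(SiteRecord(key[0], key[1], depth, mod_count, mod_count / depth))
    if n_depth0:
        log.warning("fraction track: dropped %d depth-0 position(s)", n_depth0)
    return sites
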