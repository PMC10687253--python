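"""Synthetic transcriptomes and modification calls with a planted context bias.

The generator emulates the statistical structure of a direct RNA sequencing
modification-calling experiment in which the per-read false-call probability
is elevated in a specific 3-mer context (GCU by default) — the defining
feature being that the elevation is a property of the *caller*, so it appears
identically in native RNA and in fully unmodified in-vitro-transcribed (IVT)
RNA.  True modification sites (present only in native samples) are planted
with their own per-read modified fraction.

Defaults are the package's study conditions: 20 transcripts of ~1.5 kb
(≈30 kb total, several hundred GCU sites at GC 0.5), per-site coverage
Poisson with mean 100, baseline per-read false-call probability 0.10 and
0.25 in GCU context — a planted GCU/other median fold of 2.5.

Everything is deterministic given the config seed: the reference, depths,
per-read calls and truth table reproduce bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import CALL_TABLE_COLUMNS, SiteRecord, Transcript, to_rna

_LETTERS = np.array(list("ACGT"))

TRUTH_COLUMNS = ["transcript_id", "pos", "kmer", "p_call", "is_true_modified"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated sample.

    p_context maps central 3-mers (RNA alphabet, e.g. "GCU") to the per-read
    call probability at matching cytosines; all other cytosines use p_base.
    true_sites = (count, fraction_modified): count cytosines are drawn
    uniformly (seeded) and their reads are called modified with probability
    fraction_modified instead of the context rate.
    """

    n_transcripts: int = 20
    length_mean: int = 1500
    gc: float = 0.5
    depth_mean: float = 100.0
    depth_model: str = "poisson"  # or "negative_binomial"
    nb_size: float = 10.0  # NB dispersion (size); used only for negative_binomial
    p_base: float = 0.1
    p_context: dict[str, float] = field(default_factory=lambda: {"GCU": 0.25})
    true_sites: tuple[int, float] = (0, 0.9)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.gc < 1:
            raise ConfigError(f"gc {self.gc} outside (0, 1)")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if self.depth_model not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown depth_model {self.depth_model!r}")
        probs = [self.p_base, self.true_sites[1], *self.p_context.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.n_transcripts < 1 or self.length_mean < 10:
            raise ConfigError("need n_transcripts >= 1 and length_mean >= 10")


def generate_transcriptome(config: SimulationConfig) -> list[Transcript]:
    """i.i.d.-letter transcripts with P(G)=P(C)=gc/2; lengths uniform ±20%
    around length_mean. Deterministic under config.seed."""
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    half_gc, half_at = config.gc / 2.0, (1.0 - config.gc) / 2.0
    p = np.array([half_at, half_gc, half_gc, half_at])  # A C G T
    lo, hi = int(round(0.8 * config.length_mean)), int(round(1.2 * config.length_mean))
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    width = len(str(config.n_transcripts))
    return [
        Transcript(
            f"tx{i + 1:0{width}d}",
            "".join(_LETTERS[rng.choice(4, size=n, p=p)]),
        )
        for i, n in enumerate(lengths)
    ]


def _site_plan(ref: list[Transcript], config: SimulationConfig) -> pd.DataFrame:
    """Enumerate every C site with its central 3-mer, generating probability
    and true-modification flag.  Edge cytosines (no full 3-mer) use p_base."""
    rows = []
    for t in ref:
        seq = t.seq
        for pos, base in enumerate(seq):
            if base != "C":
                continue
            if 1 <= pos <= len(seq) - 2:
                kmer = to_rna(seq[pos - 1 : pos + 2])
            else:
                kmer = ""
            rows.append((t.id, pos, kmer))
    plan = pd.DataFrame(rows, columns=["transcript_id", "pos", "kmer"])
    plan["p_call"] = [
        config.p_context.get(km, config.p_base) if km else config.p_base
        for km in plan["kmer"]
    ]
    plan["is_true_modified"] = False
    n_true, frac_true = config.true_sites
    if n_true > 0:
        if n_true > len(plan):
            raise ConfigError(
                f"true_sites count {n_true} exceeds available C sites ({len(plan)})"
            )
        rng = np.random.default_rng([int(config.seed), 1])
        chosen = rng.choice(len(plan), size=n_true, replace=False)
        plan.loc[chosen, "is_true_modified"] = True
        plan.loc[chosen, "p_call"] = frac_true
    return plan


def _draw_depths(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.depth_model == "poisson":
        return rng.poisson(config.depth_mean, size=n)
    # negative binomial parameterized by size (dispersion) and mean
    size = config.nb_size
    return rng.negative_binomial(size, size / (size + config.depth_mean), n)


def simulate_site_table(
    ref: list[Transcript], config: SimulationConfig
) -> tuple[list[SiteRecord], pd.DataFrame]:
    """Direct per-site simulation: depth ~ depth_model(depth_mean), then
    mod_count ~ Binomial(depth, p_site).  Distributionally identical to
    expanding binary per-read calls and aggregating them (and bit-identical
    to :func:`simulate_calls` under the same seed).  Depth-0 sites are
    omitted from the site list but retained in the truth table."""
    config.validate()
    plan = _site_plan(ref, config)
    rng = np.random.default_rng([int(config.seed), 2])
    depths = _draw_depths(len(plan), config, rng)
    mods = rng.binomial(depths, plan["p_call"].to_numpy())
    sites = [
        SiteRecord(tid, int(pos), int(d), int(m), int(m) / int(d))
        for tid, pos, d, m in zip(plan["transcript_id"], plan["pos"], depths, mods)
        if d > 0
    ]
    truth = plan[TRUTH_COLUMNS].copy()
    return sites, truth


def simulate_calls(
    ref: list[Transcript], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-read binary modification calls plus the generating truth table.

    For each C site: depth reads; each read is called modified (p_mod = 1)
    with the site's generating probability, else canonical (p_mod = 0).
    Returns (calls DataFrame with columns read_id/transcript_id/pos/p_mod,
    truth DataFrame covering every C site)."""
    config.validate()
    plan = _site_plan(ref, config)
    rng = np.random.default_rng([int(config.seed), 2])
    depths = _draw_depths(len(plan), config, rng)
    mods = rng.binomial(depths, plan["p_call"].to_numpy())

    total = int(depths.sum())
    tids = np.repeat(plan["transcript_id"].to_numpy(), depths)
    poss = np.repeat(plan["pos"].to_numpy(), depths)
    # within each site: modified reads first, then canonical — the site-level
    # (depth, mod_count) law is all that matters downstream
    read_index = np.concatenate([np.arange(d) for d in depths]) if total else np.array([], int)
    p_mod = (read_index < np.repeat(mods, depths)).astype(float)
    calls = pd.DataFrame(
        {
            "read_id": [f"{t}:{p}:r{i}" for t, p, i in zip(tids, poss, read_index)],
            "transcript_id": tids,
            "pos": poss.astype("int64"),
            "p_mod": p_mod,
        },
        columns=CALL_TABLE_COLUMNS,
    )
    truth = plan[TRUTH_COLUMNS].copy()
    return calls, truth


def make_ivt_config(native: SimulationConfig, seed: Optional[int] = None) -> SimulationConfig:
    """The IVT counterpart of a native config: same context bias (it belongs
    to the caller, not the RNA), no true modification sites, its own seed."""
    return replace(
        native,
        true_sites=(0, native.true_sites[1]),
        seed=native.seed + 1 if seed is None else seed,
    )


def simulate_pair(
    ref: list[Transcript],
    config_native: SimulationConfig,
    config_ivt: SimulationConfig,
    per_read: bool = False,
):
    """Simulate a native/IVT pair over one shared reference.

    Both samples share the reference and (conventionally) the context bias;
    the IVT config normally has no true sites.  RNG streams derive from each
    config's own seed, so the samples are independent.  With ``per_read``
    False (default) returns two (sites, truth) tuples; with True, two
    (calls, truth) tuples.
    """
    if config_native.seed == config_ivt.seed:
        raise ConfigError("native and IVT configs must use different seeds")
    sim = simulate_calls if per_read else simulate_site_table
    return sim(ref, config_native), sim(ref, config_ivt)
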