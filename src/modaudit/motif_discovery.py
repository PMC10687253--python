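"""Motif discovery in top-site context windows.

Two complementary views of context enrichment:

* :func:`count_central_kmers` — exhaustive counting of the k-mer centered on
  each candidate cytosine ("is GCU several-fold more frequent than the
  runner-up among the top sites?").
* :func:`discover_motifs` — a ZOOPS (zero-or-one occurrence per sequence)
  EM position-weight-matrix learner with a 0-order background estimated from
  the input letters, searching the given strand only, widths competing in
  [minw, maxw], successive motifs found after probabilistic erasure, and
  significance from a mononucleotide-shuffle permutation null.

The EM machinery is authored here; significance is empirical (shuffle null)
rather than an analytic E-value: the scientific question — *is the enriched
motif GCU?* — is answered by rank statistics against composition-preserving
shuffles, which are exact and assumption-free at the cost of a resolution
floor of 1/(n_shuffles+1).

Width selection uses a max-standardized-score statistic: every candidate
width's log-likelihood-ratio score is standardized against that width's own
shuffle-null mean and standard deviation, the width with the largest
standardized score wins (ties → smaller width), and the reported empirical
p-value is the selection-adjusted permutation p of the max statistic
(Westfall–Young).  A raw permutation p cannot rank two widths that both beat
every shuffle, so the standardized score is the comparable scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import InputError, InsufficientDataError
from .io_formats import normalize_seq, to_rna
from .site_stats import ContextWindow

ALPHABET = "ACGT"
_ENC = {c: i for i, c in enumerate(ALPHABET)}

#: Pseudocount added to every PWM cell in the M-step and in seeding.
PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class MotifModel:
    """A learned PWM motif with ZOOPS occupancy and empirical significance."""

    width: int
    pwm: np.ndarray  # 4 x width, columns sum to 1, all entries > 0
    occupancy: float  # ZOOPS prior lambda: fraction of sequences with a site
    loglik: float
    consensus: str  # per-column argmax, RNA alphabet
    p_empirical: float
    n_sites: int  # sequences with posterior site probability > 0.5
    score: float = float("nan")  # log-likelihood ratio vs background-only
    loglik_history: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self):
        if self.pwm.shape != (4, self.width):
            raise InputError(f"pwm shape {self.pwm.shape} != (4, {self.width})")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-9):
            raise InputError("pwm columns must sum to 1")
        if (self.pwm <= 0).any():
            raise InputError("pwm entries must be strictly positive")


@dataclass(frozen=True)
class KmerEnrichment:
    """Central k-mer census of a window set (RNA-alphabet keys)."""

    counts: dict[str, int]
    k: int
    total: int

    @property
    def top(self) -> str | None:
        if not self.counts:
            return None
        return max(self.counts, key=lambda m: (self.counts[m], m))

    @property
    def top_to_runner_up_ratio(self) -> float:
        """Count of the most frequent central k-mer over the runner-up count."""
        if len(self.counts) < 2:
            return float("inf") if self.counts else float("nan")
        first, second = sorted(self.counts.values(), reverse=True)[:2]
        return first / second if second else float("inf")


def _windows_to_array(windows: Sequence) -> np.ndarray:
    """Encode equal-length windows as an int8 matrix (A=0,C=1,G=2,T=3)."""
    seqs = []
    for w in windows:
        s = w.window if isinstance(w, ContextWindow) else normalize_seq(str(w))
        bad = set(s) - set(ALPHABET)
        if bad:
            raise InputError(f"window contains letters outside ACGT: {sorted(bad)}")
        seqs.append(s)
    if not seqs:
        return np.zeros((0, 0), dtype=np.int8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise InputError(f"windows have unequal lengths {sorted(lengths)}")
    return np.array([[_ENC[c] for c in s] for s in seqs], dtype=np.int8)


def count_central_kmers(windows: Sequence[ContextWindow], k: int = 3) -> KmerEnrichment:
    """Count the central k-mer of every window (RNA-alphabet report)."""
    if k % 2 != 1:
        raise InputError("k must be odd")
    counts: Counter[str] = Counter()
    for w in windows:
        seq = w.window if isinstance(w, ContextWindow) else normalize_seq(str(w))
        if k > len(seq):
            raise InputError(f"k={k} exceeds window length {len(seq)}")
        mid = len(seq) // 2
        counts[to_rna(seq[mid - k // 2 : mid + k // 2 + 1])] += 1
    return KmerEnrichment(dict(counts), k=k, total=sum(counts.values()))


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

def background_frequencies(X: np.ndarray) -> np.ndarray:
    """0-order background from the input letter frequencies (pseudocounted)."""
    counts = np.bincount(X.ravel(), minlength=4).astype(float) + PSEUDOCOUNT
    return counts / counts.sum()


def seed_pwm(X: np.ndarray, width: int, avail: np.ndarray | None = None) -> np.ndarray:
    """Initialize a PWM from the most frequent width-w word among the windows.

    Word occurrences are weighted by positional availability (product over the
    word's positions), so erased regions stop re-seeding the same motif.
    Ties break toward the lexicographically smallest word (A<C<G<T).
    """
    n, L = X.shape
    m = L - width + 1
    if m < 1:
        raise InputError(f"width {width} exceeds window length {L}")
    win = np.lib.stride_tricks.sliding_window_view(X, width, axis=1)  # n x m x w
    powers = 4 ** np.arange(width - 1, -1, -1)
    codes = win.astype(np.int64) @ powers  # n x m
    if avail is None:
        weights = np.ones_like(codes, dtype=float)
    else:
        weights = np.exp(
            np.lib.stride_tricks.sliding_window_view(
                np.log(np.clip(avail, 1e-12, 1.0)), width, axis=1
            ).sum(axis=2)
        )
    tot = np.bincount(codes.ravel(), weights=weights.ravel(), minlength=4**width)
    best = int(np.argmax(tot))  # argmax returns first (smallest code) on ties
    word = []
    for _ in range(width):
        word.append(best % 4)
        best //= 4
    word = word[::-1]
    pwm = np.full((4, width), PSEUDOCOUNT)
    for k, a in enumerate(word):
        pwm[a, k] += 1.0
    return pwm / pwm.sum(axis=0, keepdims=True)


def em_zoops(
    windows,
    width: int,
    background: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    avail: np.ndarray | None = None,
    init_pwm: np.ndarray | None = None,
    init_lambda: float = 0.5,
    n_shuffles_for_p: int | None = None,
    return_posteriors: bool = False,
):
    """Fit a single ZOOPS motif of fixed ``width`` by EM.

    Model: with probability λ a sequence carries exactly one motif site at a
    uniformly chosen offset (letters ~ PWM there, 0-order background
    elsewhere); with probability 1−λ it is all background.  The E-step
    computes the per-sequence posterior over {no site, site at offset j}; the
    M-step re-estimates the PWM (pseudocount 0.1 per cell) and λ.  Stops when
    the relative log-likelihood change drops below ``tol`` or after
    ``max_iter`` iterations; the log-likelihood is non-decreasing.

    ``avail`` (n x L in [0,1]) down-weights positions claimed by previously
    discovered motifs.  ``seed`` is accepted for interface symmetry; the fit
    itself is deterministic (seeding is the most-frequent-word heuristic).
    """
    X = _windows_to_array(windows) if not isinstance(windows, np.ndarray) else windows
    n, L = X.shape
    m = L - width + 1
    if m < 1:
        raise InputError(f"width {width} exceeds window length {L}")
    bg = background_frequencies(X) if background is None else np.asarray(background, float)
    pwm = seed_pwm(X, width, avail) if init_pwm is None else np.asarray(init_pwm, float)
    lam = float(init_lambda)

    win = np.lib.stride_tricks.sliding_window_view(X, width, axis=1)  # n x m x w
    log_bg_total = np.log(bg)[X].sum()  # background-only loglik, all sequences
    if avail is None:
        log_u = np.zeros((n, m))
    else:
        log_u = np.lib.stride_tricks.sliding_window_view(
            np.log(np.clip(avail, 1e-12, 1.0)), width, axis=1
        ).sum(axis=2)

    cols = np.arange(width)
    history: list[float] = []
    Z = np.zeros((n, m))
    for _ in range(max_iter):
        log_ratio = np.log(pwm) - np.log(bg)[:, None]  # 4 x w
        # s_ij = prod_k pwm[x_(i,j+k),k] / bg[x_(i,j+k)], availability-damped
        logs = log_ratio[win, cols].sum(axis=2) + log_u  # n x m
        s = np.exp(logs)
        site_mass = (lam / m) * s  # n x m
        denom = (1.0 - lam) + site_mass.sum(axis=1)  # n
        ll = log_bg_total + np.log(denom).sum()
        history.append(ll)
        Z = site_mass / denom[:, None]  # posterior of a site at offset j
        q = Z.sum(axis=1)  # posterior of having any site
        if len(history) >= 2 and abs(history[-1] - history[-2]) <= tol * max(
            1.0, abs(history[-1])
        ):
            break
        # M-step
        lam = float(q.mean())
        counts = np.full((4, width), PSEUDOCOUNT)
        zr = Z.ravel()
        for k in range(width):
            counts[:, k] += np.bincount(win[:, :, k].ravel(), weights=zr, minlength=4)
        pwm = counts / counts.sum(axis=0, keepdims=True)

    ll = history[-1]
    consensus = to_rna("".join(ALPHABET[a] for a in pwm.argmax(axis=0)))
    model = MotifModel(
        width=width,
        pwm=pwm,
        occupancy=lam,
        loglik=ll,
        consensus=consensus,
        p_empirical=1.0,
        n_sites=int((Z.sum(axis=1) > 0.5).sum()),
        score=ll - log_bg_total,
        loglik_history=tuple(history),
    )
    if return_posteriors:
        return model, Z
    return model


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def shuffle_windows(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mononucleotide-shuffle every window independently (composition of each
    window preserved exactly)."""
    order = np.argsort(rng.random(X.shape), axis=1)
    return np.take_along_axis(X, order, axis=1)


def shuffle_null(
    windows,
    motif_score_fn: Callable[[np.ndarray], float],
    n_shuffles: int = 100,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Empirical p-value of an observed motif score against a shuffle null.

    Each replicate mononucleotide-shuffles every window independently and
    re-scores with ``motif_score_fn`` (typically: best single-motif EM
    log-likelihood-ratio at the same width).  Returns
    ``p = (1 + #{null >= observed}) / (1 + n_shuffles)`` and the null scores.
    """
    if n_shuffles < 19:
        raise InputError("n_shuffles must be >= 19 for any resolution below 0.05")
    X = _windows_to_array(windows) if not isinstance(windows, np.ndarray) else windows
    rng = np.random.default_rng(seed)
    observed = motif_score_fn(X)
    null = np.array([motif_score_fn(shuffle_windows(X, rng)) for _ in range(n_shuffles)])
    p = (1.0 + int((null >= observed).sum())) / (1.0 + n_shuffles)
    return p, null


# ---------------------------------------------------------------------------
# Multi-motif discovery
# ---------------------------------------------------------------------------

def discover_motifs(
    windows,
    nmotifs: int = 5,
    minw: int = 3,
    maxw: int = 6,
    n_shuffles: int = 100,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> list[MotifModel]:
    """Discover up to ``nmotifs`` enriched motifs with widths in [minw, maxw].

    Given strand only; 0-order background from the input letters.  For each
    motif, EM runs at every candidate width; the width with the largest
    shuffle-standardized log-likelihood-ratio score wins, and its
    selection-adjusted permutation p-value is reported.  Before the next
    motif, each position's availability is multiplied by (1 − its posterior
    site coverage) under the accepted motif (probabilistic erasure).  Null
    score distributions are computed once per width on shuffled windows and
    shared across motifs, which makes later motifs' p-values conservative.

    Deterministic given ``seed``.  Returns motifs sorted by
    (p_empirical, −loglik).
    """
    X = _windows_to_array(windows) if not isinstance(windows, np.ndarray) else windows
    n, L = X.shape
    if n < 10:
        raise InsufficientDataError(f"need >= 10 windows for motif discovery, got {n}")
    if not (1 <= minw <= maxw <= L):
        raise InputError(f"need 1 <= minw <= maxw <= window length; got {minw}..{maxw}, L={L}")
    if nmotifs < 1:
        raise InputError("nmotifs must be >= 1")
    bg = background_frequencies(X)
    widths = list(range(minw, maxw + 1))
    rng = np.random.default_rng(seed)

    def fit_score(Xs: np.ndarray, width: int) -> float:
        model = em_zoops(Xs, width, background=bg, max_iter=max_iter, tol=tol)
        return model.score

    # Null LLR scores, one shuffle set per replicate evaluated at every width.
    null_scores = np.zeros((len(widths), n_shuffles))
    for r in range(n_shuffles):
        Xs = shuffle_windows(X, rng)
        for wi, w in enumerate(widths):
            null_scores[wi, r] = fit_score(Xs, w)
    null_mean = null_scores.mean(axis=1)
    null_sd = np.maximum(null_scores.std(axis=1, ddof=1), 1e-9)
    null_z = (null_scores - null_mean[:, None]) / null_sd[:, None]
    null_max_z = null_z.max(axis=0)  # per-replicate max over widths

    avail = np.ones((n, L))
    motifs: list[MotifModel] = []
    for _ in range(nmotifs):
        fits = []
        for w in widths:
            model, Z = em_zoops(
                X, w, background=bg, max_iter=max_iter, tol=tol,
                avail=avail, return_posteriors=True,
            )
            fits.append((model, Z))
        z_scores = np.array(
            [(f[0].score - null_mean[wi]) / null_sd[wi] for wi, f in enumerate(fits)]
        )
        best_wi = int(np.argmax(z_scores))  # first index wins ties → smaller width
        best_model, best_Z = fits[best_wi]
        T = z_scores[best_wi]
        p = (1.0 + int((null_max_z >= T).sum())) / (1.0 + n_shuffles)
        motifs.append(
            MotifModel(
                width=best_model.width,
                pwm=best_model.pwm,
                occupancy=best_model.occupancy,
                loglik=best_model.loglik,
                consensus=best_model.consensus,
                p_empirical=p,
                n_sites=best_model.n_sites,
                score=best_model.score,
                loglik_history=best_model.loglik_history,
            )
        )
        # Probabilistic erasure: positions claimed by this motif become
        # unavailable in proportion to their posterior site coverage.
        w = best_model.width
        coverage = np.zeros((n, L))
        for j in range(best_Z.shape[1]):
            coverage[:, j : j + w] += best_Z[:, [j]]
        avail *= 1.0 - np.clip(coverage, 0.0, 1.0)
    motifs.sort(key=lambda mdl: (mdl.p_empirical, -mdl.loglik))
    return motifs


def motif_report_rows(motifs: Iterable[MotifModel]) -> list[dict]:
    """Flatten motifs for the TSV report (consensus, width, occupancy, …)."""
    return [
        {
            "consensus": m.consensus,
            "width": m.width,
            "occupancy": round(m.occupancy, 6),
            "n_sites": m.n_sites,
            "score": round(m.score, 4),
            "p_empirical": m.p_empirical,
        }
        for m in motifs
    ]


def format_pwm(m: MotifModel) -> str:
    """Text block for one PWM (rows A/C/G/U; columns are motif positions)."""
    lines = [f"MOTIF {m.consensus} width={m.width} p={m.p_empirical:g}"]
    for i, letter in enumerate("ACGU"):
        row = " ".join(f"{v:.4f}" for v in m.pwm[i])
        lines.append(f"{letter} {row}")
    return "\n".join(lines)
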