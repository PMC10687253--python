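"""Motif discovery: k-mer census oracle, ZOOPS EM guarantees, permutation null."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from modaudit.errors import InputError, InsufficientDataError
from modaudit.motif_discovery import (
    _windows_to_array,
    background_frequencies,
    count_central_kmers,
    discover_motifs,
    em_zoops,
    seed_pwm,
    shuffle_null,
    shuffle_windows,
)

LETTERS = "ACGT"


def _random_windows(rng, n, L):
    return ["".join(rng.choice(list(LETTERS), size=L)) for _ in range(n)]


# --- central k-mer census --------------------------------------------------

def test_count_central_kmers_example():
    wins = ["AGCTA", "TGCTA", "AACTA", "GGCTC"]
    enr = count_central_kmers(wins, k=3)
    assert enr.counts == {"GCU": 3, "ACU": 1}
    assert enr.total == 4
    assert enr.top == "GCU"
    assert enr.top_to_runner_up_ratio == 3.0


def test_count_central_kmers_empty():
    enr = count_central_kmers([], k=3)
    assert enr.counts == {} and enr.total == 0 and enr.top is None


@given(st.integers(0, 2**32 - 1), st.sampled_from([1, 3, 5]))
def test_count_agrees_with_bruteforce(seed, k):
    rng = np.random.default_rng(seed)
    wins = _random_windows(rng, rng.integers(1, 40), 7)
    enr = count_central_kmers(wins, k=k)
    # independent oracle: literal string slicing + Counter
    expected = Counter(
        w[len(w) // 2 - k // 2 : len(w) // 2 + k // 2 + 1].replace("T", "U")
        for w in wins
    )
    assert enr.counts == dict(expected)
    assert sum(enr.counts.values()) == enr.total == len(wins)


# --- ZOOPS EM --------------------------------------------------------------

def test_em_single_window_closed_form():
    """One sequence "AAAA", width 2, uniform background: the fitted columns
    are A-dominated and the final log-likelihood matches the closed form
    evaluated at the fitted parameters:
    log P = log B + log((1-l) + (l/m) * sum_j prod pwm/bg)."""
    bg = np.full(4, 0.25)
    model = em_zoops(["AAAA"], width=2, background=bg)
    assert model.pwm[0].min() > 0.5  # A dominates both columns
    logB = 4 * math.log(0.25)
    s = [model.pwm[0, 0] * model.pwm[0, 1] / (0.25 * 0.25)] * 3  # offsets 0..2
    lam = model.occupancy
    expected = logB + math.log((1 - lam) + lam / 3 * sum(s))
    assert model.loglik == pytest.approx(expected, abs=1e-9)


def test_em_lambda_zero_is_fixed_point():
    init = np.full((4, 3), 0.25)
    model = em_zoops(["ACGTACG", "GGGTTTA"], width=3, init_pwm=init, init_lambda=0.0)
    assert model.occupancy == 0.0
    np.testing.assert_allclose(model.pwm, init, atol=1e-12)


@pytest.mark.parametrize("seed", [0, 7, 123])
def test_em_loglik_monotone(seed):
    rng = np.random.default_rng(seed)
    wins = _random_windows(rng, 30, 11)
    model = em_zoops(wins, width=4)
    hist = np.array(model.loglik_history)
    assert (np.diff(hist) >= -1e-9).all()


def test_em_pwm_columns_normalized():
    rng = np.random.default_rng(5)
    model = em_zoops(_random_windows(rng, 25, 11), width=5)
    np.testing.assert_allclose(model.pwm.sum(axis=0), 1.0, atol=1e-9)
    assert (model.pwm > 0).all()


def test_em_width_exceeding_length_rejected():
    with pytest.raises(InputError):
        em_zoops(["ACGT"], width=5)


def test_seed_pwm_prefers_most_frequent_word():
    # "GCT" appears twice; every other 3-mer at most once
    pwm = seed_pwm(_windows_to_array(["TGCTA", "GGCTC"]), width=3)
    best = "".join(LETTERS[i] for i in pwm.argmax(axis=0))
    assert best == "GCT"


# --- shuffle null ----------------------------------------------------------

def test_shuffle_preserves_letter_counts(rng):
    X = _windows_to_array(_random_windows(rng, 20, 11))
    Xs = shuffle_windows(X, np.random.default_rng(1))
    for row, srow in zip(X, Xs):
        assert np.array_equal(np.bincount(row, minlength=4), np.bincount(srow, minlength=4))
    assert not np.array_equal(X, Xs)


def test_shuffle_null_p_bounds():
    wins = _random_windows(np.random.default_rng(3), 15, 9)
    # score function ignoring content: observed always below nulls -> p = 1
    p, null = shuffle_null(wins, lambda X: 0.0 if X is not None else 0.0, 99, seed=0)
    assert p == 1.0
    # observed strictly above every null -> p = 1/(1+99)
    toggle = {"first": True}

    def fn(X):
        if toggle["first"]:
            toggle["first"] = False
            return 1.0
        return 0.0

    p, _ = shuffle_null(wins, fn, 99, seed=0)
    assert p == pytest.approx(0.01)


def test_shuffle_null_requires_19():
    with pytest.raises(InputError):
        shuffle_null(["ACGTA"] * 10, lambda X: 0.0, n_shuffles=5)


# --- discover_motifs -------------------------------------------------------

def test_discover_planted_word_small():
    """20 windows each embedding ACGTT once recover the word quickly."""
    rng = np.random.default_rng(9)
    word = "ACGTT"
    wins = []
    for _ in range(20):
        s = rng.choice(list(LETTERS), size=12)
        off = rng.integers(0, 12 - 5 + 1)
        s[off : off + 5] = list(word)
        wins.append("".join(s))
    motifs = discover_motifs(wins, nmotifs=1, n_shuffles=49, seed=0)
    assert motifs[0].consensus == "ACGUU"
    assert motifs[0].occupancy > 0.9
    assert motifs[0].p_empirical == pytest.approx(1 / 50)


def test_discover_requires_ten_windows():
    with pytest.raises(InsufficientDataError):
        discover_motifs(["ACGTACGTAAA"] * 9)


def test_discover_rejects_unequal_lengths():
    with pytest.raises(InputError):
        discover_motifs(["ACGTACGTAAA"] * 10 + ["ACGT"], nmotifs=1)


def test_discover_nmotifs_one():
    rng = np.random.default_rng(2)
    motifs = discover_motifs(_random_windows(rng, 12, 11), nmotifs=1, n_shuffles=19, seed=4)
    assert len(motifs) == 1


def test_discover_deterministic_under_seed():
    rng = np.random.default_rng(17)
    wins = _random_windows(rng, 15, 11)
    a = discover_motifs(wins, nmotifs=2, n_shuffles=19, seed=99)
    b = discover_motifs(wins, nmotifs=2, n_shuffles=19, seed=99)
    assert len(a) == len(b) == 2
    for ma, mb in zip(a, b):
        assert ma.consensus == mb.consensus
        assert ma.p_empirical == mb.p_empirical
        assert ma.loglik == mb.loglik
        np.testing.assert_array_equal(ma.pwm, mb.pwm)


def test_motif_p_floor_invariant():
    rng = np.random.default_rng(8)
    motifs = discover_motifs(_random_windows(rng, 12, 11), nmotifs=3, n_shuffles=19, seed=0)
    for m in motifs:
        assert m.p_empirical >= 1 / 20
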