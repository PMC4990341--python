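"""Model-free deviation-from-randomness statistics.

Three classic signatures of human "random" sequence generation, plus
Monte-Carlo chance bands to compare them against:

* lagged conditional probabilities ``Pr(a_t = 1 | a_{t-k} = 1)`` — 0.5 for
  every lag under a fair coin;
* the distribution of Heads counts in disjoint windows of 10 trials — human
  sequences are over-balanced (narrower than Binomial(10, 0.5));
* the probability of alternating as a function of the preceding run length —
  alternation bias at short runs, and its suppression at long runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._errors import InsufficientDataError, ValidationError
from .generators import generate_fair_coin
from .sequences import ChoiceSequence

__all__ = [
    "RunLengthStats",
    "conditional_probability",
    "conditional_probability_profile",
    "heads_count_distribution",
    "alternation_by_run_length",
    "chance_band",
]


def _as_list(seqs) -> list[ChoiceSequence]:
    if isinstance(seqs, ChoiceSequence):
        return [seqs]
    return list(seqs)


def conditional_probability(seqs, k: int) -> tuple[float, int]:
    """Pooled estimate of ``Pr(a_t = 1 | a_{t-k} = 1)`` with its count.

    Accepts one sequence or an iterable (trials pooled across sequences,
    never across sequence boundaries).  Returns ``(nan, 0)`` when no trial
    satisfies the conditioning event.
    """
    if k < 1:
        raise ValidationError("lag k must be >= 1")
    hits = 0
    total = 0
    for s in _as_list(seqs):
        a = s.choices
        if a.size < k + 1:
            raise InsufficientDataError(f"sequence shorter than k+1={k + 1}")
        cond = a[:-k] == 1
        total += int(cond.sum())
        hits += int((a[k:][cond] == 1).sum())
    if total == 0:
        return float("nan"), 0
    return hits / total, total


def conditional_probability_profile(
    seqs, ks: Sequence[int], pooled: bool = True
) -> pd.DataFrame:
    """Conditional probabilities over a range of lags.

    ``pooled=True`` pools conditioning trials across participants before the
    ratio; ``pooled=False`` averages per-participant estimates (both views
    are reported because population and individual analyses differ when
    participants are heterogeneous).
    """
    seqs = _as_list(seqs)
    rows = []
    for k in ks:
        if pooled:
            p, n = conditional_probability(seqs, k)
        else:
            per = [conditional_probability(s, k) for s in seqs]
            vals = [v for v, n in per if n > 0]
            p = float(np.mean(vals)) if vals else float("nan")
            n = int(sum(n for _, n in per))
        rows.append({"lag": k, "p_cond": p, "n_cond": n})
    return pd.DataFrame(rows)


def heads_count_distribution(seqs, window: int = 10) -> np.ndarray:
    """Distribution of the number of 1s in disjoint consecutive windows.

    Windows are disjoint (not sliding), mirroring the row structure of the
    original generation task.  Returns a probability vector over counts
    ``0..window`` that sums to 1 exactly.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    counts = np.zeros(window + 1)
    for s in _as_list(seqs):
        a = s.choices
        n_win = a.size // window
        if n_win == 0:
            raise InsufficientDataError(
                f"sequence of length {a.size} has no complete window of {window}"
            )
        sums = a[: n_win * window].reshape(n_win, window).sum(axis=1)
        counts += np.bincount(sums, minlength=window + 1)
    return counts / counts.sum()


@dataclass
class RunLengthStats:
    """Alternation probability conditioned on the preceding run length."""

    run_lengths: np.ndarray  # distinct RL values observed, ascending
    p_alternate: np.ndarray  # Pr(a_t != a_{t-1} | RL)
    counts: np.ndarray  # tallies per RL; sums to N-1 per sequence

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_length": self.run_lengths,
                "p_alternate": self.p_alternate,
                "count": self.counts,
            }
        )


def alternation_by_run_length(seqs) -> RunLengthStats:
    """Probability of alternating after runs of each observed length.

    For every trial ``t >= 2`` the preceding run length is the maximal number
    of identical symbols ending at ``t-1`` (runs truncated by the sequence
    start count at their observed length).
    """
    alt_counts: dict[int, int] = {}
    tot_counts: dict[int, int] = {}
    for s in _as_list(seqs):
        a = s.choices
        if a.size < 2:
            raise InsufficientDataError("need at least 2 trials")
        same = a[1:] == a[:-1]
        # run length ending at each trial: distance to the last run start
        starts = np.concatenate(([0], np.flatnonzero(~same) + 1))
        t_idx = np.arange(a.size)
        rl = t_idx - starts[np.searchsorted(starts, t_idx, side="right") - 1] + 1
        keys = rl[:-1]  # preceding run length for trials t = 2..N (1-based)
        alts = ~same
        tot_b = np.bincount(keys)
        alt_b = np.bincount(keys[alts], minlength=tot_b.size)
        for r in np.flatnonzero(tot_b):
            tot_counts[int(r)] = tot_counts.get(int(r), 0) + int(tot_b[r])
            alt_counts[int(r)] = alt_counts.get(int(r), 0) + int(alt_b[r])
    rls = np.array(sorted(tot_counts), dtype=np.int64)
    tot = np.array([tot_counts[r] for r in rls], dtype=np.int64)
    alt = np.array([alt_counts.get(int(r), 0) for r in rls], dtype=np.int64)
    return RunLengthStats(run_lengths=rls, p_alternate=alt / tot, counts=tot)


def chance_band(
    statistic: Callable[[list[ChoiceSequence]], np.ndarray],
    n_trials: int,
    n_sims: int = 1000,
    seed: int | None = None,
    n_sequences: int = 1,
    band: tuple[float, float] = (2.5, 97.5),
) -> dict[str, np.ndarray]:
    """Monte-Carlo null distribution of a statistic under fair coins.

    ``statistic`` maps a list of sequences to a fixed-length array; it is
    recomputed on ``n_sims`` fair-coin datasets matched in size.  Returns the
    per-entry null mean and two-sided percentile band.
    """
    if n_sims < 100:
        raise ValidationError("n_sims must be >= 100 for a stable band")
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_sims):
        coins = generate_fair_coin(
            n_trials, n_sequences, seed=int(rng.integers(0, 2**31))
        )
        sims.append(np.asarray(statistic(coins), dtype=float))
    sims = np.vstack(sims)
    return {
        "mean": np.nanmean(sims, axis=0),
        "lo": np.nanpercentile(sims, band[0], axis=0),
        "hi": np.nanpercentile(sims, band[1], axis=0),
    }
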