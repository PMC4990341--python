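"""Choice/reward sequence containers, long-format CSV/TSV I/O, lagged designs.

A :class:`ChoiceSequence` holds one participant's ordered binary choices
``a_t`` (1 = Heads, 0 = Tails) and, for operant tasks, the rewards ``r_t``
received on each trial.  :func:`build_lag_design` converts a sequence into the
regression layout used throughout the package: for each trial ``t`` the signed
history codes ``s_{t-k} = a_{t-k} - (1 - a_{t-k}) ∈ {-1, +1}`` for lags
``k = 1..L``, optionally interacted with past rewards.  Under this coding a
negative lag-1 coefficient means a propensity to alternate and a positive one
means inertia.

Trial indices are 1-based in files and 0-based in memory.  The first ``L``
trials of a sequence have incomplete history and are dropped from the design
(no padding), so a length-``N`` sequence yields exactly ``N - L`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import FormatError, InsufficientDataError, ValidationError

__all__ = [
    "ChoiceSequence",
    "LagDesign",
    "build_lag_design",
    "stack_designs",
    "read_sequences",
    "write_sequences",
]


@dataclass
class ChoiceSequence:
    """One participant's ordered binary choices with optional rewards.

    Parameters
    ----------
    participant_id : str
        Identifier of the participant the sequence belongs to.
    choices : array-like of {0, 1}
        Ordered choices, index 0 = first trial.
    rewards : array-like of float, optional
        Reward delivered on each trial; same length as ``choices``.  Absent
        for random-sequence-generation data.
    block_id : str, optional
        Block label for operant sessions; histories never cross blocks.
    """

    participant_id: str
    choices: np.ndarray
    rewards: np.ndarray | None = None
    block_id: str | None = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices)
        if self.choices.ndim != 1 or self.choices.size < 1:
            raise ValidationError("choices must be a non-empty 1-D array")
        if not np.isin(self.choices, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(self.choices, (0, 1)))[0]
            raise ValidationError(
                f"choice at trial {bad + 1} of participant "
                f"{self.participant_id!r} is not in {{0, 1}}"
            )
        self.choices = self.choices.astype(np.int8)
        if self.rewards is not None:
            self.rewards = np.asarray(self.rewards, dtype=float)
            if self.rewards.shape != self.choices.shape:
                raise ValidationError(
                    "rewards must have the same length as choices"
                )
            if not np.isfinite(self.rewards).all():
                raise ValidationError("rewards must be finite")

    def __len__(self) -> int:
        return int(self.choices.size)

    @property
    def n_trials(self) -> int:
        return len(self)


@dataclass
class LagDesign:
    """Signed-lag design matrix aligned to a binary response vector.

    Row ``i`` corresponds to trial ``t = L + 1 + i`` (1-based) of the source
    sequence; column ``k-1`` of ``signed_lags`` holds
    ``s_{t-k} = 2 a_{t-k} - 1``.  ``reward_lags`` (when present) holds
    ``s_{t-k} * r_{t-k}`` in the same layout.
    """

    responses: np.ndarray
    signed_lags: np.ndarray
    L: int
    reward_lags: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.signed_lags = np.asarray(self.signed_lags, dtype=float)
        if self.signed_lags.shape != (self.responses.size, self.L):
            raise ValidationError("signed_lags shape does not match responses/L")
        if not np.isin(self.signed_lags, (-1.0, 1.0)).all():
            raise ValidationError("signed_lags entries must be -1 or +1")
        if self.reward_lags is not None:
            self.reward_lags = np.asarray(self.reward_lags, dtype=float)
            if self.reward_lags.shape != self.signed_lags.shape:
                raise ValidationError("reward_lags shape mismatch")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.responses.shape:
                raise ValidationError("weights length mismatch")
            if (not np.isfinite(self.weights).all()) or (self.weights < 0).any():
                raise ValidationError("weights must be finite and non-negative")
            if self.weights.sum() <= 0:
                raise ValidationError("weights must have positive sum")

    @property
    def n_obs(self) -> int:
        return int(self.responses.size)

    def matrix(self, include_rewards: bool = False) -> np.ndarray:
        """Full design matrix with an intercept column first.

        Column order: intercept, s_{t-1}..s_{t-L}[, s_{t-1}r_{t-1}..s_{t-L}r_{t-L}].
        """
        cols = [np.ones((self.n_obs, 1)), self.signed_lags]
        if include_rewards:
            if self.reward_lags is None:
                raise ValidationError("design has no reward_lags")
            cols.append(self.reward_lags)
        return np.hstack(cols)

    def subset(self, idx: np.ndarray) -> "LagDesign":
        """Row-subset of the design (used by cross-validation folds)."""
        return LagDesign(
            responses=self.responses[idx],
            signed_lags=self.signed_lags[idx],
            L=self.L,
            reward_lags=None if self.reward_lags is None else self.reward_lags[idx],
            weights=None if self.weights is None else self.weights[idx],
        )


def build_lag_design(
    seq: ChoiceSequence, L: int, include_rewards: bool = False
) -> LagDesign:
    """Build the lagged design for one sequence.

    The first ``L`` trials are dropped (their history is incomplete); the
    design has exactly ``len(seq) - L`` rows.

    Raises
    ------
    InsufficientDataError
        If ``L >= len(seq)``.
    ValidationError
        If ``L < 1`` or rewards are requested but absent.
    """
    if L < 1:
        raise ValidationError(f"L must be >= 1, got {L}")
    n = len(seq)
    if L >= n:
        raise InsufficientDataError(
            f"sequence of length {n} cannot support lag order L={L}"
        )
    if include_rewards and seq.rewards is None:
        raise ValidationError("include_rewards=True but sequence has no rewards")

    a = seq.choices.astype(float)
    s = 2.0 * a - 1.0
    # column k-1 holds s_{t-k}: shift the signed series right by k
    signed = np.column_stack([s[L - k : n - k] for k in range(1, L + 1)])
    reward_lags = None
    if include_rewards:
        r = seq.rewards
        reward_lags = np.column_stack(
            [s[L - k : n - k] * r[L - k : n - k] for k in range(1, L + 1)]
        )
    return LagDesign(
        responses=a[L:], signed_lags=signed, L=L, reward_lags=reward_lags
    )


def stack_designs(designs: Sequence[LagDesign]) -> LagDesign:
    """Stack designs row-wise (pooled fits; histories never cross sources)."""
    designs = list(designs)
    if not designs:
        raise ValidationError("no designs to stack")
    L = designs[0].L
    if any(d.L != L for d in designs):
        raise ValidationError("all designs must share the same L")
    has_r = all(d.reward_lags is not None for d in designs)
    has_w = all(d.weights is not None for d in designs)
    return LagDesign(
        responses=np.concatenate([d.responses for d in designs]),
        signed_lags=np.vstack([d.signed_lags for d in designs]),
        L=L,
        reward_lags=np.vstack([d.reward_lags for d in designs]) if has_r else None,
        weights=np.concatenate([d.weights for d in designs]) if has_w else None,
    )


_REQUIRED = ("participant", "trial", "choice")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_sequences(path: str | Path) -> list[ChoiceSequence]:
    """Read long-format choice data into a list of :class:`ChoiceSequence`.

    The file must have a header with columns ``participant,trial,choice`` and
    may have ``reward`` and ``block``.  Trials are 1-based in files.  One
    sequence is returned per participant, or per (participant, block) pair
    when a block column is present.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    bad = df.loc[~df["choice"].isin((0, 1))]
    if len(bad):
        row = bad.index[0]
        raise ValidationError(
            f"{path.name}: choice {bad['choice'].iloc[0]!r} at file row "
            f"{row + 2} is not in {{0, 1}}"
        )
    keys = ["participant"] + (["block"] if "block" in df.columns else [])
    if df.duplicated(subset=keys + ["trial"]).any():
        dup = df[df.duplicated(subset=keys + ["trial"], keep=False)].iloc[0]
        raise ValidationError(
            f"{path.name}: duplicate trial {dup['trial']} for participant "
            f"{dup['participant']!r}"
        )
    out: list[ChoiceSequence] = []
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("trial")
        if not isinstance(key, tuple):
            key = (key,)
        pid = str(key[0])
        block = str(key[1]) if len(key) > 1 else None
        rewards = None
        if "reward" in df.columns:
            rewards = grp["reward"].to_numpy()
            if np.isnan(rewards).all():
                rewards = None  # mixed files: reward-free sequences stay so
        out.append(
            ChoiceSequence(
                participant_id=pid,
                choices=grp["choice"].to_numpy(),
                rewards=rewards,
                block_id=block,
            )
        )
    return out


def write_sequences(seqs: Iterable[ChoiceSequence], path: str | Path) -> None:
    """Write sequences in the long format :func:`read_sequences` accepts."""
    path = Path(path)
    rows = []
    seqs = list(seqs)
    any_reward = any(s.rewards is not None for s in seqs)
    any_block = any(s.block_id is not None for s in seqs)
    for s in seqs:
        for i, c in enumerate(s.choices):
            row = {"participant": s.participant_id, "trial": i + 1, "choice": int(c)}
            if any_reward:
                row["reward"] = s.rewards[i] if s.rewards is not None else np.nan
            if any_block:
                row["block"] = s.block_id
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def group_by_participant(
    seqs: Iterable[ChoiceSequence],
) -> dict[str, list[ChoiceSequence]]:
    """Group sequences (e.g. operant blocks) by participant id, order kept."""
    out: dict[str, list[ChoiceSequence]] = {}
    for s in seqs:
        out.setdefault(s.participant_id, []).append(s)
    return out
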