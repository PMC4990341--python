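"""Sequence containers, file round-trips and lagged design construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqfx import (
    ChoiceSequence,
    build_lag_design,
    read_sequences,
    stack_designs,
    write_sequences,
)
from seqfx._errors import (
    FormatError,
    InsufficientDataError,
    ValidationError,
)


def test_read_two_row_csv(tmp_path):
    p = tmp_path / "tiny.csv"
    p.write_text("participant,trial,choice\np1,1,1\np1,2,0\n")
    seqs = read_sequences(p)
    assert len(seqs) == 1
    assert seqs[0].participant_id == "p1"
    assert seqs[0].choices.tolist() == [1, 0]


@pytest.mark.parametrize(
    "content,exc",
    [
        ("participant,trial\np1,1\n", FormatError),
        ("participant,trial,choice\np1,1,2\n", ValidationError),
        ("participant,trial,choice\np1,1,1\np1,1,0\n", ValidationError),
    ],
)
def test_read_rejects_malformed_files(tmp_path, content, exc):
    p = tmp_path / "bad.csv"
    p.write_text(content)
    with pytest.raises(exc):
        read_sequences(p)


@pytest.mark.parametrize("ext", ["csv", "tsv"])
def test_write_read_roundtrip(tmp_path, rng, ext):
    seqs = [
        ChoiceSequence("a", rng.integers(0, 2, 50)),
        ChoiceSequence("b", rng.integers(0, 2, 50), rewards=rng.random(50)),
    ]
    p = tmp_path / f"rt.{ext}"
    write_sequences(seqs, p)
    back = read_sequences(p)
    for orig, rb in zip(seqs, back):
        assert rb.participant_id == orig.participant_id
        np.testing.assert_array_equal(rb.choices, orig.choices)
        if orig.rewards is not None:
            np.testing.assert_allclose(rb.rewards, orig.rewards)
    # second round-trip is the identity
    p2 = tmp_path / f"rt2.{ext}"
    write_sequences(back, p2)
    assert [s.choices.tolist() for s in read_sequences(p2)] == [
        s.choices.tolist() for s in back
    ]


def test_blocks_become_separate_sequences(tmp_path):
    p = tmp_path / "blocks.csv"
    p.write_text(
        "participant,trial,choice,block\n"
        "p1,1,1,b1\np1,2,0,b1\np1,1,1,b2\np1,2,1,b2\n"
    )
    seqs = read_sequences(p)
    assert [(s.participant_id, s.block_id) for s in seqs] == [
        ("p1", "b1"),
        ("p1", "b2"),
    ]


def test_choice_sequence_validates():
    with pytest.raises(ValidationError):
        ChoiceSequence("p", [0, 1, 2])
    with pytest.raises(ValidationError):
        ChoiceSequence("p", [0, 1], rewards=[1.0])
    with pytest.raises(ValidationError):
        ChoiceSequence("p", [])


def test_build_lag_design_coding():
    seq = ChoiceSequence("p", [1, 0, 1, 1])
    d = build_lag_design(seq, 2)
    assert d.responses.tolist() == [1.0, 1.0]
    # row for trial 3: (s_2, s_1) = (-1, +1); trial 4: (s_3, s_2) = (+1, -1)
    assert d.signed_lags.tolist() == [[-1.0, 1.0], [1.0, -1.0]]


def test_build_lag_design_reward_interaction():
    seq = ChoiceSequence("p", [1, 1, 1], rewards=[1.0, 0.0, 1.0])
    d = build_lag_design(seq, 1, include_rewards=True)
    assert d.reward_lags.tolist() == [[1.0], [0.0]]


def test_all_zero_sequence_gives_all_minus_one():
    d = build_lag_design(ChoiceSequence("p", np.zeros(10, dtype=int)), 3)
    assert (d.signed_lags == -1.0).all()


def test_build_lag_design_errors():
    seq = ChoiceSequence("p", [1, 0, 1])
    with pytest.raises(InsufficientDataError):
        build_lag_design(seq, 3)
    with pytest.raises(ValidationError):
        build_lag_design(seq, 0)
    with pytest.raises(ValidationError):
        build_lag_design(seq, 1, include_rewards=True)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    bits=st.lists(st.integers(0, 1), min_size=2, max_size=40),
    data=st.data(),
)
def test_design_shape_and_flip_symmetry(bits, data):
    """N-L rows for any valid L; flipping every bit negates the coding."""
    L = data.draw(st.integers(1, len(bits) - 1))
    seq = ChoiceSequence("p", bits)
    d = build_lag_design(seq, L)
    assert d.n_obs == len(bits) - L
    flipped = build_lag_design(ChoiceSequence("p", [1 - b for b in bits]), L)
    np.testing.assert_array_equal(flipped.signed_lags, -d.signed_lags)
    np.testing.assert_array_equal(flipped.responses, 1.0 - d.responses)


def test_stack_designs_concatenates_rows(rng):
    s1 = ChoiceSequence("a", rng.integers(0, 2, 20))
    s2 = ChoiceSequence("b", rng.integers(0, 2, 30))
    stacked = stack_designs([build_lag_design(s, 4) for s in (s1, s2)])
    assert stacked.n_obs == (20 - 4) + (30 - 4)
    assert stacked.L == 4
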