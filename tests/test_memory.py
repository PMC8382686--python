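"""Instance memory: encoding/merging, base-level activation, blending."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matg import InstanceChunk, MemoryStore, activation
from matg.exceptions import ClockError, NoExperienceError, RetrievalFailureError
from matg.memory import recency_bin, return_bin

CTX = ("high", "1")


class TestEncoding:
    def test_single_observation_creates_one_chunk(self):
        store = MemoryStore()
        store.encode_instance(0, CTX, 0.75, 1)
        assert len(store.chunks) == 1
        assert store.chunks[0].encodings == [1]

    def test_repeated_observation_strengthens_chunk(self):
        store = MemoryStore()
        store.encode_instance(0, CTX, 0.75, 3)
        store.encode_instance(0, CTX, 0.75, 7)
        assert len(store.chunks) == 1
        assert store.chunks[0].encodings == [3, 7]

    def test_distinct_values_make_distinct_chunks(self):
        store = MemoryStore()
        store.encode_instance(0, CTX, 0.25, 1)
        store.encode_instance(0, CTX, 0.75, 2)
        assert len(store.chunks) == 2

    def test_clock_must_not_run_backwards(self):
        store = MemoryStore()
        store.encode_instance(0, CTX, 0.75, 5)
        with pytest.raises(ClockError):
            store.encode_instance(1, CTX, 0.5, 4)

    def test_same_round_different_counterparts_allowed(self):
        store = MemoryStore()
        store.encode_instance(0, CTX, 0.75, 5)
        store.encode_instance(1, CTX, 0.25, 5)
        assert len(store.chunks) == 2


class TestActivation:
    def test_single_encoding_one_round_ago(self):
        chunk = InstanceChunk(0, CTX, 0.5, [9])
        assert activation(chunk, 10, d=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_two_encodings_closed_form(self):
        # encodings 1 and 4 rounds ago: ln(1 + 4^-0.5) = ln 1.5
        chunk = InstanceChunk(0, CTX, 0.5, [6, 9])
        assert activation(chunk, 10, d=0.5) == pytest.approx(math.log(1.5), abs=1e-9)

    def test_activation_decays_with_time(self):
        chunk = InstanceChunk(0, CTX, 0.5, [3, 8])
        acts = [activation(chunk, now, 0.5) for now in range(9, 40)]
        assert all(a > b for a, b in zip(acts, acts[1:]))

    def test_re_encoding_increases_activation(self):
        weak = InstanceChunk(0, CTX, 0.5, [3])
        strong = InstanceChunk(0, CTX, 0.5, [3, 8])
        for now in (9, 15, 50):
            assert activation(strong, now, 0.5) > activation(weak, now, 0.5)

    def test_recency_beats_equal_frequency(self):
        older = InstanceChunk(0, CTX, 0.5, [2, 4])
        newer = InstanceChunk(0, CTX, 0.5, [6, 8])
        assert activation(newer, 10, 0.5) > activation(older, 10, 0.5)

    def test_empty_chunk_signals_retrieval_failure(self):
        with pytest.raises(RetrievalFailureError):
            activation(InstanceChunk(0, CTX, 0.5, []), 10, 0.5)


class TestBlending:
    def test_single_chunk_returns_its_value(self):
        store = MemoryStore()
        store.encode_instance(0, CTX, 0.75, 1)
        assert store.blended_prediction(0, CTX, 5) == pytest.approx(0.75)

    def test_equal_activation_symmetric_average(self):
        store = MemoryStore()
        store.encode_instance(0, CTX, 0.5, 3)
        store.encode_instance(0, CTX, 1.0, 3)
        assert store.blended_prediction(0, CTX, 10) == pytest.approx(0.75, abs=1e-9)

    def test_boltzmann_weights_closed_form(self):
        # chunk B's activation exceeds chunk A's by tau*ln 3, so the weights
        # are exactly 1/4 and 3/4 and the blend of values 0 and 1 is 0.75
        d = 0.5
        a1 = 0.0                      # one encoding 1 round ago
        a2 = math.log(1 + 2 ** -0.5)  # encodings 1 and 2 rounds ago
        tau = (a2 - a1) / math.log(3.0)
        store = MemoryStore(d=d, tau=tau)
        store.encode_instance(0, CTX, 1.0, 8)
        store.encode_instance(0, CTX, 0.0, 9)
        # re-encode value 1.0 so its chunk holds encodings [8, 9]
        store.encode_instance(0, CTX, 1.0, 9)
        assert store.blended_prediction(0, CTX, 10) == pytest.approx(0.75, abs=1e-9)

    def test_context_fallback_uses_all_counterpart_chunks(self):
        store = MemoryStore()
        store.encode_instance(0, ("low", "1"), 0.25, 1)
        pred = store.blended_prediction(0, ("high", "4+"), 5)
        assert pred == pytest.approx(0.25)

    def test_no_experience_signalled(self):
        with pytest.raises(NoExperienceError):
            MemoryStore().blended_prediction(0, CTX, 5)

    @settings(max_examples=40, deadline=None)
    @given(
        values=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=6
        ),
        now_offset=st.integers(1, 30),
    )
    def test_blend_matches_brute_force_and_is_convex(self, values, now_offset):
        store = MemoryStore()
        for i, v in enumerate(values):
            store.encode_instance(0, CTX, v, i + 1)
        now = len(values) + now_offset
        pred = store.blended_prediction(0, CTX, now)
        # independent brute-force oracle over the stored chunks
        chunks = store.chunks
        acts = np.array(
            [np.log(np.sum((now - np.array(c.encodings)) ** -0.5)) for c in chunks]
        )
        w = np.exp(acts / store.tau - np.max(acts / store.tau))
        w = w / w.sum()
        expected = float(np.dot(w, [c.value for c in chunks]))
        assert pred == pytest.approx(expected, abs=1e-9)
        vals = [c.value for c in chunks]
        assert min(vals) - 1e-12 <= pred <= max(vals) + 1e-12


class TestContextBins:
    @pytest.mark.parametrize(
        "frac,bin_", [(None, "none"), (0.2, "low"), (0.5, "neutral"), (0.75, "high")]
    )
    def test_return_bins(self, frac, bin_):
        assert return_bin(frac) == bin_

    @pytest.mark.parametrize(
        "since,bin_", [(1, "1"), (2, "2-3"), (3, "2-3"), (4, "4+"), (None, "4+")]
    )
    def test_recency_bins(self, since, bin_):
        assert recency_bin(since) == bin_


def test_jsonl_round_trip(tmp_path):
    store = MemoryStore()
    store.encode_instance(0, ("high", "1"), 0.75, 1)
    store.encode_instance(1, ("low", "4+"), 0.25, 2)
    store.encode_instance(0, ("high", "1"), 0.75, 3)
    path = tmp_path / "memory.jsonl"
    store.dump_jsonl(path)
    loaded = MemoryStore.load_jsonl(path)
    assert {(c.counterpart, c.context, c.value, tuple(c.encodings)) for c in loaded.chunks} == {
        (c.counterpart, c.context, c.value, tuple(c.encodings)) for c in store.chunks
    }
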