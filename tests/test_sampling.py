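"""Undersampling, incremental oversampling, and training-set assembly."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beatvote.dataset import AamiClass
from beatvote.sampling import (
    build_training_set,
    oversample_incremental,
    standard_sampling_config,
    undersample,
)
from beatvote.segmentation import BeatSegment


def _segments(cls, n, length=8):
    return [
        BeatSegment(np.full(length, float(i)), cls, f"r{i}", i) for i in range(n)
    ]


class TestStandardSamplingConfig:
    def test_targets(self):
        cfg = standard_sampling_config(1, base_seed=0)
        assert cfg.target_counts[AamiClass.N] == 11188
        assert cfg.target_counts[AamiClass.S] == 7544
        assert cfg.target_counts[AamiClass.V] == 4592
        assert cfg.target_counts[AamiClass.F] == "unchanged"
        assert cfg.target_counts[AamiClass.Q] == "unchanged"

    def test_n_seed_differs_per_member_but_shared_seed_is_common(self):
        cfgs = [standard_sampling_config(i, base_seed=42) for i in range(1, 7)]
        assert len({c.n_seed for c in cfgs}) == 6
        assert len({c.shared_seed for c in cfgs}) == 1

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            standard_sampling_config(0, 0)
        with pytest.raises(ValueError):
            standard_sampling_config(7, 0)

    def test_n_fraction_of_training_set_with_ds1_like_counts(self):
        # DS1 pool sizes; F and Q pass through, so the trained-set total
        # is 11188+7544+4592+414+8 and N sits just above 47.1% of it.
        total = 11188 + 7544 + 4592 + 414 + 8
        frac = 100 * 11188 / total
        assert 47.11 <= frac <= 47.12


class TestUndersample:
    def test_exact_size_and_distinct(self):
        pool = _segments(AamiClass.N, 200)
        out = undersample(pool, 50, seed=1)
        assert len(out) == 50
        assert len({id(s) for s in out}) == 50

    def test_target_equal_pool_is_set_identity(self):
        pool = _segments(AamiClass.N, 10)
        out = undersample(pool, 10, seed=5)
        assert {id(s) for s in out} == {id(s) for s in pool}

    def test_target_above_pool_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            undersample(_segments(AamiClass.N, 5), 6, seed=0)

    def test_deterministic_under_seed(self):
        pool = _segments(AamiClass.N, 100)
        a = [s.r_index for s in undersample(pool, 30, seed=9)]
        b = [s.r_index for s in undersample(pool, 30, seed=9)]
        assert a == b

    def test_inclusion_frequency_matches_hypergeometric_marginal(self):
        """Each item should be included with probability target/|pool|."""
        pool = list(range(20))
        target, reps = 8, 2000
        counts = collections.Counter()
        for seed in range(reps):
            counts.update(undersample(pool, target, seed=seed))
        expected = target / len(pool) * reps  # 800
        sd = np.sqrt(reps * (target / len(pool)) * (1 - target / len(pool)))  # ~22
        for item in pool:
            assert abs(counts[item] - expected) < 5 * sd


class TestOversampleIncremental:
    def test_size_and_every_original_present(self):
        pool = _segments(AamiClass.S, 943)
        out = oversample_incremental(pool, 7544, seed=2)
        assert len(out) == 7544
        assert {id(s) for s in pool} <= {id(s) for s in out}

    def test_identity_when_target_equals_pool(self):
        pool = _segments(AamiClass.S, 7)
        assert oversample_incremental(pool, 7, seed=0) == pool

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            oversample_incremental([], 5, seed=0)

    @given(n=st.integers(1, 10), extra=st.integers(0, 35), seed=st.integers(0, 99))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_multiplicity_spread_at_most_one(self, n, extra, seed):
        pool = list(range(n))
        out = oversample_incremental(pool, n + extra, seed=seed)
        counts = collections.Counter(out)
        assert len(out) == n + extra
        assert max(counts.values()) - min(counts[i] for i in pool) <= 1


class TestBuildTrainingSet:
    def _pools(self):
        return {
            AamiClass.N: _segments(AamiClass.N, 400),
            AamiClass.S: _segments(AamiClass.S, 30),
            AamiClass.V: _segments(AamiClass.V, 60),
            AamiClass.F: _segments(AamiClass.F, 9),
            AamiClass.Q: _segments(AamiClass.Q, 2),
        }

    def test_scaled_targets_respected_per_class(self):
        targets = {
            AamiClass.N: 100,
            AamiClass.S: 90,
            AamiClass.V: 80,
            AamiClass.F: "unchanged",
            AamiClass.Q: "unchanged",
        }
        cfg = standard_sampling_config(1, 0)
        cfg = type(cfg)(target_counts=targets, n_seed=cfg.n_seed, shared_seed=cfg.shared_seed)
        ts = build_training_set(self._pools(), cfg)
        assert ts.class_counts == {
            AamiClass.N: 100,
            AamiClass.S: 90,
            AamiClass.V: 80,
            AamiClass.F: 9,
            AamiClass.Q: 2,
        }
        assert sum(ts.class_counts.values()) == len(ts.segments)

    def test_rebuild_is_identical_and_shared_classes_equal_across_members(self):
        pools = self._pools()
        sets = {}
        for member in (1, 2):
            cfg = standard_sampling_config(member, base_seed=7)
            cfg = type(cfg)(
                target_counts={
                    AamiClass.N: 100, AamiClass.S: 90, AamiClass.V: 80,
                    AamiClass.F: "unchanged", AamiClass.Q: "unchanged",
                },
                n_seed=cfg.n_seed,
                shared_seed=cfg.shared_seed,
            )
            sets[member] = build_training_set(pools, cfg)
            again = build_training_set(pools, cfg)
            assert [id(s) for s in again.segments] == [
                id(s) for s in sets[member].segments
            ]

        def by_class(ts, cls):
            return [id(s) for s in ts.segments if s.label is cls]

        for cls in (AamiClass.S, AamiClass.V, AamiClass.F, AamiClass.Q):
            assert by_class(sets[1], cls) == by_class(sets[2], cls)
        assert by_class(sets[1], AamiClass.N) != by_class(sets[2], AamiClass.N)
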