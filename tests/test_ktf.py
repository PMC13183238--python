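"""Kernel-team fusion: partition rules, forward contracts, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles
from ktyolo.ktf import KernelTeamConfig, KTFBlock, KernelTeam, partition_channels


def cfg(**kw):
    return KernelTeamConfig(**kw)


class TestPartition:
    @pytest.mark.parametrize(
        "total, expected_groups, expected_kernels",
        [
            (64, [16, 16, 16, 16], [1, 3, 5, 7]),
            (36, [9, 9, 9, 9], [1, 3, 5, 7]),
            (20, [10, 10], [1, 3]),  # drop-largest fallback keeps each >= 8
            (6, [6], [3]),           # degenerate single-group rule
        ],
    )
    def test_documented_partitions(self, total, expected_groups, expected_kernels):
        p = partition_channels(total, cfg())
        assert p.group_channels == expected_groups
        assert p.group_kernels == expected_kernels

    def test_remainder_goes_to_smallest_kernels_first(self):
        p = partition_channels(34, cfg())
        assert p.group_channels == [9, 9, 8, 8]
        assert p.group_kernels == [1, 3, 5, 7]

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            partition_channels(0, cfg())

    @given(total=st.integers(1, 512))
    @settings(max_examples=512, deadline=None)
    def test_channel_conservation_and_minimum_over_sweep(self, total):
        c = cfg()
        p = partition_channels(total, c)
        assert sum(p.group_channels) == total
        if not p.degenerate:
            assert all(g >= c.min_channels_per_group for g in p.group_channels)
        else:
            assert len(p.group_channels) == 1
        # largest kernels are dropped first, so surviving kernels are a prefix
        assert p.group_kernels == list(c.kernel_sizes[: len(p.group_kernels)]) or p.degenerate

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KernelTeamConfig(kernel_sizes=(2, 3))
        with pytest.raises(ValueError):
            KernelTeamConfig(kernel_sizes=(3, 3))
        with pytest.raises(ValueError):
            KernelTeamConfig(kernel_sizes=())
        with pytest.raises(ValueError):
            KernelTeamConfig(work_fraction=0.0)


class TestKernelTeamForward:
    def test_shape_contract_and_spatial_preservation(self):
        rng = np.random.default_rng(0)
        p = partition_channels(64, cfg())
        team = KernelTeam(p, 64, rng=rng)
        x = rng.normal(size=(2, 64, 11, 7)).astype(np.float32)
        y = team(x)
        assert y.shape == (2, 64, 11, 7)

    def test_channel_mismatch_rejected(self):
        team = KernelTeam(partition_channels(16, cfg()), 16)
        with pytest.raises(ValueError):
            team(np.zeros((1, 12, 4, 4), dtype=np.float32))

    def test_zero_input_zero_betas_gives_zero_output(self):
        # with BN shift terms zeroed, SiLU(0) = 0 propagates through the stack
        team = KernelTeam(partition_channels(16, cfg()), 8)
        y = team(np.zeros((1, 16, 5, 5), dtype=np.float32))
        assert np.allclose(y, 0.0)

    def test_matches_bruteforce_convolution_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(12):
            total = int(rng.integers(4, 24))
            out = int(rng.integers(2, 12))
            team = KernelTeam(partition_channels(total, cfg()), out,
                              rng=np.random.default_rng(100 + trial))
            # randomize BN statistics so eval mode is nontrivial
            for m in team.branches + [team.fuse]:
                m.bn.running_mean[:] = rng.normal(0, 0.2, m.bn.running_mean.shape)
                m.bn.running_var[:] = rng.uniform(0.5, 2.0, m.bn.running_var.shape)
            h, w = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            x = rng.normal(size=(1, total, h, w)).astype(np.float32)
            ref = _oracles.kernel_team_ref(team, x)
            got = team(x)
            assert got.shape == ref.shape
            assert np.max(np.abs(got - ref)) < 1e-5


class TestKTFBlock:
    def test_shape_contract(self):
        c = cfg(out_channels=64)
        blk = KTFBlock(64, c, rng=np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(1, 64, 10, 10)).astype(np.float32)
        assert blk(x).shape == (1, 64, 10, 10)

    def test_invalid_out_channels_rejected(self):
        with pytest.raises(ValueError):
            KTFBlock(8, cfg(out_channels=0))

    def test_gradient_reaches_both_split_halves(self):
        c = cfg(out_channels=16)
        blk = KTFBlock(16, c, rng=np.random.default_rng(0))
        x = np.random.default_rng(2).normal(size=(1, 16, 6, 6)).astype(np.float32)
        y = blk(x, train=True)
        dx = blk.backward(np.ones_like(y))
        assert dx.shape == x.shape
        assert np.abs(dx).min() >= 0 and (np.abs(dx) > 0).mean() > 0.99

    def test_matches_composition_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(8):
            cin = int(rng.integers(4, 20))
            cout = int(rng.integers(4, 16))
            blk = KTFBlock(cin, cfg(out_channels=cout),
                           rng=np.random.default_rng(300 + trial))
            mods = [blk.entry, blk.fuse, blk.team.fuse] + blk.team.branches
            for m in mods:
                m.bn.running_mean[:] = rng.normal(0, 0.2, m.bn.running_mean.shape)
                m.bn.running_var[:] = rng.uniform(0.5, 2.0, m.bn.running_var.shape)
            x = rng.normal(size=(1, cin, 6, 6)).astype(np.float32)
            ref = _oracles.ktf_block_ref(blk, x)
            got = blk(x)
            assert np.max(np.abs(got - ref)) < 1e-5

    def test_eval_mode_is_deterministic(self):
        blk = KTFBlock(12, cfg(out_channels=12), rng=np.random.default_rng(0))
        x = np.random.default_rng(3).normal(size=(2, 12, 5, 5)).astype(np.float32)
        assert np.array_equal(blk(x), blk(x))
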