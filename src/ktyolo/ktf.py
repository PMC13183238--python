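"""Kernel-Team Fusion: multi-kernel channel-partitioned convolution blocks.

The kernel team splits its input channels into groups, one per kernel size
(default 1/3/5/7, all same-padded), convolves each group in parallel with
its own kernel, stacks the branch outputs along channels and fuses them with
a 1x1 convolution.  The enclosing KTF block wraps the team CSP-style: an
entry 1x1 projection, a channel split into a shortcut part and a work part,
the kernel team on the work part, then concatenation and a final 1x1 fusion.

Channel partitioning is even with a minimum group width: when the input is
too narrow to give every kernel its minimum share, the largest kernels are
dropped one at a time; below the minimum altogether, a single group with the
smallest non-1x1 kernel takes all channels.  Remainder channels from uneven
division go to the smallest-kernel groups first, keeping the expensive
large-kernel branches at or below the even share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Concat, ConvBN, Module

__all__ = [
    "KernelTeamConfig",
    "ChannelPartition",
    "partition_channels",
    "KernelTeam",
    "KTFBlock",
]


@dataclass
class KernelTeamConfig:
    kernel_sizes: tuple = (1, 3, 5, 7)
    min_channels_per_group: int = 8
    work_fraction: float = 0.5
    out_channels: int | None = None

    def __post_init__(self):
        ks = tuple(self.kernel_sizes)
        if not ks:
            raise ValueError("kernel_sizes must be non-empty")
        if any(k < 1 or k % 2 == 0 for k in ks):
            raise ValueError("kernel sizes must be odd positive integers")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("kernel sizes must be strictly increasing")
        if self.min_channels_per_group < 1:
            raise ValueError("min_channels_per_group must be >= 1")
        if not 0.0 < self.work_fraction <= 1.0:
            raise ValueError("work_fraction must lie in (0, 1]")
        self.kernel_sizes = ks


@dataclass
class ChannelPartition:
    group_channels: list
    group_kernels: list
    degenerate: bool = field(default=False)

    def __post_init__(self):
        if len(self.group_channels) != len(self.group_kernels):
            raise ValueError("group_channels and group_kernels must align")
        if any(c < 1 for c in self.group_channels):
            raise ValueError("every group must hold at least one channel")

    @property
    def total(self) -> int:
        return int(sum(self.group_channels))


def partition_channels(total_channels: int, cfg: KernelTeamConfig) -> ChannelPartition:
    """Partition ``total_channels`` across the configured kernel sizes.

    Even division with remainder channels assigned to the smallest kernels
    first; kernels are dropped largest-first while the even share would fall
    below ``min_channels_per_group``; if even a single minimum share does not
    fit, one degenerate group with the smallest non-1x1 kernel holds all
    channels.
    """
    if total_channels <= 0:
        raise ValueError(f"total_channels must be positive, got {total_channels}")
    kernels = list(cfg.kernel_sizes)
    m = cfg.min_channels_per_group
    if total_channels < m:
        fallback = next((k for k in kernels if k > 1), None)
        if fallback is None:
            fallback = 3 if not kernels else kernels[0]
        return ChannelPartition([total_channels], [fallback], degenerate=True)
    while len(kernels) > 1 and total_channels < len(kernels) * m:
        kernels.pop()  # drop the largest kernel
    n = len(kernels)
    base, rem = divmod(total_channels, n)
    groups = [base + (1 if i < rem else 0) for i in range(n)]
    return ChannelPartition(groups, kernels)


class KernelTeam(Module):
    """Parallel per-group convolutions + SiLU, stacked and fused by 1x1."""

    def __init__(self, partition: ChannelPartition, out_channels: int,
                 rng: np.random.Generator | None = None):
        if out_channels < 1:
            raise ValueError("out_channels must be positive")
        rng = rng or np.random.default_rng(0)
        self.partition = partition
        self.branches = [
            ConvBN(c, c, k, rng=rng)
            for c, k in zip(partition.group_channels, partition.group_kernels)
        ]
        self.stack = Concat()
        self.fuse = ConvBN(partition.total, out_channels, 1, rng=rng)
        self.out_channels = out_channels

    def forward(self, work, train: bool = False):
        if work.shape[1] != self.partition.total:
            raise ValueError(
                f"work tensor has {work.shape[1]} channels, partition expects {self.partition.total}"
            )
        outs, at = [], 0
        for c, branch in zip(self.partition.group_channels, self.branches):
            outs.append(branch(work[:, at : at + c], train=train))
            at += c
        return self.fuse(self.stack(*outs, train=train), train=train)

    def backward(self, dy):
        dstack = self.stack.backward(self.fuse.backward(dy))
        parts = [b.backward(d) for b, d in zip(self.branches, dstack)]
        return np.concatenate(parts, axis=1)


class KTFBlock(Module):
    """CSP-style block around a kernel team; spatial size is preserved.

    Entry 1x1 projects to the block width (= ``cfg.out_channels``); the last
    ``work_fraction`` of the channels feed the kernel team, the rest pass
    through as a shortcut; shortcut and team output are concatenated and
    fused to ``out_channels`` by a final 1x1 convolution.
    """

    def __init__(self, cin: int, cfg: KernelTeamConfig,
                 rng: np.random.Generator | None = None):
        if cin < 2:
            raise ValueError("KTF block needs at least 2 input channels")
        if cfg.out_channels is None or cfg.out_channels <= 0:
            raise ValueError("cfg.out_channels must be a positive integer")
        rng = rng or np.random.default_rng(0)
        cout = cfg.out_channels
        width = max(2, cout)
        work_c = int(round(cfg.work_fraction * width))
        work_c = min(max(work_c, 1), width - 1) if cfg.work_fraction < 1.0 else width
        self.entry = ConvBN(cin, width, 1, rng=rng)
        self.shortcut_channels = width - work_c
        self.work_channels = work_c
        self.team = KernelTeam(partition_channels(work_c, cfg), work_c, rng=rng)
        self.concat = Concat()
        self.fuse = ConvBN(width, cout, 1, rng=rng)
        self.cfg = cfg
        self.out_channels = cout

    def forward(self, x, train: bool = False):
        y = self.entry(x, train=train)
        s = self.shortcut_channels
        if s > 0:
            short, work = y[:, :s], y[:, s:]
            team_out = self.team(work, train=train)
            merged = self.concat(short, team_out, train=train)
        else:
            merged = self.team(y, train=train)
        return self.fuse(merged, train=train)

    def backward(self, dy):
        dmerged = self.fuse.backward(dy)
        s = self.shortcut_channels
        if s > 0:
            dshort, dteam = self.concat.backward(dmerged)
            dwork = self.team.backward(dteam)
            dentry = np.concatenate([dshort, dwork], axis=1)
        else:
            dentry = self.team.backward(dmerged)
        return self.entry.backward(dentry)
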