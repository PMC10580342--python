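"""Canonical 10-20 scalp montage and edge vectorization.

All feature vectors in the pipeline are ordered by the upper triangle
(row-major, i < j) of the channel-by-channel matrix over this fixed
19-channel order, giving C(19, 2) = 171 edges.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "F7", "F8",
    "T3", "T4", "T5", "T6", "O1", "O2", "Fz", "Cz", "Pz",
)

N_CHANNELS = len(CHANNELS)
N_EDGES = N_CHANNELS * (N_CHANNELS - 1) // 2  # 171

CHANNEL_INDEX = {name.upper(): k for k, name in enumerate(CHANNELS)}


def channel_index(name: str) -> int:
    """Index of a channel label (case-insensitive, 'EEG ' prefix tolerated)."""
    key = name.upper().removeprefix("EEG ").strip()
    try:
        return CHANNEL_INDEX[key]
    except KeyError:
        raise KeyError(f"unknown channel label {name!r}") from None


def edge_pairs(n_channels: int = N_CHANNELS) -> list[tuple[int, int]]:
    """Upper-triangle (i, j) index pairs in canonical row-major order."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def edge_labels(channels: tuple[str, ...] = CHANNELS) -> list[str]:
    """Edge names like ``'C3-C4'`` in canonical edge order."""
    return [f"{channels[i]}-{channels[j]}" for i, j in edge_pairs(len(channels))]


def edge_index(i: int, j: int, n_channels: int = N_CHANNELS) -> int:
    """Position of unordered pair (i, j) in the canonical edge vector."""
    if i == j:
        raise ValueError("self-pairs carry no edge")
    if i > j:
        i, j = j, i
    if not 0 <= i < j < n_channels:
        raise ValueError(f"pair ({i}, {j}) outside montage of {n_channels}")
    return i * n_channels - i * (i + 1) // 2 + (j - i - 1)
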