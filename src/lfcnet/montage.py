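"""Canonical 12-channel 10-20 montage, electrode pairs, and scalp regions.

The pipeline analyses 12 standard scalp electrodes (Fp1, Fp2, F3, Fz, F4,
C3, Cz, C4, P3, Pz, P4, Oz).  All modules refer to channels through the
fixed order defined here, and to electrode pairs through the canonical
upper-triangle enumeration ``all_pairs()``.
"""

from __future__ import annotations

from typing import Sequence

CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4",
    "C3", "Cz", "C4", "P3", "Pz", "P4", "Oz",
)

N_CHANNELS = len(CHANNELS)

#: Channels carrying the P300-like deflection in the generator and the
#: automated P300 screen (centro-parietal sites).
CENTRO_PARIETAL: tuple[str, ...] = ("C3", "Cz", "C4", "P3", "Pz")

#: Scalp-region grouping of the 12 electrodes.  The prefrontal and frontal
#: rows are additionally pooled into a "joint F region".
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "Fz", "F4"),
    "prefrontal": ("Fp1", "Fp2"),
    "left central": ("C3",),
    "right central": ("C4",),
    "middle central": ("Cz",),
    "left parietal": ("P3",),
    "right parietal": ("P4",),
    "middle parietal": ("Pz",),
    "occipital": ("Oz",),
}

JOINT_F_REGION: tuple[str, ...] = ("Fp1", "Fp2", "F3", "Fz", "F4")

#: Approximate 2-D scalp layout (x: left-negative, y: anterior-positive),
#: used only for network plotting.
LAYOUT_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F3": (-0.55, 0.48), "Fz": (0.0, 0.50), "F4": (0.55, 0.48),
    "C3": (-0.65, 0.0), "Cz": (0.0, 0.0), "C4": (0.65, 0.0),
    "P3": (-0.55, -0.48), "Pz": (0.0, -0.50), "P4": (0.55, -0.48),
    "Oz": (0.0, -0.95),
}


def channel_index(name: str) -> int:
    """Index of ``name`` in the canonical order; raises for unknown labels."""
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise ValueError(
            f"unknown electrode {name!r}; montage is {', '.join(CHANNELS)}"
        ) from None


def all_pairs(channels: Sequence[str] = CHANNELS) -> list[tuple[str, str]]:
    """All unordered channel pairs in canonical (index-sorted) order.

    For the 12-channel montage this enumerates the 66 = 12*11/2 pairs.
    """
    return [
        (channels[i], channels[j])
        for i in range(len(channels))
        for j in range(i + 1, len(channels))
    ]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a pair by channel index; validates both labels."""
    ia, ib = channel_index(a), channel_index(b)
    if ia == ib:
        raise ValueError(f"pair must join two distinct electrodes, got {a!r} twice")
    return (a, b) if ia < ib else (b, a)


def pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


def map_regions(electrode: str) -> list[str]:
    """Scalp region(s) for an electrode.

    Prefrontal/frontal electrodes belong both to their own row and to the
    pooled "joint F region"; all other electrodes map to a single region.
    """
    channel_index(electrode)  # validate
    out = [name for name, chans in REGIONS.items() if electrode in chans]
    if electrode in JOINT_F_REGION:
        out.append("joint F")
    return out
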