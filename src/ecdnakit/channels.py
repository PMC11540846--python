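"""SBS96 trinucleotide channel conventions.

Channels follow the conventional pyrimidine-centred order: six substitution
blocks C>A, C>G, C>T, T>A, T>C, T>G, each expanded over the 16 flanking-base
combinations with the 5' base varying slowest, e.g. ``A[C>A]A``, ``A[C>A]C``,
..., ``T[T>G]T``. Indices are 1-based (1..96) throughout the package and in
the TNC INFO tag of VCFs.
"""

from __future__ import annotations

from .errors import FormatError

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: The 96 channel strings in canonical order.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

N_CHANNELS = 96

_INDEX = {name: i + 1 for i, name in enumerate(CHANNELS)}


def channel_string(index: int) -> str:
    """Return the channel string (e.g. ``"A[C>A]A"``) for a 1-based index."""
    if not 1 <= index <= N_CHANNELS:
        raise FormatError(f"channel index {index} outside 1..{N_CHANNELS}")
    return CHANNELS[index - 1]


def channel_index(channel: int | str) -> int:
    """Coerce a channel given as index or string to its 1-based index."""
    if isinstance(channel, str):
        try:
            return _INDEX[channel]
        except KeyError:
            raise FormatError(f"unknown channel string {channel!r}") from None
    idx = int(channel)
    if not 1 <= idx <= N_CHANNELS:
        raise FormatError(f"channel index {idx} outside 1..{N_CHANNELS}")
    return idx


def ref_alt(channel: int | str) -> tuple[str, str]:
    """Reference and alternate base (pyrimidine-centred) for a channel."""
    name = channel_string(channel_index(channel))
    return name[2], name[4]
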