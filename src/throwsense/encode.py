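"""Symbolic encoding of leveled triples.

Each ternary triple (lx, ly, lz) in {-1, 0, +1}^3 maps to one of 27
symbols per channel: 'A'..'Z' plus '1' for the forearm, 'a'..'z' plus '2'
for the upper arm.  Both alphabets derive from one canonical status table
so the two channels can never drift apart.  The digit symbols encode the
all-zero (rest) triple and are retained in sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CHANNELS, FOREARM, UPPERARM

#: Canonical status table: triples in status order 0..26; status k maps to
#: the k-th character of each channel alphabet.
TABLE_TRIPLES: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 0, -1), (0, -1, 0), (-1, 0, 0),
    (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
    (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1), (1, -1, -1), (-1, 1, -1),
    (-1, -1, 1), (-1, -1, -1),
    (0, 0, 0),
)

FOREARM_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ1"
UPPERARM_ALPHABET = "abcdefghijklmnopqrstuvwxyz2"
ALPHABETS = {FOREARM: FOREARM_ALPHABET, UPPERARM: UPPERARM_ALPHABET}

REST_SYMBOLS = {"1", "2"}

_TRIPLE_TO_STATUS = {t: i for i, t in enumerate(TABLE_TRIPLES)}
_SYMBOL_TO_STATUS = {c: i for i, c in enumerate(FOREARM_ALPHABET)}
_SYMBOL_TO_STATUS.update({c: i for i, c in enumerate(UPPERARM_ALPHABET)})

# flat lookup from (lx+1)*9 + (ly+1)*3 + (lz+1) to status index, for array encoding
_FLAT_STATUS = np.empty(27, dtype=np.intp)
for _t, _i in _TRIPLE_TO_STATUS.items():
    _FLAT_STATUS[(_t[0] + 1) * 9 + (_t[1] + 1) * 3 + (_t[2] + 1)] = _i


def triple_to_symbol(triple, channel: str) -> str:
    """Map one leveled triple to its channel symbol (Table-driven bijection)."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    key = tuple(int(v) for v in triple)
    if key not in _TRIPLE_TO_STATUS:
        raise ValueError(f"triple {key} has components outside {{-1, 0, 1}}")
    return ALPHABETS[channel][_TRIPLE_TO_STATUS[key]]


def symbol_to_triple(symbol: str) -> tuple[tuple[int, int, int], str]:
    """Inverse map: symbol -> (triple, channel)."""
    if symbol not in _SYMBOL_TO_STATUS:
        raise ValueError(f"unknown symbol {symbol!r}")
    channel = FOREARM if symbol in FOREARM_ALPHABET else UPPERARM
    return TABLE_TRIPLES[_SYMBOL_TO_STATUS[symbol]], channel


def symbol_channel(symbol: str) -> str:
    """Channel a symbol belongs to."""
    return symbol_to_triple(symbol)[1]


def encode_levels(levels: np.ndarray, channel: str) -> str:
    """Vectorized encoding of an (n, 3) level array into a symbol string."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    lv = np.asarray(levels, dtype=np.int64)
    if lv.size == 0:
        return ""
    if lv.ndim != 2 or lv.shape[1] != 3:
        raise ValueError("levels must have shape (n, 3)")
    if np.any(np.abs(lv) > 1):
        raise ValueError("level components must lie in {-1, 0, 1}")
    flat = (lv[:, 0] + 1) * 9 + (lv[:, 1] + 1) * 3 + (lv[:, 2] + 1)
    alpha = np.frombuffer(ALPHABETS[channel].encode(), dtype=np.uint8)
    return alpha[_FLAT_STATUS[flat]].tobytes().decode()


@dataclass(frozen=True)
class ThrowSequencePair:
    """Time-aligned forearm and upper-arm symbol strings for one recording."""

    forearm: str
    upper: str

    def __post_init__(self) -> None:
        if len(self.forearm) != len(self.upper):
            raise ValueError("channel sequences must have equal length")

    def __len__(self) -> int:
        return len(self.forearm)

    def segment(self, start: int, stop: int) -> "ThrowSequencePair":
        return ThrowSequencePair(self.forearm[start:stop], self.upper[start:stop])


def encode_pair(forearm_levels: np.ndarray, upper_levels: np.ndarray) -> ThrowSequencePair:
    """Encode both channels' level traces into an aligned sequence pair."""
    f = np.asarray(forearm_levels)
    u = np.asarray(upper_levels)
    if f.shape != u.shape:
        raise ValueError("channel level traces must have equal length")
    return ThrowSequencePair(encode_levels(f, FOREARM), encode_levels(u, UPPERARM))


@dataclass
class RunLengthSeq:
    """Lossless run-length view of a symbol string."""

    symbols: list[str]
    lengths: list[int]

    def expand(self) -> str:
        return "".join(s * n for s, n in zip(self.symbols, self.lengths))

    def __len__(self) -> int:
        return len(self.symbols)


def compress_runs(seq: str) -> RunLengthSeq:
    """Run-length encode a string; adjacent symbols in the output always differ."""
    symbols: list[str] = []
    lengths: list[int] = []
    for ch in seq:
        if symbols and symbols[-1] == ch:
            lengths[-1] += 1
        else:
            symbols.append(ch)
            lengths.append(1)
    return RunLengthSeq(symbols, lengths)
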