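"""Lightweight read containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

_RNA2DNA = str.maketrans("acgun", "ACGTN")
_UP = str.maketrans("acgtun", "ACGTTN")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA letters (U) to the DNA alphabet (T)."""
    return seq.translate(_UP).replace("U", "T")


@dataclass
class ReadRecord:
    """One basecalled (or simulated) direct-RNA read, stored 5'->3' in DNA letters."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)
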