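"""Shared domain primitives: isomiR keys and small sequence helpers."""

from __future__ import annotations

import re
from dataclasses import dataclass

_KEY_RE = re.compile(r"^(?P<acc>[^|]+)\|(?P<shift>-?\d+)$")

_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")


@dataclass(frozen=True, order=True)
class IsomiRKey:
    """Identity of a 5' isoform: mature accession plus signed 5' shift.

    ``shift`` is the signed nucleotide offset of the isoform 5' start
    relative to the archetype 5' start. Positive shifts point downstream
    (into the miRNA body), negative shifts upstream. The archetype itself
    carries shift 0 and renders as ``"<accession>|0"``.
    """

    accession: str
    shift: int

    @property
    def label(self) -> str:
        return f"{self.accession}|{self.shift}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def parse(cls, label: str) -> "IsomiRKey":
        m = _KEY_RE.match(label.strip())
        if m is None:
            raise ValueError(f"not a valid isomiR label: {label!r}")
        return cls(m.group("acc"), int(m.group("shift")))

    @property
    def is_archetype(self) -> bool:
        return self.shift == 0


def reverse_complement(seq: str) -> str:
    """Reverse complement in RNA space (T treated as U)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")
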