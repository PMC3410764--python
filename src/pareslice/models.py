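"""Core record types shared across the pipeline.

Internal sequence alphabet is DNA: transcripts are stored with ``T`` and
miRNAs keep their native RNA alphabet (``U``); pairing logic converts on
the fly.  All coordinates are 1-based inclusive.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Tuple

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp_dna(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Tissue(str, Enum):
    COTYLEDON = "cotyledon"
    SEED_COAT = "seed_coat"

    @classmethod
    def parse(cls, value: "Tissue | str") -> "Tissue":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace(" ", "_").replace("-", "_")
        for member in cls:
            if member.value == key:
                return member
        raise ValueError(f"unknown tissue {value!r}")


class Region(str, Enum):
    """Transcript region holding a cleavage site."""

    UTR5 = "5'UTR"
    CDS = "CDS"
    UTR3 = "3'UTR"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: "Region | str") -> "Region":
        if isinstance(value, cls):
            return value
        key = str(value).strip().replace(" ", "").upper()
        mapping = {
            "5'UTR": cls.UTR5,
            "CDS": cls.CDS,
            "3'UTR": cls.UTR3,
            "UNKNOWN": cls.UNKNOWN,
        }
        if key in mapping:
            return mapping[key]
        raise ValueError(f"unknown region {value!r}")


@dataclass(frozen=True)
class Transcript:
    """A mapping-target sequence with optional CDS interval and annotation."""

    id: str
    seq: str
    cds: Optional[Tuple[int, int]] = None
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id}: characters outside ACGTN: {sorted(bad)}"
            )
        if self.cds is not None:
            start, end = self.cds
            if not (1 <= start <= end <= len(self.seq)):
                raise ValueError(
                    f"transcript {self.id}: CDS interval {self.cds} outside "
                    f"[1, {len(self.seq)}]"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA, 5'->3' in the RNA alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("miRNA id must be nonempty")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"miRNA {self.id}: characters outside ACGUN: {sorted(bad)}")
        if not 19 <= len(self.seq) <= 24:
            warnings.warn(
                f"miRNA {self.id}: unusual length {len(self.seq)} (expected 19-24)",
                stacklevel=2,
            )

    @property
    def dna(self) -> str:
        """The miRNA with U mapped to T (for exact-match arithmetic)."""
        return self.seq.replace("U", "T")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; ``quals`` are Phred scores when available."""

    id: str
    seq: str
    quals: Optional[Tuple[int, ...]] = None

    @property
    def mean_quality(self) -> Optional[float]:
        if self.quals is None:
            return None
        if not self.quals:
            return 0.0
        return sum(self.quals) / len(self.quals)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Library:
    """A degradome read library with its tissue/stage metadata.

    Tissue and stage come from configuration, never from the name.
    """

    name: str
    tissue: Tissue
    stage: str = ""
    reads: List[ReadRecord] = field(default_factory=list)


@dataclass(frozen=True)
class TargetCall:
    """One classified cleavage-target call (one output table row)."""

    library: str
    mirna: str
    target: str
    c_site: int
    location: Region
    category: int
    tp100m: float
    p_value: float
    score: float = math.nan
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in (0, 1, 2, 3, 4):
            raise ValueError(f"category must be in 0..4, got {self.category}")
        if self.tp100m < 0:
            raise ValueError("tp100m must be >= 0")
        if self.c_site < 1:
            raise ValueError("c_site must be >= 1")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")

    def sort_key(self) -> Tuple[str, str, str, int]:
        return (self.library, self.mirna, self.target, self.c_site)
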