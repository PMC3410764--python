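"""Shared fixtures: small random sequence factories and crafted libraries."""
from __future__ import annotations

from typing import List, Optional

import numpy as np
import pytest

from pareslice.models import (
    Library,
    MatureMiRNA,
    ReadRecord,
    Tissue,
    Transcript,
    revcomp_dna,
)

# A real mature miRNA sequence (21 nt), used as a stable test anchor.
MIR160_SEQ = "UGCCUGGCUCCCUGUAUGCCA"


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=length)])


def plant_site(seq: str, mirna: MatureMiRNA, end: int) -> str:
    """Embed the exact reverse complement of ``mirna`` so that miRNA nt 1
    pairs 1-based position ``end``; returns the modified sequence."""
    site = revcomp_dna(mirna.dna)
    start = end - len(site)
    assert start >= 0
    return seq[:start] + site + seq[end:]


def make_library(
    name: str,
    seqs: List[str],
    quals: Optional[int] = 40,
    tissue: Tissue = Tissue.COTYLEDON,
) -> Library:
    reads = [
        ReadRecord(
            f"{name}_r{i}",
            s,
            None if quals is None else (quals,) * len(s),
        )
        for i, s in enumerate(seqs)
    ]
    return Library(name=name, tissue=tissue, reads=reads)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120716)


@pytest.fixture
def mir160() -> MatureMiRNA:
    return MatureMiRNA("gma-miR160", MIR160_SEQ)


@pytest.fixture
def planted_transcript(rng, mir160) -> Transcript:
    """A 400 nt transcript carrying the exact miR160 complement at 101-121."""
    seq = plant_site(random_dna(rng, 400), mir160, end=121)
    return Transcript("t1", seq, cds=(51, 350))
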