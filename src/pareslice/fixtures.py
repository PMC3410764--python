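"""Packaged table fixtures transcribed from the source study.

``table3``/``table4`` hold the cotyledon-only and seed-coat-only target
tables as call records; ``table5`` holds the three annotation columns of
the dataset comparison.
"""
from __future__ import annotations

import math
from importlib import resources
from typing import List, NamedTuple

from .models import Region, TargetCall

_FILES = {"table3": "table3.tsv", "table4": "table4.tsv", "table5": "table5.tsv"}


class AnnotationFixture(NamedTuple):
    """The three columns of the comparison table, in printed order."""

    only_a: List[str]  # unique to the five-library dataset
    only_b: List[str]  # unique to the early-seed dataset
    common: List[str]


def _read(name: str) -> List[str]:
    text = (
        resources.files("pareslice").joinpath("data", _FILES[name]).read_text()
    )
    return [
        line
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def load_fixture(name: str):
    """Load a packaged fixture: ``table3``/``table4`` -> list of TargetCall,
    ``table5`` -> :class:`AnnotationFixture`."""
    if name not in _FILES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(_FILES)}")
    lines = _read(name)
    if name == "table5":
        cols: List[List[str]] = [[], [], []]
        for line in lines[1:]:
            cells = line.split("\t")
            for i in range(3):
                if i < len(cells) and cells[i].strip():
                    cols[i].append(cells[i].strip())
        return AnnotationFixture(only_a=cols[0], only_b=cols[1], common=cols[2])
    calls: List[TargetCall] = []
    for line in lines[1:]:
        mirna, tissue, target, annotation, c_site, location, category, tp, p = (
            line.split("\t")
        )
        calls.append(
            TargetCall(
                library=tissue,
                mirna=mirna,
                target=target,
                c_site=int(c_site),
                location=Region.parse(location),
                category=int(category),
                tp100m=float(tp),
                p_value=float(p),
                score=math.nan,
                annotation=annotation,
            )
        )
    return calls


#: tissue metadata for the library names used in the packaged tables
FIXTURE_LIBRARY_TISSUES = {
    "C25": "cotyledon",
    "C100": "cotyledon",
    "C300": "cotyledon",
    "SC25": "seed_coat",
    "SC100": "seed_coat",
}
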