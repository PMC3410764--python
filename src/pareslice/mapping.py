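"""Read filtering and exact-match mapping onto transcripts.

Only sense-strand, perfect matches count as degradome evidence.  Identical
read sequences are collapsed to (sequence, multiplicity) before matching
and every matching locus receives the full multiplicity (no fractional
weighting of multi-mappers).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .models import Library, ReadRecord, Transcript

logger = logging.getLogger(__name__)


@dataclass
class FilteredReads:
    """Length/quality-filtered reads plus the accounting needed for reports."""

    library: str
    reads: List[ReadRecord]
    total_input: int
    total_len_selected: int
    n_dropped_length: int = 0
    n_dropped_quality: int = 0


def filter_reads(
    library: Library,
    min_len: int = 20,
    max_len: int = 21,
    min_mean_q: float = 20.0,
    adapter: Optional[str] = None,
) -> FilteredReads:
    """Keep reads with length in ``[min_len, max_len]`` and mean Phred >= ``min_mean_q``.

    Reads without qualities skip the quality filter (a notice is logged).
    ``adapter`` is a pass-through hook: reads still starting with the
    configured adapter prefix are flagged in the log, not removed.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept: List[ReadRecord] = []
    n_len = 0
    n_qual = 0
    n_adapter = 0
    quality_notice_sent = False
    probe = adapter[:10] if adapter else None
    for read in library.reads:
        if probe and read.seq.startswith(probe):
            n_adapter += 1
        if not (min_len <= len(read) <= max_len):
            n_len += 1
            continue
        mq = read.mean_quality
        if mq is None:
            if not quality_notice_sent:
                logger.info(
                    "library %s: reads carry no qualities; quality filter skipped",
                    library.name,
                )
                quality_notice_sent = True
        elif mq < min_mean_q:
            n_qual += 1
            continue
        kept.append(read)
    if n_adapter:
        logger.warning(
            "library %s: %d reads still begin with the configured adapter prefix",
            library.name,
            n_adapter,
        )
    return FilteredReads(
        library=library.name,
        reads=kept,
        total_input=len(library.reads),
        total_len_selected=len(kept),
        n_dropped_length=n_len,
        n_dropped_quality=n_qual,
    )


@dataclass
class SignatureProfile:
    """Per-transcript 5'-end signature counts for one library.

    ``counts`` maps transcript id -> {1-based position -> raw count}.
    """

    library: str
    counts: Dict[str, Dict[int, int]] = field(default_factory=dict)
    total_mapped: int = 0
    total_input: int = 0
    total_len_selected: int = 0

    def transcript_counts(self, transcript_id: str) -> Dict[int, int]:
        return self.counts.get(transcript_id, {})


def build_profile(
    filtered: FilteredReads, transcripts: Sequence[Transcript]
) -> SignatureProfile:
    """Map reads exactly (sense strand) and accumulate 5'-end counts.

    Each read contributes its full multiplicity at *every* matching locus;
    a read with at least one match increments ``total_mapped`` once per
    copy.  Reads containing N never match.
    """
    profile = SignatureProfile(
        library=filtered.library,
        total_input=filtered.total_input,
        total_len_selected=filtered.total_len_selected,
    )
    distinct = Counter(r.seq for r in filtered.reads)
    usable = {s: m for s, m in distinct.items() if s and "N" not in s}
    if not usable:
        return profile
    k = min(len(s) for s in usable)
    index: Dict[str, List[Tuple[int, int]]] = {}
    for ti, tr in enumerate(transcripts):
        seq = tr.seq
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((ti, pos))
    for seq, mult in usable.items():
        hit = False
        for ti, pos in index.get(seq[:k], ()):
            tr = transcripts[ti]
            if tr.seq[pos : pos + len(seq)] == seq:
                hit = True
                per = profile.counts.setdefault(tr.id, {})
                per[pos + 1] = per.get(pos + 1, 0) + mult
        if hit:
            profile.total_mapped += mult
    return profile


def library_report(profiles: Iterable[SignatureProfile]) -> pd.DataFrame:
    """Per-library accounting: raw, length-selected and transcriptome-matched reads."""
    rows = [
        {
            "library": p.library,
            "raw_reads": p.total_input,
            "len_selected_reads": p.total_len_selected,
            "transcriptome_matched_reads": p.total_mapped,
        }
        for p in profiles
    ]
    if not rows:
        raise ValueError("library_report requires at least one profile")
    return pd.DataFrame(rows)


def write_profile(profile: SignatureProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tposition\tcount\n")
        for tid in sorted(profile.counts):
            for pos in sorted(profile.counts[tid]):
                fh.write(f"{tid}\t{pos}\t{profile.counts[tid][pos]}\n")


def read_profile(path, library: str = "", totals: Optional[Tuple[int, int, int]] = None) -> SignatureProfile:
    """Load a profile dump; ``totals`` is (mapped, len_selected, input) if known."""
    profile = SignatureProfile(library=library)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript"):
            raise ValueError(f"unexpected profile header in {path}")
        for line in fh:
            tid, pos, count = line.rstrip("\n").split("\t")
            profile.counts.setdefault(tid, {})[int(pos)] = int(count)
    if totals is not None:
        profile.total_mapped, profile.total_len_selected, profile.total_input = totals
    else:
        profile.total_mapped = sum(
            v for per in profile.counts.values() for v in per.values()
        )
    return profile
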