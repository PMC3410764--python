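"""Classified cleavage-target calling from signature profiles.

Category semantics (applied in this order to a site with >= 1 read):

* 4 - the site carries exactly 1 read (very low abundance, checked first);
* 0 - the site count is the transcript maximum and that maximum is unique;
* 1 - the site count equals a maximum attained at more than one position;
* 2 - above the median of the occupied positions;
* 3 - at or below that median.

The median is taken over positions with >= 1 read only (the site included);
including the zero positions would make category 2 vacuous on any
expressed transcript.
"""
from __future__ import annotations

import logging
import statistics
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import duplex
from .mapping import SignatureProfile
from .models import MatureMiRNA, Region, TargetCall, Transcript

logger = logging.getLogger(__name__)

#: sentinel in category arrays for positions without degradome evidence
NO_EVIDENCE = 5


@dataclass(frozen=True)
class CategoryEvidence:
    """Abundance summary of one candidate site on one transcript."""

    site_count: int
    max_count: int
    n_max_positions: int
    median_count: float

    def __post_init__(self) -> None:
        if self.site_count > self.max_count:
            raise ValueError("site_count cannot exceed max_count")
        if self.n_max_positions < 1:
            raise ValueError("n_max_positions must be >= 1")


def evidence_at(counts: Mapping[int, int], site: int) -> CategoryEvidence:
    """Summarize a transcript's count map around ``site`` (which may hold 0)."""
    if not counts:
        raise ValueError("transcript has no degradome evidence")
    values = list(counts.values())
    max_count = max(values)
    return CategoryEvidence(
        site_count=counts.get(site, 0),
        max_count=max_count,
        n_max_positions=sum(1 for v in values if v == max_count),
        median_count=float(statistics.median(values)),
    )


def classify_category(evidence: CategoryEvidence) -> Optional[int]:
    """Category 0-4 for a site, or None when the site has no reads (no call)."""
    if evidence.site_count == 0:
        return None
    if evidence.site_count == 1:
        return 4
    if evidence.site_count == evidence.max_count:
        return 0 if evidence.n_max_positions == 1 else 1
    if evidence.site_count > evidence.median_count:
        return 2
    return 3


def category_array(counts: Mapping[int, int], length: int) -> np.ndarray:
    """Per-position category for one transcript; ``NO_EVIDENCE`` where empty.

    Index 0 is unused (coordinates are 1-based).
    """
    arr = np.full(length + 1, NO_EVIDENCE, dtype=np.int8)
    if not counts:
        return arr
    values = list(counts.values())
    max_count = max(values)
    n_max = sum(1 for v in values if v == max_count)
    median = float(statistics.median(values))
    for pos, c in counts.items():
        if c == 1:
            cat = 4
        elif c == max_count:
            cat = 0 if n_max == 1 else 1
        elif c > median:
            cat = 2
        else:
            cat = 3
        arr[pos] = cat
    return arr


def tp100m(site_count: int, total_mapped: int) -> float:
    """Tags per 100 million transcriptome-matched reads."""
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return site_count * 1e8 / total_mapped


def locate_region(c_site: int, cds: Optional[Tuple[int, int]]) -> Region:
    """Place a cleavage site in the 5'UTR/CDS/3'UTR (unknown without a CDS)."""
    if cds is None:
        return Region.UNKNOWN
    start, end = cds
    if c_site < start:
        return Region.UTR5
    if c_site <= end:
        return Region.CDS
    return Region.UTR3


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Composition-preserving (mononucleotide) shuffle."""
    letters = np.array(list(seq))
    return "".join(rng.permutation(letters))


def empirical_pvalue(
    mirna: MatureMiRNA,
    transcripts: Sequence[Transcript],
    profile: SignatureProfile,
    observed: TargetCall,
    n_shuffles: int = 100,
    seed: int = 0,
    scheme: duplex.PenaltyScheme = duplex.DEFAULT_SCHEME,
    allow_bulge: bool = True,
    _category_cache: Optional[Dict[str, np.ndarray]] = None,
) -> float:
    """Add-one-corrected shuffle-null p-value for one call.

    ``k`` counts composition-preserving shuffles of the miRNA that produce,
    anywhere in the transcript set, an alignment scoring <= the observed
    score whose cleavage site holds a category <= the observed category;
    p = (1 + k) / (1 + n_shuffles).
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19")
    rng = np.random.default_rng(seed)
    cache = _category_cache if _category_cache is not None else {}
    scanned = [t for t in transcripts if profile.transcript_counts(t.id)]
    encoded = [(t, duplex.encode_dna(t.seq)) for t in scanned]
    k = 0
    for _ in range(n_shuffles):
        shuffled = duplex.encode_rna(shuffle_sequence(mirna.seq, rng))
        for tr, t_idx in encoded:
            csites = duplex.qualifying_csites(
                shuffled, t_idx, observed.score, scheme, allow_bulge
            )
            if csites.size == 0:
                continue
            cats = cache.get(tr.id)
            if cats is None:
                cats = category_array(profile.transcript_counts(tr.id), len(tr))
                cache[tr.id] = cats
            if (cats[csites] <= observed.category).any():
                k += 1
                break
    return (1 + k) / (1 + n_shuffles)


def _call_seed(seed: int, library: str, mirna: str, target: str, c_site: int) -> int:
    token = f"{library}|{mirna}|{target}|{c_site}".encode()
    return int(np.random.SeedSequence([seed, zlib.crc32(token)]).generate_state(1)[0])


def call_targets(
    profiles: Iterable[SignatureProfile],
    mirnas: Sequence[MatureMiRNA],
    transcripts: Sequence[Transcript],
    max_score: float = 7.0,
    n_shuffles: int = 100,
    seed: int = 0,
    scheme: duplex.PenaltyScheme = duplex.DEFAULT_SCHEME,
    allow_bulge: bool = True,
    compute_pvalues: bool = True,
) -> List[TargetCall]:
    """Classify every candidate site backed by >= 1 degradome read.

    One call per library x miRNA x site; when several alignments of one
    miRNA on one transcript share a cleavage coordinate, the lowest-penalty
    one is reported.  Deterministic for a given seed regardless of input
    order (per-call RNG streams are derived from the call identity).
    """
    calls: List[TargetCall] = []
    for profile in profiles:
        if profile.total_mapped < 1:
            continue
        cat_cache: Dict[str, np.ndarray] = {}
        expressed = [t for t in transcripts if profile.transcript_counts(t.id)]
        for mirna in mirnas:
            for tr in expressed:
                sites = duplex.find_candidate_sites(
                    mirna, tr, max_score=max_score, scheme=scheme, allow_bulge=allow_bulge
                )
                best_by_csite: Dict[int, duplex.DuplexAlignment] = {}
                for aln in sites:
                    cur = best_by_csite.get(aln.c_site)
                    if cur is None or aln.score < cur.score:
                        best_by_csite[aln.c_site] = aln
                counts = profile.transcript_counts(tr.id)
                for c_site, aln in sorted(best_by_csite.items()):
                    site_count = counts.get(c_site, 0)
                    if site_count < 1:
                        continue
                    category = classify_category(evidence_at(counts, c_site))
                    assert category is not None
                    provisional = TargetCall(
                        library=profile.library,
                        mirna=mirna.id,
                        target=tr.id,
                        c_site=c_site,
                        location=locate_region(c_site, tr.cds),
                        category=category,
                        tp100m=tp100m(site_count, profile.total_mapped),
                        p_value=1.0,
                        score=aln.score,
                        annotation=tr.annotation,
                    )
                    if compute_pvalues:
                        p = empirical_pvalue(
                            mirna,
                            transcripts,
                            profile,
                            provisional,
                            n_shuffles=n_shuffles,
                            seed=_call_seed(seed, profile.library, mirna.id, tr.id, c_site),
                            scheme=scheme,
                            allow_bulge=allow_bulge,
                            _category_cache=cat_cache,
                        )
                        provisional = TargetCall(
                            **{**provisional.__dict__, "p_value": p}
                        )
                    calls.append(provisional)
    calls.sort(key=lambda c: c.sort_key())
    return calls


@dataclass
class TPlot:
    """Signature abundance along one transcript with the candidate site flagged."""

    transcript: str
    pairs: List[Tuple[int, int]] = field(default_factory=list)
    c_site: int = 0
    zero_evidence: bool = False


def tplot_data(profile: SignatureProfile, transcript: Transcript, c_site: int) -> TPlot:
    """Per-position count series for plotting, positions strictly increasing."""
    counts = profile.transcript_counts(transcript.id)
    pairs = sorted(counts.items())
    return TPlot(
        transcript=transcript.id,
        pairs=pairs,
        c_site=c_site,
        zero_evidence=counts.get(c_site, 0) == 0,
    )


def write_tplot(tplot: TPlot, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tcount\tis_c_site\n")
        for pos, count in tplot.pairs:
            fh.write(f"{pos}\t{count}\t{int(pos == tplot.c_site)}\n")


def plot_tplot(tplot: TPlot, path) -> None:
    """Render a t-plot to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    if tplot.pairs:
        pos, counts = zip(*tplot.pairs)
        ax.vlines(pos, 0, counts, color="0.4", linewidth=1)
    site_count = dict(tplot.pairs).get(tplot.c_site, 0)
    ax.annotate(
        "",
        xy=(tplot.c_site, site_count),
        xytext=(tplot.c_site, site_count + max(site_count, 1) * 0.2 + 1),
        arrowprops=dict(color="red", arrowstyle="->"),
    )
    ax.set_xlabel("transcript position (nt)")
    ax.set_ylabel("signature count")
    ax.set_title(tplot.transcript)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
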