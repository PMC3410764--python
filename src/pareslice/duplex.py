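"""miRNA:mRNA complementarity search and cleavage-coordinate arithmetic.

The duplex is evaluated antiparallel: miRNA nt 1 (5' end) pairs the 3'-most
transcript base of the site.  Penalties follow the plant target-prediction
convention: Watson-Crick 0, G:U wobble 0.5, mismatch 1, gap 1 per gapped
position, everything doubled over miRNA positions 2-13.  Slicing happens
between the transcript bases pairing miRNA nt 10 and 11, so both of those
positions must be paired (WC or G:U) for a site to be retained; the
cleavage coordinate is the transcript base pairing miRNA nt 10.

At most one single-nucleotide bulge is considered per duplex - on either
strand - and never between miRNA positions 10 and 11.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import MatureMiRNA, Transcript

_BIG = np.inf


class PairState(Enum):
    WC = "WC"
    GU = "GU"
    MM = "MM"
    GAP = "GAP"


@dataclass(frozen=True)
class PenaltyScheme:
    """Per-position duplex penalties; every knob is configurable."""

    mismatch: float = 1.0
    gu: float = 0.5
    gap: float = 1.0
    core_start: int = 2
    core_end: int = 13
    core_multiplier: float = 2.0

    def position_weight(self, pos: int) -> float:
        """Penalty multiplier at 1-based miRNA position ``pos``."""
        return self.core_multiplier if self.core_start <= pos <= self.core_end else 1.0

    def bulge_weight(self, left_flank: int) -> float:
        """Multiplier for a target-strand bulge between miRNA positions
        ``left_flank`` and ``left_flank + 1`` (1-based)."""
        if self.core_start <= left_flank < self.core_end:
            return self.core_multiplier
        return 1.0

    def state_penalty(self, state: PairState) -> float:
        if state is PairState.WC:
            return 0.0
        if state is PairState.GU:
            return self.gu
        if state is PairState.MM:
            return self.mismatch
        return self.gap


DEFAULT_SCHEME = PenaltyScheme()

_RNA_INDEX = {b: i for i, b in enumerate("ACGUN")}
_DNA_INDEX = {b: i for i, b in enumerate("ACGTN")}

# state codes: 0 = WC, 1 = GU, 2 = MM; rows miRNA base, cols target base (DNA)
_STATE_TABLE = np.full((5, 5), 2, dtype=np.int8)
_STATE_TABLE[_RNA_INDEX["A"], _DNA_INDEX["T"]] = 0
_STATE_TABLE[_RNA_INDEX["C"], _DNA_INDEX["G"]] = 0
_STATE_TABLE[_RNA_INDEX["G"], _DNA_INDEX["C"]] = 0
_STATE_TABLE[_RNA_INDEX["U"], _DNA_INDEX["A"]] = 0
_STATE_TABLE[_RNA_INDEX["G"], _DNA_INDEX["T"]] = 1  # G : U wobble
_STATE_TABLE[_RNA_INDEX["U"], _DNA_INDEX["G"]] = 1  # U : G wobble

_STATE_BY_CODE = (PairState.WC, PairState.GU, PairState.MM)


def encode_rna(seq: str) -> np.ndarray:
    return np.fromiter((_RNA_INDEX.get(c, 4) for c in seq), dtype=np.intp, count=len(seq))


def encode_dna(seq: str) -> np.ndarray:
    return np.fromiter((_DNA_INDEX.get(c, 4) for c in seq), dtype=np.intp, count=len(seq))


def classify_pair(mirna_base: str, target_base: str) -> PairState:
    """Pairing state of one miRNA (RNA) base against one target (DNA) base."""
    code = _STATE_TABLE[_RNA_INDEX.get(mirna_base, 4), _DNA_INDEX.get(target_base, 4)]
    return _STATE_BY_CODE[code]


def score_duplex(
    mirna_seq: str,
    site_seq: str,
    pairing: Sequence[PairState],
    scheme: PenaltyScheme = DEFAULT_SCHEME,
) -> float:
    """Penalty of a pairing vector (one state per miRNA position, 5'->3').

    The score is a pure, order-independent sum of per-position penalties.
    ``site_seq`` is carried for interface symmetry; the states already
    encode the base comparisons.
    """
    if len(pairing) != len(mirna_seq):
        raise ValueError(
            f"pairing vector length {len(pairing)} != miRNA length {len(mirna_seq)}"
        )
    del site_seq
    return float(
        sum(
            scheme.position_weight(i + 1) * scheme.state_penalty(state)
            for i, state in enumerate(pairing)
        )
    )


# A duplex configuration: ("free", None) is gap-free; ("mgap", j) leaves
# 0-based miRNA position j unpaired; ("tbulge", j) leaves one transcript
# base unpaired between 0-based miRNA positions j and j+1.
Config = Tuple[str, Optional[int]]


@dataclass(frozen=True)
class DuplexAlignment:
    """One miRNA:transcript-site pairing with its penalty and cleavage site.

    ``start``/``end`` are 1-based inclusive transcript coordinates; miRNA
    nt 1 pairs position ``end``.  ``c_site`` is the transcript base pairing
    miRNA nt 10 (``end - 9`` whenever the duplex is gap-free).
    """

    mirna: str
    target: str
    start: int
    end: int
    pairing: Tuple[PairState, ...]
    score: float
    c_site: int
    config: Config = ("free", None)

    @property
    def n_gaps(self) -> int:
        return 0 if self.config[0] == "free" else 1

    @property
    def n_gu(self) -> int:
        return sum(1 for s in self.pairing if s is PairState.GU)


def cleavage_site(alignment: DuplexAlignment) -> int:
    """1-based coordinate of the 5' nucleotide of the 3' cleavage fragment."""
    return alignment.c_site


def enumerate_configs(mirna_len: int, allow_bulge: bool = True) -> List[Config]:
    """All duplex configurations considered for a site, gap-free first."""
    configs: List[Config] = [("free", None)]
    if not allow_bulge:
        return configs
    for j in range(1, mirna_len - 1):
        if j in (9, 10):  # miRNA nt 10/11 must pair
            continue
        configs.append(("mgap", j))
    for j in range(0, mirna_len - 1):
        if j == 9:  # never between miRNA nt 10 and 11
            continue
        configs.append(("tbulge", j))
    return configs


def build_pairing(
    mirna_seq: str, transcript_seq: str, end: int, config: Config
) -> Tuple[List[PairState], List[Optional[int]], int]:
    """Explicit pairing map for a duplex anchored with miRNA nt 1 at ``end``.

    Returns (states, partners, start): ``partners[i]`` is the 1-based
    transcript coordinate paired with miRNA position i (None for a miRNA
    gap); ``start`` is the 5'-most transcript coordinate of the site
    (including a bulged base, if any).
    """
    L = len(mirna_seq)
    kind, j = config
    states: List[PairState] = []
    partners: List[Optional[int]] = []
    for i in range(L):
        if kind == "mgap" and i == j:
            states.append(PairState.GAP)
            partners.append(None)
            continue
        if kind == "mgap" and i > j:
            pos = end - i + 1
        elif kind == "tbulge" and i > j:
            pos = end - i - 1
        else:
            pos = end - i
        if not (1 <= pos <= len(transcript_seq)):
            raise IndexError(f"pairing runs off the transcript at position {pos}")
        partners.append(pos)
        states.append(classify_pair(mirna_seq[i], transcript_seq[pos - 1]))
    paired = [p for p in partners if p is not None]
    start = min(paired)
    if kind == "tbulge":
        start = min(start, end - (j if j is not None else 0) - 1)
    return states, partners, start


def _config_score(
    states: Sequence[PairState], config: Config, scheme: PenaltyScheme
) -> float:
    score = sum(
        scheme.position_weight(i + 1) * scheme.state_penalty(s)
        for i, s in enumerate(states)
        if s is not PairState.GAP
    )
    kind, j = config
    if kind == "mgap":
        score += scheme.position_weight(j + 1) * scheme.gap
    elif kind == "tbulge":
        score += scheme.bulge_weight(j + 1) * scheme.gap
    return float(score)


@dataclass
class WindowScan:
    """Vectorized scan results for one (miRNA, transcript) pair.

    Arrays are indexed by the 0-based anchor ``e0`` (transcript index
    pairing miRNA nt 1); invalid anchors carry +inf scores.
    """

    configs: List[Config]
    scores: np.ndarray  # (n_configs, n) penalty per anchor
    gate: np.ndarray  # (n_configs, n) True where nt 10 and 11 both pair
    csite0: np.ndarray  # (n_configs, n) 0-based index pairing miRNA nt 10


def scan_windows(
    m_idx: np.ndarray,
    t_idx: np.ndarray,
    scheme: PenaltyScheme = DEFAULT_SCHEME,
    allow_bulge: bool = True,
) -> WindowScan:
    """Score every anchor under every configuration in O(L * n) vector work.

    Scores are assembled from prefix/suffix cumulative sums of the shifted
    per-position penalty rows, so single-bulge configurations cost no more
    than the gap-free scan.
    """
    L = len(m_idx)
    n = len(t_idx)
    if L < 11:
        raise ValueError("miRNA shorter than 11 nt cannot define a cleavage site")
    weights = np.array([scheme.position_weight(i + 1) for i in range(L)])
    pen = np.array([0.0, scheme.gu, scheme.mismatch])
    state_mat = _STATE_TABLE[m_idx][:, t_idx]  # (L, n)
    rows = pen[state_mat] * weights[:, None]

    # M[i, col] = penalty of miRNA i against t[e0 - i], with col = e0 + 1
    M = np.full((L, n + 2), _BIG)
    for i in range(L):
        span = min(n, n + 1 - i)
        M[i, i + 1 : i + 1 + span] = rows[i, :span]
    A = np.vstack([np.zeros((1, n + 2)), np.cumsum(M, axis=0)])  # A[j] = sum_{i<j}
    C = np.vstack([np.cumsum(M[::-1], axis=0)[::-1], np.zeros((1, n + 2))])  # C[j] = sum_{i>=j}

    e0 = np.arange(n)

    def gate_arr(off10: int, off11: int) -> np.ndarray:
        i10 = e0 + off10
        i11 = e0 + off11
        ok = (i10 >= 0) & (i10 < n) & (i11 >= 0) & (i11 < n)
        g = np.zeros(n, dtype=bool)
        s10 = _STATE_TABLE[m_idx[9], t_idx[np.clip(i10, 0, n - 1)]]
        s11 = _STATE_TABLE[m_idx[10], t_idx[np.clip(i11, 0, n - 1)]]
        g[ok] = (s10[ok] <= 1) & (s11[ok] <= 1)
        return g

    gate_v0 = gate_arr(-9, -10)  # gap-free geometry around the cleavage site
    gate_plus = gate_arr(-8, -9)  # miRNA gap 5' of nt 10
    gate_minus = gate_arr(-10, -11)  # transcript bulge 5' of nt 10

    configs = enumerate_configs(L, allow_bulge)
    scores = np.empty((len(configs), n))
    gate = np.empty((len(configs), n), dtype=bool)
    csite0 = np.empty((len(configs), n), dtype=np.intp)
    for ci, (kind, j) in enumerate(configs):
        if kind == "free":
            scores[ci] = A[L, 1 : n + 1]
            gate[ci] = gate_v0
            csite0[ci] = e0 - 9
        elif kind == "mgap":
            gw = scheme.position_weight(j + 1) * scheme.gap
            scores[ci] = A[j, 1 : n + 1] + gw + C[j + 1, 2 : n + 2]
            if j < 9:
                gate[ci] = gate_plus
                csite0[ci] = e0 - 8
            else:
                gate[ci] = gate_v0
                csite0[ci] = e0 - 9
        else:  # tbulge
            bw = scheme.bulge_weight(j + 1) * scheme.gap
            scores[ci] = A[j + 1, 1 : n + 1] + bw + C[j + 1, 0:n]
            if j < 9:
                gate[ci] = gate_minus
                csite0[ci] = e0 - 10
            else:
                gate[ci] = gate_v0
                csite0[ci] = e0 - 9
    return WindowScan(configs=configs, scores=scores, gate=gate, csite0=csite0)


def find_candidate_sites(
    mirna: MatureMiRNA,
    transcript: Transcript,
    max_score: float = 7.0,
    scheme: PenaltyScheme = DEFAULT_SCHEME,
    allow_bulge: bool = True,
) -> List[DuplexAlignment]:
    """All sites whose best pairing scores <= ``max_score`` with miRNA nt 10
    and 11 both paired.

    Every anchor (transcript base pairing miRNA nt 1) is one candidate
    site; the minimum-penalty configuration is kept per anchor, ties broken
    toward fewer gaps, then fewer G:U pairs.
    """
    L = len(mirna)
    n = len(transcript)
    if n < L:
        warnings.warn(
            f"transcript {transcript.id} shorter than miRNA {mirna.id}; no sites",
            stacklevel=2,
        )
        return []
    scan = scan_windows(encode_rna(mirna.seq), encode_dna(transcript.seq), scheme, allow_bulge)
    best = scan.scores.min(axis=0)
    hits: List[DuplexAlignment] = []
    for e0 in np.nonzero(best <= max_score)[0]:
        tied = np.nonzero(np.isclose(scan.scores[:, e0], best[e0]))[0]
        ci = int(tied[0])
        if len(tied) > 1 and scan.configs[ci][0] != "free":
            # all tied configs carry exactly one gap: prefer fewer G:U
            def gu_count(c: int) -> int:
                states, _, _ = build_pairing(
                    mirna.seq, transcript.seq, int(e0) + 1, scan.configs[c]
                )
                return sum(1 for s in states if s is PairState.GU)

            ci = int(min(tied, key=lambda c: (gu_count(int(c)), int(c))))
        if not scan.gate[ci, e0]:
            continue
        config = scan.configs[ci]
        states, partners, start = build_pairing(
            mirna.seq, transcript.seq, int(e0) + 1, config
        )
        score = _config_score(states, config, scheme)
        assert abs(score - float(scan.scores[ci, e0])) < 1e-9
        c_site = partners[9]
        assert c_site is not None and c_site == int(scan.csite0[ci, e0]) + 1
        hits.append(
            DuplexAlignment(
                mirna=mirna.id,
                target=transcript.id,
                start=start,
                end=int(e0) + 1,
                pairing=tuple(states),
                score=score,
                c_site=c_site,
                config=config,
            )
        )
    return hits


def qualifying_csites(
    m_idx: np.ndarray,
    t_idx: np.ndarray,
    max_score: float,
    scheme: PenaltyScheme = DEFAULT_SCHEME,
    allow_bulge: bool = True,
) -> np.ndarray:
    """1-based cleavage sites of all alignments passing the score and
    nt-10/11 gates (fast path for shuffle-null searches)."""
    if len(t_idx) < len(m_idx):
        return np.empty(0, dtype=np.intp)
    # a single-nt bulge costs at least the gap penalty, so bulged
    # configurations cannot qualify under a tighter threshold
    if allow_bulge and max_score < scheme.gap:
        allow_bulge = False
    scan = scan_windows(m_idx, t_idx, scheme, allow_bulge)
    mask = (scan.scores <= max_score) & scan.gate
    if not mask.any():
        return np.empty(0, dtype=np.intp)
    return np.unique(scan.csite0[mask]) + 1


def alignment_text(alignment: DuplexAlignment, mirna: MatureMiRNA, transcript: Transcript) -> str:
    """Three-line human-readable rendering of a duplex (target 5'->3' on top)."""
    _, partners, start = build_pairing(
        mirna.seq, transcript.seq, alignment.end, alignment.config
    )
    site = transcript.seq[start - 1 : alignment.end]
    marks = {
        pos: {PairState.WC: "|", PairState.GU: "o", PairState.MM: " ", PairState.GAP: " "}[s]
        for pos, s in zip(partners, alignment.pairing)
        if pos is not None
    }
    midline = "".join(marks.get(start + k, " ") for k in range(len(site)))
    mline = [" "] * len(site)
    for i, pos in enumerate(partners):
        if pos is not None:
            mline[pos - start] = mirna.seq[i]
    return "\n".join(
        [
            f"5' {site} 3' {transcript.id}[{start}-{alignment.end}]",
            f"   {midline}",
            f"3' {''.join(mline)[::-1][::-1]} 5' {mirna.id} (reversed)",
        ]
    )
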