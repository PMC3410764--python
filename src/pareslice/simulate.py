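"""Synthetic degradome libraries with known ground truth.

The signal model plants the exact reverse complement of a miRNA inside a
random transcript and emits 20-21 nt reads whose 5' ends sit at the
canonical cleavage coordinate (the transcript base pairing miRNA nt 10).
Background decay is modeled as uniform-position Poisson starts with no
positional bias.  Simulated qualities are a constant Q40; low-quality
reads for filter tests are crafted separately.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import seqio
from .models import Library, MatureMiRNA, ReadRecord, Tissue, Transcript, revcomp_dna

_SIM_QUALITY = 40


@dataclass(frozen=True)
class PlantedTarget:
    """One cleavage event to embed: which miRNA cuts which transcript, how often."""

    mirna: str
    transcript: str
    lambda_signal: float

    def __post_init__(self) -> None:
        if self.lambda_signal < 0:
            raise ValueError("lambda_signal must be >= 0")


@dataclass
class SimConfig:
    seed: int
    n_transcripts: int = 10
    transcript_len: Tuple[int, int] = (500, 2000)
    gc: float = 0.5
    planted: List[PlantedTarget] = field(default_factory=list)
    decoy_mirnas: List[str] = field(default_factory=list)
    background_rate: float = 0.01
    read_len_weights: Dict[int, float] = field(default_factory=lambda: {20: 0.5, 21: 0.5})
    mirna_length: int = 21
    library_name: str = "sim"
    tissue: Tissue = Tissue.COTYLEDON
    stage: str = ""

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        total = sum(self.read_len_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"read_len_weights must sum to 1, got {total}")
        if self.transcript_len[0] > self.transcript_len[1]:
            raise ValueError("transcript_len range is inverted")
        self.tissue = Tissue.parse(self.tissue)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["planted"] = [PlantedTarget(**p) for p in raw.get("planted", [])]
        if "transcript_len" in raw:
            raw["transcript_len"] = tuple(raw["transcript_len"])
        return cls(**raw)


@dataclass(frozen=True)
class PlantedEvent:
    """Ground truth for one planted cleavage event."""

    mirna: str
    transcript: str
    c_site: int
    n_signal_reads: int


@dataclass
class SimTruth:
    events: List[PlantedEvent] = field(default_factory=list)
    n_signal_reads: int = 0
    n_background_reads: int = 0


@dataclass
class SimResult:
    library: Library
    transcripts: List[Transcript]
    mirnas: List[MatureMiRNA]
    truth: SimTruth


def _random_seq(rng: np.random.Generator, length: int, gc: float, alphabet: str) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(alphabet))[rng.choice(4, size=length, p=p)])


def _draw_lengths(rng: np.random.Generator, weights: Dict[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(weights))
    probs = np.array([weights[l] for l in lengths], dtype=float)
    return lengths[rng.choice(len(lengths), size=n, p=probs)]


def simulate_library(config: SimConfig) -> SimResult:
    """Generate one synthetic degradome library, fully reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    L = config.mirna_length
    max_read = max(config.read_len_weights)

    lo, hi = config.transcript_len
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    seqs = {
        f"tx{i + 1:04d}": list(_random_seq(rng, int(n), config.gc, "ACGT"))
        for i, n in enumerate(lengths)
    }

    mirna_ids = [p.mirna for p in config.planted]
    for decoy in config.decoy_mirnas:
        if decoy not in mirna_ids:
            mirna_ids.append(decoy)
    mirnas = [
        MatureMiRNA(mid, _random_seq(rng, L, config.gc, "ACGU")) for mid in mirna_ids
    ]
    by_id = {m.id: m for m in mirnas}

    truth = SimTruth()
    reads: List[ReadRecord] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {}

    for planted in config.planted:
        if planted.transcript not in seqs:
            raise ValueError(f"planted target names unknown transcript {planted.transcript}")
        tseq = seqs[planted.transcript]
        n_t = len(tseq)
        # the 3' fragment must accommodate a 20 nt read: c_site + 19 <= n_t
        e_max = n_t - 10
        if e_max < L:
            raise ValueError(
                f"transcript {planted.transcript} too short to plant a site with "
                f"room for a 20 nt read"
            )
        taken = occupied.setdefault(planted.transcript, [])
        for _ in range(200):
            e = int(rng.integers(L, e_max + 1))
            s = e - L + 1
            if all(e < a or s > b for a, b in taken):
                break
        else:
            raise ValueError(
                f"could not place planted site on {planted.transcript} without overlap"
            )
        taken.append((s, e))
        site = revcomp_dna(by_id[planted.mirna].dna)
        tseq[s - 1 : e] = list(site)
        c_site = e - 9
        n_sig = int(rng.poisson(planted.lambda_signal))
        read_lens = _draw_lengths(rng, config.read_len_weights, n_sig)
        for k in range(n_sig):
            end = min(c_site - 1 + int(read_lens[k]), n_t)
            seq = "".join(tseq[c_site - 1 : end])
            reads.append(
                ReadRecord(
                    f"sig_{planted.mirna}_{planted.transcript}_{k:05d}",
                    seq,
                    (_SIM_QUALITY,) * len(seq),
                )
            )
        truth.events.append(
            PlantedEvent(planted.mirna, planted.transcript, c_site, n_sig)
        )
        truth.n_signal_reads += n_sig

    for tid in sorted(seqs):
        tseq = seqs[tid]
        n_t = len(tseq)
        n_bg = int(rng.poisson(config.background_rate * n_t))
        # starts leave room for the shortest read, so emitted lengths stay
        # within the configured 20-21 nt window
        min_read = min(config.read_len_weights)
        starts = rng.integers(1, max(n_t - min_read + 1, 1) + 1, size=n_bg)
        read_lens = _draw_lengths(rng, config.read_len_weights, n_bg)
        for k in range(n_bg):
            start = int(starts[k])
            end = min(start - 1 + int(read_lens[k]), n_t)
            seq = "".join(tseq[start - 1 : end])
            reads.append(
                ReadRecord(f"bg_{tid}_{k:05d}", seq, (_SIM_QUALITY,) * len(seq))
            )
        truth.n_background_reads += n_bg

    transcripts = [Transcript(tid, "".join(seqs[tid])) for tid in sorted(seqs)]
    library = Library(
        name=config.library_name, tissue=config.tissue, stage=config.stage, reads=reads
    )
    return SimResult(library=library, transcripts=transcripts, mirnas=mirnas, truth=truth)


def write_sim(result: SimResult, directory) -> None:
    """Write reads.fastq, transcripts.fasta, mirnas.fasta and truth.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seqio.write_fastq(result.library.reads, directory / "reads.fastq")
    seqio.write_fasta(
        [(t.id, t.seq) for t in result.transcripts], directory / "transcripts.fasta"
    )
    seqio.write_fasta(
        [(m.id, m.seq) for m in result.mirnas], directory / "mirnas.fasta"
    )
    with open(directory / "truth.tsv", "w") as fh:
        fh.write("miRNA\ttranscript\tc_site\tn_signal_reads\n")
        for ev in result.truth.events:
            fh.write(f"{ev.mirna}\t{ev.transcript}\t{ev.c_site}\t{ev.n_signal_reads}\n")
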