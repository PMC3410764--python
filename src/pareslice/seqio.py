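"""Readers and writers for the external formats used by the pipeline.

FASTA/FASTQ parsing is delegated to Biopython; GFF3 to gffutils.  Output
tables are plain TSV so that they survive text-only archiving.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import pandas as pd
from Bio import SeqIO

from .models import (
    DNA_ALPHABET,
    RNA_ALPHABET,
    MatureMiRNA,
    Region,
    ReadRecord,
    TargetCall,
    Transcript,
)

logger = logging.getLogger(__name__)

#: Column order of the call table (matches the published table layout,
#: minus the free-text annotation column).
CALL_COLUMNS = (
    "miRNA",
    "Tissue",
    "Target",
    "C.Site",
    "Location",
    "Category",
    "TP100M",
    "P-Value",
)


class FastaRecord(NamedTuple):
    id: str
    seq: str
    description: str


def read_fasta(path: "str | Path", alphabet: str = "dna") -> List[FastaRecord]:
    """Read a FASTA file, normalizing case and the T/U alphabet.

    ``alphabet`` is ``"dna"`` (U mapped to T) or ``"rna"`` (T mapped to U).
    Duplicate ids and empty files are hard errors.
    """
    if alphabet not in ("dna", "rna"):
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    allowed = DNA_ALPHABET if alphabet == "dna" else RNA_ALPHABET
    records: List[FastaRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seq = seq.replace("U", "T") if alphabet == "dna" else seq.replace("T", "U")
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {rec.id!r}: characters outside the {alphabet} alphabet: "
                f"{sorted(bad)}"
            )
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(FastaRecord(rec.id, seq, desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_transcripts(
    path: "str | Path",
    cds: Optional[Dict[str, Tuple[int, int]]] = None,
) -> List[Transcript]:
    """Read transcripts from FASTA; the description line becomes the annotation."""
    cds = cds or {}
    out = []
    for rec in read_fasta(path, alphabet="dna"):
        interval = cds.get(rec.id)
        if interval is not None and interval[1] > len(rec.seq):
            raise ValueError(
                f"CDS interval {interval} exceeds length of transcript {rec.id}"
            )
        out.append(
            Transcript(rec.id, rec.seq, cds=interval, annotation=rec.description or None)
        )
    return out


def read_mirnas(path: "str | Path") -> List[MatureMiRNA]:
    return [MatureMiRNA(rec.id, rec.seq) for rec in read_fasta(path, alphabet="rna")]


def read_reads(path: "str | Path") -> List[ReadRecord]:
    """Read degradome reads from FASTQ (Phred+33) or FASTA."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads: List[ReadRecord] = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = None
        if fmt == "fastq":
            quals = tuple(rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(rec.id, str(rec.seq).upper().replace("U", "T"), quals))
    return reads


def read_cds_table(path: "str | Path") -> Dict[str, Tuple[int, int]]:
    """Read per-transcript CDS intervals (1-based inclusive).

    Accepts either a 3-column table (id, start, end) or GFF3, in which case
    the CDS features of each mRNA are collapsed to min-start/max-end.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_cds_gff3(path)
    intervals: Dict[str, Tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected (id, start, end)")
            tid = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            if tid in intervals:
                old = intervals[tid]
                intervals[tid] = (min(old[0], start), max(old[1], end))
            else:
                intervals[tid] = (start, end)
    return intervals


def _read_cds_gff3(path: Path) -> Dict[str, Tuple[int, int]]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    # transcript-space GFF3: the seqid names the transcript the CDS
    # coordinates live on, so CDS features collapse per seqid
    intervals: Dict[str, Tuple[int, int]] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.seqid
        if tid in intervals:
            old = intervals[tid]
            intervals[tid] = (min(old[0], feat.start), max(old[1], feat.end))
        else:
            intervals[tid] = (feat.start, feat.end)
    for tid, (start, end) in intervals.items():
        if start > end:
            raise ValueError(f"CDS of {tid}: start {start} > end {end}")
    return intervals


def validate_cds_against_transcripts(
    cds: Dict[str, Tuple[int, int]], transcripts: Iterable[Transcript]
) -> None:
    """Warn about CDS entries with no matching transcript; error on overflow."""
    by_id = {t.id: t for t in transcripts}
    for tid, (start, end) in cds.items():
        tr = by_id.get(tid)
        if tr is None:
            logger.warning("CDS table names unknown transcript %s", tid)
        elif end > len(tr):
            raise ValueError(f"CDS of {tid} extends past transcript end ({end} > {len(tr)})")


def _fmt_float(x: float) -> str:
    # repr() round-trips exactly and always carries >= 4 significant digits
    return repr(float(x))


def write_call_table(calls: Iterable[TargetCall], path: "str | Path") -> None:
    """Write calls as TSV in the standard column order.

    Rows are sorted by (library, miRNA, target, c_site) so output is
    deterministic regardless of input order.
    """
    rows = sorted(calls, key=lambda c: c.sort_key())
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                "\t".join(
                    (
                        c.mirna,
                        c.library,
                        c.target,
                        str(c.c_site),
                        c.location.value,
                        str(c.category),
                        _fmt_float(c.tp100m),
                        _fmt_float(c.p_value),
                    )
                )
                + "\n"
            )


def read_call_table(path: "str | Path") -> List[TargetCall]:
    """Parse a call table written by :func:`write_call_table`."""
    calls: List[TargetCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CALL_COLUMNS:
            raise ValueError(f"unexpected call-table header in {path}: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(
                TargetCall(
                    library=f[1],
                    mirna=f[0],
                    target=f[2],
                    c_site=int(f[3]),
                    location=Region.parse(f[4]),
                    category=int(f[5]),
                    tp100m=float(f[6]),
                    p_value=float(f[7]),
                    score=math.nan,
                )
            )
    return calls


def write_fasta(records: Iterable[Tuple[str, str]], path: "str | Path", width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[ReadRecord], path: "str | Path") -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.quals if r.quals is not None else (40,) * len(r.seq)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qline}\n")


def write_table(df: pd.DataFrame, path: "str | Path") -> None:
    df.to_csv(path, sep="\t", index=False)
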