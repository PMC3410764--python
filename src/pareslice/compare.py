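"""Cross-library set logic: tissue partitioning and annotation comparison.

Tissue specificity is evaluated on distinct (miRNA, target-transcript)
pairs pooled over all libraries of a tissue regardless of stage; transcript
ids are compared in full, isoform suffix included.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

from .models import TargetCall, Tissue

Pair = Tuple[str, str]  # (mirna id, transcript id)


@dataclass
class TissuePartition:
    """Shared vs tissue-exclusive (miRNA, target) pairs with their supporting libraries."""

    shared: Dict[Pair, FrozenSet[str]] = field(default_factory=dict)
    cotyledon_only: Dict[Pair, FrozenSet[str]] = field(default_factory=dict)
    seedcoat_only: Dict[Pair, FrozenSet[str]] = field(default_factory=dict)

    def _mirnas_by_tissue(self) -> Tuple[Set[str], Set[str]]:
        cot = {m for m, _ in self.shared} | {m for m, _ in self.cotyledon_only}
        sc = {m for m, _ in self.shared} | {m for m, _ in self.seedcoat_only}
        return cot, sc

    @property
    def shared_mirnas(self) -> Set[str]:
        """miRNAs with >= 1 call in at least one library of each tissue."""
        cot, sc = self._mirnas_by_tissue()
        return cot & sc

    @property
    def cotyledon_only_mirnas(self) -> Set[str]:
        cot, sc = self._mirnas_by_tissue()
        return cot - sc

    @property
    def seedcoat_only_mirnas(self) -> Set[str]:
        cot, sc = self._mirnas_by_tissue()
        return sc - cot

    def counts(self) -> Dict[str, int]:
        return {
            "shared_pairs": len(self.shared),
            "cotyledon_only_pairs": len(self.cotyledon_only),
            "seedcoat_only_pairs": len(self.seedcoat_only),
            "shared_mirnas": len(self.shared_mirnas),
            "cotyledon_only_mirnas": len(self.cotyledon_only_mirnas),
            "seedcoat_only_mirnas": len(self.seedcoat_only_mirnas),
        }


def partition_by_tissue(
    calls: Iterable[TargetCall], library_meta: Mapping[str, "Tissue | str"]
) -> TissuePartition:
    """Partition called (miRNA, target) pairs into shared / cotyledon-only /
    seed-coat-only compartments.

    ``library_meta`` maps each library name to its tissue; an unknown
    library name is a hard error.  The result is invariant to call and
    library order.
    """
    meta = {name: Tissue.parse(t) for name, t in library_meta.items()}
    support: Dict[Pair, Set[str]] = {}
    tissues: Dict[Pair, Set[Tissue]] = {}
    for call in calls:
        if call.library not in meta:
            raise KeyError(f"library {call.library!r} missing from library metadata")
        pair = (call.mirna, call.target)
        support.setdefault(pair, set()).add(call.library)
        tissues.setdefault(pair, set()).add(meta[call.library])
    partition = TissuePartition()
    for pair, seen in tissues.items():
        libs = frozenset(support[pair])
        if seen == {Tissue.COTYLEDON, Tissue.SEED_COAT}:
            partition.shared[pair] = libs
        elif seen == {Tissue.COTYLEDON}:
            partition.cotyledon_only[pair] = libs
        else:
            partition.seedcoat_only[pair] = libs
    return partition


def normalize_annotation(text: str) -> str:
    """Lowercase, collapse internal whitespace, strip trailing punctuation."""
    return " ".join(text.split()).lower().rstrip(".,;:")


@dataclass
class AnnotationComparison:
    """Set comparison of two annotation collections (original spellings kept)."""

    only_a: List[str]
    common: List[str]
    only_b: List[str]

    def counts(self) -> Tuple[int, int, int]:
        return (len(self.only_a), len(self.common), len(self.only_b))


def compare_annotation_sets(
    set_a: Iterable[str], set_b: Iterable[str]
) -> AnnotationComparison:
    """Difference/intersection of annotation strings after normalization.

    The first-seen original spelling represents each normalized group in
    the output; lists are sorted case-insensitively.
    """

    def collect(items: Iterable[str]) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for item in items:
            key = normalize_annotation(item)
            if key and key not in out:
                out[key] = " ".join(item.split())
        return out

    a = collect(set_a)
    b = collect(set_b)
    sort = lambda d, keys: sorted((d[k] for k in keys), key=str.casefold)  # noqa: E731
    return AnnotationComparison(
        only_a=sort(a, set(a) - set(b)),
        common=sort(a, set(a) & set(b)),
        only_b=sort(b, set(b) - set(a)),
    )


def write_partition(partition: TissuePartition, directory) -> None:
    """Dump the three compartments as TSVs (mirna, target, libraries)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, compartment in (
        ("shared", partition.shared),
        ("cotyledon_only", partition.cotyledon_only),
        ("seedcoat_only", partition.seedcoat_only),
    ):
        with open(directory / f"{name}.tsv", "w") as fh:
            fh.write("miRNA\ttarget\tlibraries\n")
            for (mirna, target), libs in sorted(compartment.items()):
                fh.write(f"{mirna}\t{target}\t{','.join(sorted(libs))}\n")


def write_annotation_comparison(comparison: AnnotationComparison, path) -> None:
    """Three-column TSV: unique-to-A, unique-to-B, common."""
    rows = max(len(comparison.only_a), len(comparison.only_b), len(comparison.common))
    with open(path, "w") as fh:
        fh.write("only_a\tonly_b\tcommon\n")
        for i in range(rows):
            fh.write(
                "\t".join(
                    col[i] if i < len(col) else ""
                    for col in (comparison.only_a, comparison.only_b, comparison.common)
                )
                + "\n"
            )
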