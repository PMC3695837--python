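"""Stage 1 — sequence quality control, renaming and length summaries."""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .core_formats import SequenceRecord, Source, _open_out, _open_text
from .errors import EnvPathError

_NON_ACGT = re.compile(r"[^ACGT]")


@dataclass
class LengthStats:
    """Length-distribution summary of a sequence collection."""

    count: int
    min_len: int | None
    max_len: int | None
    mean: float | None
    total: int

    @classmethod
    def of(cls, lengths: Sequence[int]) -> "LengthStats":
        if not lengths:
            return cls(0, None, None, None, 0)
        total = sum(lengths)
        return cls(len(lengths), min(lengths), max(lengths), total / len(lengths), total)


# ordered (sequential_name, original_name) pairs; survivors only
NameMapping = list[tuple[str, str]]


def length_stats(records: Iterable[SequenceRecord]) -> LengthStats:
    return LengthStats.of([len(r) for r in records])


def qc_nucleotides(
    records: Sequence[SequenceRecord],
    sample_name: str,
    min_length: int = 180,
) -> tuple[list[SequenceRecord], NameMapping, LengthStats, LengthStats]:
    """Filter, sanitize and sequentially rename nucleotide sequences.

    Residues outside {A,C,G,T} (IUPAC ambiguity codes, gaps, anything
    else) become 'N'; sequences shorter than ``min_length`` are removed;
    survivors are renamed ``<sample_name>_0``, ``<sample_name>_1``, … in
    input order.  Returns (kept, mapping, before-stats, after-stats).
    """
    if min_length < 1:
        raise EnvPathError("min_length must be >= 1")
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.seq_id] = seen.get(rec.seq_id, 0) + 1
    dups = sorted(name for name, n in seen.items() if n > 1)
    if dups:
        raise EnvPathError(f"duplicate input sequence ids: {', '.join(dups)}")

    before = length_stats(records)
    kept: list[SequenceRecord] = []
    mapping: NameMapping = []
    for rec in records:
        residues = _NON_ACGT.sub("N", rec.residues.upper())
        if len(residues) < min_length:
            continue
        new_id = f"{sample_name}_{len(kept)}"
        kept.append(SequenceRecord(new_id, residues, original_id=rec.seq_id))
        mapping.append((new_id, rec.seq_id))
    return kept, mapping, before, length_stats(kept)


def filter_orfs_by_length(orfs: Sequence, min_aa: int = 60):
    """Keep ORFs whose translation is at least ``min_aa`` residues.

    'Below the threshold' is strict: a 60-aa translation survives the
    default cutoff, a 59-aa one does not.  Order is preserved.
    """
    if min_aa < 1:
        raise EnvPathError("min_aa must be >= 1")
    return [o for o in orfs if len(o.translation) >= min_aa]


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_mapping(mapping: NameMapping, dest: Source) -> None:
    handle, close = _open_out(dest)
    try:
        for sequential, original in mapping:
            handle.write(f"{sequential}\t{original}\n")
    finally:
        if close:
            handle.close()


def read_mapping(source: Source) -> NameMapping:
    handle, close = _open_text(source)
    try:
        return [tuple(line.rstrip("\n").split("\t", 1)) for line in handle if line.strip()]
    finally:
        if close:
            handle.close()


def _stats_block(handle, label: str, stats: LengthStats) -> None:
    handle.write(f"{label}\n")
    handle.write(f"count\t{stats.count}\n")
    handle.write(f"min\t{stats.min_len if stats.min_len is not None else '-'}\n")
    handle.write(f"max\t{stats.max_len if stats.max_len is not None else '-'}\n")
    handle.write(f"mean\t{f'{stats.mean:.2f}' if stats.mean is not None else '-'}\n")
    handle.write(f"total\t{stats.total}\n")


def write_stats(before: LengthStats, after: LengthStats, dest: Source) -> None:
    """Write BEFORE/AFTER length-distribution blocks (key<TAB>value)."""
    handle, close = _open_out(dest)
    try:
        _stats_block(handle, "BEFORE", before)
        _stats_block(handle, "AFTER", after)
    finally:
        if close:
            handle.close()
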