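"""Readers and writers for the external file formats used by the pipeline.

All other modules exchange data through the types defined here (plus
:class:`~envpath.orfcall.OrfCall`): FASTA sequence sets, 12+-column tabular
homology-search output, GFF3 gene-coordinate files and the line-oriented
parameters file that drives a run.

Internal coordinates are 0-based half-open everywhere; GFF3 and GenBank
emission converts to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from .errors import ConfigError, FormatError

Source = Union[str, Path, IO[str]]

__all__ = [
    "SequenceRecord",
    "HomologyHit",
    "ParametersFile",
    "STAGES",
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_gff_orf_features",
    "write_gff_orf_features",
    "read_parameters",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named sequence; ``original_id`` is filled in by QC renaming."""

    seq_id: str
    residues: str
    original_id: str = ""
    moltype: str = "nucleotide"  # {nucleotide, protein}

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HomologyHit:
    """One row of 12+-column tabular homology-search output."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    subject_description: str = ""
    source_db: str = ""


STAGES = ("qc", "annotation", "analysis", "pgdb", "export")

_FLAGS = ("yes", "skip", "grid")

# threshold key -> (parser, default)
_THRESHOLD_KEYS = {
    "min_nucleotide_length": (int, 180),
    "min_orf_aa": (int, 60),
    "max_evalue": (float, 1e-5),
    "min_bsr": (float, 0.4),
    "min_aln_length": (int, 1),
    "pathway_tau": (float, 0.5),
    "lca_top_fraction": (float, 0.9),
    "lca_min_hits": (int, 1),
    "rrna_min_identity": (float, 90.0),
    "rrna_min_bits": (float, 50.0),
    "rrna_max_evalue": (float, 1e-5),
    "dbs": (lambda v: tuple(x.strip() for x in v.split(",") if x.strip()), ()),
    "db_priority": (lambda v: tuple(x.strip() for x in v.split(",") if x.strip()), ()),
}


@dataclass
class ParametersFile:
    """Stage flags plus the threshold map controlling every filter."""

    stages: dict[str, str] = field(default_factory=lambda: {s: "yes" for s in STAGES})
    min_nucleotide_length: int = 180
    min_orf_aa: int = 60
    max_evalue: float = 1e-5
    min_bsr: float = 0.4
    min_aln_length: int = 1
    pathway_tau: float = 0.5
    lca_top_fraction: float = 0.9
    lca_min_hits: int = 1
    rrna_min_identity: float = 90.0
    rrna_min_bits: float = 50.0
    rrna_max_evalue: float = 1e-5
    dbs: tuple[str, ...] = ()
    db_priority: tuple[str, ...] = ()

    def snapshot_lines(self) -> list[str]:
        """Render back to parameters-file syntax (used by the run receipt)."""
        lines = [f"{stage} {flag}" for stage, flag in self.stages.items()]
        for key in _THRESHOLD_KEYS:
            value = getattr(self, key)
            if isinstance(value, tuple):
                value = ",".join(value)
            lines.append(f"{key} {value}")
        return lines


# ---------------------------------------------------------------------------
# stream plumbing
# ---------------------------------------------------------------------------

def _open_text(source: Source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _open_out(dest: Source) -> tuple[IO[str], bool]:
    if isinstance(dest, (str, Path)):
        Path(dest).parent.mkdir(parents=True, exist_ok=True)
        return open(dest, "w", encoding="utf-8"), True
    return dest, False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: Source, moltype: str = "nucleotide") -> list[SequenceRecord]:
    """Parse FASTA into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes ``seq_id``;
    residues are uppercased and whitespace-stripped.
    """
    handle, close = _open_text(source)
    records: list[SequenceRecord] = []
    seq_id: str | None = None
    chunks: list[str] = []
    try:
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seq_id is not None:
                    records.append(SequenceRecord(seq_id, "".join(chunks), moltype=moltype))
                seq_id = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if seq_id is None:
                    raise FormatError("expected FASTA header ('>')", line=lineno)
                chunks.append(line.upper())
        if seq_id is not None:
            records.append(SequenceRecord(seq_id, "".join(chunks), moltype=moltype))
    finally:
        if close:
            handle.close()
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: Source, width: int = 70) -> None:
    handle, close = _open_out(dest)
    try:
        for rec in records:
            handle.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")
            if not rec.residues:
                handle.write("\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# tabular homology hits
# ---------------------------------------------------------------------------

def read_tabular_hits(source: Source, source_db: str = "") -> list[HomologyHit]:
    """Parse 12+-column tab-separated homology output.

    Columns 13+ are joined with tabs into ``subject_description``; when
    absent the description falls back to the subject id.  Lines starting
    with ``#`` are skipped; input row order is preserved.
    """
    handle, close = _open_text(source)
    hits: list[HomologyHit] = []
    try:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"expected >=12 tab-separated columns, got {len(cols)}", line=lineno
                )
            try:
                hit = HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                    subject_description="\t".join(cols[12:]) if len(cols) > 12 else cols[1],
                    source_db=source_db,
                )
            except ValueError as exc:
                raise FormatError(f"unparseable numeric field ({exc})", line=lineno) from exc
            if hit.evalue < 0:
                raise FormatError("negative e-value", line=lineno)
            if hit.aln_length < 1:
                raise FormatError("alignment length < 1", line=lineno)
            if not math.isfinite(hit.bit_score):
                raise FormatError("non-finite bit score", line=lineno)
            hits.append(hit)
    finally:
        if close:
            handle.close()
    return hits


def write_tabular_hits(hits: Iterable[HomologyHit], dest: Source) -> None:
    handle, close = _open_out(dest)
    try:
        for h in hits:
            cols = [
                h.query_id, h.subject_id, f"{h.pct_identity:g}", str(h.aln_length),
                str(h.mismatches), str(h.gap_opens), str(h.q_start), str(h.q_end),
                str(h.s_start), str(h.s_end), f"{h.evalue:g}", f"{h.bit_score:g}",
            ]
            if h.subject_description and h.subject_description != h.subject_id:
                cols.append(h.subject_description)
            handle.write("\t".join(cols) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GFF3 gene features
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff_orf_features(source: Source):
    """Parse CDS/ORF rows of a GFF3 file into OrfCall objects.

    GFF 1-based inclusive coordinates are converted to internal 0-based
    half-open.  ``partial=XY`` attributes (X = 5' flag, Y = 3' flag, as
    emitted by common prokaryotic gene callers) are honoured.
    """
    from .orfcall import OrfCall  # deferred: orfcall imports this module's types

    handle, close = _open_text(source)
    calls: list[OrfCall] = []
    try:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError("expected 9 GFF columns", line=lineno)
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols[:9]
            if ftype not in ("CDS", "ORF", "gene"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"bad coordinate ({exc})", line=lineno) from exc
            if end1 < start1:
                raise FormatError("feature end < start", line=lineno)
            if strand not in ("+", "-"):
                raise FormatError("strand must be '+' or '-' for CDS features", line=lineno)
            attrs = _parse_gff_attributes(attr_s)
            if "ID" not in attrs:
                raise FormatError("missing ID attribute", line=lineno)
            partial = attrs.get("partial", "00")
            partial_5 = partial[:1] == "1" or attrs.get("partial_5") == "true"
            partial_3 = partial[1:2] == "1" or attrs.get("partial_3") == "true"
            calls.append(
                OrfCall(
                    orf_id=attrs["ID"],
                    contig_id=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    partial_5=partial_5,
                    partial_3=partial_3,
                    translation=attrs.get("translation", ""),
                )
            )
    finally:
        if close:
            handle.close()
    return calls


def write_gff_orf_features(
    orfs: Iterable,
    dest: Source,
    extra_attrs: dict[str, dict[str, str]] | None = None,
    source_tag: str = "envpath",
) -> None:
    """Emit ORF calls as GFF3 CDS rows (1-based inclusive coordinates)."""
    handle, close = _open_out(dest)
    try:
        handle.write("##gff-version 3\n")
        for orf in orfs:
            attrs = [f"ID={orf.orf_id}"]
            partial = f"{int(orf.partial_5)}{int(orf.partial_3)}"
            attrs.append(f"partial={partial}")
            for key, value in (extra_attrs or {}).get(orf.orf_id, {}).items():
                attrs.append(f"{key}={value}")
            handle.write(
                "\t".join(
                    [
                        orf.contig_id, source_tag, "CDS",
                        str(orf.start + 1), str(orf.end), ".",
                        orf.strand, "0", ";".join(attrs),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# parameters file
# ---------------------------------------------------------------------------

def read_parameters(source: Source) -> ParametersFile:
    """Parse the line-oriented run-parameters file.

    Accepts ``key value`` and ``key: value`` separators; keys are
    case-insensitive; ``#`` starts a comment.  Unknown keys are rejected.
    Absent thresholds fall back to defaults; absent stages default to
    ``yes``.
    """
    handle, close = _open_text(source)
    params = ParametersFile()
    seen_stages: set[str] = set()
    try:
        for lineno, raw in enumerate(handle, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" in line:
                key, value = line.split(":", 1)
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ConfigError(f"line {lineno}: expected 'key value', got {line!r}")
                key, value = parts
            key = key.strip().lower()
            value = value.strip()
            if key in STAGES:
                if key in seen_stages:
                    raise ConfigError(f"line {lineno}: stage {key!r} named more than once")
                if value.lower() not in _FLAGS:
                    raise ConfigError(
                        f"line {lineno}: stage {key!r} flag must be one of "
                        f"{_FLAGS}, got {value!r}"
                    )
                params.stages[key] = value.lower()
                seen_stages.add(key)
            elif key in _THRESHOLD_KEYS:
                parser, _default = _THRESHOLD_KEYS[key]
                try:
                    setattr(params, key, parser(value))
                except ValueError as exc:
                    raise ConfigError(f"line {lineno}: bad value for {key!r}: {exc}") from exc
            else:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
    finally:
        if close:
            handle.close()
    return params
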