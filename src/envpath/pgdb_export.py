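"""Stage 4 — composite-genome concatenation and PGDB input emission.

Contigs are concatenated (no spacer) into a single "chromosomal" element
with a lift-over table so per-contig ORF coordinates can be projected
onto the composite and back.  Emission targets the PathoLogic input
dialect (.pf + genetic-elements + organism-params + FASTA) and GenBank
flat files.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .annotate import Annotation
from .core_formats import SequenceRecord, Source, _open_out, _open_text
from .errors import EnvPathError
from .orfcall import OrfCall


@dataclass
class CompositeGenome:
    """Concatenated contigs plus the coordinate lift-over table."""

    residues: str
    offsets: list[tuple[str, int, int]]  # (contig_id, start_offset, length)

    def __post_init__(self):
        self._offset_of = {cid: off for cid, off, _len in self.offsets}

    def __len__(self) -> int:
        return len(self.residues)

    def lift(self, contig_id: str, start: int, end: int) -> tuple[int, int]:
        """Project contig-local 0-based half-open coordinates onto the composite."""
        if contig_id not in self._offset_of:
            raise EnvPathError(f"unknown contig {contig_id!r}")
        offset = self._offset_of[contig_id]
        return offset + start, offset + end

    def unlift(self, start: int, end: int) -> tuple[str, int, int]:
        """Invert :meth:`lift`; the interval must lie within one contig."""
        for contig_id, offset, length in self.offsets:
            if offset <= start and end <= offset + length:
                return contig_id, start - offset, end - offset
        raise EnvPathError(f"interval ({start}, {end}) does not fit any contig")


def concatenate_contigs(records: Sequence[SequenceRecord]) -> CompositeGenome:
    """Concatenate contigs in input order into a composite genome."""
    if not records:
        raise EnvPathError("cannot concatenate an empty contig set")
    offsets = []
    cursor = 0
    for rec in records:
        offsets.append((rec.seq_id, cursor, len(rec.residues)))
        cursor += len(rec.residues)
    return CompositeGenome("".join(r.residues for r in records), offsets)


# ---------------------------------------------------------------------------
# PathoLogic input dialect
# ---------------------------------------------------------------------------

def write_pathologic_input(
    composite: CompositeGenome,
    orfs: Sequence[OrfCall],
    annotations: Mapping[str, Annotation],
    sample_name: str,
    out_dir: str | Path,
    ncbi_taxon_id: int = 12908,  # unclassified sequences
) -> dict[str, Path]:
    """Emit the four PGDB-construction input files into ``out_dir``.

    ORF coordinates are lifted onto the composite; STARTBASE/ENDBASE are
    1-based inclusive with STARTBASE > ENDBASE encoding the minus strand.
    Returns {role: path}.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    element_id = f"{sample_name}-chromosome-1"

    pf_path = out / f"{sample_name}.pf"
    with open(pf_path, "w", encoding="utf-8") as handle:
        for orf in orfs:
            start, end = composite.lift(orf.contig_id, orf.start, orf.end)
            if not (0 <= start < end <= len(composite)):
                raise EnvPathError(
                    f"ORF {orf.orf_id} lifts outside the composite genome"
                )
            if orf.strand == "+":
                startbase, endbase = start + 1, end
            else:
                startbase, endbase = end, start + 1
            ann = annotations.get(orf.orf_id)
            product = ann.product if ann is not None else "hypothetical protein"
            handle.write(f"ID\t{orf.orf_id}\n")
            handle.write(f"NAME\t{orf.orf_id}\n")
            handle.write(f"STARTBASE\t{startbase}\n")
            handle.write(f"ENDBASE\t{endbase}\n")
            handle.write(f"PRODUCT\t{product}\n")
            handle.write("PRODUCT-TYPE\tP\n")
            if ann is not None:
                for ec in sorted(ann.ec_numbers):
                    handle.write(f"EC\t{ec}\n")
            handle.write("//\n")

    fasta_path = out / f"{sample_name}.fasta"
    with open(fasta_path, "w", encoding="utf-8") as handle:
        handle.write(f">{element_id}\n")
        for i in range(0, len(composite.residues), 70):
            handle.write(composite.residues[i : i + 70] + "\n")

    elements_path = out / "genetic-elements.dat"
    with open(elements_path, "w", encoding="utf-8") as handle:
        handle.write(f"ID\t{element_id}\n")
        handle.write(f"NAME\t{sample_name} composite chromosome\n")
        handle.write("TYPE\t:CHRSM\n")
        handle.write("CIRCULAR?\tN\n")
        handle.write(f"ANNOT-FILE\t{pf_path.name}\n")
        handle.write(f"SEQ-FILE\t{fasta_path.name}\n")
        handle.write("//\n")

    params_path = out / "organism-params.dat"
    with open(params_path, "w", encoding="utf-8") as handle:
        handle.write(f"ID\t{sample_name}\n")
        handle.write(f"NAME\t{sample_name}\n")
        handle.write("STORAGE\tFILE\n")
        handle.write(f"NCBI-TAXON-ID\t{ncbi_taxon_id}\n")

    return {
        "pf": pf_path,
        "fasta": fasta_path,
        "genetic_elements": elements_path,
        "organism_params": params_path,
    }


def read_pf(source: Source) -> list[dict[str, object]]:
    """Parse a .pf annotation file back into per-ORF field dicts."""
    handle, close = _open_text(source)
    records: list[dict[str, object]] = []
    current: dict[str, object] = {}
    try:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.strip() == "//":
                if current:
                    records.append(current)
                current = {}
                continue
            key, _sep, value = line.partition("\t")
            if key == "EC":
                current.setdefault("EC", []).append(value)
            elif key in ("STARTBASE", "ENDBASE"):
                current[key] = int(value)
            else:
                current[key] = value
        if current:
            records.append(current)
    finally:
        if close:
            handle.close()
    return records


# ---------------------------------------------------------------------------
# GenBank emission
# ---------------------------------------------------------------------------

def write_genbank(
    records: Sequence[SequenceRecord],
    orfs_by_contig: Mapping[str, Sequence[OrfCall]],
    annotations: Mapping[str, Annotation],
    dest: str | Path,
) -> None:
    """Write contigs with CDS features as a GenBank flat file."""
    bio_records = []
    for rec in records:
        bio = BioSeqRecord(
            Seq(rec.residues),
            id=rec.seq_id,
            name=rec.seq_id[:16],
            description=rec.original_id or rec.seq_id,
        )
        bio.annotations["molecule_type"] = "DNA"
        bio.annotations["data_file_division"] = "ENV"
        bio.annotations["topology"] = "linear"
        bio.annotations["date"] = (
            datetime.date.today().strftime("%d-%b-%Y").upper()
        )
        for orf in orfs_by_contig.get(rec.seq_id, ()):
            ann = annotations.get(orf.orf_id)
            qualifiers: dict[str, list[str]] = {
                "locus_tag": [orf.orf_id],
                "product": [ann.product if ann else "hypothetical protein"],
            }
            if ann and ann.ec_numbers:
                qualifiers["EC_number"] = sorted(ann.ec_numbers)
            if orf.translation:
                qualifiers["translation"] = [orf.translation]
            bio.features.append(
                SeqFeature(
                    FeatureLocation(orf.start, orf.end, strand=1 if orf.strand == "+" else -1),
                    type="CDS",
                    qualifiers=qualifiers,
                )
            )
        bio_records.append(bio)
    Path(dest).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(bio_records, str(dest), "genbank")


def read_genbank(source: str | Path) -> tuple[list[SequenceRecord], dict[str, list[OrfCall]], dict[str, Annotation]]:
    """Re-parse a GenBank flat file into pipeline types (round-trip aid)."""
    contigs: list[SequenceRecord] = []
    orfs: dict[str, list[OrfCall]] = {}
    annotations: dict[str, Annotation] = {}
    for bio in SeqIO.parse(str(source), "genbank"):
        contigs.append(SequenceRecord(bio.id, str(bio.seq).upper()))
        for feat in bio.features:
            if feat.type != "CDS":
                continue
            orf_id = feat.qualifiers.get("locus_tag", ["?"])[0]
            orf = OrfCall(
                orf_id=orf_id,
                contig_id=bio.id,
                start=int(feat.location.start),
                end=int(feat.location.end),
                strand="+" if feat.location.strand >= 0 else "-",
                translation=feat.qualifiers.get("translation", [""])[0],
            )
            orfs.setdefault(bio.id, []).append(orf)
            annotations[orf_id] = Annotation(
                orf_id=orf_id,
                product=feat.qualifiers.get("product", [""])[0],
                ec_numbers=frozenset(feat.qualifiers.get("EC_number", [])),
            )
    return contigs, orfs, annotations


def write_feature_table(
    orfs: Sequence[OrfCall],
    annotations: Mapping[str, Annotation],
    taxa: Mapping[str, str] | None,
    dest: Source,
) -> None:
    """Tab-separated gene feature table (replaces legacy submission formats)."""
    handle, close = _open_out(dest)
    try:
        handle.write("#orf_id\tcontig\tstart\tend\tstrand\tproduct\tec\ttaxon\n")
        for orf in orfs:
            ann = annotations.get(orf.orf_id)
            product = ann.product if ann else ""
            ecs = ",".join(sorted(ann.ec_numbers)) if ann else ""
            taxon = (taxa or {}).get(orf.orf_id, "")
            handle.write(
                f"{orf.orf_id}\t{orf.contig_id}\t{orf.start}\t{orf.end}"
                f"\t{orf.strand}\t{product}\t{ecs}\t{taxon}\n"
            )
    finally:
        if close:
            handle.close()
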