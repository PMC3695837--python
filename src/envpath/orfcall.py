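"""Fallback ORF discovery and translation.

When no external gene-caller GFF is supplied, a six-frame scan finds
maximal stop-free stretches and reports them as ORFs.  All translation in
the pipeline (bacterial/archaeal code, table 11) goes through
:func:`translate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import EnvPathError

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
TRANSLATION_TABLE = 11

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


@dataclass
class OrfCall:
    """A coordinate-anchored ORF on a contig (0-based half-open)."""

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    partial_5: bool = False
    partial_3: bool = False
    translation: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"ORF {self.orf_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.orf_id}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def reverse_complement(nucleotides: str) -> str:
    return nucleotides.upper().translate(_COMPLEMENT)[::-1]


def translate(nucleotides: str, strand: str = "+") -> str:
    """Conceptually translate a nucleotide stretch (table 11).

    Codons containing 'N' or other ambiguity codes become 'X'; the
    terminal stop (if any) is removed; internal stops render as '*'.
    Strand '-' translates the reverse complement.  A trailing partial
    codon is ignored.
    """
    if len(nucleotides) < 3:
        raise EnvPathError("cannot translate fewer than 3 nucleotides")
    nts = nucleotides.upper().replace("U", "T")
    if strand == "-":
        nts = reverse_complement(nts)
    nts = nts[: len(nts) - len(nts) % 3]
    amino = str(Seq(nts).translate(table=TRANSLATION_TABLE))
    if amino.endswith("*"):
        amino = amino[:-1]
    return amino


def _scan_frame(frame_seq: str, min_aa: int):
    """Yield (start, end, partial_5, partial_3) in frame-local nt offsets.

    Segments between stops become candidate ORFs.  A segment flush with
    the sequence start/end is partial at that edge; interior segments must
    begin at a start codon.  Coordinates include the stop codon.
    """
    n_codons = len(frame_seq) // 3
    codons = [frame_seq[3 * i : 3 * (i + 1)] for i in range(n_codons)]
    seg_start = 0  # codon index of current stop-free segment
    after_stop = False  # segment preceded by a stop codon?
    for i, codon in enumerate(codons + ["TAA"]):  # sentinel closes last segment
        at_end = i == n_codons
        if codon in STOP_CODONS or at_end:
            seg_codons = codons[seg_start:i]
            if seg_codons:
                partial_3 = at_end
                first_start = next(
                    (j for j in range(seg_start, i) if codons[j] in START_CODONS),
                    None,
                )
                if first_start is not None:
                    orf_start, partial_5 = first_start, False
                elif not after_stop and not at_end:
                    # 5'-edge stretch anchored by its stop codon
                    orf_start, partial_5 = seg_start, True
                else:
                    # no start codon and no stop anchor: not reportable
                    orf_start = None
                if orf_start is not None:
                    orf_end = i if partial_3 else i + 1  # include stop codon
                    aa_len = i - orf_start
                    if aa_len >= min_aa:
                        yield orf_start * 3, orf_end * 3, partial_5, partial_3
            seg_start = i + 1
            after_stop = True


def scan_orfs_six_frame(record, min_aa: int = 60) -> list[OrfCall]:
    """Report ORFs from maximal stop-free stretches in all six frames.

    An ORF runs from the first start codon (ATG/GTG/TTG) of a stretch to
    its stop codon; stretches flush with a contig edge are reported as
    partial.  ORFs whose translation is shorter than ``min_aa`` — or all
    'X' (fully ambiguous sequence) — are dropped.  Ids are assigned
    ``<contig>_<k>`` in (start, strand) order.
    """
    seq = record.residues.upper()
    length = len(seq)
    found: list[tuple[int, str, int, bool, bool]] = []
    for strand in ("+", "-"):
        template = seq if strand == "+" else reverse_complement(seq)
        for offset in range(3):
            frame_seq = template[offset:]
            for fs, fe, p5, p3 in _scan_frame(frame_seq, min_aa):
                s, e = offset + fs, offset + fe
                if strand == "+":
                    found.append((s, strand, e, p5, p3))
                else:
                    # mirror onto forward coordinates; partial flags stay
                    # biological (5' = reading-direction start)
                    found.append((length - e, strand, length - s, p5, p3))
    found.sort(key=lambda t: (t[0], t[1]))
    calls: list[OrfCall] = []
    for k, (start, strand, end, p5, p3) in enumerate(found):
        aa = translate(seq[start:end], strand)
        if not aa or set(aa) == {"X"}:
            continue
        calls.append(
            OrfCall(
                orf_id=f"{record.seq_id}_{len(calls)}",
                contig_id=record.seq_id,
                start=start,
                end=end,
                strand=strand,
                partial_5=p5,
                partial_3=p3,
                translation=aa,
            )
        )
    return calls


def attach_translations(orfs, contigs_by_id) -> None:
    """Fill in translations for externally-called ORFs from their contigs."""
    for orf in orfs:
        if orf.translation:
            continue
        contig = contigs_by_id[orf.contig_id]
        orf.translation = translate(contig.residues[orf.start : orf.end], orf.strand)
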