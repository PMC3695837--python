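"""Stage 2 — self-scores, BSR filtering and consensus product naming.

A hit survives when its e-value, alignment length and BLAST-score ratio
(bit score over the query's self-alignment bit score) all pass their
thresholds; the BSR cutoff defaults to 0.4 and is inclusive.  Among the
per-database best hits, the product description with the highest
"information score" (distinct enzymatic words, +10 for an EC number)
wins; ORFs with no surviving hit become "hypothetical protein".
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices

from .core_formats import HomologyHit, Source, _open_out, _open_text
from .errors import AnnotationError, EnvPathError

# gapped Karlin-Altschul constants for BLOSUM62 (BLAST defaults)
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_DIAGONAL = {aa: float(_BLOSUM62[aa, aa]) for aa in _BLOSUM62.alphabet}
_X_SELF = _DIAGONAL["X"]  # -1; used for any residue outside the matrix

EC_PATTERN = re.compile(
    r"\bEC[\s:]*((?:\d+|-)\.(?:\d+|-)\.(?:\d+|-)\.(?:n?\d+|-))", re.IGNORECASE
)

# words carrying no enzymatic information; excluded from the score
NON_INFORMATIVE_WORDS = frozenset(
    {
        "protein", "putative", "probable", "possible", "predicted",
        "hypothetical", "unknown", "uncharacterized", "conserved", "domain",
        "family", "subunit", "precursor", "like", "related", "unnamed",
        "product", "gene", "orf", "fragment", "partial",
    }
)

_TOKEN = re.compile(r"[a-z0-9]+")


@dataclass
class ParsedHitRow(HomologyHit):
    """A homology hit that survived filtering, with its BSR attached."""

    bsr: float = 0.0


@dataclass
class Annotation:
    """Consensus functional annotation of one ORF."""

    orf_id: str
    product: str
    ec_numbers: frozenset[str] = frozenset()
    source_db: str = ""
    info_score: int = 0
    best_hit: ParsedHitRow | None = None


@dataclass
class HitFilterThresholds:
    max_evalue: float = 1e-5
    min_bsr: float = 0.4
    min_aln_length: int = 1


@dataclass
class RrnaThresholds:
    min_identity: float = 90.0
    min_bits: float = 50.0
    max_evalue: float = 1e-5


@dataclass
class RrnaRow:
    query_id: str
    pct_identity: float
    evalue: float
    bit_score: float
    taxon: str
    source_db: str


# ---------------------------------------------------------------------------
# self-scores and BSR
# ---------------------------------------------------------------------------

def self_bit_score(translation: str) -> float:
    """Bit score of a protein aligned to itself.

    The raw score is the sum of BLOSUM62 diagonal values over the
    residues ('X' and unknown characters contribute -1); conversion to
    bits uses the gapped Karlin-Altschul constants above.  Stands in for
    an actual self-alignment when no precomputed score table is supplied.
    """
    if not translation:
        raise EnvPathError("cannot score an empty sequence")
    raw = sum(_DIAGONAL.get(aa, _X_SELF) for aa in translation.upper())
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)


def read_refscores(source: Source) -> dict[str, float]:
    """Read a precomputed query<TAB>bits self-score table (overrides computation)."""
    handle, close = _open_text(source)
    try:
        scores: dict[str, float] = {}
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            query, bits = line.split("\t")[:2]
            scores[query] = float(bits)
        return scores
    finally:
        if close:
            handle.close()


def write_refscores(scores: Mapping[str, float], dest: Source) -> None:
    handle, close = _open_out(dest)
    try:
        for query, bits in scores.items():
            handle.write(f"{query}\t{bits:.2f}\n")
    finally:
        if close:
            handle.close()


def bsr(hit_bits: float, self_bits: float) -> float:
    """BLAST-score ratio: hit bit score over the query's self bit score."""
    if self_bits <= 0:
        raise EnvPathError(f"self bit score must be positive, got {self_bits}")
    return hit_bits / self_bits


def filter_hits(
    hits: Sequence[HomologyHit],
    self_scores: Mapping[str, float],
    thresholds: HitFilterThresholds | None = None,
) -> list[ParsedHitRow]:
    """Apply e-value, alignment-length and BSR thresholds.

    Surviving rows carry their BSR and are grouped by query (first-
    appearance order), sorted within each query by ascending e-value then
    descending bit score.  The BSR boundary is inclusive: 0.40 survives
    the default cutoff, 0.39 does not.
    """
    thr = thresholds or HitFilterThresholds()
    by_query: dict[str, list[ParsedHitRow]] = {}
    for hit in hits:
        if hit.query_id not in self_scores:
            raise AnnotationError(f"no self score for query {hit.query_id!r}")
        ratio = bsr(hit.bit_score, self_scores[hit.query_id])
        if hit.evalue > thr.max_evalue:
            continue
        if hit.aln_length < thr.min_aln_length:
            continue
        if ratio < thr.min_bsr:
            continue
        row = ParsedHitRow(**vars(hit), bsr=ratio)
        by_query.setdefault(hit.query_id, []).append(row)
    out: list[ParsedHitRow] = []
    for rows in by_query.values():
        rows.sort(key=lambda r: (r.evalue, -r.bit_score))
        out.extend(rows)
    return out


# ---------------------------------------------------------------------------
# information score and consensus annotation
# ---------------------------------------------------------------------------

def extract_ec_numbers(description: str) -> frozenset[str]:
    return frozenset(m.group(1) for m in EC_PATTERN.finditer(description))


def information_score(description: str) -> int:
    """Count distinct enzymatic words; +10 if an EC number is present.

    EC substrings are cut out before tokenizing; remaining text is split
    on non-alphanumeric boundaries, lowercased, and tokens shorter than 3
    characters or on the non-informative list are dropped.
    """
    has_ec = bool(EC_PATTERN.search(description))
    text = EC_PATTERN.sub(" ", description).lower()
    words = {
        tok
        for tok in _TOKEN.findall(text)
        if len(tok) >= 3 and tok not in NON_INFORMATIVE_WORDS
    }
    return len(words) + (10 if has_ec else 0)


HYPOTHETICAL = "hypothetical protein"


def select_annotation(
    orf_id: str,
    hits_by_db: Mapping[str, Sequence[ParsedHitRow]],
    db_priority: Sequence[str] = (),
) -> Annotation:
    """Reduce per-database filtered hits to one consensus annotation.

    From each database the lowest-e-value row (ties: higher bit score) is
    a candidate; the candidate whose description has the highest
    information score wins.  Ties break by ``db_priority`` order, then by
    bit score.  No candidates at all → "hypothetical protein".
    """
    candidates: list[tuple[str, ParsedHitRow, int]] = []
    for db, rows in hits_by_db.items():
        mine = [r for r in rows if r.query_id == orf_id]
        if not mine:
            continue
        best = min(mine, key=lambda r: (r.evalue, -r.bit_score))
        candidates.append((db, best, information_score(best.subject_description)))
    if not candidates:
        return Annotation(orf_id=orf_id, product=HYPOTHETICAL)

    def rank(db: str) -> int:
        try:
            return list(db_priority).index(db)
        except ValueError:
            return len(db_priority)

    db, best, score = max(
        candidates, key=lambda c: (c[2], -rank(c[0]), c[1].bit_score)
    )
    description = best.subject_description or best.subject_id
    return Annotation(
        orf_id=orf_id,
        product=description,
        ec_numbers=extract_ec_numbers(description),
        source_db=db,
        info_score=score,
        best_hit=best,
    )


def annotate_orfs(
    orf_ids: Sequence[str],
    hits_by_db: Mapping[str, Sequence[ParsedHitRow]],
    db_priority: Sequence[str] = (),
) -> list[Annotation]:
    return [select_annotation(oid, hits_by_db, db_priority) for oid in orf_ids]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_hierarchy(
    annotations: Iterable[Annotation],
    hierarchy_table: Mapping[str, Sequence[str]],
    db: str,
) -> dict[int, Counter]:
    """Count annotated ORFs per category at each hierarchy level.

    Only annotations won by ``db`` contribute; subjects absent from the
    table are tallied under "Unknown" at level 1.
    """
    levels: dict[int, Counter] = {}
    for ann in annotations:
        if ann.best_hit is None or ann.source_db != db:
            continue
        path = hierarchy_table.get(ann.best_hit.subject_id)
        if path is None:
            levels.setdefault(1, Counter())["Unknown"] += 1
            continue
        for depth, category in enumerate(path, start=1):
            levels.setdefault(depth, Counter())[category] += 1
    return levels


def classify_rrna(
    hits: Sequence[HomologyHit],
    thresholds: RrnaThresholds | None = None,
) -> list[RrnaRow]:
    """Best passing nucleotide hit per query, with the subject's taxon."""
    thr = thresholds or RrnaThresholds()
    best: dict[str, HomologyHit] = {}
    order: list[str] = []
    for hit in hits:
        if hit.query_id not in best:
            order.append(hit.query_id)
            best[hit.query_id] = hit
        elif hit.bit_score > best[hit.query_id].bit_score:
            best[hit.query_id] = hit
    rows = []
    for query in order:
        hit = best[query]
        if (
            hit.pct_identity >= thr.min_identity
            and hit.bit_score >= thr.min_bits
            and hit.evalue <= thr.max_evalue
        ):
            rows.append(
                RrnaRow(
                    query_id=query,
                    pct_identity=hit.pct_identity,
                    evalue=hit.evalue,
                    bit_score=hit.bit_score,
                    taxon=hit.subject_description or hit.subject_id,
                    source_db=hit.source_db,
                )
            )
    return rows


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_parsed_hits(rows: Iterable[ParsedHitRow], dest: Source) -> None:
    """Write the parsed-hit summary table (declared column dialect)."""
    handle, close = _open_out(dest)
    try:
        handle.write(
            "#query\tsubject\tpct_identity\taln_length\tevalue\tbit_score\tbsr"
            "\tdescription\tdb\n"
        )
        for r in rows:
            handle.write(
                f"{r.query_id}\t{r.subject_id}\t{r.pct_identity:g}\t{r.aln_length}"
                f"\t{r.evalue:g}\t{r.bit_score:g}\t{r.bsr:.3f}"
                f"\t{r.subject_description}\t{r.source_db}\n"
            )
    finally:
        if close:
            handle.close()


def write_functional_stats(levels: Mapping[int, Counter], dest: Source) -> None:
    handle, close = _open_out(dest)
    try:
        handle.write("#level\tcategory\tcount\n")
        for depth in sorted(levels):
            for category, count in levels[depth].most_common():
                handle.write(f"{depth}\t{category}\t{count}\n")
    finally:
        if close:
            handle.close()


def write_rrna_stats(rows: Iterable[RrnaRow], dest: Source) -> None:
    handle, close = _open_out(dest)
    try:
        handle.write("#query\tpct_identity\tevalue\tbit_score\ttaxon\tdb\n")
        for r in rows:
            handle.write(
                f"{r.query_id}\t{r.pct_identity:g}\t{r.evalue:g}\t{r.bit_score:g}"
                f"\t{r.taxon}\t{r.source_db}\n"
            )
    finally:
        if close:
            handle.close()


def annotated_gff_attrs(annotations: Iterable[Annotation]) -> dict[str, dict[str, str]]:
    """Per-ORF extra GFF attributes (product=, ec=, db=, bsr=)."""
    attrs: dict[str, dict[str, str]] = {}
    for ann in annotations:
        entry = {"product": ann.product.replace(";", ",").replace("=", " ")}
        if ann.ec_numbers:
            entry["ec"] = ",".join(sorted(ann.ec_numbers))
        if ann.source_db:
            entry["db"] = ann.source_db
        if ann.best_hit is not None:
            entry["bsr"] = f"{ann.best_hit.bsr:.3f}"
        attrs[ann.orf_id] = entry
    return attrs
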