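"""Stage 5 — rule-based pathway inference, export tables and the
classification-statistics harness.

A pathway is predicted when the fraction of its reactions covered by
annotated EC numbers reaches a threshold τ and, when the catalog flags
key reactions, at least one of them is covered.  Predictions are scored
against a gold-standard pathway set over a fixed pathway universe with
the usual confusion-table statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Set

from .annotate import Annotation
from .core_formats import Source, _open_out, _open_text
from .errors import CatalogError, EnvPathError, FormatError


@dataclass
class PathwayDefinition:
    pathway_id: str
    name: str
    reactions: frozenset[str]  # EC-keyed reaction ids
    key_reactions: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.reactions:
            raise CatalogError(f"pathway {self.pathway_id}: empty reaction set")
        if not self.key_reactions <= self.reactions:
            raise CatalogError(
                f"pathway {self.pathway_id}: key reactions not a subset of reactions"
            )


@dataclass
class PathwayPrediction:
    pathway_id: str
    covered: frozenset[str]
    coverage: float
    predicted: bool
    orfs_per_reaction: dict[str, frozenset[str]] = field(default_factory=dict)


@dataclass
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PerfStats:
    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f_measure: float
    matthews: float


# ---------------------------------------------------------------------------
# catalog I/O
# ---------------------------------------------------------------------------

def read_pathway_catalog(source: Source) -> list[PathwayDefinition]:
    """TSV: pathway_id, name, ';'-joined reaction ECs, ';'-joined key ECs."""
    handle, close = _open_text(source)
    catalog = []
    try:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError("expected >=3 catalog columns", line=lineno)
            reactions = frozenset(r.strip() for r in cols[2].split(";") if r.strip())
            keys = frozenset(
                r.strip() for r in (cols[3] if len(cols) > 3 else "").split(";") if r.strip()
            )
            catalog.append(PathwayDefinition(cols[0], cols[1], reactions, keys))
    finally:
        if close:
            handle.close()
    return catalog


def write_pathway_catalog(catalog: Iterable[PathwayDefinition], dest: Source) -> None:
    handle, close = _open_out(dest)
    try:
        for p in catalog:
            handle.write(
                f"{p.pathway_id}\t{p.name}\t{';'.join(sorted(p.reactions))}"
                f"\t{';'.join(sorted(p.key_reactions))}\n"
            )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def infer_pathways(
    annotations: Iterable[Annotation],
    catalog: Sequence[PathwayDefinition],
    tau: float = 0.5,
    require_key: bool = True,
) -> list[PathwayPrediction]:
    """Predict pathways from the EC numbers carried by the annotations.

    predicted ⇔ coverage ≥ τ AND (no key reactions OR ≥1 key covered,
    when ``require_key``).  Coverage and per-reaction ORF lists are
    reported for every pathway, predicted or not.
    """
    if not 0 < tau <= 1:
        raise EnvPathError(f"tau must be in (0, 1], got {tau}")
    orfs_by_ec: dict[str, set[str]] = {}
    for ann in annotations:
        for ec in ann.ec_numbers:
            orfs_by_ec.setdefault(ec, set()).add(ann.orf_id)
    predictions = []
    for pwy in catalog:
        covered = frozenset(r for r in pwy.reactions if r in orfs_by_ec)
        coverage = len(covered) / len(pwy.reactions)
        key_ok = not require_key or not pwy.key_reactions or bool(
            pwy.key_reactions & covered
        )
        predictions.append(
            PathwayPrediction(
                pathway_id=pwy.pathway_id,
                covered=covered,
                coverage=coverage,
                predicted=coverage >= tau and key_ok,
                orfs_per_reaction={
                    r: frozenset(orfs_by_ec.get(r, ())) for r in sorted(pwy.reactions)
                },
            )
        )
    return predictions


def predicted_set(predictions: Iterable[PathwayPrediction]) -> frozenset[str]:
    return frozenset(p.pathway_id for p in predictions if p.predicted)


def export_pathway_tables(
    predictions: Sequence[PathwayPrediction],
    catalog: Sequence[PathwayDefinition],
    pathways_dest: Source,
    rxns_dest: Source,
) -> None:
    """Write the per-pathway and per-reaction export tables."""
    names = {p.pathway_id: p.name for p in catalog}
    sizes = {p.pathway_id: len(p.reactions) for p in catalog}
    handle, close = _open_out(pathways_dest)
    try:
        handle.write("#pathway_id\tname\tcoverage\tn_reactions\tn_covered\tpredicted\n")
        for pred in predictions:
            handle.write(
                f"{pred.pathway_id}\t{names.get(pred.pathway_id, '')}"
                f"\t{pred.coverage:.4f}\t{sizes.get(pred.pathway_id, 0)}"
                f"\t{len(pred.covered)}\t{'yes' if pred.predicted else 'no'}\n"
            )
    finally:
        if close:
            handle.close()
    handle, close = _open_out(rxns_dest)
    try:
        handle.write("#pathway_id\treaction\tcovered\torfs\n")
        for pred in predictions:
            for reaction, orfs in pred.orfs_per_reaction.items():
                covered = "yes" if reaction in pred.covered else "no"
                handle.write(
                    f"{pred.pathway_id}\t{reaction}\t{covered}\t{','.join(sorted(orfs))}\n"
                )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def confusion(
    predicted: Set[str], gold: Set[str], universe: Set[str]
) -> ConfusionTable:
    """TP/FP/FN/TN counts of predicted vs gold over a fixed universe."""
    predicted, gold, universe = set(predicted), set(gold), set(universe)
    if not predicted <= universe:
        raise EnvPathError("predicted set extends beyond the universe")
    if not gold <= universe:
        raise EnvPathError("gold set extends beyond the universe")
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = len(universe - (predicted | gold))
    return ConfusionTable(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0  # 0/0 -> 0 by convention


def f_measure(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    return _ratio(2 * precision * sensitivity, precision + sensitivity)


def perf_stats(table: ConfusionTable) -> PerfStats:
    """Classification statistics from a confusion table.

    Degenerate 0/0 ratios are 0 by convention; an all-zero table is an
    error.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if min(tp, fp, fn, tn) < 0:
        raise EnvPathError("confusion counts must be non-negative")
    if table.total == 0:
        raise EnvPathError("confusion table is all zero")
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    accuracy = _ratio(tp + tn, table.total)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    matthews = _ratio(tp * tn - fp * fn, mcc_den)
    return PerfStats(
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        f_measure=f_measure(precision, sensitivity),
        matthews=matthews,
    )


def pathway_recovery(predicted: Set[str], gold: Set[str]) -> float:
    """Percentage of gold pathways recovered by the prediction."""
    if not gold:
        raise EnvPathError("gold set must be non-empty")
    return 100.0 * len(set(predicted) & set(gold)) / len(gold)


def write_confusion_stats(
    table: ConfusionTable, stats: PerfStats, dest: Source
) -> None:
    handle, close = _open_out(dest)
    try:
        handle.write("#key\tvalue\n")
        for key in ("tp", "fp", "fn", "tn"):
            handle.write(f"{key}\t{getattr(table, key)}\n")
        for key in (
            "precision", "sensitivity", "specificity", "accuracy",
            "f_measure", "matthews",
        ):
            handle.write(f"{key}\t{getattr(stats, key):.6f}\n")
    finally:
        if close:
            handle.close()
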