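"""Stage 3 analytic module — lowest-common-ancestor taxonomic binning.

Hits within a configurable bit-score window of the best hit have their
subject taxon names resolved against the taxonomy (official names are
preferred over synonyms); the ORF is assigned the deepest node common to
every resolved taxon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_formats import HomologyHit, Source, _open_out, _open_text
from .errors import EnvPathError, FormatError


@dataclass
class TaxonomyNode:
    tax_id: int
    parent_id: int
    rank: str
    official_name: str
    synonyms: frozenset[str] = frozenset()


@dataclass
class TaxonAssignment:
    orf_id: str
    tax_id: int | None
    supporting_hits: int = 0
    unresolved_names: frozenset[str] = frozenset()


_BRACKETED = re.compile(r"\[([^\[\]]+)\]\s*$")


class Taxonomy:
    """A rooted taxonomy tree with name and synonym lookup."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.tax_id in self.nodes:
                raise EnvPathError(f"duplicate tax_id {node.tax_id}")
            self.nodes[node.tax_id] = node
        roots = [n.tax_id for n in self.nodes.values() if n.parent_id == n.tax_id]
        if len(roots) != 1:
            raise EnvPathError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._by_name: dict[str, int] = {}
        self._by_synonym: dict[str, int] = {}
        for node in self.nodes.values():
            key = node.official_name.lower()
            if key in self._by_name:
                raise EnvPathError(f"official name not unique: {node.official_name!r}")
            self._by_name[key] = node.tax_id
            for syn in node.synonyms:
                self._by_synonym.setdefault(syn.lower(), node.tax_id)
        self._depth: dict[int, int] = {}
        for tax_id in self.nodes:
            self._depth_of(tax_id)

    def _depth_of(self, tax_id: int) -> int:
        if tax_id == self.root:
            return self._depth.setdefault(tax_id, 0)
        if tax_id in self._depth:
            return self._depth[tax_id]
        chain = []
        cursor = tax_id
        while cursor not in self._depth:
            if cursor not in self.nodes:
                raise EnvPathError(f"unknown parent {cursor} in taxonomy")
            chain.append(cursor)
            parent = self.nodes[cursor].parent_id
            if parent == cursor and cursor != self.root:
                raise EnvPathError(f"node {cursor} is a second root")
            if len(chain) > len(self.nodes):
                raise EnvPathError("cycle in taxonomy parent chain")
            cursor = parent
        base = self._depth[cursor]
        for node in reversed(chain):
            base += 1
            self._depth[node] = base
        return self._depth[tax_id]

    # -- lookup ------------------------------------------------------------

    def depth(self, tax_id: int) -> int:
        return self._depth[tax_id]

    def name(self, tax_id: int) -> str:
        return self.nodes[tax_id].official_name

    def rank(self, tax_id: int) -> str:
        return self.nodes[tax_id].rank

    def path_to_root(self, tax_id: int) -> list[int]:
        """Node ids from ``tax_id`` up to and including the root."""
        path = [tax_id]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent_id)
        return path

    def resolve_name(self, name: str) -> int | None:
        """Exact official-name match first, synonyms second, else None."""
        key = name.strip().lower()
        if key in self._by_name:
            return self._by_name[key]
        return self._by_synonym.get(key)

    # -- LCA ---------------------------------------------------------------

    def _lca_pair(self, a: int, b: int) -> int:
        # equalize depths, then ascend in lockstep
        while self._depth[a] > self._depth[b]:
            a = self.nodes[a].parent_id
        while self._depth[b] > self._depth[a]:
            b = self.nodes[b].parent_id
        while a != b:
            a = self.nodes[a].parent_id
            b = self.nodes[b].parent_id
        return a

    def lca(self, tax_ids: Iterable[int]) -> int:
        """Deepest node lying on every input's path to the root."""
        ids = list(tax_ids)
        if not ids:
            raise EnvPathError("lca of an empty set is undefined")
        for tid in ids:
            if tid not in self.nodes:
                raise EnvPathError(f"unknown tax_id {tid}")
        result = ids[0]
        for tid in ids[1:]:
            result = self._lca_pair(result, tid)
        return result

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, source: Source) -> "Taxonomy":
        """Load from TSV: tax_id, parent_id, rank, official_name, synonyms.

        Synonyms are pipe-separated in the fifth column (optional).
        """
        handle, close = _open_text(source)
        nodes = []
        try:
            for lineno, raw in enumerate(handle, 1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 4:
                    raise FormatError("expected >=4 taxonomy columns", line=lineno)
                synonyms = frozenset(
                    s.strip() for s in (cols[4] if len(cols) > 4 else "").split("|") if s.strip()
                )
                nodes.append(
                    TaxonomyNode(int(cols[0]), int(cols[1]), cols[2], cols[3], synonyms)
                )
        finally:
            if close:
                handle.close()
        return cls(nodes)

    def to_tsv(self, dest: Source) -> None:
        handle, close = _open_out(dest)
        try:
            for node in self.nodes.values():
                handle.write(
                    f"{node.tax_id}\t{node.parent_id}\t{node.rank}"
                    f"\t{node.official_name}\t{'|'.join(sorted(node.synonyms))}\n"
                )
        finally:
            if close:
                handle.close()


def subject_taxon_name(hit: HomologyHit, side_table: Mapping[str, str] | None = None) -> str:
    """Taxon name for a hit: side table, else trailing [bracketed] text,
    else the whole description."""
    if side_table is not None and hit.subject_id in side_table:
        return side_table[hit.subject_id]
    match = _BRACKETED.search(hit.subject_description)
    if match:
        return match.group(1)
    return hit.subject_description or hit.subject_id


def assign_orf_taxonomy(
    orf_id: str,
    hits: Sequence[HomologyHit],
    taxonomy: Taxonomy,
    taxon_names: Mapping[str, str] | None = None,
    top_bits_fraction: float = 0.9,
    min_hits: int = 1,
) -> TaxonAssignment:
    """LCA placement from the hits within the top bit-score window.

    Hits whose bit score is at least ``top_bits_fraction`` of the best
    contribute; their names are resolved (officials before synonyms) and
    the assignment is the LCA of the resolved ids.  Unresolved names are
    recorded, never fatal; if nothing resolves (or fewer than
    ``min_hits`` do) the ORF stays unassigned.
    """
    if not hits:
        return TaxonAssignment(orf_id=orf_id, tax_id=None)
    best_bits = max(h.bit_score for h in hits)
    window = [h for h in hits if h.bit_score >= top_bits_fraction * best_bits]
    resolved: list[int] = []
    unresolved: set[str] = set()
    for hit in window:
        name = subject_taxon_name(hit, taxon_names)
        tax_id = taxonomy.resolve_name(name)
        if tax_id is None:
            unresolved.add(name)
        else:
            resolved.append(tax_id)
    if len(resolved) < max(min_hits, 1):
        return TaxonAssignment(orf_id=orf_id, tax_id=None, unresolved_names=frozenset(unresolved))
    return TaxonAssignment(
        orf_id=orf_id,
        tax_id=taxonomy.lca(resolved),
        supporting_hits=len(resolved),
        unresolved_names=frozenset(unresolved),
    )


def write_fxn_taxa_table(
    assignments: Sequence[TaxonAssignment],
    annotations: Mapping[str, object],
    taxonomy: Taxonomy,
    dest: Source,
) -> None:
    """Write the combined function-and-taxonomy table.

    Columns: orf_id, product, ec, taxon name, taxon rank, supporting
    hits; trailing placement columns are left empty (external marker-gene
    placement is out of scope).
    """
    handle, close = _open_out(dest)
    try:
        handle.write(
            "#orf_id\tproduct\tec\ttaxon\trank\tsupporting_hits\tplacement\n"
        )
        for a in assignments:
            ann = annotations.get(a.orf_id)
            product = getattr(ann, "product", "")
            ecs = ",".join(sorted(getattr(ann, "ec_numbers", ()) or ()))
            if a.tax_id is None:
                taxon, rank = "unassigned", ""
            else:
                taxon, rank = taxonomy.name(a.tax_id), taxonomy.rank(a.tax_id)
            handle.write(
                f"{a.orf_id}\t{product}\t{ecs}\t{taxon}\t{rank}\t{a.supporting_hits}\t\n"
            )
    finally:
        if close:
            handle.close()
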