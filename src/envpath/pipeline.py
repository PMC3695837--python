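"""Pipeline orchestration: run the five stages per the parameters file.

Stages always execute in the fixed order qc → annotation → analysis →
pgdb → export regardless of parameter-file entry order.  A stage flagged
``skip`` reuses its prior on-disk outputs (error if absent); ``grid`` is
accepted and degrades to local execution with a logged notice.  The run
receipt is written last and only when every requested stage succeeded.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import annotate as ann_mod
from . import qc as qc_mod
from .annotate import Annotation, HitFilterThresholds
from .core_formats import (
    ParametersFile,
    STAGES,
    read_fasta,
    read_gff_orf_features,
    read_tabular_hits,
    write_fasta,
    write_gff_orf_features,
)
from .errors import PipelineError
from .orfcall import OrfCall, attach_translations, scan_orfs_six_frame
from .pathways import (
    export_pathway_tables,
    infer_pathways,
    read_pathway_catalog,
)
from .pgdb_export import (
    concatenate_contigs,
    write_feature_table,
    write_genbank,
    write_pathologic_input,
)
from .taxonomy import Taxonomy, assign_orf_taxonomy, write_fxn_taxa_table


@dataclass
class RunReceipt:
    """Record of a successful pipeline execution."""

    timestamp: str
    parameters: list[str]
    stage_status: dict[str, str]  # completed | skipped | failed
    manifest: list[str]  # paths relative to the output directory

    def write(self, dest: Path) -> None:
        with open(dest, "w", encoding="utf-8") as handle:
            handle.write(f"timestamp\t{self.timestamp}\n")
            handle.write("[parameters]\n")
            for line in self.parameters:
                handle.write(f"{line}\n")
            handle.write("[stages]\n")
            for stage, status in self.stage_status.items():
                handle.write(f"{stage}\t{status}\n")
            handle.write("[outputs]\n")
            for path in self.manifest:
                handle.write(f"{path}\n")


class PipelineRun:
    """State carried across stages of one sample's run."""

    def __init__(
        self,
        params: ParametersFile,
        input_fasta: str | Path,
        out_dir: str | Path,
        sample_name: str,
        orfs_gff: str | Path | None = None,
        hit_tables: Mapping[str, str | Path] | None = None,
        refscores: str | Path | None = None,
        taxonomy_tsv: str | Path | None = None,
        catalog_tsv: str | Path | None = None,
    ):
        self.params = params
        self.input_fasta = Path(input_fasta)
        self.out = Path(out_dir)
        self.sample = sample_name
        self.orfs_gff = Path(orfs_gff) if orfs_gff else None
        self.hit_tables = {db: Path(p) for db, p in (hit_tables or {}).items()}
        self.refscores_path = Path(refscores) if refscores else None
        self.taxonomy_tsv = Path(taxonomy_tsv) if taxonomy_tsv else None
        self.catalog_tsv = Path(catalog_tsv) if catalog_tsv else None

        self.contigs = []
        self.mapping = []
        self.orfs: list[OrfCall] = []
        self.annotations: dict[str, Annotation] = {}
        self.hits_by_db: dict[str, list] = {}
        self.status: dict[str, str] = {}
        self.manifest: list[str] = []
        self.log_lines: list[str] = []

    # -- plumbing ----------------------------------------------------------

    def _register(self, path: Path) -> Path:
        self.manifest.append(str(path.relative_to(self.out)))
        return path

    def _log(self, message: str) -> None:
        self.log_lines.append(message)

    def _require(self, stage: str, path: Path) -> Path:
        if not path.exists():
            raise PipelineError(
                f"stage {stage!r}: missing prerequisite file {path}"
            )
        return path

    # -- stage 1: QC + ORF prediction --------------------------------------

    def stage_qc(self, flag: str) -> None:
        pre = self.out / "preprocessed"
        orf_dir = self.out / "orf_prediction"
        fasta_out = pre / f"{self.sample}.fasta"
        mapping_out = pre / f"{self.sample}.mapping.txt"
        gff_out = orf_dir / f"{self.sample}.gff"
        if flag == "skip":
            for path in (fasta_out, mapping_out, gff_out):
                self._require("qc", path)
            self.contigs = read_fasta(fasta_out)
            self.mapping = qc_mod.read_mapping(mapping_out)
            self.orfs = read_gff_orf_features(gff_out)
            attach_translations(self.orfs, {c.seq_id: c for c in self.contigs})
            self._log(f"qc: skipped, reloaded {len(self.contigs)} contigs, {len(self.orfs)} ORFs")
            return
        records = read_fasta(self.input_fasta)
        kept, mapping, before, after = qc_mod.qc_nucleotides(
            records, self.sample, self.params.min_nucleotide_length
        )
        self.contigs, self.mapping = kept, mapping
        write_fasta(kept, self._register(fasta_out))
        qc_mod.write_mapping(mapping, self._register(mapping_out))
        qc_mod.write_stats(before, after, self._register(pre / f"{self.sample}.nuc.stats"))

        by_id = {c.seq_id: c for c in kept}
        orig_to_seq = {orig: seq for seq, orig in mapping}
        if self.orfs_gff is not None:
            orfs = read_gff_orf_features(self.orfs_gff)
            for orf in orfs:
                if orf.contig_id in orig_to_seq:
                    orf.contig_id = orig_to_seq[orf.contig_id]
            orfs = [o for o in orfs if o.contig_id in by_id]
            attach_translations(orfs, by_id)
        else:
            orfs = [
                orf
                for contig in kept
                for orf in scan_orfs_six_frame(contig, self.params.min_orf_aa)
            ]
        aa_before = qc_mod.LengthStats.of([len(o.translation) for o in orfs])
        qced = qc_mod.filter_orfs_by_length(orfs, self.params.min_orf_aa)
        aa_after = qc_mod.LengthStats.of([len(o.translation) for o in qced])
        self.orfs = qced

        write_gff_orf_features(qced, self._register(gff_out))
        from .core_formats import SequenceRecord

        write_fasta(
            [SequenceRecord(o.orf_id, by_id[o.contig_id].residues[o.start : o.end]) for o in qced],
            self._register(orf_dir / f"{self.sample}.fna"),
        )
        write_fasta(
            [SequenceRecord(o.orf_id, o.translation, moltype="protein") for o in orfs],
            self._register(orf_dir / f"{self.sample}.faa"),
        )
        write_fasta(
            [SequenceRecord(o.orf_id, o.translation, moltype="protein") for o in qced],
            self._register(orf_dir / f"{self.sample}.qced.faa"),
        )
        qc_mod.write_stats(
            aa_before, aa_after, self._register(orf_dir / f"{self.sample}.amino.stats")
        )
        self._log(
            f"qc: {before.count} sequences in, {after.count} kept; "
            f"{len(orfs)} ORFs called, {len(qced)} after length filter"
        )

    # -- stage 2: annotation ----------------------------------------------

    def stage_annotation(self, flag: str) -> None:
        ann_dir = self.out / "annotation"
        gff_out = ann_dir / f"{self.sample}.annotated.gff"
        if flag == "skip":
            self._require("annotation", gff_out)
            self.annotations = _reload_annotations(gff_out)
            self._log(f"annotation: skipped, reloaded {len(self.annotations)} annotations")
            return
        if self.refscores_path is not None:
            self_scores = ann_mod.read_refscores(self.refscores_path)
        else:
            self_scores = {
                o.orf_id: ann_mod.self_bit_score(o.translation)
                for o in self.orfs
                if o.translation
            }
        ann_mod.write_refscores(
            self_scores, self._register(ann_dir / f"{self.sample}.refscores")
        )
        thresholds = HitFilterThresholds(
            max_evalue=self.params.max_evalue,
            min_bsr=self.params.min_bsr,
            min_aln_length=self.params.min_aln_length,
        )
        self.hits_by_db = {}
        for db, path in self.hit_tables.items():
            hits = read_tabular_hits(self._require("annotation", path), db)
            hits = [h for h in hits if h.query_id in self_scores]
            rows = ann_mod.filter_hits(hits, self_scores, thresholds)
            self.hits_by_db[db] = rows
            ann_mod.write_parsed_hits(
                rows, self._register(ann_dir / f"{self.sample}.{db}.blastout.parsed.txt")
            )
        priority = self.params.db_priority or tuple(self.hit_tables)
        anns = ann_mod.annotate_orfs(
            [o.orf_id for o in self.orfs], self.hits_by_db, priority
        )
        self.annotations = {a.orf_id: a for a in anns}
        write_gff_orf_features(
            self.orfs, self._register(gff_out), ann_mod.annotated_gff_attrs(anns)
        )
        n_hyp = sum(1 for a in anns if a.best_hit is None)
        self._log(
            f"annotation: {len(anns)} ORFs annotated over {len(self.hits_by_db)} "
            f"databases, {n_hyp} hypothetical"
        )

    # -- stage 3: analysis (taxonomic binning) -----------------------------

    def stage_analysis(self, flag: str) -> None:
        if self.taxonomy_tsv is None:
            self.status["analysis"] = "skipped"
            self._log("analysis: no taxonomy table supplied, nothing to do")
            return
        tax_dir = self.out / "results" / "taxonomy"
        table_out = tax_dir / "fxn_and_taxa_table.txt"
        if flag == "skip":
            self._require("analysis", table_out)
            self._log("analysis: skipped, prior output present")
            return
        taxonomy = Taxonomy.from_tsv(self.taxonomy_tsv)
        db = next(
            (d for d in self.hits_by_db if "refseq" in d.lower()),
            next(iter(self.hits_by_db), None),
        )
        rows_by_orf: dict[str, list] = {}
        for row in self.hits_by_db.get(db, []):
            rows_by_orf.setdefault(row.query_id, []).append(row)
        assignments = [
            assign_orf_taxonomy(
                o.orf_id,
                rows_by_orf.get(o.orf_id, []),
                taxonomy,
                top_bits_fraction=self.params.lca_top_fraction,
                min_hits=self.params.lca_min_hits,
            )
            for o in self.orfs
        ]
        write_fxn_taxa_table(
            assignments, self.annotations, taxonomy, self._register(table_out)
        )
        assigned = sum(1 for a in assignments if a.tax_id is not None)
        self._log(f"analysis: {assigned}/{len(assignments)} ORFs taxonomically binned")

    # -- stage 4: PGDB input construction ----------------------------------

    def stage_pgdb(self, flag: str) -> None:
        ptools = self.out / "ptools"
        if flag == "skip":
            self._require("pgdb", ptools / f"{self.sample}.pf")
            self._log("pgdb: skipped, prior output present")
            return
        if not self.contigs:
            raise PipelineError("stage 'pgdb': no QC-passed contigs available")
        composite = concatenate_contigs(self.contigs)
        paths = write_pathologic_input(
            composite, self.orfs, self.annotations, self.sample, ptools
        )
        for path in paths.values():
            self._register(path)
        orfs_by_contig: dict[str, list[OrfCall]] = {}
        for orf in self.orfs:
            orfs_by_contig.setdefault(orf.contig_id, []).append(orf)
        write_genbank(
            self.contigs,
            orfs_by_contig,
            self.annotations,
            self._register(self.out / "genbank" / f"{self.sample}.gbk"),
        )
        write_feature_table(
            self.orfs,
            self.annotations,
            None,
            self._register(self.out / "genbank" / f"{self.sample}.features.tsv"),
        )
        self._log(
            f"pgdb: composite of {len(composite)} nt from {len(self.contigs)} contigs, "
            f"{len(self.orfs)} ORF records"
        )

    # -- stage 5: pathway export -------------------------------------------

    def stage_export(self, flag: str) -> None:
        if self.catalog_tsv is None:
            self.status["export"] = "skipped"
            self._log("export: no pathway catalog supplied, nothing to do")
            return
        pwy_dir = self.out / "results" / "pathways"
        pathways_out = pwy_dir / f"{self.sample}.pathways.txt"
        if flag == "skip":
            self._require("export", pathways_out)
            self._log("export: skipped, prior output present")
            return
        catalog = read_pathway_catalog(self.catalog_tsv)
        predictions = infer_pathways(
            self.annotations.values(), catalog, tau=self.params.pathway_tau
        )
        export_pathway_tables(
            predictions,
            catalog,
            self._register(pathways_out),
            self._register(pwy_dir / "pathway_rxns.txt"),
        )
        n_pred = sum(1 for p in predictions if p.predicted)
        self._log(f"export: {n_pred}/{len(predictions)} pathways predicted")

    # -- driver ------------------------------------------------------------

    def run(self) -> RunReceipt:
        self.out.mkdir(parents=True, exist_ok=True)
        handlers = {
            "qc": self.stage_qc,
            "annotation": self.stage_annotation,
            "analysis": self.stage_analysis,
            "pgdb": self.stage_pgdb,
            "export": self.stage_export,
        }
        for stage in STAGES:
            flag = self.params.stages.get(stage, "yes")
            if flag == "grid":
                self._log(f"{stage}: 'grid' requested; executing locally instead")
                flag = "yes"
            try:
                handlers[stage](flag)
            except Exception:
                self.status[stage] = "failed"
                self._write_log()
                raise
            self.status.setdefault(
                stage, "skipped" if flag == "skip" else "completed"
            )
        receipt = RunReceipt(
            timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
            parameters=self.params.snapshot_lines(),
            stage_status=dict(self.status),
            manifest=sorted(self.manifest),
        )
        receipt_path = self.out / f"{self.sample}.run_parameters.txt"
        receipt.manifest = sorted(self.manifest + [receipt_path.name])
        receipt.write(receipt_path)
        self._write_log()
        return receipt

    def _write_log(self) -> None:
        with open(self.out / "run.log", "w", encoding="utf-8") as handle:
            for line in self.log_lines:
                handle.write(line + "\n")


def _reload_annotations(gff_path: Path) -> dict[str, Annotation]:
    """Rebuild annotations from a previously written annotated GFF."""
    import re

    annotations: dict[str, Annotation] = {}
    with open(gff_path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            attr_text = line.rstrip("\n").split("\t")[8]
            attrs = dict(
                part.split("=", 1) for part in attr_text.split(";") if "=" in part
            )
            orf_id = attrs["ID"]
            annotations[orf_id] = Annotation(
                orf_id=orf_id,
                product=attrs.get("product", "hypothetical protein"),
                ec_numbers=frozenset(
                    e for e in attrs.get("ec", "").split(",") if e
                ),
                source_db=attrs.get("db", ""),
            )
    return annotations


def run_pipeline(
    params: ParametersFile,
    input_fasta: str | Path,
    out_dir: str | Path,
    sample_name: str,
    **inputs,
) -> RunReceipt:
    """Convenience wrapper: construct a :class:`PipelineRun` and run it."""
    return PipelineRun(params, input_fasta, out_dir, sample_name, **inputs).run()
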