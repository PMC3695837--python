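"""Shotgun-read simulation and the synthetic-community fixture generator.

``simulate_shotgun`` draws reads with normally distributed lengths
(default mean 700 bp, sd 100 bp) from a weighted genome mixture until a
target fraction of the community's total unique sequence length has been
sampled.  ``make_synthetic_community`` builds a fully self-consistent
test world: genomes with planted ORFs whose products carry EC numbers
from a generated pathway catalog, a reference "database" table, a toy
taxonomy, per-genome gold pathway sets, and a homology-hit emulator that
replaces an actual sequence search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotate import HitFilterThresholds, annotate_orfs, filter_hits
from .core_formats import HomologyHit, SequenceRecord, write_fasta, write_tabular_hits
from .errors import EnvPathError
from .orfcall import STOP_CODONS, reverse_complement
from .pathways import (
    ConfusionTable,
    PathwayDefinition,
    PerfStats,
    confusion,
    infer_pathways,
    pathway_recovery,
    perf_stats,
    predicted_set,
    write_pathway_catalog,
)
from .taxonomy import Taxonomy, TaxonomyNode

MIN_READ_LENGTH = 100


@dataclass
class ShotgunSimConfig:
    """Settings of one simulated sequencing experiment."""

    coverage_fraction: float = 1.0  # Gm: fraction of total unique length sampled
    mean_length: float = 700.0
    sd_length: float = 100.0
    abundance_weights: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.coverage_fraction <= 1:
            raise EnvPathError("coverage_fraction must be in (0, 1]")
        if self.abundance_weights is not None and any(
            w <= 0 for w in self.abundance_weights
        ):
            raise EnvPathError("abundance weights must be positive")


@dataclass
class ReadTruth:
    read_id: str
    genome_id: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str


def simulate_shotgun(
    genomes: Sequence[SequenceRecord],
    config: ShotgunSimConfig,
    n_reads: int | None = None,
) -> tuple[list[SequenceRecord], list[ReadTruth]]:
    """Draw shotgun reads from a weighted genome mixture.

    Genomes are chosen proportionally to weight x length; starts are
    uniform; lengths are Normal(mean, sd) truncated to [100, genome
    length]; strands are uniform.  Sampling stops once total bases reach
    ``coverage_fraction`` x total genome length (or after ``n_reads``
    reads when given).  Fully reproducible from the seed.
    """
    if not genomes:
        raise EnvPathError("no genomes to sample from")
    for g in genomes:
        if len(g) < MIN_READ_LENGTH:
            raise EnvPathError(
                f"genome {g.seq_id!r} shorter than {MIN_READ_LENGTH} bp"
            )
    rng = np.random.default_rng(config.seed)
    weights = (
        np.asarray(config.abundance_weights, dtype=float)
        if config.abundance_weights is not None
        else np.ones(len(genomes))
    )
    if len(weights) != len(genomes):
        raise EnvPathError("one abundance weight per genome required")
    lengths = np.array([len(g) for g in genomes], dtype=float)
    probs = weights * lengths
    probs /= probs.sum()
    budget = config.coverage_fraction * lengths.sum()

    reads: list[SequenceRecord] = []
    truth: list[ReadTruth] = []
    sampled = 0
    while (sampled < budget) if n_reads is None else (len(reads) < n_reads):
        gi = int(rng.choice(len(genomes), p=probs))
        genome = genomes[gi]
        read_len = int(round(rng.normal(config.mean_length, config.sd_length)))
        read_len = max(MIN_READ_LENGTH, min(read_len, len(genome)))
        start = int(rng.integers(0, len(genome) - read_len + 1))
        end = start + read_len
        strand = "+" if rng.random() < 0.5 else "-"
        fragment = genome.residues[start:end]
        if strand == "-":
            fragment = reverse_complement(fragment)
        read_id = f"read_{len(reads)}"
        reads.append(SequenceRecord(read_id, fragment))
        truth.append(ReadTruth(read_id, genome.seq_id, start, end, strand))
        sampled += read_len
    return reads, truth


def write_truth_table(truth: Sequence[ReadTruth], dest) -> None:
    from .core_formats import _open_out

    handle, close = _open_out(dest)
    try:
        handle.write("#read_id\tgenome_id\tstart\tend\tstrand\n")
        for t in truth:
            handle.write(f"{t.read_id}\t{t.genome_id}\t{t.start}\t{t.end}\t{t.strand}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# synthetic community
# ---------------------------------------------------------------------------

_ENZYME_WORDS = (
    "dehydrogenase", "kinase", "synthase", "reductase", "hydrolase",
    "transferase", "isomerase", "ligase", "oxidase", "carboxylase",
    "phosphatase", "mutase", "aldolase", "epimerase", "decarboxylase",
    "aminotransferase", "hydratase", "cyclase", "esterase", "peptidase",
)
_SUBSTRATE_WORDS = (
    "glycerol", "malate", "citrate", "pyruvate", "succinate", "fumarate",
    "glucose", "xylose", "arabinose", "acetate", "lactate", "glutamate",
    "aspartate", "serine", "alanine", "choline", "butyrate", "propionate",
    "methanol", "formate", "sulfate", "nitrate", "urea", "chitin",
)

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)


@dataclass
class PlantedOrf:
    """Ground-truth coordinates of an ORF planted in a synthetic genome."""

    orf_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    ec: str
    subject_id: str
    product: str


@dataclass
class SyntheticCommunity:
    """Genomes, reference tables and gold standards for pipeline testing."""

    catalog: list[PathwayDefinition]
    genomes: list[SequenceRecord]
    planted: dict[str, list[PlantedOrf]]  # genome_id -> ORFs
    reference: dict[str, tuple[str, str]]  # subject_id -> (product, taxon)
    taxonomy: Taxonomy
    gold: dict[str, frozenset[str]]  # genome_id -> fully planted pathways

    @property
    def community_gold(self) -> frozenset[str]:
        out: set[str] = set()
        for pwys in self.gold.values():
            out |= pwys
        return frozenset(out)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(p.pathway_id for p in self.catalog)

    # -- homology-hit emulation -------------------------------------------

    def emulate_hits(
        self,
        truth: Sequence[ReadTruth],
        noise: float = 0.0,
        seed: int = 0,
        min_overlap_fraction: float = 0.5,
    ) -> tuple[list[HomologyHit], dict[str, float]]:
        """Produce tabular hits for planted ORFs overlapped by each read.

        Stands in for a homology search: a read covering at least
        ``min_overlap_fraction`` of a planted ORF yields one hit whose
        query is the read-local ORF fragment.  The query's self bit score
        is 2 bits/nt of overlap; the hit's bit score is scaled by the
        covered fraction, so BSR equals overlap/ORF-length.  E-values
        decay exponentially with overlap.  ``noise`` adds spurious
        hits (wrong subject, uniform random BSR) per read with that
        probability.  Returns (hits, self-score table).
        """
        rng = np.random.default_rng(seed)
        subjects = sorted(self.reference)
        hits: list[HomologyHit] = []
        refscores: dict[str, float] = {}
        for t in truth:
            k = 0
            for orf in self.planted.get(t.genome_id, ()):
                overlap = min(t.end, orf.end) - max(t.start, orf.start)
                orf_len = orf.end - orf.start
                if overlap < min_overlap_fraction * orf_len:
                    continue
                query_id = f"{t.read_id}_orf{k}"
                k += 1
                self_bits = 2.0 * overlap
                bit_score = self_bits * (overlap / orf_len)
                evalue = max(10.0 ** (-overlap / 20.0), 1e-180)
                product, taxon = self.reference[orf.subject_id]
                refscores[query_id] = self_bits
                hits.append(
                    HomologyHit(
                        query_id=query_id,
                        subject_id=orf.subject_id,
                        pct_identity=100.0,
                        aln_length=max(overlap // 3, 1),
                        mismatches=0,
                        gap_opens=0,
                        q_start=1,
                        q_end=max(overlap // 3, 1),
                        s_start=1,
                        s_end=max(overlap // 3, 1),
                        evalue=evalue,
                        bit_score=bit_score,
                        subject_description=f"{product} [{taxon}]",
                        source_db="refdb",
                    )
                )
            if noise > 0 and rng.random() < noise:
                query_id = f"{t.read_id}_noise"
                subject = subjects[int(rng.integers(0, len(subjects)))]
                product, taxon = self.reference[subject]
                self_bits = 2.0 * (t.end - t.start)
                ratio = float(rng.uniform(0.05, 0.95))
                refscores[query_id] = self_bits
                hits.append(
                    HomologyHit(
                        query_id=query_id,
                        subject_id=subject,
                        pct_identity=float(rng.uniform(30, 70)),
                        aln_length=50,
                        mismatches=25,
                        gap_opens=5,
                        q_start=1,
                        q_end=50,
                        s_start=1,
                        s_end=50,
                        evalue=float(10.0 ** -rng.uniform(6, 30)),
                        bit_score=self_bits * ratio,
                        subject_description=f"{product} [{taxon}]",
                        source_db="refdb",
                    )
                )
        return hits, refscores

    def full_coverage_truth(self) -> list[ReadTruth]:
        """One pseudo-read spanning each full genome (closure fixture)."""
        return [
            ReadTruth(f"full_{g.seq_id}", g.seq_id, 0, len(g), "+")
            for g in self.genomes
        ]

    # -- fixture dump ------------------------------------------------------

    def write_fixture(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genomes": out / "genomes.fasta",
            "catalog": out / "pathway_catalog.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "reference": out / "reference_db.tsv",
            "gold": out / "gold_pathways.tsv",
            "orfs": out / "planted_orfs.gff",
        }
        write_fasta(self.genomes, paths["genomes"])
        write_pathway_catalog(self.catalog, paths["catalog"])
        self.taxonomy.to_tsv(paths["taxonomy"])
        with open(paths["reference"], "w", encoding="utf-8") as handle:
            for subject, (product, taxon) in sorted(self.reference.items()):
                handle.write(f"{subject}\t{product}\t{taxon}\n")
        with open(paths["gold"], "w", encoding="utf-8") as handle:
            for genome_id, pwys in self.gold.items():
                handle.write(f"{genome_id}\t{';'.join(sorted(pwys))}\n")
        from .core_formats import write_gff_orf_features
        from .orfcall import OrfCall

        calls = [
            OrfCall(o.orf_id, o.genome_id, o.start, o.end, o.strand, translation="M")
            for orfs in self.planted.values()
            for o in orfs
        ]
        write_gff_orf_features(calls, paths["orfs"])
        return paths


def _random_coding_block(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    body = "".join(_SENSE_CODONS[i] for i in codons)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    return "ATG" + body + stop


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_synthetic_community(
    n_genomes: int = 10,
    n_pathways: int = 40,
    seed: int = 0,
    core_pathways: int = 8,
    accessory_per_genome: int = 3,
    first_genome_accessory: int = 0,
    reactions_per_pathway: tuple[int, int] = (3, 6),
    orf_codons: tuple[int, int] = (90, 180),
) -> SyntheticCommunity:
    """Generate a closed synthetic community fixture.

    Every reaction EC is unique to its pathway, so with a noise-free hit
    emulator a pathway can only be covered through genuinely planted
    ORFs.  Each genome plants all reactions of the shared core pathways
    plus ``accessory_per_genome`` pathways of its own; its gold standard
    is exactly that pathway set.  The core/accessory split gives the
    community the collector's-curve structure of real metagenomes (core
    metabolism accumulates first).  The first genome — the designated
    overrepresentation target of skewed abundance profiles — carries
    ``first_genome_accessory`` accessory pathways (default none), so
    oversampling it mostly resamples community-wide core content.
    """
    if n_genomes < 2 or n_pathways < 2:
        raise EnvPathError("need at least 2 genomes and 2 pathways")
    if core_pathways + accessory_per_genome > n_pathways:
        raise EnvPathError("catalog too small for requested core/accessory split")
    rng = np.random.default_rng(seed)

    # pathway catalog with globally unique ECs
    catalog: list[PathwayDefinition] = []
    ec_counter = 0
    for p in range(n_pathways):
        n_rxn = int(rng.integers(reactions_per_pathway[0], reactions_per_pathway[1] + 1))
        ecs = []
        for _ in range(n_rxn):
            ec_counter += 1
            ecs.append(
                f"{ec_counter % 6 + 1}.{ec_counter % 20 + 1}.{ec_counter % 30 + 1}.{ec_counter}"
            )
        name = (
            f"{_SUBSTRATE_WORDS[p % len(_SUBSTRATE_WORDS)]} "
            f"{'degradation' if p % 2 else 'biosynthesis'} {p}"
        )
        catalog.append(
            PathwayDefinition(f"PWY{p:04d}", name, frozenset(ecs), frozenset({ecs[0]}))
        )

    # toy taxonomy: root / 2 phyla / one genus+species per genome
    nodes = [TaxonomyNode(1, 1, "root", "root")]
    nodes.append(TaxonomyNode(2, 1, "phylum", "Alphamicrobiota"))
    nodes.append(TaxonomyNode(3, 1, "phylum", "Betamicrobiota"))
    species_of_genome: dict[str, str] = {}
    next_id = 10
    for g in range(n_genomes):
        phylum = 2 if g % 2 == 0 else 3
        genus_id, species_id = next_id, next_id + 1
        next_id += 2
        genus = f"Simulibacter{g}"
        species = f"Simulibacter{g} communis"
        nodes.append(TaxonomyNode(genus_id, phylum, "genus", genus))
        nodes.append(
            TaxonomyNode(
                species_id, genus_id, "species", species,
                frozenset({f"{genus} sp. strain{g}"}),
            )
        )
        species_of_genome[f"genome_{g:02d}"] = species
    taxonomy = Taxonomy(nodes)

    # genomes with planted ORFs
    genomes: list[SequenceRecord] = []
    planted: dict[str, list[PlantedOrf]] = {}
    reference: dict[str, tuple[str, str]] = {}
    gold: dict[str, frozenset[str]] = {}
    core_idx = list(range(core_pathways))
    accessory_pool = list(range(core_pathways, n_pathways))
    for g in range(n_genomes):
        genome_id = f"genome_{g:02d}"
        n_acc = first_genome_accessory if g == 0 else accessory_per_genome
        accessory = rng.choice(accessory_pool, size=n_acc, replace=False)
        chosen = core_idx + [int(i) for i in accessory]
        gold[genome_id] = frozenset(catalog[int(i)].pathway_id for i in chosen)
        parts: list[str] = [_random_spacer(rng, int(rng.integers(100, 300)))]
        cursor = len(parts[0])
        orfs: list[PlantedOrf] = []
        for pi in chosen:
            pwy = catalog[int(pi)]
            for ec in sorted(pwy.reactions):
                n_codons = int(rng.integers(orf_codons[0], orf_codons[1] + 1))
                block = _random_coding_block(rng, n_codons)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    block = reverse_complement(block)
                orf_id = f"{genome_id}_orf{len(orfs)}"
                subject_id = f"ref|{orf_id}"
                word1 = _SUBSTRATE_WORDS[int(rng.integers(0, len(_SUBSTRATE_WORDS)))]
                word2 = _ENZYME_WORDS[int(rng.integers(0, len(_ENZYME_WORDS)))]
                product = f"{word1} {word2} (EC {ec})"
                orfs.append(
                    PlantedOrf(
                        orf_id=orf_id,
                        genome_id=genome_id,
                        start=cursor,
                        end=cursor + len(block),
                        strand=strand,
                        ec=ec,
                        subject_id=subject_id,
                        product=product,
                    )
                )
                reference[subject_id] = (product, species_of_genome[genome_id])
                parts.append(block)
                cursor += len(block)
                spacer = _random_spacer(rng, int(rng.integers(50, 200)))
                parts.append(spacer)
                cursor += len(spacer)
        genomes.append(SequenceRecord(genome_id, "".join(parts)))
        planted[genome_id] = orfs

    # pad the overrepresentation target with non-coding sequence to just
    # above the community mean, so oversampling it resamples redundant
    # content rather than concentrating on a gene-dense replicon
    mean_len = sum(len(g) for g in genomes[1:]) / (n_genomes - 1)
    target = int(1.15 * mean_len)
    if len(genomes[0]) < target:
        genomes[0].residues += _random_spacer(rng, target - len(genomes[0]))

    return SyntheticCommunity(
        catalog=catalog,
        genomes=genomes,
        planted=planted,
        reference=reference,
        taxonomy=taxonomy,
        gold=gold,
    )


# ---------------------------------------------------------------------------
# coverage-experiment harness
# ---------------------------------------------------------------------------

@dataclass
class CoverageResult:
    """Scores of one simulated sequencing experiment."""

    coverage_fraction: float
    n_reads: int
    table: ConfusionTable
    stats: PerfStats
    recovery: float  # percent of community gold pathways recovered


def run_coverage_experiment(
    community: SyntheticCommunity,
    coverage_fraction: float,
    seed: int = 0,
    abundance_weights: Sequence[float] | None = None,
    noise: float = 0.0,
    tau: float = 0.5,
    thresholds: HitFilterThresholds | None = None,
) -> CoverageResult:
    """Simulate reads, emulate hits, annotate, infer pathways and score.

    The gold standard is the union of the per-genome gold pathway sets;
    the universe is the whole catalog.
    """
    config = ShotgunSimConfig(
        coverage_fraction=coverage_fraction,
        abundance_weights=abundance_weights,
        seed=seed,
    )
    _reads, truth = simulate_shotgun(community.genomes, config)
    hits, refscores = community.emulate_hits(truth, noise=noise, seed=seed)
    rows = filter_hits(hits, refscores, thresholds or HitFilterThresholds())
    query_ids = sorted({r.query_id for r in rows})
    annotations = annotate_orfs(query_ids, {"refdb": rows}, ("refdb",))
    predictions = infer_pathways(annotations, community.catalog, tau=tau)
    pred = predicted_set(predictions)
    table = confusion(pred, community.community_gold, community.universe)
    return CoverageResult(
        coverage_fraction=coverage_fraction,
        n_reads=len(truth),
        table=table,
        stats=perf_stats(table),
        recovery=pathway_recovery(pred, community.community_gold),
    )
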