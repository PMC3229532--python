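"""Synthetic study corpora with known ground truth.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for -- annotated plant genomes with duplicate genes of
six mechanistic origins, syntenic anchor lists, protein homology tables,
expression matrices with controlled pair correlation, coding/promoter
sequences with controlled divergence, methylation probe tracks, gene-family
memberships with planted origin biases, and a two-species ortholog panel --
so every downstream module can be exercised end-to-end against planted
truth.  It is deliberately not a molecular-evolution simulator: no indels,
no rate heterogeneity, no transposon sequence models.

Planted events are mutually non-interfering by default (each gene joins one
event), so classifier recovery is exact; ``interference=True`` additionally
plants tandem partners next to WGD anchor genes to exercise the
origin-priority rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_analyses import MethylationTrack, TermAnnotation
from .cross_species_ec import OrthologFrame
from .dup_classifier import DuplicationMode, MODE_PRIORITY
from .expression import ExpressionMatrix
from .genome_io import (
    AnchorCollection,
    Gene,
    GenomeAnnotation,
    HomologyHit,
    write_anchors,
    write_blast_tab,
    write_fasta,
    write_gff,
)
from .seq_divergence import CODON_TO_AA, STOP_CODONS

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "PlantedPair",
    "GroundTruth",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_expression",
    "simulate_sequences",
    "simulate_methylation",
    "simulate_families",
    "simulate_two_species",
]

_MODES = (
    DuplicationMode.WGD,
    DuplicationMode.TANDEM,
    DuplicationMode.PROXIMAL,
    DuplicationMode.RETROTRANSPOSED,
    DuplicationMode.DNA_TRANSPOSED,
    DuplicationMode.DISPERSED,
)

_PRIORITY_RANK = {m: i for i, m in enumerate(MODE_PRIORITY)}

_SENSE_CODONS = tuple(sorted(CODON_TO_AA))
_NUCS = "ACGT"
#: first-two-base prefixes whose four third-position codons share an amino acid
_FOURFOLD_PREFIXES = frozenset(
    p
    for p in {c[:2] for c in _SENSE_CODONS}
    if len({CODON_TO_AA.get(p + n) for n in _NUCS}) == 1
    and all(p + n in CODON_TO_AA for n in _NUCS)
)

_GENE_SPACING = 1_000  # bp between gene starts on a chromosome
_GENE_LENGTH = 600


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic corpus.

    Defaults give 2 chromosomes x 500 genes, 50 planted events per mode, a
    200-sample expression matrix, per-mode expression correlations and
    mutation pressures following the qualitative ordering reported for real
    duplicate populations (tandem/WGD most conserved, transposed and
    dispersed least), a promoter methylation rate of 0.2, and a two-species
    panel of 200 orthologs per class.
    """

    seed: int = 0
    n_chromosomes: int = 2
    genes_per_chromosome: int = 500
    events_per_mode: int = 50
    wgd_block_size: int = 5
    wgd_events: tuple[str, ...] = ("alpha", "beta", "gamma")
    proximal_window: int = 20
    interference: bool = False
    n_interference: int = 10
    n_decoy_hits: int = 50
    # expression
    n_samples: int = 200
    mode_target_r: Mapping[DuplicationMode, float] = field(
        default_factory=lambda: {
            DuplicationMode.WGD: 0.45,
            DuplicationMode.TANDEM: 0.50,
            DuplicationMode.PROXIMAL: 0.35,
            DuplicationMode.DNA_TRANSPOSED: 0.15,
            DuplicationMode.RETROTRANSPOSED: 0.12,
            DuplicationMode.DISPERSED: 0.20,
        }
    )
    # sequences
    n_codons: int = 200
    promoter_length: int = 1000
    promoter_p: float = 0.10
    mode_p_syn: Mapping[DuplicationMode, float] = field(
        default_factory=lambda: {
            DuplicationMode.TANDEM: 0.10,
            DuplicationMode.PROXIMAL: 0.15,
            DuplicationMode.WGD: 0.20,
            DuplicationMode.DNA_TRANSPOSED: 0.30,
            DuplicationMode.RETROTRANSPOSED: 0.30,
            DuplicationMode.DISPERSED: 0.35,
        }
    )
    mode_p_nonsyn: Mapping[DuplicationMode, float] = field(
        default_factory=lambda: {
            DuplicationMode.TANDEM: 0.03,
            DuplicationMode.PROXIMAL: 0.04,
            DuplicationMode.WGD: 0.04,
            DuplicationMode.DNA_TRANSPOSED: 0.08,
            DuplicationMode.RETROTRANSPOSED: 0.10,
            DuplicationMode.DISPERSED: 0.08,
        }
    )
    # methylation
    probe_spacing: int = 150
    methylation_rate: float = 0.20
    # families
    n_families: int = 12
    family_size_min: int = 10
    family_size_max: int = 30
    family_bias: float = 0.8
    # two-species ortholog panel
    n_orthologs_per_class: int = 200
    ortholog_samples: int = 100
    n_factors: int = 8
    factor_noise_sd: float = 0.5
    class_sigma: Mapping[str, float] = field(
        default_factory=lambda: {"S-S": 1.0, "S-D": 2.0, "D-D": 4.0}
    )

    def __post_init__(self):
        if self.events_per_mode < 0:
            raise ValueError("events_per_mode must be >= 0")
        for r in self.mode_target_r.values():
            if not -1.0 <= r <= 1.0:
                raise ValueError("target r must lie in [-1, 1]")
        for p in list(self.mode_p_syn.values()) + list(self.mode_p_nonsyn.values()) + [
            self.promoter_p
        ]:
            if not 0.0 <= p <= 0.74:
                raise ValueError("target p-distances must lie in [0, 0.74]")
        if self.events_per_mode > 0 and self.n_chromosomes < 2:
            raise ValueError("planting events needs >= 2 chromosomes")


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str
    gene_b: str
    mode: DuplicationMode
    parental_copy: str | None = None
    event: str | None = None

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class GroundTruth:
    pairs: list[PlantedPair]
    origins: dict[str, DuplicationMode]
    singletons: set[str]
    families: dict[str, DuplicationMode | None] = field(default_factory=dict)

    def pairs_of_mode(self, mode: DuplicationMode) -> list[PlantedPair]:
        return [p for p in self.pairs if p.mode == mode]

    def to_json(self, path) -> None:
        payload = {
            "pairs": [
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "mode": p.mode.value,
                    "parental_copy": p.parental_copy,
                    "event": p.event,
                }
                for p in self.pairs
            ],
            "origins": {g: m.value for g, m in sorted(self.origins.items())},
            "singletons": sorted(self.singletons),
            "families": {
                f: (m.value if m is not None else None)
                for f, m in sorted(self.families.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _origins_from_pairs(pairs: Iterable[PlantedPair]) -> dict[str, DuplicationMode]:
    origins: dict[str, DuplicationMode] = {}
    for p in pairs:
        for g in p.genes:
            prev = origins.get(g)
            if prev is None or _PRIORITY_RANK[p.mode] < _PRIORITY_RANK[prev]:
                origins[g] = p.mode
    return origins


@dataclass
class SimulatedGenome:
    annotation: GenomeAnnotation
    anchors: AnchorCollection
    hits: list[HomologyHit]
    truth: GroundTruth
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        """Emit GFF3 + anchor TSVs + BLAST TSV + ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff": outdir / "genome.gff3",
            "anchors": outdir / "anchors.tsv",
            "ortholog_anchors": outdir / "ortholog_anchors.tsv",
            "blast": outdir / "blast.tsv",
            "truth": outdir / "ground_truth.json",
        }
        write_gff(self.annotation, paths["gff"])
        write_anchors(self.anchors, paths["anchors"], paths["ortholog_anchors"])
        write_blast_tab(self.hits, paths["blast"])
        self.truth.to_json(paths["truth"])
        return paths


class _Allocator:
    """Claims free (chromosome, rank) slots for planted genes."""

    def __init__(self, n_chrom: int, per_chrom: int, rng: np.random.Generator):
        self.free = [np.ones(per_chrom, dtype=bool) for _ in range(n_chrom)]
        self.per_chrom = per_chrom
        self.rng = rng

    def claim_run(self, chrom: int, length: int, max_tries: int = 5000) -> int:
        free = self.free[chrom]
        for _ in range(max_tries):
            start = int(self.rng.integers(0, self.per_chrom - length + 1))
            if free[start:start + length].all():
                free[start:start + length] = False
                return start
        raise RuntimeError("more planted genes than available loci")

    def claim_pair_at_distance(self, chrom: int, dist: int, max_tries: int = 5000) -> tuple[int, int]:
        free = self.free[chrom]
        for _ in range(max_tries):
            start = int(self.rng.integers(0, self.per_chrom - dist))
            if free[start] and free[start + dist]:
                free[start] = free[start + dist] = False
                return start, start + dist
        raise RuntimeError("more planted genes than available loci")

    def claim_single(self, chrom: int, max_tries: int = 5000) -> int:
        free = self.free[chrom]
        for _ in range(max_tries):
            r = int(self.rng.integers(0, self.per_chrom))
            if free[r]:
                free[r] = False
                return r
        raise RuntimeError("more planted genes than available loci")

    def try_claim(self, chrom: int, rank: int) -> bool:
        if 0 <= rank < self.per_chrom and self.free[chrom][rank]:
            self.free[chrom][rank] = False
            return True
        return False


def _gene_id(chrom: int, rank: int) -> str:
    return f"G{chrom + 1:02d}_{rank:04d}"


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Annotated genome with planted duplication events of every mode.

    WGD events emit collinear anchor blocks across two chromosomes; tandem
    copies sit at adjacent ranks; proximal at rank distance uniform in
    [2, window]; retro/DNA-transposed parents are made ancestral through
    cross-species ortholog anchors, their copies landing on another
    chromosome (retro copies intronless); dispersed pairs link non-ancestral
    loci on different chromosomes.  Every planted pair emits qualifying
    homology hits in both directions; decoy hits above the e-value threshold
    are sprinkled between random genes.
    """
    rng = np.random.default_rng([config.seed, 1])
    nc, gpc = config.n_chromosomes, config.genes_per_chromosome
    alloc = _Allocator(nc, gpc, rng)
    exon_counts: dict[tuple[int, int], int] = {}
    pairs: list[PlantedPair] = []
    anchors = AnchorCollection()
    n = config.events_per_mode

    def place(chrom: int, rank: int, exons: int) -> str:
        exon_counts[(chrom, rank)] = exons
        return _gene_id(chrom, rank)

    # --- WGD: collinear blocks across chromosome pairs -------------------
    n_blocks = -(-n // config.wgd_block_size) if n else 0
    planted_wgd = 0
    wgd_gene_slots: list[tuple[int, int]] = []
    for b in range(n_blocks):
        block_len = min(config.wgd_block_size, n - planted_wgd)
        c0, c1 = (2 * b) % nc, (2 * b + 1) % nc
        if c0 == c1:
            c1 = (c0 + 1) % nc
        r0 = alloc.claim_run(c0, block_len)
        r1 = alloc.claim_run(c1, block_len)
        event = config.wgd_events[b % len(config.wgd_events)]
        for i in range(block_len):
            ga = place(c0, r0 + i, int(rng.integers(1, 9)))
            gb = place(c1, r1 + i, int(rng.integers(1, 9)))
            anchors.add_pair(ga, gb, f"blk{b:03d}", event)
            key = tuple(sorted((ga, gb)))
            pairs.append(PlantedPair(key[0], key[1], DuplicationMode.WGD, event=event))
            wgd_gene_slots.extend([(c0, r0 + i), (c1, r1 + i)])
        planted_wgd += block_len

    # --- tandem ----------------------------------------------------------
    for i in range(n):
        c = int(rng.integers(0, nc))
        r, r2 = alloc.claim_pair_at_distance(c, 1)
        ga, gb = place(c, r, int(rng.integers(1, 9))), place(c, r2, int(rng.integers(1, 9)))
        key = tuple(sorted((ga, gb)))
        pairs.append(PlantedPair(key[0], key[1], DuplicationMode.TANDEM))

    # --- proximal --------------------------------------------------------
    for i in range(n):
        c = int(rng.integers(0, nc))
        dist = int(rng.integers(2, config.proximal_window + 1))
        r, r2 = alloc.claim_pair_at_distance(c, dist)
        ga, gb = place(c, r, int(rng.integers(1, 9))), place(c, r2, int(rng.integers(1, 9)))
        key = tuple(sorted((ga, gb)))
        pairs.append(PlantedPair(key[0], key[1], DuplicationMode.PROXIMAL))

    # --- retrotransposed: ancestral multi-exon parent, intronless copy ---
    for i in range(n):
        cp = int(rng.integers(0, nc))
        cc = int((cp + 1 + rng.integers(0, nc - 1)) % nc)
        rp = alloc.claim_single(cp)
        rc = alloc.claim_single(cc)
        parent = place(cp, rp, int(rng.integers(3, 9)))
        child = place(cc, rc, 1)
        anchors.add_ortholog(parent, f"ORTH_R{i:04d}", f"oblk_r{i:04d}")
        key = tuple(sorted((parent, child)))
        pairs.append(
            PlantedPair(key[0], key[1], DuplicationMode.RETROTRANSPOSED, parental_copy=parent)
        )

    # --- DNA-based transposed: ancestral parent, intron-retaining copy ---
    for i in range(n):
        cp = int(rng.integers(0, nc))
        cc = int((cp + 1 + rng.integers(0, nc - 1)) % nc)
        rp = alloc.claim_single(cp)
        rc = alloc.claim_single(cc)
        parent = place(cp, rp, int(rng.integers(2, 9)))
        child = place(cc, rc, int(rng.integers(2, 9)))
        anchors.add_ortholog(parent, f"ORTH_D{i:04d}", f"oblk_d{i:04d}")
        key = tuple(sorted((parent, child)))
        pairs.append(
            PlantedPair(key[0], key[1], DuplicationMode.DNA_TRANSPOSED, parental_copy=parent)
        )

    # --- dispersed: non-ancestral loci on different chromosomes ----------
    for i in range(n):
        c0 = int(rng.integers(0, nc))
        c1 = int((c0 + 1 + rng.integers(0, nc - 1)) % nc)
        ga = place(c0, alloc.claim_single(c0), int(rng.integers(1, 9)))
        gb = place(c1, alloc.claim_single(c1), int(rng.integers(1, 9)))
        key = tuple(sorted((ga, gb)))
        pairs.append(PlantedPair(key[0], key[1], DuplicationMode.DISPERSED))

    # --- optional interference: tandem partners of WGD anchor genes ------
    if config.interference:
        planted = 0
        for (c, r) in wgd_gene_slots:
            if planted >= config.n_interference:
                break
            for neighbour in (r + 1, r - 1):
                if alloc.try_claim(c, neighbour):
                    g = _gene_id(c, r)
                    h = place(c, neighbour, int(rng.integers(1, 9)))
                    key = tuple(sorted((g, h)))
                    pairs.append(PlantedPair(key[0], key[1], DuplicationMode.TANDEM))
                    planted += 1
                    break
        if planted < config.n_interference:
            logger.warning("planted only %d interfering tandem pairs", planted)

    # --- fill every remaining rank with singleton genes ------------------
    genes: list[Gene] = []
    for c in range(nc):
        for r in range(gpc):
            exons = exon_counts.get((c, r), int(rng.integers(1, 9)))
            start = 1 + r * _GENE_SPACING
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Gene(_gene_id(c, r), f"chr{c + 1}", start, start + _GENE_LENGTH - 1, strand, exons)
            )
    lengths = {f"chr{c + 1}": gpc * _GENE_SPACING + _GENE_LENGTH for c in range(nc)}
    annotation = GenomeAnnotation(genes, lengths)

    # --- homology hits ----------------------------------------------------
    hits: list[HomologyHit] = []
    for p in pairs:
        ev = 10.0 ** -rng.uniform(15, 150)
        bs = float(rng.uniform(200, 1000))
        hits.append(HomologyHit(p.gene_a, p.gene_b, ev, bs))
        hits.append(HomologyHit(p.gene_b, p.gene_a, ev, bs))
    all_ids = [g.gene_id for g in genes]
    for _ in range(config.n_decoy_hits):
        qi, si = rng.choice(len(all_ids), size=2, replace=False)
        hits.append(
            HomologyHit(
                all_ids[qi], all_ids[si], 10.0 ** -rng.uniform(0, 8), float(rng.uniform(30, 60))
            )
        )

    origins = _origins_from_pairs(pairs)
    singletons = set(all_ids) - set(origins)
    truth = GroundTruth(pairs=pairs, origins=origins, singletons=singletons)
    return SimulatedGenome(annotation, anchors, hits, truth, config)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    pairs: Sequence[PlantedPair],
    gene_ids: Sequence[str],
    seed: int | None = None,
) -> ExpressionMatrix:
    """Expression matrix in which each planted pair attains its target
    correlation in expectation.

    The first gene of a pair gets an i.i.d. standard-normal profile z; its
    partner gets r z + sqrt(1 - r^2) eps, so the population correlation is
    exactly the per-mode target.  Unpaired genes get independent noise.  A
    gene already assigned a profile (interference) serves as the latent z
    for its later partners.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 2])
    ns = config.n_samples
    profiles: dict[str, np.ndarray] = {}
    for p in pairs:
        r = float(config.mode_target_r.get(p.mode, 0.0))
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target r {r} outside [-1, 1]")
        if p.gene_a not in profiles:
            profiles[p.gene_a] = rng.standard_normal(ns)
        if p.gene_b not in profiles:
            z = profiles[p.gene_a]
            eps = rng.standard_normal(ns)
            profiles[p.gene_b] = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps
    for g in gene_ids:
        if g not in profiles:
            profiles[g] = rng.standard_normal(ns)
    order = [g for g in gene_ids if g in profiles]
    frame = pd.DataFrame(
        np.vstack([profiles[g] for g in order]),
        index=order,
        columns=[f"sample_{i:04d}" for i in range(ns)],
    )
    return ExpressionMatrix(frame)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _random_cds(n_codons: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return [_SENSE_CODONS[i] for i in idx]


def _mutate_synonymous(codons: list[str], p: float, rng: np.random.Generator) -> list[str]:
    """Third-position changes at 4-fold codons only: never alters the protein."""
    out = []
    for codon in codons:
        if codon[:2] in _FOURFOLD_PREFIXES and rng.random() < p:
            alt = [n for n in _NUCS if n != codon[2]]
            codon = codon[:2] + alt[int(rng.integers(0, 3))]
        out.append(codon)
    return out


def _mutate_nonsynonymous(codons: list[str], p: float, rng: np.random.Generator) -> list[str]:
    """First-position changes constrained to sense, amino-acid-altering codons."""
    out = []
    for codon in codons:
        if rng.random() < p:
            cands = [
                n + codon[1:]
                for n in _NUCS
                if n != codon[0]
                and (n + codon[1:]) in CODON_TO_AA
                and CODON_TO_AA[n + codon[1:]] != CODON_TO_AA[codon]
            ]
            if cands:
                codon = cands[int(rng.integers(0, len(cands)))]
        out.append(codon)
    return out


def _random_promoter(length: int, rng: np.random.Generator) -> str:
    return "".join(_NUCS[i] for i in rng.integers(0, 4, size=length))


def _mutate_promoter(seq: str, p: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < p:
            alt = [n for n in _NUCS if n != ch]
            ch = alt[int(rng.integers(0, 3))]
        out.append(ch)
    return "".join(out)


@dataclass
class SequenceSet:
    cds: dict[str, str]
    protein: dict[str, str]
    promoter: dict[str, str]

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cds": outdir / "cds.fasta",
            "protein": outdir / "protein.fasta",
            "promoter": outdir / "promoter.fasta",
        }
        write_fasta(self.cds, paths["cds"])
        write_fasta(self.protein, paths["protein"])
        write_fasta(self.promoter, paths["promoter"])
        return paths


def simulate_sequences(
    config: SimulationConfig,
    pairs: Sequence[PlantedPair],
    seed: int | None = None,
) -> SequenceSet:
    """CDS/protein/promoter FASTA sets with controlled divergence per pair.

    Each pair descends from an ancestor of ``n_codons`` uniform sense codons.
    The second copy receives synonymous changes at 4-fold third positions
    (per-site probability = the mode's synonymous pressure) and
    amino-acid-altering first-position changes (the mode's nonsynonymous
    pressure); promoters mutate at ``promoter_p`` per site.  Genes appearing
    in several pairs keep their first-assigned sequences.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 3])
    cds: dict[str, str] = {}
    protein: dict[str, str] = {}
    promoter: dict[str, str] = {}

    def translate(codons: Iterable[str]) -> str:
        return "".join(CODON_TO_AA[c] for c in codons)

    for p in pairs:
        p_syn = float(config.mode_p_syn.get(p.mode, 0.2))
        p_non = float(config.mode_p_nonsyn.get(p.mode, 0.05))
        if p.gene_a not in cds:
            codons = _random_cds(config.n_codons, rng)
            cds[p.gene_a] = "".join(codons)
            protein[p.gene_a] = translate(codons)
            promoter[p.gene_a] = _random_promoter(config.promoter_length, rng)
        if p.gene_b not in cds:
            parent = [cds[p.gene_a][i:i + 3] for i in range(0, len(cds[p.gene_a]), 3)]
            child = _mutate_synonymous(parent, p_syn, rng)
            child = _mutate_nonsynonymous(child, p_non, rng)
            cds[p.gene_b] = "".join(child)
            protein[p.gene_b] = translate(child)
            promoter[p.gene_b] = _mutate_promoter(promoter[p.gene_a], config.promoter_p, rng)
    return SequenceSet(cds=cds, protein=protein, promoter=promoter)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    seed: int | None = None,
) -> MethylationTrack:
    """Probe track on a regular grid with i.i.d. Bernoulli methylation."""
    rng = np.random.default_rng([config.seed if seed is None else seed, 4])
    probes: list[tuple[str, int, bool]] = []
    for chrom in annotation.chromosomes():
        length = annotation.chromosome_lengths.get(
            chrom, max(g.end for g in annotation.genes_on(chrom)) + config.probe_spacing
        )
        for pos in range(config.probe_spacing, length + 1, config.probe_spacing):
            probes.append((chrom, pos, bool(rng.random() < config.methylation_rate)))
    return MethylationTrack(probes)


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------

def simulate_families(
    config: SimulationConfig,
    origins: Mapping[str, DuplicationMode],
    seed: int | None = None,
) -> tuple[TermAnnotation, dict[str, DuplicationMode | None]]:
    """Gene families over the origin-assigned universe, two of three planted
    with an origin bias (a ``family_bias`` fraction of members drawn from one
    mode), the rest sampled at random (null families)."""
    rng = np.random.default_rng([config.seed if seed is None else seed, 5])
    universe = sorted(origins)
    by_mode: dict[DuplicationMode, list[str]] = {}
    for g in universe:
        by_mode.setdefault(origins[g], []).append(g)
    usable_modes = [m for m in _MODES if len(by_mode.get(m, [])) >= config.family_size_max]
    membership: dict[str, set[str]] = {}
    planted: dict[str, DuplicationMode | None] = {}
    for i in range(config.n_families):
        fam = f"FAM{i:03d}"
        size = int(rng.integers(config.family_size_min, config.family_size_max + 1))
        if i % 3 == 2 or not usable_modes:
            members = list(rng.choice(universe, size=size, replace=False))
            planted[fam] = None
        else:
            mode = usable_modes[i % len(usable_modes)]
            n_biased = int(round(config.family_bias * size))
            pool = by_mode[mode]
            members = list(rng.choice(pool, size=min(n_biased, len(pool)), replace=False))
            others = [g for g in universe if origins[g] != mode]
            members += list(rng.choice(others, size=size - len(members), replace=False))
            planted[fam] = mode
        for g in members:
            membership.setdefault(g, set()).add(fam)
    return TermAnnotation(membership), planted


# ---------------------------------------------------------------------------
# Two-species ortholog panel
# ---------------------------------------------------------------------------

def simulate_two_species(
    config: SimulationConfig, seed: int | None = None
) -> tuple[OrthologFrame, dict[str, float]]:
    """Ortholog panel whose co-expression structure degrades by ortholog class.

    Species-1 profiles follow a shared latent-factor model (so co-expression
    is informative); species-2 profiles are the species-1 profiles plus
    class-specific perturbation noise with sigma_SS < sigma_SD < sigma_DD,
    so the true mean expression divergence d = 1 - EC orders
    S-S < S-D < D-D.  With all sigmas zero the two matrices are identical
    and every EC is exactly 1.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 6])
    classes = (
        ["S-S"] * config.n_orthologs_per_class
        + ["S-D"] * config.n_orthologs_per_class
        + ["D-D"] * config.n_orthologs_per_class
    )
    k = len(classes)
    n = config.ortholog_samples
    loadings = rng.standard_normal((k, config.n_factors))
    factors = rng.standard_normal((config.n_factors, n))
    a = loadings @ factors + config.factor_noise_sd * rng.standard_normal((k, n))
    b = a.copy()
    for i, cls in enumerate(classes):
        sigma = float(config.class_sigma[cls])
        if sigma > 0:
            b[i] = a[i] + sigma * rng.standard_normal(n)
    class_a = ["singleton" if c[0] == "S" else "duplicate" for c in classes]
    class_b = ["singleton" if c[-1] == "S" else "duplicate" for c in classes]
    frame = OrthologFrame(
        genes_a=[f"sp1_{i:04d}" for i in range(k)],
        genes_b=[f"sp2_{i:04d}" for i in range(k)],
        matrix_a=a,
        matrix_b=b,
        class_a=class_a,
        class_b=class_b,
    )
    return frame, dict(config.class_sigma)
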