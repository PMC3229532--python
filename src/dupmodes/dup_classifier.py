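"""Classification of duplicate gene pairs into mechanistic modes.

The procedure mirrors the standard flowchart used for angiosperm duplicate
classification: build the candidate duplicate population from protein
homology hits (top-N non-self matches under an e-value ceiling), peel off
whole-genome-duplication (WGD) pairs given by syntenic anchors, then tandem
(adjacent gene ranks), proximal (within a gene-rank window), then transposed
pairs (exactly one copy at an ancestral, synteny-supported locus), splitting
these into retrotransposed (multi-exon parent, intronless copy) and DNA-based
transposed; what remains is dispersed.  Each gene finally receives a unique
origin, the highest-priority mode among its pairs:

    WGD > tandem > proximal > retrotransposed > DNA transposed > dispersed
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .genome_io import AnchorCollection, GenomeAnnotation, HomologyHit

logger = logging.getLogger(__name__)

__all__ = [
    "DuplicationMode",
    "DuplicatePair",
    "ClassifierConfig",
    "ClassificationResult",
    "MODE_PRIORITY",
    "build_candidate_pairs",
    "classify_tandem_proximal",
    "classify_transposed",
    "classify_all",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_origins_tsv",
]


class DuplicationMode(str, Enum):
    WGD = "wgd"
    TANDEM = "tandem"
    PROXIMAL = "proximal"
    RETROTRANSPOSED = "retrotransposed"
    DNA_TRANSPOSED = "dna_transposed"
    DISPERSED = "dispersed"
    UNCLASSIFIED = "unclassified"


#: Gene-origin priority, highest first.  UNCLASSIFIED (single-exon pairs with
#: one ancestral copy) sits below dispersed: those pairs are uninformative.
MODE_PRIORITY: tuple[DuplicationMode, ...] = (
    DuplicationMode.WGD,
    DuplicationMode.TANDEM,
    DuplicationMode.PROXIMAL,
    DuplicationMode.RETROTRANSPOSED,
    DuplicationMode.DNA_TRANSPOSED,
    DuplicationMode.DISPERSED,
    DuplicationMode.UNCLASSIFIED,
)

_PRIORITY_RANK = {m: i for i, m in enumerate(MODE_PRIORITY)}


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    mode: DuplicationMode
    parental_copy: str | None = None
    event: str | None = None

    def __post_init__(self):
        if self.parental_copy is not None and self.parental_copy not in (self.gene_a, self.gene_b):
            raise ValueError("parental_copy must be one of the pair's genes")

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the classification procedure.

    evalue_max: homology hits above this e-value are ignored.  The
        conventional 1e-10 of this literature.
    top_n_hits: per query, only the best ``top_n_hits`` qualifying non-self
        matches seed candidate pairs.
    proximal_window: maximum gene-rank distance for a proximal call
        (adjacency, distance 1, is tandem).
    retro_min_parent_exons: minimum parent exon count for a retrotransposition
        call ("more than two exons" read literally as >= 3).
    """

    evalue_max: float = 1e-10
    top_n_hits: int = 5
    proximal_window: int = 20
    retro_min_parent_exons: int = 3

    def __post_init__(self):
        if self.top_n_hits < 1:
            raise ValueError("top_n_hits must be >= 1")
        if self.proximal_window < 2:
            raise ValueError("proximal_window must be >= 2")


@dataclass
class ClassificationResult:
    pairs: list[DuplicatePair]
    origins: dict[str, DuplicationMode]
    singletons: set[str]

    def mode_counts(self) -> dict[DuplicationMode, int]:
        counts: dict[DuplicationMode, int] = {}
        for p in self.pairs:
            counts[p.mode] = counts.get(p.mode, 0) + 1
        return counts

    def pairs_of_mode(self, mode: DuplicationMode) -> list[DuplicatePair]:
        return [p for p in self.pairs if p.mode == mode]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_candidate_pairs(
    hits: Iterable[HomologyHit],
    config: ClassifierConfig = ClassifierConfig(),
    annotation: GenomeAnnotation | None = None,
) -> tuple[set[tuple[str, str]], set[str]]:
    """Candidate duplicate pairs and singletons from homology hits.

    Per query, the <= ``top_n_hits`` best hits (ascending e-value, descending
    bitscore) with e-value <= ``evalue_max`` contribute unordered pairs; the
    pair set is the deduplicated union over both directions.  Singletons are
    the genes (of the annotation when given, else of the hit table) with no
    qualifying hit in either direction.  Hits naming genes absent from the
    annotation are excluded with a warning.
    """
    by_query: dict[str, list[HomologyHit]] = {}
    universe: set[str] = set(annotation.gene_ids) if annotation is not None else set()
    n_dropped = 0
    for h in hits:
        if annotation is not None and (h.query_id not in annotation or h.subject_id not in annotation):
            n_dropped += 1
            continue
        if annotation is None:
            universe.add(h.query_id)
            universe.add(h.subject_id)
        by_query.setdefault(h.query_id, []).append(h)
    if n_dropped:
        logger.warning("excluded %d hits naming genes absent from the annotation", n_dropped)

    pairs: set[tuple[str, str]] = set()
    for query, qhits in by_query.items():
        qhits = sorted(qhits, key=lambda h: (h.evalue, -h.bitscore))
        kept = 0
        for h in qhits:
            if h.evalue > config.evalue_max:
                continue
            if h.query_id == h.subject_id:
                continue
            pairs.add(_pair_key(h.query_id, h.subject_id))
            kept += 1
            if kept >= config.top_n_hits:
                break
    paired = {g for pair in pairs for g in pair}
    singletons = universe - paired
    return pairs, singletons


def classify_tandem_proximal(
    pair: tuple[str, str],
    annotation: GenomeAnnotation,
    config: ClassifierConfig = ClassifierConfig(),
) -> DuplicationMode | None:
    """Tandem (adjacent ranks, same chromosome), proximal (rank distance in
    [2, window]), or ``None``."""
    a, b = annotation[pair[0]], annotation[pair[1]]
    if a.chromosome != b.chromosome:
        return None
    dist = abs(a.rank - b.rank)
    if dist == 1:
        return DuplicationMode.TANDEM
    if 2 <= dist <= config.proximal_window:
        return DuplicationMode.PROXIMAL
    return None


def classify_transposed(
    pair: tuple[str, str],
    ancestral: set[str],
    annotation: GenomeAnnotation,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[DuplicationMode | None, str | None]:
    """Transposed-duplication call for a pair not already WGD/tandem/proximal.

    Requires exactly one copy at an ancestral locus (the parental copy).
    Returns ``(mode, parental_copy)``; mode is ``None`` when zero or two
    copies are ancestral (the pair falls through to dispersed).
    """
    a_anc = pair[0] in ancestral
    b_anc = pair[1] in ancestral
    if a_anc == b_anc:
        return None, None
    parent_id, child_id = (pair[0], pair[1]) if a_anc else (pair[1], pair[0])
    parent = annotation[parent_id]
    child = annotation[child_id]
    if parent.exon_count == 1 and child.exon_count == 1:
        return DuplicationMode.UNCLASSIFIED, parent_id
    if parent.exon_count >= config.retro_min_parent_exons and child.exon_count == 1:
        return DuplicationMode.RETROTRANSPOSED, parent_id
    return DuplicationMode.DNA_TRANSPOSED, parent_id


def classify_all(
    annotation: GenomeAnnotation,
    hits: Iterable[HomologyHit],
    anchors: AnchorCollection,
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassificationResult:
    """Run the full classification flowchart.

    Anchor pairs are authoritative WGD calls (the supplied anchor list is the
    WGD pair set verbatim); remaining candidate pairs are tested tandem ->
    proximal -> transposed, and the rest are dispersed.  Output pairs are
    sorted by (gene_a, gene_b); gene origins use the priority order.
    """
    candidates, singletons = build_candidate_pairs(hits, config, annotation)
    ancestral = anchors.ancestral_gene_ids

    classified: dict[tuple[str, str], DuplicatePair] = {}
    for key, ap in anchors.anchor_pairs.items():
        if key not in candidates:
            logger.info("anchor pair %s absent from candidate population; kept as WGD", key)
        classified[key] = DuplicatePair(key[0], key[1], DuplicationMode.WGD, event=ap.event)

    for key in sorted(candidates):
        if key in classified:
            continue
        if key[0] not in annotation or key[1] not in annotation:
            # build_candidate_pairs already filtered against the annotation
            continue
        mode = classify_tandem_proximal(key, annotation, config)
        parental = None
        if mode is None:
            mode, parental = classify_transposed(key, ancestral, annotation, config)
        if mode is None:
            mode = DuplicationMode.DISPERSED
        classified[key] = DuplicatePair(key[0], key[1], mode, parental_copy=parental)

    pairs = [classified[k] for k in sorted(classified)]

    origins: dict[str, DuplicationMode] = {}
    for p in pairs:
        for g in p.genes:
            prev = origins.get(g)
            if prev is None or _PRIORITY_RANK[p.mode] < _PRIORITY_RANK[prev]:
                origins[g] = p.mode

    # genes pulled in only through anchors still must not be counted singleton
    singletons -= set(origins)
    return ClassificationResult(pairs=pairs, origins=origins, singletons=singletons)


# ---------------------------------------------------------------------------
# Tabular output of classification results
# ---------------------------------------------------------------------------

def write_pairs_tsv(pairs: Iterable[DuplicatePair], path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_a\tgene_b\tmode\tparental_copy\tevent\n")
        for p in pairs:
            fh.write(
                f"{p.gene_a}\t{p.gene_b}\t{p.mode.value}\t"
                f"{p.parental_copy or ''}\t{p.event or ''}\n"
            )


def read_pairs_tsv(path) -> list[DuplicatePair]:
    out: list[DuplicatePair] = []
    with open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}: missing pairs header")
        for line in fh:
            a, b, mode, parental, event = (line.rstrip("\n").split("\t") + ["", ""])[:5]
            out.append(
                DuplicatePair(a, b, DuplicationMode(mode), parental or None, event or None)
            )
    return out


def write_origins_tsv(origins: Mapping[str, DuplicationMode], path) -> None:
    with open(path, "wt") as fh:
        fh.write("gene_id\torigin\n")
        for g in sorted(origins):
            fh.write(f"{g}\t{origins[g].value}\n")
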