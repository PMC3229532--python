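"""Readers/writers for the standard files the pipeline consumes and the
in-memory genome model.

Coordinates are 1-based inclusive throughout (GFF3 convention); any half-open
arithmetic is local to sequence slicing.  Gene order ("rank") is the 0-based
position of a gene among *all* annotated genes on its chromosome, ordered by
``(start, end, gene_id)`` -- the proximal rule counts annotated genes, not
expressed ones.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "HomologyHit",
    "AnchorPair",
    "AnchorCollection",
    "GFFParseError",
    "BlastParseError",
    "read_gff",
    "write_gff",
    "read_blast_tab",
    "write_blast_tab",
    "read_anchors",
    "write_anchors",
    "read_fasta",
    "write_fasta",
]


class GFFParseError(ValueError):
    """Raised for malformed GFF3 input, naming the offending line."""


class BlastParseError(ValueError):
    """Raised for malformed tabular BLAST input."""


def _open_text(path):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class Gene:
    """One annotated gene.

    ``rank`` is the 0-based position among the genes of its chromosome
    ordered by start coordinate (ties broken by end, then gene_id).
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_count: int = 1
    rank: int = -1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")


class GenomeAnnotation:
    """Collection of :class:`Gene` keyed by gene_id with per-chromosome ranks."""

    def __init__(self, genes: Iterable[Gene], chromosome_lengths: Mapping[str, int] | None = None):
        records = list(genes)
        ids = [g.gene_id for g in records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        self._genes: dict[str, Gene] = {}
        by_chrom: dict[str, list[Gene]] = {}
        for g in records:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for rank, g in enumerate(gs):
                g = Gene(g.gene_id, g.chromosome, g.start, g.end, g.strand, g.exon_count, rank)
                self._genes[g.gene_id] = g
        self.chromosome_lengths = dict(chromosome_lengths or {})

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    def __iter__(self):
        return iter(self._genes.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def chromosomes(self) -> list[str]:
        return sorted({g.chromosome for g in self._genes.values()})

    def genes_on(self, chromosome: str) -> list[Gene]:
        """Genes of one chromosome in rank order."""
        gs = [g for g in self._genes.values() if g.chromosome == chromosome]
        return sorted(gs, key=lambda g: g.rank)

    def subset(self, chromosome: str) -> "GenomeAnnotation":
        """New annotation restricted to one chromosome (ranks recomputed)."""
        return GenomeAnnotation(
            self.genes_on(chromosome),
            {chromosome: self.chromosome_lengths[chromosome]}
            if chromosome in self.chromosome_lengths
            else None,
        )


@dataclass(frozen=True)
class HomologyHit:
    """One protein homology hit (BLASTP outfmt-6 style)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class AnchorPair:
    """One syntenic anchor pair; gene ids stored in sorted order."""

    gene_a: str
    gene_b: str
    block_id: str
    event: str | None = None


class AnchorCollection:
    """Syntenic anchor pairs grouped by block, plus cross-species ortholog anchors.

    A gene locus counts as *ancestral* when the resident gene occurs, with a
    paralog or an ortholog, at corresponding loci of a pair of syntenic
    blocks -- i.e. when it appears in at least one anchor pair of either kind.
    Only within-species anchor pairs define WGD duplicate pairs.
    """

    def __init__(self):
        self._pairs: dict[tuple[str, str], AnchorPair] = {}
        self._ortho: dict[tuple[str, str], AnchorPair] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_pair(self, gene_a: str, gene_b: str, block_id: str, event: str | None = None) -> None:
        key = self._key(gene_a, gene_b)
        prev = self._pairs.get(key)
        if prev is not None:
            if (prev.event or None) != (event or None):
                raise ValueError(
                    f"anchor pair {key} tagged with two events: {prev.event!r} and {event!r}"
                )
            return
        self._pairs[key] = AnchorPair(key[0], key[1], block_id, event or None)

    def add_ortholog(self, gene_a: str, gene_b: str, block_id: str) -> None:
        key = self._key(gene_a, gene_b)
        self._ortho.setdefault(key, AnchorPair(key[0], key[1], block_id))

    @property
    def anchor_pairs(self) -> dict[tuple[str, str], AnchorPair]:
        return dict(self._pairs)

    @property
    def ortholog_pairs(self) -> dict[tuple[str, str], AnchorPair]:
        return dict(self._ortho)

    @property
    def ancestral_gene_ids(self) -> set[str]:
        out: set[str] = set()
        for a, b in self._pairs:
            out.add(a)
            out.add(b)
        for a, b in self._ortho:
            out.add(a)
            out.add(b)
        return out

    def events(self) -> set[str]:
        return {p.event for p in self._pairs.values() if p.event is not None}

    def __len__(self) -> int:
        return len(self._pairs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    Exon features are attributed to genes through Parent chains (gffutils).
    A gene with no exon records gets ``exon_count = 1`` with a warning.
    Malformed feature lines raise :class:`GFFParseError` naming the line.
    """
    import gffutils

    with _open_text(path) as fh:
        text = fh.read()

    region_lengths: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                region_lengths[parts[1]] = int(parts[3])
            continue
        if not line.strip() or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise GFFParseError(f"{path}: line {lineno}: expected 9 tab-separated columns")

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[Gene] = []
    for feat in db.features_of_type("gene"):
        n_exons = sum(1 for _ in db.children(feat, featuretype="exon"))
        if n_exons == 0:
            logger.warning("gene %s has no exon records; defaulting exon_count to 1", feat.id)
            n_exons = 1
        genes.append(Gene(feat.id, feat.seqid, feat.start, feat.end, feat.strand, n_exons))
    return GenomeAnnotation(genes, region_lengths or None)


def write_gff(annotation: GenomeAnnotation, path) -> None:
    """Write a GenomeAnnotation as GFF3 (gene + mRNA + exon features).

    Exon coordinates are synthesized as equal, non-overlapping slices of the
    gene body; only their count is semantically meaningful on re-read.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes():
            if chrom in annotation.chromosome_lengths:
                fh.write(f"##sequence-region {chrom} 1 {annotation.chromosome_lengths[chrom]}\n")
        for chrom in annotation.chromosomes():
            for g in annotation.genes_on(chrom):
                attrs = f"ID={g.gene_id}"
                fh.write(
                    f"{chrom}\tdupmodes\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                mrna = f"{g.gene_id}.1"
                fh.write(
                    f"{chrom}\tdupmodes\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={mrna};Parent={g.gene_id}\n"
                )
                length = g.end - g.start + 1
                k = g.exon_count
                # k equal slices with 1-bp gaps between them, clipped to the body
                step = max(2, length // k)
                for i in range(k):
                    es = g.start + i * step
                    ee = min(g.end, es + max(0, step - 2))
                    if es > g.end:
                        es, ee = g.end, g.end
                    fh.write(
                        f"{chrom}\tdupmodes\texon\t{es}\t{ee}\t.\t{g.strand}\t.\t"
                        f"ID={mrna}.exon{i + 1};Parent={mrna}\n"
                    )


# ---------------------------------------------------------------------------
# Tabular BLAST
# ---------------------------------------------------------------------------

def read_blast_tab(path) -> list[HomologyHit]:
    """Read 12-column outfmt-6-style hits.

    Self-hits are removed; per query, hits are sorted by ascending e-value
    then descending bitscore.  Columns beyond (query, subject, evalue,
    bitscore) are ignored.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", header=None, comment="#", dtype=str)
    if df.empty:
        return []
    if df.shape[1] < 12:
        raise BlastParseError(f"{path}: expected 12 tab-separated columns, got {df.shape[1]}")
    out = pd.DataFrame(
        {
            "query_id": df[0],
            "subject_id": df[1],
            "evalue": pd.to_numeric(df[10], errors="coerce"),
            "bitscore": pd.to_numeric(df[11], errors="coerce"),
        }
    )
    if out["evalue"].isna().any():
        bad = df[10][out["evalue"].isna()].iloc[0]
        raise BlastParseError(f"{path}: non-numeric evalue {bad!r}")
    if (out["evalue"] < 0).any():
        raise BlastParseError(f"{path}: negative evalue")
    out = out[out["query_id"] != out["subject_id"]]
    out = out.sort_values(
        ["query_id", "evalue", "bitscore"], ascending=[True, True, False], kind="mergesort"
    )
    return [
        HomologyHit(r.query_id, r.subject_id, float(r.evalue), float(r.bitscore))
        for r in out.itertuples(index=False)
    ]


def write_blast_tab(hits: Iterable[HomologyHit], path) -> None:
    """Write hits as 12-column outfmt-6 rows (unused columns zero-filled)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Anchor files
# ---------------------------------------------------------------------------

def read_anchors(
    path,
    ortholog_path=None,
    annotation: GenomeAnnotation | None = None,
    on_missing: str = "warn",
) -> AnchorCollection:
    """Read syntenic anchor pairs (and optional cross-species ortholog anchors).

    Rows are ``geneA <tab> geneB <tab> block_id [<tab> event]``; the pair is
    stored unordered and deduplicated.  With an annotation supplied, pairs
    naming unknown genes are kept with a warning (``on_missing='warn'``,
    default) or rejected (``on_missing='fail'``).
    """
    if on_missing not in ("warn", "fail"):
        raise ValueError("on_missing must be 'warn' or 'fail'")
    coll = AnchorCollection()

    def _rows(p):
        with _open_text(p) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{p}: anchor rows need >= 3 columns: {line!r}")
                yield parts

    for parts in _rows(path):
        a, b, block = parts[0], parts[1], parts[2]
        event = parts[3] if len(parts) > 3 and parts[3] else None
        if annotation is not None:
            missing = [g for g in (a, b) if g not in annotation]
            if missing:
                if on_missing == "fail":
                    raise KeyError(f"anchor gene(s) {missing} absent from annotation")
                logger.warning("anchor gene(s) %s absent from annotation; kept", missing)
        coll.add_pair(a, b, block, event)

    if ortholog_path is not None:
        for parts in _rows(ortholog_path):
            coll.add_ortholog(parts[0], parts[1], parts[2])
    return coll


def write_anchors(anchors: AnchorCollection, path, ortholog_path=None) -> None:
    path = Path(path)
    with open(path, "wt") as fh:
        for (a, b), p in sorted(anchors.anchor_pairs.items()):
            fh.write(f"{a}\t{b}\t{p.block_id}\t{p.event or ''}\n")
    if ortholog_path is not None:
        with open(ortholog_path, "wt") as fh:
            for (a, b), p in sorted(anchors.ortholog_pairs.items()):
                fh.write(f"{a}\t{b}\t{p.block_id}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping (gzip-aware)."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
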