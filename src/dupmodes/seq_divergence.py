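"""Coding and noncoding sequence divergence between duplicate genes.

Ka and Ks are estimated with the unweighted-pathway method of Nei & Gojobori
(1986): per codon, the synonymous site count is the sum over the three
positions of the fraction of the three possible single-nucleotide changes
that are synonymous (changes creating a stop codon count as nonsynonymous);
site totals S and N are averaged over the two sequences.  Codon pairs
differing at two or three positions have their synonymous/nonsynonymous
difference counts averaged over all substitution orderings, discarding
pathways that pass through a stop codon; a codon pair whose every pathway
hits a stop is skipped entirely.  The raw proportions pS = Sd/S and
pN = Nd/N are corrected for multiple hits with the Jukes-Cantor formula
K = -(3/4) ln(1 - 4p/3), which is undefined (invalid) for p >= 3/4.

Noncoding divergence (promoters, UTRs) is the plain Jukes-Cantor nucleotide
substitution rate mu over ungapped alignment columns.  Promoter regions run
up to 1,000 bp upstream of the transcription start site, truncated where the
nearest upstream gene is closer; a pair of promoters counts as duplicated
(non-disrupted) when their global-alignment identity exceeds 45%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Mapping

from Bio.Data import CodonTable

from .genome_io import Gene, GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "MuResult",
    "codon_backtranslate",
    "nei_gojobori",
    "synonymous_sites",
    "jukes_cantor",
    "jukes_cantor_mu",
    "promoter_extract",
    "promoter_identity",
    "promoter_duplicated",
    "CODON_TO_AA",
    "STOP_CODONS",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
_NUCS = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


@dataclass(frozen=True)
class CodonAlignment:
    """Two frame-preserved, gap-aware coding sequences of equal length.

    Gaps come in units of three (from a protein alignment); codon pairs
    containing a gap, an ambiguous base, or a stop codon in either sequence
    are excluded from Ka/Ks counting.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a = self.seq_a.upper()
        b = self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError("aligned length not divisible by 3")

    def __len__(self) -> int:
        return len(self.seq_a)

    def codon_pairs(self):
        """All aligned codon pairs, countable or not."""
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]

    def countable_codon_pairs(self) -> list[tuple[str, str]]:
        out = []
        for ca, cb in self.codon_pairs():
            if any(c not in _NUCS for c in ca + cb):
                continue  # gap or ambiguous base
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            out.append((ca, cb))
        return out


def codon_backtranslate(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Map a protein alignment back onto the source CDSs.

    Each aligned amino acid expands to its source codon; protein gaps become
    triple-nucleotide gaps.  A trailing stop codon on a CDS is tolerated and
    trimmed; internal stops and length mismatches are errors.
    """
    out = []
    for prot, cds in ((protein_a, cds_a), (protein_b, cds_b)):
        cds = cds.upper()
        prot = prot.upper()
        n_aa = sum(1 for c in prot if c != "-")
        if len(cds) == 3 * (n_aa + 1) and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        if len(cds) != 3 * n_aa:
            raise ValueError(
                f"CDS length {len(cds)} does not match {n_aa} aligned residues"
            )
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        for codon in codons:
            if codon in STOP_CODONS:
                raise ValueError(f"internal stop codon {codon}")
        aligned = []
        it = iter(codons)
        for aa in prot:
            if aa == "-":
                aligned.append("---")
            else:
                codon = next(it)
                if codon in CODON_TO_AA and CODON_TO_AA[codon] != aa:
                    logger.warning(
                        "codon %s translates to %s, alignment says %s",
                        codon, CODON_TO_AA[codon], aa,
                    )
                aligned.append(codon)
        out.append("".join(aligned))
    return CodonAlignment(out[0], out[1])


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """Synonymous site count of one sense codon.

    Sum over the three positions of (synonymous single-nucleotide changes)/3;
    changes producing a stop codon are counted as nonsynonymous.
    """
    if not _is_sense(codon):
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if CODON_TO_AA.get(alt) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(Sd, Nd) between two sense codons, averaged over all substitution
    orderings; pathways through stop codons are discarded.  ``None`` when
    every pathway hits a stop."""
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_positions):
        current = codon_a
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                valid = False
                break
            if CODON_TO_AA[current] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        if valid:
            totals.append((sd, nd))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction K = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= 0.75:
        raise ValueError("Jukes-Cantor correction undefined for p >= 3/4")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # +0.0 normalizes -0.0


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None
    ks: float | None
    ka_valid: bool
    ks_valid: bool
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int


def nei_gojobori(alignment: CodonAlignment) -> KaKsResult:
    """Unweighted-pathway Ka/Ks over the countable codon pairs.

    Invalid flags are set when a Jukes-Cantor argument leaves its domain
    (p >= 3/4) or when differences are observed on a zero site count.
    """
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in alignment.countable_codon_pairs():
        counts = _pathway_counts(ca, cb)
        if counts is None:
            logger.info("codon pair %s/%s skipped: all pathways hit stops", ca, cb)
            continue
        n_codons += 1
        S_a += synonymous_sites(ca)
        S_b += synonymous_sites(cb)
        Sd += counts[0]
        Nd += counts[1]
    if n_codons == 0:
        raise ValueError("no countable codon pairs")
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S

    def _correct(d: float, sites: float) -> tuple[float | None, bool]:
        if sites <= 0:
            return (0.0, True) if d == 0 else (None, False)
        p = d / sites
        try:
            return jukes_cantor(p), True
        except ValueError:
            return None, False

    ks, ks_valid = _correct(Sd, S)
    ka, ka_valid = _correct(Nd, N)
    return KaKsResult(ka, ks, ka_valid, ks_valid, S, N, Sd, Nd, n_codons)


@dataclass(frozen=True)
class MuResult:
    mu: float | None
    valid: bool
    p: float
    n_sites: int


def jukes_cantor_mu(aligned_a: str, aligned_b: str) -> MuResult:
    """Jukes-Cantor nucleotide substitution rate over ungapped columns.

    p = 0 gives mu = 0 (valid); p >= 3/4 sets the invalid flag; an alignment
    with zero ungapped columns is an error.
    """
    a = aligned_a.upper()
    b = aligned_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    n = mismatches = 0
    for x, y in zip(a, b):
        if x not in _NUCS or y not in _NUCS:
            continue
        n += 1
        if x != y:
            mismatches += 1
    if n == 0:
        raise ValueError("no ungapped columns")
    p = mismatches / n
    if p >= 0.75:
        return MuResult(None, False, p, n)
    return MuResult(jukes_cantor(p), True, p, n)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def promoter_extract(
    gene_id: str,
    annotation: GenomeAnnotation,
    chromosome_sequences: Mapping[str, str],
    max_length: int = 1000,
) -> str:
    """Promoter sequence of a gene: up to ``max_length`` bp upstream of the
    TSS, truncated at the nearest annotated gene boundary upstream.

    "Upstream" is strand-aware; the TSS is the annotated gene start (+) or
    end (-).  Minus-strand promoters are reverse-complemented so the returned
    sequence reads 5'->3' toward the gene.  A gene at the chromosome edge is
    clipped, not an error; the result may be empty if a neighbour abuts the
    TSS.
    """
    gene = annotation[gene_id]
    try:
        chrom_seq = chromosome_sequences[gene.chromosome]
    except KeyError:
        raise KeyError(f"no sequence for chromosome {gene.chromosome!r}") from None
    others = [g for g in annotation.genes_on(gene.chromosome) if g.gene_id != gene_id]
    if gene.strand == "+":
        upstream_ends = [g.end for g in others if g.end < gene.start]
        floor = max(upstream_ends) if upstream_ends else 0
        start = max(1, gene.start - max_length, floor + 1)
        end = gene.start - 1
        return chrom_seq[start - 1:end].upper()
    upstream_starts = [g.start for g in others if g.start > gene.end]
    ceiling = min(upstream_starts) if upstream_starts else len(chrom_seq) + 1
    start = gene.end + 1
    end = min(len(chrom_seq), gene.end + max_length, ceiling - 1)
    return _revcomp(chrom_seq[start - 1:end].upper())


def _global_alignment_columns(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Best global alignment (match 1, mismatch 0, gap -1) as two gapped rows."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


def promoter_identity(seq_a: str, seq_b: str, aligned: bool = False) -> float | None:
    """Global-alignment identity of two promoter sequences.

    Identity = matching columns / all alignment columns (gap columns count
    in the denominator).  Pre-aligned input (equal-length, possibly gapped)
    is accepted with ``aligned=True``.  Returns ``None`` (undetermined) when
    either promoter is empty.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not a.replace("-", "") or not b.replace("-", ""):
        return None
    if not aligned:
        a, b = _global_alignment_columns(a, b)
    elif len(a) != len(b):
        raise ValueError("pre-aligned sequences differ in length")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def promoter_duplicated(
    seq_a: str, seq_b: str, min_identity: float = 0.45, aligned: bool = False
) -> tuple[bool, float] | None:
    """Whether a promoter pair is duplicated (non-disrupted).

    Duplicated iff global-alignment identity is strictly greater than
    ``min_identity`` (45%).  Returns ``(duplicated, identity)``; ``None``
    when undetermined (an empty promoter).
    """
    identity = promoter_identity(seq_a, seq_b, aligned=aligned)
    if identity is None:
        return None
    return identity > min_identity, identity
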