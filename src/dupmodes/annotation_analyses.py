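"""Promoter methylation calls and term/family enrichment.

A gene counts as methylated in its promoter when two or more *adjacent*
methylated probes fall inside the promoter region; "adjacent" means
consecutive in the genome-ordered probe track (the in-region probes form a
contiguous run of the track, so adjacency is checked within that run).

Enrichment of a gene subset for GO terms, Pfam domains or gene-family
membership uses the one-sided (over-representation) Fisher exact test with
Bonferroni correction over the tested terms.  Families of fewer than ten
genes are excluded from the family-by-mode scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationTrack",
    "TermAnnotation",
    "promoter_methylated",
    "methylation_change_proportion",
    "methylated_proportion",
    "fisher_enrichment",
    "family_mode_enrichment",
]


class MethylationTrack:
    """Per-chromosome ordered methylation probes.

    Positions must be strictly increasing within a chromosome; rows are
    ``(chromosome, position, methylated)``.
    """

    def __init__(self, probes: Iterable[tuple[str, int, bool]]):
        by_chrom: dict[str, list[tuple[int, bool]]] = {}
        for chrom, pos, meth in probes:
            by_chrom.setdefault(chrom, []).append((int(pos), bool(meth)))
        self._positions: dict[str, np.ndarray] = {}
        self._methylated: dict[str, np.ndarray] = {}
        for chrom, rows in by_chrom.items():
            rows.sort(key=lambda r: r[0])
            pos = np.array([r[0] for r in rows], dtype=np.int64)
            if len(pos) > 1 and (np.diff(pos) <= 0).any():
                raise ValueError(f"duplicate probe positions on {chrom}")
            self._positions[chrom] = pos
            self._methylated[chrom] = np.array([r[1] for r in rows], dtype=bool)

    @classmethod
    def from_tsv(cls, path) -> "MethylationTrack":
        """Read BED-like rows ``chrom <tab> position <tab> methylated(0/1)``."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "meth"], comment="#"
        )
        return cls(
            (r.chrom, int(r.pos), bool(int(r.meth))) for r in df.itertuples(index=False)
        )

    def to_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            for chrom in sorted(self._positions):
                for pos, meth in zip(self._positions[chrom], self._methylated[chrom]):
                    fh.write(f"{chrom}\t{pos}\t{int(meth)}\n")

    def chromosomes(self) -> list[str]:
        return sorted(self._positions)

    def probes_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Methylation states of the probes within [start, end], track order."""
        if chrom not in self._positions:
            return np.zeros(0, dtype=bool)
        pos = self._positions[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return self._methylated[chrom][lo:hi]


def promoter_methylated(
    region: tuple[str, int, int], track: MethylationTrack
) -> bool:
    """True iff two consecutive-in-track probes inside ``region`` are both
    methylated.  Regions with fewer than two probes are callable and
    unmethylated."""
    chrom, start, end = region
    states = track.probes_in(chrom, start, end)
    if states.size < 2:
        return False
    return bool((states[:-1] & states[1:]).any())


def methylation_change_proportion(pairs: pd.DataFrame) -> pd.Series:
    """Per-mode fraction of duplicate pairs whose two methylation calls differ.

    ``pairs`` needs columns mode, call_a, call_b (boolean or NA); pairs with
    a missing call are excluded and counted in the log.
    """
    for col in ("mode", "call_a", "call_b"):
        if col not in pairs.columns:
            raise ValueError(f"pairs frame must carry {col!r}")
    valid = pairs.dropna(subset=["call_a", "call_b"])
    n_dropped = len(pairs) - len(valid)
    if n_dropped:
        logger.warning("excluded %d pairs with a missing methylation call", n_dropped)
    changed = valid["call_a"].astype(bool) != valid["call_b"].astype(bool)
    return changed.groupby(valid["mode"], observed=True).mean()


def methylated_proportion(
    calls: Mapping[str, bool], classes: Mapping[str, str]
) -> pd.Series:
    """Fraction of genes methylated in the promoter, per gene class
    (singleton / duplicate)."""
    rows = [
        {"gene": g, "call": bool(calls[g]), "cls": classes[g]}
        for g in calls
        if g in classes
    ]
    if not rows:
        raise ValueError("no genes with both a call and a class")
    df = pd.DataFrame(rows)
    return df.groupby("cls")["call"].mean()


class TermAnnotation:
    """Flat gene -> term-set mapping (GO, Pfam, or gene-family ids)."""

    def __init__(self, gene_terms: Mapping[str, Iterable[str]]):
        self._gene_terms: dict[str, frozenset[str]] = {}
        for gene, terms in gene_terms.items():
            terms = frozenset(str(t) for t in terms if str(t))
            if any(not t for t in terms):
                raise ValueError("empty term id")
            if terms:
                self._gene_terms[gene] = terms

    @classmethod
    def from_tsv(cls, path, gene_col: int = 0, term_col: int = 1) -> "TermAnnotation":
        """Two-column ``gene <tab> term`` rows (column indices configurable,
        which also covers GAF-lite exports)."""
        mapping: dict[str, set[str]] = {}
        with open(path, "rt") as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "!")):
                    continue
                parts = line.rstrip("\n").split("\t")
                mapping.setdefault(parts[gene_col], set()).add(parts[term_col])
        return cls(mapping)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self._gene_terms.get(gene, frozenset())

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self._gene_terms.values():
            out |= terms
        return out

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self._gene_terms.items() if term in ts}

    def genes(self) -> set[str]:
        return set(self._gene_terms)

    def __len__(self) -> int:
        return len(self._gene_terms)


def fisher_enrichment(
    subset: Iterable[str],
    universe: Iterable[str],
    terms: TermAnnotation,
    alpha: float = 0.05,
    correct_over: str = "tested",
) -> pd.DataFrame:
    """Per-term over-representation of ``subset`` within ``universe``.

    One-sided Fisher exact p per term (2x2 table of subset membership vs
    term membership over the universe); Bonferroni-corrected by the number
    of tested terms (``correct_over='annotated'`` uses all annotated terms
    instead).  Terms absent from the universe are skipped.
    """
    subset = set(subset)
    universe = set(universe)
    if not subset <= universe:
        raise ValueError("subset must be contained in universe")
    term_genes = {
        t: terms.genes_with(t) & universe
        for t in sorted(terms.all_terms())
    }
    tested = {t: g for t, g in term_genes.items() if g}
    if correct_over == "tested":
        m = len(tested)
    elif correct_over == "annotated":
        m = len(term_genes)
    else:
        raise ValueError("correct_over must be 'tested' or 'annotated'")
    rows = []
    n_u = len(universe)
    n_s = len(subset)
    for term, genes in tested.items():
        a = len(genes & subset)
        b = n_s - a
        c = len(genes) - a
        d = n_u - n_s - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        p = float(p)
        p_corr = min(1.0, p * m) if m else 1.0
        expected = n_s * len(genes) / n_u
        rows.append(
            {
                "term": term,
                "n_subset_term": a,
                "n_universe_term": len(genes),
                "expected": expected,
                "enriched": a > expected,
                "p_raw": p,
                "p_corrected": p_corr,
                "significant": p_corr < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "n_subset_term", "n_universe_term", "expected",
            "enriched", "p_raw", "p_corrected", "significant",
        ],
    )


def family_mode_enrichment(
    families: TermAnnotation,
    origins: Mapping[str, object],
    alpha: float = 0.05,
    min_family_size: int = 10,
) -> pd.DataFrame:
    """Per-(family, mode) over-representation of a duplication mode among a
    gene family's members.

    The universe is the set of genes with an origin assignment.  Families
    with fewer than ``min_family_size`` genes in the universe are excluded;
    the Bonferroni denominator is the number of (family x mode) tests run.
    """
    universe = set(origins)
    mode_of = {g: str(getattr(m, "value", m)) for g, m in origins.items()}
    modes = sorted(set(mode_of.values()))
    fam_genes = {
        f: families.genes_with(f) & universe for f in sorted(families.all_terms())
    }
    fam_genes = {f: g for f, g in fam_genes.items() if len(g) >= min_family_size}
    tests = []
    n_u = len(universe)
    for fam, genes in fam_genes.items():
        for mode in modes:
            mode_genes = {g for g in universe if mode_of[g] == mode}
            a = len(genes & mode_genes)
            b = len(genes) - a
            c = len(mode_genes) - a
            d = n_u - len(genes) - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            tests.append(
                {
                    "family": fam,
                    "mode": mode,
                    "family_size": len(genes),
                    "n_family_mode": a,
                    "expected": len(genes) * len(mode_genes) / n_u,
                    "p_raw": float(p),
                }
            )
    df = pd.DataFrame(
        tests,
        columns=["family", "mode", "family_size", "n_family_mode", "expected", "p_raw"],
    )
    m = len(df)
    if m:
        df["p_corrected"] = (df["p_raw"] * m).clip(upper=1.0)
        df["significant"] = df["p_corrected"] < alpha
    else:
        df["p_corrected"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
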