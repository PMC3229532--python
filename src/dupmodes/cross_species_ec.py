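"""Cross-species expression conservation (EC) of positional orthologs.

Expression data measured on different platforms in two species cannot be
compared value-for-value, but co-expression structure can.  Given k ortholog
pairs with expression matrices A (k x nA, species 1) and B (k x nB,
species 2), each matrix is converted to a k x k Pearson correlation matrix
within its species.  The EC of ortholog pair i is then the correlation of
row i of the two correlation matrices -- how similarly gene i co-expresses
with the shared ortholog set in the two species -- and its expression
divergence is d = 1 - EC.  The self-entry (which is 1 in both matrices and
would mechanically inflate EC) is excluded by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ConstantProfileError, pearson_r

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologFrame",
    "coexpression_matrix",
    "ec_score",
    "ec_scores",
    "class_contrast",
]

_CLASS_LABELS = {"S-S", "S-D", "D-D"}


@dataclass
class OrthologFrame:
    """Ortholog-indexed expression data for two species.

    Row i of ``matrix_a`` and ``matrix_b`` are the expression profiles of the
    same ortholog pair in species 1 and 2 respectively; ``class_a`` /
    ``class_b`` say whether each gene is a singleton or a duplicate in its
    own genome.
    """

    genes_a: list[str]
    genes_b: list[str]
    matrix_a: np.ndarray
    matrix_b: np.ndarray
    class_a: list[str]
    class_b: list[str]

    def __post_init__(self):
        k = len(self.genes_a)
        if k < 3:
            raise ValueError("need >= 3 ortholog pairs")
        self.matrix_a = np.asarray(self.matrix_a, dtype=float)
        self.matrix_b = np.asarray(self.matrix_b, dtype=float)
        if not (
            len(self.genes_b) == k
            and self.matrix_a.shape[0] == k
            and self.matrix_b.shape[0] == k
            and len(self.class_a) == k
            and len(self.class_b) == k
        ):
            raise ValueError("ortholog frame rows are not aligned")
        for c in list(self.class_a) + list(self.class_b):
            if c not in ("singleton", "duplicate"):
                raise ValueError(f"unknown gene class {c!r}")

    @property
    def k(self) -> int:
        return len(self.genes_a)

    def pair_class(self, i: int) -> str:
        a, b = self.class_a[i], self.class_b[i]
        if a == "singleton" and b == "singleton":
            return "S-S"
        if a == "duplicate" and b == "duplicate":
            return "D-D"
        return "S-D"

    @classmethod
    def from_files(cls, matrix_a_tsv, matrix_b_tsv, orthologs_tsv) -> "OrthologFrame":
        """Assemble from two expression TSVs and an ortholog-pair table
        ``(gene_a, gene_b, class_a, class_b)``; pairs missing from either
        matrix are dropped with a warning.  A gene mapping to several
        ortholog pairs contributes one independent row per pair.
        """
        ma = pd.read_csv(matrix_a_tsv, sep="\t", index_col=0)
        mb = pd.read_csv(matrix_b_tsv, sep="\t", index_col=0)
        orth = pd.read_csv(
            orthologs_tsv,
            sep="\t",
            header=None,
            names=["gene_a", "gene_b", "class_a", "class_b"],
            comment="#",
        )
        keep = orth["gene_a"].isin(ma.index) & orth["gene_b"].isin(mb.index)
        if (~keep).any():
            logger.warning("dropped %d ortholog pairs missing from a matrix", int((~keep).sum()))
        orth = orth[keep]
        return cls(
            genes_a=list(orth["gene_a"]),
            genes_b=list(orth["gene_b"]),
            matrix_a=ma.loc[orth["gene_a"]].to_numpy(),
            matrix_b=mb.loc[orth["gene_b"]].to_numpy(),
            class_a=list(orth["class_a"]),
            class_b=list(orth["class_b"]),
        )


def coexpression_matrix(matrix: np.ndarray, gene_ids: Sequence[str] | None = None) -> np.ndarray:
    """k x k Pearson correlation matrix of the rows of a k x n matrix."""
    matrix = np.asarray(matrix, dtype=float)
    ptp = matrix.max(axis=1) - matrix.min(axis=1)
    if (ptp == 0).any():
        idx = int(np.argmax(ptp == 0))
        name = gene_ids[idx] if gene_ids is not None else f"row {idx}"
        raise ConstantProfileError(f"constant expression profile for {name}")
    corr = np.corrcoef(matrix)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def ec_score(ca: np.ndarray, cb: np.ndarray, i: int, include_self: bool = False) -> float:
    """EC of ortholog pair i from the two co-expression matrices.

    Computed as the Pearson correlation of row i of ``ca`` and row i of
    ``cb`` over the k-1 off-self entries (the self entry is 1 in both
    matrices; ``include_self=True`` keeps it for sensitivity analysis).
    """
    ca = np.asarray(ca, float)
    cb = np.asarray(cb, float)
    if ca.shape != cb.shape or ca.shape[0] != ca.shape[1]:
        raise ValueError("correlation matrices must be square and same shape")
    k = ca.shape[0]
    if include_self:
        a, b = ca[i], cb[i]
    else:
        mask = np.arange(k) != i
        a, b = ca[i][mask], cb[i][mask]
    if a.size < 3:
        raise ValueError("too few orthologs for an EC correlation")
    return pearson_r(a, b)


def ec_scores(frame: OrthologFrame, include_self: bool = False) -> pd.DataFrame:
    """EC and d = 1 - EC for every ortholog pair of the frame."""
    ca = coexpression_matrix(frame.matrix_a, frame.genes_a)
    cb = coexpression_matrix(frame.matrix_b, frame.genes_b)
    rows = []
    for i in range(frame.k):
        ec = ec_score(ca, cb, i, include_self=include_self)
        rows.append(
            {
                "gene_a": frame.genes_a[i],
                "gene_b": frame.genes_b[i],
                "pair_class": frame.pair_class(i),
                "ec": ec,
                "d": 1.0 - ec,
            }
        )
    return pd.DataFrame(rows)


def class_contrast(scores: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Mean d per ortholog class (S-S, S-D, D-D) and pairwise two-sample
    t-tests between the classes present; contrasts with an empty or
    single-observation side are skipped with a log entry."""
    if "pair_class" not in scores.columns or "d" not in scores.columns:
        raise ValueError("scores frame must carry 'pair_class' and 'd'")
    order = ["S-S", "S-D", "D-D"]
    present = [c for c in order if (scores["pair_class"] == c).any()]
    means = scores.groupby("pair_class")["d"].mean().reindex(present)
    rows = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            da = scores.loc[scores["pair_class"] == a, "d"].to_numpy()
            db = scores.loc[scores["pair_class"] == b, "d"].to_numpy()
            if len(da) < 2 or len(db) < 2:
                logger.info("skipping contrast %s vs %s: too few scores", a, b)
                continue
            t, p = stats.ttest_ind(da, db)
            rows.append(
                {
                    "class_a": a,
                    "class_b": b,
                    "mean_d_a": float(da.mean()),
                    "mean_d_b": float(db.mean()),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return means, pd.DataFrame(rows)
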