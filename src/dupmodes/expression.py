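"""Within-species expression analysis of duplicate gene pairs.

Similarity between the expression profiles of two genes across samples is
measured by Pearson's correlation coefficient r (Spearman's rho available as
an alternative); expression divergence is d = 1 - r, so d in [0, 2].  A pair
is called *divergent* when its r falls below the 95% quantile of r over
randomly selected gene pairs (the empirical null), and *expression conserved*
when d is below a divergence threshold (default 1 minus the null r quantile).
Replicate samples are never averaged: correlations run across all individual
samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ConstantProfileError",
    "pearson_r",
    "spearman_r",
    "expression_divergence",
    "pair_expression_stats",
    "random_pair_threshold",
    "divergence_proportion",
    "dual_conservation",
    "expression_level",
    "compare_levels",
]


class ConstantProfileError(ValueError):
    """Correlation is undefined for a constant expression profile."""


class ExpressionMatrix:
    """Genes x samples real-valued expression matrix.

    Rows with missing values are dropped on load with a warning; at least
    three samples are required for correlations to be meaningful.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[1] < 3:
            raise ValueError("expression matrix needs >= 3 samples")
        if frame.isna().any().any():
            n0 = len(frame)
            frame = frame.dropna(axis=0)
            logger.warning("dropped %d gene rows with missing values", n0 - len(frame))
        if frame.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        self._frame = frame.astype(float)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Load a TSV whose header holds sample ids and first column gene ids."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self._frame.to_csv(path, sep="\t", index_label="gene_id")

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def gene_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._frame.index

    def __len__(self) -> int:
        return len(self._frame)

    def profile(self, gene_id: str) -> np.ndarray:
        try:
            return self._frame.loc[gene_id].to_numpy()
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length profiles (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if x.size < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("correlation undefined for a constant profile")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.clip(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)), -1.0, 1.0))


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation alternative; highly consistent with Pearson here."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantProfileError("correlation undefined for a constant profile")
    return float(stats.spearmanr(x, y).statistic)


def expression_divergence(r: float) -> float:
    """d = 1 - r, mapping r in [-1, 1] onto d in [0, 2]."""
    return 1.0 - r


def pair_expression_stats(
    matrix: ExpressionMatrix,
    pairs: Iterable[tuple],
    corr: Callable[[Sequence[float], Sequence[float]], float] = pearson_r,
    divergence: Callable[[float], float] = expression_divergence,
) -> pd.DataFrame:
    """Per-pair r and d for every pair whose two genes are in the matrix.

    ``pairs`` yields ``(gene_a, gene_b)`` or ``(gene_a, gene_b, mode)``.
    Pairs with a missing gene or a constant profile are excluded (counted in
    the log).
    """
    rows = []
    n_skipped = 0
    for pair in pairs:
        a, b = pair[0], pair[1]
        mode = pair[2] if len(pair) > 2 else None
        if a not in matrix or b not in matrix:
            n_skipped += 1
            continue
        try:
            r = corr(matrix.profile(a), matrix.profile(b))
        except ConstantProfileError:
            n_skipped += 1
            continue
        rows.append({"gene_a": a, "gene_b": b, "mode": mode, "r": r, "d": divergence(r)})
    if n_skipped:
        logger.warning("excluded %d pairs (missing gene or constant profile)", n_skipped)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "mode", "r", "d"])


def _standardized_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled so that z_i . z_j = r_ij; flags constant rows."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    z = np.zeros_like(centered)
    z[ok] = centered[ok] / norms[ok, None]
    return z, ok


def random_pair_threshold(
    matrix: ExpressionMatrix,
    n_pairs: int = 10_000,
    quantile: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Null r threshold from randomly selected gene pairs.

    Samples ``n_pairs`` distinct unordered non-self gene pairs uniformly
    (without replacement among pairs) and returns the requested quantile of
    their Pearson r.  Constant-profile genes are excluded up front.  When
    fewer pairs exist than requested, all pairs are used with a warning.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z, ok = _standardized_rows(matrix.values)
    if (~ok).any():
        logger.warning("excluded %d constant-profile genes from the null", int((~ok).sum()))
    z = z[ok]
    g = z.shape[0]
    if g < 2:
        raise ValueError("need >= 2 non-constant genes")
    total = g * (g - 1) // 2
    if n_pairs >= total:
        if n_pairs > total:
            logger.warning("only %d distinct pairs available; using all", total)
        idx = np.arange(total)
    else:
        idx = rng.choice(total, size=n_pairs, replace=False)
    # invert the linear index of the upper triangle: pair (i, j), i < j
    i = (g - 2 - np.floor(np.sqrt(-8 * idx + 4 * g * (g - 1) - 7) / 2 - 0.5)).astype(np.int64)
    j = (idx + i + 1 - i * (2 * g - i - 1) // 2).astype(np.int64)
    rs = np.einsum("ij,ij->i", z[i], z[j])
    return float(np.quantile(rs, quantile))


def divergence_proportion(pairs: pd.DataFrame, r_threshold: float) -> pd.Series:
    """Per-mode fraction of pairs with r below the null threshold.

    Empty groups are reported as missing (NaN).
    """
    if "r" not in pairs.columns:
        raise ValueError("pairs frame must carry an 'r' column")
    df = pairs.copy()
    df["divergent"] = df["r"] < r_threshold
    return df.groupby("mode", dropna=False, observed=True)["divergent"].mean()


def dual_conservation(
    pairs: pd.DataFrame,
    ka_quartile: float | None = None,
    d_threshold: float = 0.629,
) -> tuple[pd.Series, float, float]:
    """Per-mode proportion of pairs conserved in both protein sequence and
    expression, plus the independence expectation.

    A pair is dual-conserved when Ka < ``ka_quartile`` (the 25% quantile of
    all valid Ka when not supplied) and d < ``d_threshold``.  The expected
    proportion under independence is the product of the two pooled marginal
    proportions.  Returns ``(per_mode, expected, ka_quartile)``.
    """
    if "ka" not in pairs.columns or "d" not in pairs.columns:
        raise ValueError("pairs frame must carry 'ka' and 'd' columns")
    valid = pairs.dropna(subset=["ka", "d"])
    n_dropped = len(pairs) - len(valid)
    if n_dropped:
        logger.warning("excluded %d pairs lacking valid Ka or d", n_dropped)
    if valid.empty:
        raise ValueError("no pairs with valid Ka and d")
    if ka_quartile is None:
        ka_quartile = float(np.quantile(valid["ka"], 0.25))
    conserved = (valid["ka"] < ka_quartile) & (valid["d"] < d_threshold)
    per_mode = conserved.groupby(valid["mode"], observed=True).mean()
    expected = float((valid["ka"] < ka_quartile).mean() * (valid["d"] < d_threshold).mean())
    return per_mode, expected, ka_quartile


def expression_level(matrix: ExpressionMatrix, gene_id: str | None = None):
    """Mean expression over samples, per gene (Series) or for one gene."""
    means = matrix.frame.mean(axis=1)
    if gene_id is None:
        return means
    if gene_id not in matrix:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    return float(means.loc[gene_id])


def compare_levels(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise two-sample t-tests between named groups of expression levels."""
    names = list(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs >= 2 observations")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = stats.ttest_ind(np.asarray(groups[a], float), np.asarray(groups[b], float))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_a": float(np.mean(groups[a])),
                    "mean_b": float(np.mean(groups[b])),
                    "t": float(t),
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)
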