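"""Gene-pair indicator features and the constancy filter.

The feature space is k-TSP-style relative expression ordering: for an
ordered pair of genes ``(a, b)`` and a sample ``s``, the feature is 1 when
``expr[a, s] > expr[b, s]`` (strict) and 0 otherwise, ties included.  Only
within-sample comparisons are made, so the features — and everything built
on them — are invariant under any strictly increasing per-sample transform
of the expression values.  That rank invariance is what lets a signature
fitted on one platform be applied to another without normalization.

Pairs whose indicator is almost constant across a cohort carry no
discriminative information; the *constancy filter* removes a pair when its
majority value occurs in strictly more than a threshold fraction (default
80%) of samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "IndicatorMatrix",
    "enumerate_pairs",
    "compute_indicators",
    "filter_constant_pairs",
    "build_filtered_indicators",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class FilterConfig:
    """Constancy-filter settings.

    ``constancy_threshold`` is the majority-value fraction above which
    (strictly) a pair is discarded; the default 0.80 removes pairs scoring
    0 or 1 in more than 80% of samples.
    """

    constancy_threshold: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.constancy_threshold < 1.0:
            raise ValueError("constancy_threshold must lie in (0, 1)")


@dataclass
class IndicatorMatrix:
    """Binary pair × sample matrix of within-sample ordering outcomes."""

    pairs: list[Pair]
    sample_ids: list[str]
    values: np.ndarray  # uint8, shape (n_pairs, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("indicator matrix shape does not match id lists")
        if self.values.size and self.values.max() > 1:
            raise ValueError("indicator values must be 0/1")

    @property
    def pair_ids(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.pairs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pair_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "pair"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "IndicatorMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        pairs = [tuple(p.split("|", 1)) for p in df.index]
        return cls(pairs, [str(c) for c in df.columns], df.to_numpy(dtype=np.uint8))


def enumerate_pairs(gene_ids: Sequence[str]) -> list[Pair]:
    """All n(n−1)/2 unordered gene pairs, oriented by input gene order.

    Each unordered pair appears once, as ``(a, b)`` with ``a`` preceding
    ``b`` in ``gene_ids``; the reversed orientation is the complement of the
    indicator and adds nothing.
    """
    ids = list(gene_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("gene_ids contains duplicates")
    if len(ids) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    return list(combinations(ids, 2))


def _pair_index_arrays(m: pd.DataFrame, pairs: Sequence[Pair]) -> tuple[np.ndarray, np.ndarray]:
    loc = {g: i for i, g in enumerate(m.index)}
    ia = np.empty(len(pairs), dtype=np.intp)
    ib = np.empty(len(pairs), dtype=np.intp)
    for k, (a, b) in enumerate(pairs):
        if a not in loc:
            raise KeyError(f"pair gene {a!r} absent from expression matrix")
        if b not in loc:
            raise KeyError(f"pair gene {b!r} absent from expression matrix")
        ia[k], ib[k] = loc[a], loc[b]
    return ia, ib


def compute_indicators(m: pd.DataFrame, pairs: Sequence[Pair]) -> IndicatorMatrix:
    """Score every pair in every sample: 1 iff the first gene is strictly higher.

    Ties score 0 — the indicator is 1 only for a strict "more than".
    """
    pairs = list(pairs)
    ia, ib = _pair_index_arrays(m, pairs)
    x = m.to_numpy(dtype=float)
    values = (x[ia, :] > x[ib, :]).astype(np.uint8)
    return IndicatorMatrix(pairs, [str(c) for c in m.columns], values)


def _constancy_keep_mask(values: np.ndarray, threshold: float) -> np.ndarray:
    f1 = values.mean(axis=1)
    majority = np.maximum(f1, 1.0 - f1)
    return majority <= threshold  # strict ">" removal => "<=" keeps the boundary


def filter_constant_pairs(im: IndicatorMatrix, cfg: FilterConfig = FilterConfig()) -> IndicatorMatrix:
    """Drop pairs whose majority indicator value exceeds the threshold.

    A pair is removed iff max(freq of 0s, freq of 1s) is *strictly* greater
    than ``cfg.constancy_threshold``; a pair constant in exactly the
    threshold fraction of samples is kept.  Surviving pair order is
    preserved.  May return an empty matrix.
    """
    if len(im.sample_ids) == 0:
        raise ValueError("indicator matrix has no samples")
    keep = _constancy_keep_mask(im.values, cfg.constancy_threshold)
    return IndicatorMatrix(
        [p for p, k in zip(im.pairs, keep) if k],
        im.sample_ids,
        im.values[keep],
    )


def build_filtered_indicators(
    m: pd.DataFrame,
    pairs: Sequence[Pair] | None = None,
    cfg: FilterConfig = FilterConfig(),
    chunk_size: int = 200_000,
) -> IndicatorMatrix:
    """Compute indicators and apply the constancy filter in streaming chunks.

    Equivalent to ``filter_constant_pairs(compute_indicators(m, pairs), cfg)``
    but never materializes the full pair × sample matrix: with a full immune
    universe (~2500 genes, ~3.1M pairs) only the filtered survivors are kept
    in memory.
    """
    if pairs is None:
        pairs = enumerate_pairs(list(m.index))
    pairs = list(pairs)
    ia, ib = _pair_index_arrays(m, pairs)
    x = m.to_numpy(dtype=float)
    kept_pairs: list[Pair] = []
    kept_blocks: list[np.ndarray] = []
    for start in range(0, len(pairs), chunk_size):
        sl = slice(start, start + chunk_size)
        block = (x[ia[sl], :] > x[ib[sl], :]).astype(np.uint8)
        keep = _constancy_keep_mask(block, cfg.constancy_threshold)
        if keep.any():
            kept_blocks.append(block[keep])
            kept_pairs.extend(p for p, k in zip(pairs[sl], keep) if k)
    values = (np.vstack(kept_blocks) if kept_blocks
              else np.empty((0, x.shape[1]), dtype=np.uint8))
    return IndicatorMatrix(kept_pairs, [str(c) for c in m.columns], values)
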