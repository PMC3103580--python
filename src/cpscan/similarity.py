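"""Inter-family similarity in CP space against a permutation null.

Families are compared by the Pearson correlation of their feature vectors
(solo CPs plus merged CPs, per-sequence-normalized counts).  Absolute
correlations are small, so significance is judged against a shuffle null:
each feature's per-family values are permuted across families — conserving
every feature's total coverage — the correlations of the shuffled matrix
are pooled over ``n_shuffles`` rounds, and a pair is retained when its
empirical p-value ``(1 + #{null >= r}) / (1 + #null)`` falls below
``p_cut`` (default 0.01, 100 shuffles).

The same analysis can be restricted to one analysis group (Bacteria,
Eukarya, Archaea or Mitochondria): the pipeline from hit location onward is
re-run on that group's sequences only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import GROUPS, SequenceRecord
from .space import (
    CommonPeptide,
    FeatureMatrix,
    build_feature_matrix,
    locate_hits,
    merge_overlaps,
)


def _matrix_values(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, FeatureMatrix) else matrix


def family_correlations(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over family feature vectors.

    A family with a constant feature vector has no defined correlation; its
    off-diagonal entries are set to 0 with a warning.
    """
    values = _matrix_values(matrix)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 families to correlate")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 features to correlate")
    r = _pearson(values.to_numpy(dtype=float))
    return pd.DataFrame(r, index=values.index, columns=values.index)


def _pearson(x: np.ndarray, warn_constant: bool = True) -> np.ndarray:
    n_feat = x.shape[1]
    centered = x - x.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    constant = sd == 0.0
    if constant.any() and warn_constant:
        warnings.warn(
            f"{int(constant.sum())} constant family vector(s); their "
            "correlations are reported as 0",
            stacklevel=3,
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = centered / safe_sd[:, None]
    r = z @ z.T / n_feat
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def iter_shuffled(
    matrix: FeatureMatrix | pd.DataFrame, n_shuffles: int, seed: int
):
    """Yield feature-assignment-shuffled copies of the matrix values.

    Every feature column is permuted across families independently, so
    each feature's total number of appearances is conserved exactly.
    """
    values = _matrix_values(matrix).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    for _ in range(n_shuffles):
        yield rng.permuted(values, axis=0)


def shuffle_null(
    matrix: FeatureMatrix | pd.DataFrame,
    n_shuffles: int = 100,
    seed: int = 0,
    per_pair: bool = False,
) -> np.ndarray:
    """Null correlations from feature-assignment shuffles.

    Each round independently permutes, for every feature, its per-family
    values across families, conserving each feature's total number of
    appearances.  With ``per_pair=False`` (the single-background-model
    default) all off-diagonal upper-triangle correlations are pooled into
    one sample; with ``per_pair=True`` the full correlation matrix of every
    round is returned (shape ``(n_shuffles, F, F)``).
    """
    values = _matrix_values(matrix).to_numpy(dtype=float)
    totals = values.sum(axis=0)
    iu = np.triu_indices(values.shape[0], k=1)
    out = []
    for shuffled in iter_shuffled(matrix, n_shuffles, seed):
        assert np.allclose(shuffled.sum(axis=0), totals)
        r = _pearson(shuffled, warn_constant=False)
        out.append(r if per_pair else r[iu])
    return np.stack(out) if per_pair else np.concatenate(out)


def significant_pairs(
    r: pd.DataFrame,
    null_samples: np.ndarray,
    p_cut: float = 0.01,
) -> pd.DataFrame:
    """Empirical p-values of off-diagonal pairs against the pooled null.

    ``p = (1 + #{null >= r}) / (1 + #null)``; a pair is retained iff
    ``p < p_cut``.  Returns one row per unordered pair with columns
    family_a, family_b, r, p, retained.
    """
    if null_samples.size == 0:
        raise ValueError("null_samples must be non-empty")
    null_sorted = np.sort(null_samples.ravel())
    n_null = null_sorted.size
    rows = []
    families = list(r.index)
    for i, fa in enumerate(families):
        for fb in families[i + 1 :]:
            val = float(r.at[fa, fb])
            n_ge = n_null - int(np.searchsorted(null_sorted, val, side="left"))
            p = (1 + n_ge) / (1 + n_null)
            rows.append((fa, fb, val, p, p < p_cut))
    return pd.DataFrame(rows, columns=["family_a", "family_b", "r", "p", "retained"])


@dataclass(frozen=True)
class SimilarityResult:
    """Correlations, shuffle null and retained pairs for one analysis."""

    r: pd.DataFrame
    null_samples: np.ndarray
    pairs: pd.DataFrame
    n_shuffles: int
    p_cut: float
    seed: int
    group: str | None = None
    dropped_families: tuple[str, ...] = ()

    @property
    def retained_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["retained"]].reset_index(drop=True)


def similarity_analysis(
    matrix: FeatureMatrix | pd.DataFrame,
    n_shuffles: int = 100,
    p_cut: float = 0.01,
    seed: int = 0,
    group: str | None = None,
    dropped_families: Sequence[str] = (),
) -> SimilarityResult:
    """Correlations + pooled shuffle null + retained pairs, in one call."""
    values = _matrix_values(matrix)
    if values.shape[0] < 2:
        # a single family yields no pairs (common in small analysis groups)
        r = pd.DataFrame(1.0, index=values.index, columns=values.index)
        pairs = pd.DataFrame(columns=["family_a", "family_b", "r", "p", "retained"])
        return SimilarityResult(
            r=r,
            null_samples=np.empty(0),
            pairs=pairs,
            n_shuffles=n_shuffles,
            p_cut=p_cut,
            seed=seed,
            group=group,
            dropped_families=tuple(dropped_families),
        )
    r = family_correlations(matrix)
    null = shuffle_null(matrix, n_shuffles=n_shuffles, seed=seed)
    pairs = significant_pairs(r, null, p_cut=p_cut)
    return SimilarityResult(
        r=r,
        null_samples=null,
        pairs=pairs,
        n_shuffles=n_shuffles,
        p_cut=p_cut,
        seed=seed,
        group=group,
        dropped_families=tuple(dropped_families),
    )


def per_kingdom_similarity(
    records: Sequence[SequenceRecord],
    cps: Iterable[CommonPeptide | str],
    group: str,
    n_shuffles: int = 100,
    p_cut: float = 0.01,
    seed: int = 0,
    exclude_families: Sequence[str] = (),
) -> SimilarityResult:
    """Re-run the CP-space similarity pipeline on one analysis group.

    Families with no sequences in the group are dropped and reported in the
    result; ``exclude_families`` removes configured outlier families (the
    rare nonstandard synthetase families, for instance) before correlating.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    subset = [r for r in records if r.group == group and r.family not in exclude_families]
    if not subset:
        available = sorted({r.group for r in records})
        raise ValueError(f"no sequences in group {group!r}; available: {available}")
    all_families = sorted(
        {r.family for r in records if r.family not in exclude_families}
    )
    present = sorted({r.family for r in subset})
    dropped = tuple(f for f in all_families if f not in present)

    hits = locate_hits(cps, subset)
    features, _registry = merge_overlaps(hits, subset)
    matrix = build_feature_matrix(features, subset)
    return similarity_analysis(
        matrix,
        n_shuffles=n_shuffles,
        p_cut=p_cut,
        seed=seed,
        group=group,
        dropped_families=dropped,
    )
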