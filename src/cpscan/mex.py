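"""Deterministic motif extraction via continuation-probability boundaries.

The extractor scans every recurring substring of a family corpus and asks
whether the substring ends (on both sides) at a statistically significant
drop of the continuation probability.  For a candidate ``s = a1..an``:

* the right-continuation probability at position ``i`` is
  ``p_R(i) = c(a1..ai) / c(a1..a(i-1))`` where ``c`` counts all (possibly
  overlapping) occurrences in the corpus;
* a right boundary closes the candidate after its last position when the
  best single-residue continuation declines by more than a factor ``eta``
  — ``p_R(n+1) / p_R(n) < eta`` with ``p_R(n+1) = max_x c(s+x)/c(s)`` —
  and a one-sided binomial test of ``c(s+x*)`` successes in ``c(s)`` trials
  against rate ``eta * p_R(n)`` rejects at level ``alpha``;
* the left boundary applies the same rule to single-residue extensions on
  the left (equivalently, to the reversed strings).

A substring is emitted iff it has both boundaries, its length lies in
``[l_min, l_max]`` and it occurs in at least ``min_support`` distinct
sequences.  Motifs are deterministic strings over the 20-letter alphabet;
the defaults (eta=0.9, alpha=0.01, l_min=5) make length-5-or-longer
conserved peptides the unit of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binom

from .corpus import AMINO_ACIDS, SequenceRecord

# substrings no longer than this are counted exhaustively; longer ones are
# counted only when their leading _SEED_LEN-mer recurs, which preserves the
# exact counts of every substring that occurs at least twice
_SEED_LEN = 8


@dataclass(frozen=True)
class MexParams:
    """Tunable parameters of the boundary detector."""

    eta: float = 0.9
    alpha: float = 0.01
    l_min: int = 5
    l_max: int = 30
    min_support: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must be in (0, 1), got {self.eta}")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not 5 <= self.l_min <= self.l_max:
            raise ValueError(
                f"need 5 <= l_min <= l_max, got l_min={self.l_min} l_max={self.l_max}"
            )
        if self.min_support < 1:
            raise ValueError(f"min_support must be >= 1, got {self.min_support}")


@dataclass
class SubstringCounts:
    """Occurrence counts and distinct-sequence support of recurring substrings.

    ``counts[s]`` is the number of (overlapping) occurrences of ``s`` across
    the corpus and ``support[s]`` the number of distinct sequences containing
    it, for every substring with length <= l_max + 1 occurring at least
    twice.  Lookups of unseen substrings return 0.
    """

    counts: dict[str, int]
    support: dict[str, int]
    l_max: int
    n_sequences: int

    def c(self, s: str) -> int:
        return self.counts.get(s, 0)

    def d(self, s: str) -> int:
        return self.support.get(s, 0)


def _residue_strings(records: Sequence[SequenceRecord] | Sequence[str]) -> list[str]:
    return [r.residues if isinstance(r, SequenceRecord) else r for r in records]


def count_substrings(
    records: Sequence[SequenceRecord] | Sequence[str], l_max: int
) -> SubstringCounts:
    """Exact counts of all substrings of length <= l_max+1 occurring >= 2 times.

    Overlapping self-occurrences are counted (``c("AA")`` in ``"AAAA"`` is 3).
    """
    seqs = _residue_strings(records)
    if not seqs:
        raise ValueError("count_substrings requires a non-empty corpus")
    max_len = l_max + 1
    t = min(_SEED_LEN, max_len)

    # pass 1: which length-t seeds recur anywhere in the corpus
    seed_counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - t + 1):
            k = s[i : i + t]
            seed_counts[k] = seed_counts.get(k, 0) + 1
    recurrent_seeds = {k for k, v in seed_counts.items() if v >= 2}

    counts: dict[str, int] = {}
    support: dict[str, int] = {}
    for s in seqs:
        local: dict[str, int] = {}
        n = len(s)
        for i in range(n):
            stop = min(t, n - i)
            for l in range(1, stop + 1):
                k = s[i : i + l]
                local[k] = local.get(k, 0) + 1
            if n - i >= t and s[i : i + t] in recurrent_seeds:
                stop_long = min(max_len, n - i)
                for l in range(t + 1, stop_long + 1):
                    k = s[i : i + l]
                    local[k] = local.get(k, 0) + 1
        for k, v in local.items():
            counts[k] = counts.get(k, 0) + v
            support[k] = support.get(k, 0) + 1

    counts = {k: v for k, v in counts.items() if v >= 2}
    support = {k: v for k, v in support.items() if k in counts}
    return SubstringCounts(
        counts=counts, support=support, l_max=l_max, n_sequences=len(seqs)
    )


def _has_right_boundary(s: str, sc: SubstringCounts, params: MexParams) -> bool:
    c_s = sc.c(s)
    c_pref = sc.c(s[:-1])
    if c_pref == 0:  # cannot happen for retained substrings; defensive
        return False
    p_here = c_s / c_pref
    best_ext = max(sc.c(s + x) for x in AMINO_ACIDS)
    rate = params.eta * p_here
    if best_ext >= c_s * rate:  # decline-ratio condition p_next/p_here < eta
        return False
    return binom.cdf(best_ext, c_s, rate) < params.alpha


def _has_left_boundary(s: str, sc: SubstringCounts, params: MexParams) -> bool:
    c_s = sc.c(s)
    c_suf = sc.c(s[1:])
    if c_suf == 0:
        return False
    p_here = c_s / c_suf
    best_ext = max(sc.c(x + s) for x in AMINO_ACIDS)
    rate = params.eta * p_here
    if best_ext >= c_s * rate:
        return False
    return binom.cdf(best_ext, c_s, rate) < params.alpha


def extract_motifs(
    records: Sequence[SequenceRecord] | Sequence[str],
    params: MexParams | None = None,
    counts: SubstringCounts | None = None,
) -> set[str]:
    """Extract deterministic motifs from one family corpus.

    Returns the duplicate-free set of substrings bounded on both sides by a
    significant continuation-probability decline, with length in
    ``[l_min, l_max]`` and support of at least ``min_support`` distinct
    sequences.  Precomputed ``counts`` may be supplied to amortize repeated
    extraction from the same corpus.
    """
    params = params or MexParams()
    if counts is None:
        counts = count_substrings(records, params.l_max)
    elif counts.l_max < params.l_max:
        raise ValueError(
            f"counts were built with l_max={counts.l_max} < params.l_max={params.l_max}"
        )

    motifs: set[str] = set()
    for s, d in counts.support.items():
        if d < params.min_support:
            continue
        if not params.l_min <= len(s) <= params.l_max:
            continue
        if _has_right_boundary(s, counts, params) and _has_left_boundary(
            s, counts, params
        ):
            motifs.add(s)
    return motifs


def motif_support(
    motifs: Iterable[str], records: Sequence[SequenceRecord] | Sequence[str]
) -> dict[str, int]:
    """Distinct-sequence support of each motif, by direct search."""
    seqs = _residue_strings(records)
    return {m: sum(1 for s in seqs if m in s) for m in motifs}
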