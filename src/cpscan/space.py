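"""The common-peptide feature space.

Per-family motif lists are unified into one set of common peptides (CPs),
dropping any motif that strictly contains a shorter one (the retained set
is an antichain under the substring relation).  Every CP is then searched
on every sequence — including families it was not extracted from — with an
Aho–Corasick automaton, so the search cost is linear in corpus size.

Because the extractor emits a joined motif whenever two conserved regions
co-occur, overlapping CP hits on one sequence are statistically coupled.
To decouple them, hits on each sequence are grouped into maximal chains of
mutually overlapping spans: a chain of one hit counts toward its solo CP
feature, a chain of two or more counts toward a *merged* feature identified
by the substring spanning the chain, registered globally so identical
overlap patterns on different sequences share one feature.  Each located
hit is accounted for exactly once, either solo or inside a merged chain.

The family x feature matrix holds occurrence counts normalized by family
size and is the input of the similarity analyses.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import SequenceRecord

HIT_COLUMNS = ("seq_id", "cp", "start", "end")
FEATURE_COLUMNS = ("seq_id", "feature", "start", "end", "is_merged", "n_hits")


@dataclass(frozen=True)
class CommonPeptide:
    """A deterministic motif with provenance (families it was extracted from)."""

    motif: str
    source_families: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.motif) < 5:
            raise ValueError(f"common peptide {self.motif!r} shorter than 5 residues")


class AhoCorasick:
    """Multi-pattern exact string matcher over a fixed pattern set.

    Finds every occurrence of every pattern, including overlapping
    occurrences and patterns nested inside other patterns.
    """

    def __init__(self, patterns: Iterable[str]):
        self.patterns = sorted(set(patterns))
        if any(not p for p in self.patterns):
            raise ValueError("empty pattern")
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[int]] = [[]]
        self._fail: list[int] = [0]
        for idx, pat in enumerate(self.patterns):
            node = 0
            for ch in pat:
                nxt = self._goto[node].get(ch)
                if nxt is None:
                    nxt = len(self._goto)
                    self._goto[node][ch] = nxt
                    self._goto.append({})
                    self._out.append([])
                    self._fail.append(0)
                node = nxt
            self._out[node].append(idx)
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def iter_matches(self, text: str):
        """Yield (start, end, pattern) for every occurrence in `text`."""
        node = 0
        for pos, ch in enumerate(text):
            while node and ch not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(ch, 0)
            for idx in self._out[node]:
                pat = self.patterns[idx]
                yield pos + 1 - len(pat), pos + 1, pat


def unify_and_prune(
    per_family_motifs: Mapping[str, Iterable[str]]
) -> list[CommonPeptide]:
    """Merge per-family motif sets and drop strict superstrings.

    Exact duplicates from different families are stored once with merged
    provenance; any motif that strictly contains another motif of the union
    is removed, so the result is an antichain under the substring relation.
    """
    provenance: dict[str, set[str]] = {}
    for family, motifs in per_family_motifs.items():
        for m in motifs:
            if len(m) < 5:
                raise ValueError(f"motif {m!r} from family {family!r} shorter than 5")
            provenance.setdefault(m, set()).add(family)
    if not provenance:
        return []
    ac = AhoCorasick(provenance)
    kept: list[CommonPeptide] = []
    for m in sorted(provenance):
        contains_smaller = any(
            pat != m for _s, _e, pat in ac.iter_matches(m)
        )
        if not contains_smaller:
            kept.append(CommonPeptide(m, frozenset(provenance[m])))
    return kept


def _cp_strings(cps: Iterable[CommonPeptide | str]) -> list[str]:
    return sorted({cp.motif if isinstance(cp, CommonPeptide) else cp for cp in cps})


def locate_hits(
    cps: Iterable[CommonPeptide | str], records: Sequence[SequenceRecord]
) -> pd.DataFrame:
    """Locate every occurrence of every CP on every sequence.

    Spans are 0-based half-open; overlapping occurrences of distinct CPs
    (and overlapping self-occurrences) are all reported.  The result is
    sorted by (seq_id, start, end, cp) and thus invariant to CP and record
    order.
    """
    patterns = _cp_strings(cps)
    rows: list[tuple[str, str, int, int]] = []
    if patterns:
        ac = AhoCorasick(patterns)
        for rec in records:
            for start, end, pat in ac.iter_matches(rec.residues):
                rows.append((rec.id, pat, start, end))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(list(HIT_COLUMNS)).reset_index(drop=True)


def merge_overlaps(
    hits: pd.DataFrame, records: Sequence[SequenceRecord]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Group overlapping hits into merged features, counting each hit once.

    Per sequence, hits sorted by position form maximal chains in which each
    hit shares at least one residue with the running union of its chain
    (book-ended adjacent hits do not merge).  A single-hit chain increments
    its solo CP feature; a chain of two or more increments a merged feature
    named by the spanning substring of the sequence.

    Returns the feature hit table (one row per counted chain) and the
    global registry of merged features with their occurrence totals.
    """
    seq_by_id = {r.id: r.residues for r in records}
    unknown = set(hits["seq_id"]) - set(seq_by_id)
    if unknown:
        raise KeyError(f"hits reference unknown sequence ids: {sorted(unknown)[:5]}")

    rows: list[tuple[str, str, int, int, bool, int]] = []
    registry: dict[str, int] = {}
    for seq_id, group in hits.groupby("seq_id", sort=True):
        seq = seq_by_id[seq_id]
        spans = sorted(
            zip(group["start"], group["end"], group["cp"]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        chain: list[tuple[int, int, str]] = []
        chain_end = -1

        def flush() -> None:
            if not chain:
                return
            start = chain[0][0]
            end = max(e for _s, e, _c in chain)
            if len(chain) == 1:
                rows.append((seq_id, chain[0][2], start, end, False, 1))
            else:
                merged = seq[start:end]
                rows.append((seq_id, merged, start, end, True, len(chain)))
                registry[merged] = registry.get(merged, 0) + 1

        for span in spans:
            if chain and span[0] < chain_end:
                chain.append(span)
                chain_end = max(chain_end, span[1])
            else:
                flush()
                chain = [span]
                chain_end = span[1]
        flush()

    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    features = features.sort_values(["seq_id", "start", "end"]).reset_index(drop=True)
    return features, registry


@dataclass(frozen=True)
class FeatureMatrix:
    """Families x features occurrence matrix, normalized by family size."""

    values: pd.DataFrame
    merged_features: frozenset[str]

    @property
    def families(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def build_feature_matrix(
    features: pd.DataFrame, records: Sequence[SequenceRecord]
) -> FeatureMatrix:
    """Tabulate counted feature occurrences per family / family size."""
    family_of = {r.id: r.family for r in records}
    unknown = set(features["seq_id"]) - set(family_of)
    if unknown:
        raise KeyError(
            f"features reference unknown sequence ids: {sorted(unknown)[:5]}"
        )
    family_sizes: dict[str, int] = {}
    for r in records:
        family_sizes[r.family] = family_sizes.get(r.family, 0) + 1

    families = sorted(family_sizes)
    feat_names = sorted(features["feature"].unique())
    counts = pd.DataFrame(0.0, index=families, columns=feat_names)
    for seq_id, feature in zip(features["seq_id"], features["feature"]):
        counts.at[family_of[seq_id], feature] += 1.0
    for fam in families:
        counts.loc[fam] /= family_sizes[fam]
    merged = frozenset(features.loc[features["is_merged"], "feature"])
    return FeatureMatrix(values=counts, merged_features=merged)


def write_cp_list(cps: Sequence[CommonPeptide], path: str | Path) -> None:
    """Write CPs as `motif<TAB>comma-separated source families`."""
    with open(path, "w") as fh:
        for cp in sorted(cps, key=lambda c: c.motif):
            fh.write(f"{cp.motif}\t{','.join(sorted(cp.source_families))}\n")


def read_cp_list(path: str | Path) -> list[CommonPeptide]:
    cps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                motif, families = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed CP row {line!r}") from exc
            cps.append(CommonPeptide(motif, frozenset(families.split(","))))
    return cps
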