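"""Functional-site overlap and cross-family motif sharing.

*Prevalent* CPs — present in more than half of the sequences of at least
one family — are the candidates for functional relevance.  Their hits are
compared with a table of annotated catalytic/binding residues: a CP is an
*exact* overlap when some hit covers an annotated position, a *vicinity*
overlap when the nearest site lies within ``max_dist`` residues of a hit
boundary, and significance is an upper-tail hypergeometric test drawing
the prevalent CPs from the urn of all CPs hitting annotated sequences.

The second analysis relates two independently processed corpora (for
instance a synthetase superfamily and a structurally similar outgroup
enzyme): CPs shared by exact match or full inclusion, filtered by a
minimum per-corpus prevalence, with an optional grouping of one-mutation
(equal-length, Hamming-distance-1) variants.  A residue-shuffle control
re-extracts motifs from within-sequence permuted corpora, where a real
corpus's deterministic motifs should all but vanish.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .corpus import SequenceRecord
from .mex import MexParams, extract_motifs, motif_support
from .space import AhoCorasick, CommonPeptide, _cp_strings

SITE_COLUMNS = ("seq_id", "position", "site_type", "ligand", "priority")
SITE_TYPES = ("catalytic", "binding")


def read_sites(
    path: str | Path, records: Sequence[SequenceRecord] | None = None
) -> pd.DataFrame:
    """Read the site-annotation TSV (seq_id, position, site_type, ligand[, priority]).

    Positions are 0-based residue indices; ``priority`` (smaller = higher
    priority, default 1) selects which annotated sequence represents a
    family.  When ``records`` are given, positions are bounds-checked.
    """
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (
                        row["seq_id"],
                        int(row["position"]),
                        row["site_type"],
                        row["ligand"],
                        int(row.get("priority") or 1),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed site row") from exc
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if records is not None:
        validate_sites(sites, records)
    return sites


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False, columns=list(SITE_COLUMNS))


def validate_sites(sites: pd.DataFrame, records: Sequence[SequenceRecord]) -> None:
    lengths = {r.id: len(r.residues) for r in records}
    for seq_id, pos in zip(sites["seq_id"], sites["position"]):
        if seq_id not in lengths:
            raise KeyError(f"site on unknown sequence {seq_id!r}")
        if not 0 <= pos < lengths[seq_id]:
            raise ValueError(
                f"site position {pos} outside sequence {seq_id!r} "
                f"(length {lengths[seq_id]})"
            )


def prevalent_cps(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    threshold: float = 0.5,
    stop_list: Sequence[str] = (),
) -> list[str]:
    """CPs present in more than `threshold` of some family's sequences.

    Presence counts any hit, solo or absorbed into a merged chain; the
    inequality is strict (exactly half does not qualify).  CPs containing a
    stop-list motif (configured known signatures) are removed.
    """
    family_of = {r.id: r.family for r in records}
    unknown = set(hits["seq_id"]) - set(family_of)
    if unknown:
        raise KeyError(f"hits reference unknown sequence ids: {sorted(unknown)[:5]}")
    family_sizes: dict[str, int] = {}
    for r in records:
        family_sizes[r.family] = family_sizes.get(r.family, 0) + 1
    seq_sets: dict[str, dict[str, set[str]]] = {}
    for seq_id, cp in zip(hits["seq_id"], hits["cp"]):
        seq_sets.setdefault(cp, {}).setdefault(family_of[seq_id], set()).add(seq_id)
    out = []
    for cp in sorted(seq_sets):
        if any(stop in cp for stop in stop_list):
            continue
        if any(
            len(seqs) > threshold * family_sizes[fam]
            for fam, seqs in seq_sets[cp].items()
        ):
            out.append(cp)
    return out


def select_annotated_sequences(
    sites: pd.DataFrame, records: Sequence[SequenceRecord]
) -> dict[str, str]:
    """Pick one annotated sequence per family: best (smallest) priority, then id."""
    family_of = {r.id: r.family for r in records}
    best: dict[str, tuple[int, str]] = {}
    for seq_id, priority in zip(sites["seq_id"], sites["priority"]):
        if seq_id not in family_of:
            raise KeyError(f"site on unknown sequence {seq_id!r}")
        fam = family_of[seq_id]
        key = (int(priority), seq_id)
        if fam not in best or key < best[fam]:
            best[fam] = key
    return {fam: seq_id for fam, (_p, seq_id) in best.items()}


def hit_site_distance(start: int, end: int, position: int) -> int:
    """Residue distance between a hit span [start, end) and a site position.

    0 when the site lies inside the span; otherwise the number of residues
    strictly between the site and the nearer span boundary.
    """
    if start <= position < end:
        return 0
    if position >= end:
        return position - end
    return start - position - 1


@dataclass(frozen=True)
class OverlapReport:
    """Per-CP nearest-site distances on the selected annotated sequences."""

    table: pd.DataFrame  # columns: cp, min_distance, classification
    max_dist: int
    selected_sequences: Mapping[str, str]  # family -> seq_id

    def cps_with(self, classification: str) -> list[str]:
        t = self.table
        return sorted(t.loc[t["classification"] == classification, "cp"])


def site_overlap(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    sites: pd.DataFrame,
    max_dist: int = 3,
    restrict_to_priority: bool = True,
) -> OverlapReport:
    """Classify each CP by its nearest annotated site.

    Only the highest-priority annotated sequence of each family is
    consulted (``restrict_to_priority=False`` uses every annotated
    sequence).  A CP is classified over all annotated sequences it hits:
    ``exact`` when some hit covers a site, ``vicinity`` when the minimum
    distance is at most ``max_dist``, else ``none``.  CPs with no hits on
    annotated sequences are absent from the report.
    """
    validate_sites(sites, records)
    if restrict_to_priority:
        selected = select_annotated_sequences(sites, records)
        chosen = set(selected.values())
        sites = sites[sites["seq_id"].isin(chosen)]
    else:
        family_of = {r.id: r.family for r in records}
        selected = {}
        for seq_id in sites["seq_id"]:
            selected.setdefault(family_of[seq_id] + "/" + seq_id, seq_id)
        chosen = set(sites["seq_id"])

    site_positions: dict[str, list[int]] = {}
    for seq_id, pos in zip(sites["seq_id"], sites["position"]):
        site_positions.setdefault(seq_id, []).append(int(pos))

    dist: dict[str, int] = {}
    sub = hits[hits["seq_id"].isin(chosen)]
    for seq_id, cp, start, end in zip(
        sub["seq_id"], sub["cp"], sub["start"], sub["end"]
    ):
        for pos in site_positions.get(seq_id, ()):
            d = hit_site_distance(int(start), int(end), pos)
            if cp not in dist or d < dist[cp]:
                dist[cp] = d

    rows = []
    for cp in sorted(dist):
        d = dist[cp]
        label = "exact" if d == 0 else ("vicinity" if d <= max_dist else "none")
        rows.append((cp, d, label))
    table = pd.DataFrame(rows, columns=["cp", "min_distance", "classification"])
    return OverlapReport(table=table, max_dist=max_dist, selected_sequences=selected)


def overlap_significance(
    report: OverlapReport, prevalent: Iterable[str], mode: str = "exact"
) -> dict[str, float | int]:
    """Hypergeometric enrichment of site overlap among prevalent CPs.

    Urn: all CPs hitting annotated sequences (the report's rows, ``N``);
    successes: those classified ``exact`` (or ``exact``+``vicinity`` for
    ``mode="vicinity"``), ``K``; draw: the prevalent CPs present in the
    urn, ``n``, with ``k`` successes.  Returns N, K, n, k and the
    upper-tail p-value.
    """
    if mode not in ("exact", "vicinity"):
        raise ValueError(f"mode must be 'exact' or 'vicinity', got {mode!r}")
    urn = set(report.table["cp"])
    if not urn:
        raise ValueError("empty urn: no CPs hit annotated sequences")
    good_labels = {"exact"} if mode == "exact" else {"exact", "vicinity"}
    successes = {
        cp
        for cp, label in zip(report.table["cp"], report.table["classification"])
        if label in good_labels
    }
    draw = set(prevalent) & urn
    k = len(draw & successes)
    n_pop, n_succ, n_draw = len(urn), len(successes), len(draw)
    p = float(hypergeom.sf(k - 1, n_pop, n_succ, n_draw))
    return {"N": n_pop, "K": n_succ, "n": n_draw, "k": k, "p": p}


def _distinct_seq_counts(
    patterns: Sequence[str], records: Sequence[SequenceRecord]
) -> dict[str, int]:
    if not patterns:
        return {}
    ac = AhoCorasick(patterns)
    counts = {p: 0 for p in patterns}
    for rec in records:
        seen = {pat for _s, _e, pat in ac.iter_matches(rec.residues)}
        for pat in seen:
            counts[pat] += 1
    return counts


def cross_family_shared(
    cps_a: Iterable[CommonPeptide | str],
    cps_b: Iterable[CommonPeptide | str],
    records_a: Sequence[SequenceRecord],
    records_b: Sequence[SequenceRecord],
    min_seqs: int = 20,
) -> pd.DataFrame:
    """CPs shared between two corpora by exact match or full inclusion.

    A pair is shared when the strings are equal or one is a substring of
    the other; the reported match string is the shorter of the two.  A
    shared match is kept when it occurs in at least ``min_seqs`` distinct
    sequences of *each* corpus.  The result is symmetric in (a, b) up to
    the column naming.
    """
    strings_a = _cp_strings(cps_a)
    strings_b = _cp_strings(cps_b)
    pairs: dict[str, set[tuple[str, str]]] = {}
    if strings_a and strings_b:
        ac_a = AhoCorasick(strings_a)
        for b in strings_b:
            for _s, _e, a in ac_a.iter_matches(b):
                pairs.setdefault(a, set()).add((a, b))
        ac_b = AhoCorasick(strings_b)
        for a in strings_a:
            for _s, _e, b in ac_b.iter_matches(a):
                pairs.setdefault(b, set()).add((a, b))
    matches = sorted(pairs)
    counts_a = _distinct_seq_counts(matches, records_a)
    counts_b = _distinct_seq_counts(matches, records_b)
    rows = []
    for match in matches:
        cps_in_a = sorted({a for a, _b in pairs[match]})
        cps_in_b = sorted({b for _a, b in pairs[match]})
        na, nb = counts_a[match], counts_b[match]
        rows.append(
            (match, ";".join(cps_in_a), ";".join(cps_in_b), na, nb,
             na >= min_seqs and nb >= min_seqs)
        )
    return pd.DataFrame(
        rows, columns=["match", "cps_a", "cps_b", "n_seqs_a", "n_seqs_b", "kept"]
    )


def hamming1_groups(strings: Iterable[str]) -> list[list[str]]:
    """Group equal-length strings connected by single-substitution steps."""
    items = sorted(set(strings))
    index = {s: i for i, s in enumerate(items)}
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, s in enumerate(items):
        for j in range(i + 1, len(items)):
            t = items[j]
            if len(s) == len(t) and sum(a != b for a, b in zip(s, t)) == 1:
                parent[find(i)] = find(index[t])
    groups: dict[int, list[str]] = {}
    for i, s in enumerate(items):
        groups.setdefault(find(i), []).append(s)
    return sorted(groups.values())


def shuffle_residues(
    records: Sequence[SequenceRecord], rng: np.random.Generator
) -> list[str]:
    """Independently permute the residues of each sequence.

    Lengths and per-sequence residue compositions are conserved exactly.
    """
    return ["".join(rng.permutation(list(r.residues))) for r in records]


def shuffle_control(
    records: Sequence[SequenceRecord],
    params: MexParams | None = None,
    n_shuffles: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif extraction from within-sequence residue-shuffled corpora.

    Each round independently permutes the residues of every sequence
    (conserving length and composition), re-runs the extractor, and
    records the number of motifs and the maximal distinct-sequence support.
    Deterministic motifs of a real corpus should essentially disappear.
    """
    params = params or MexParams()
    rng = np.random.default_rng(seed)
    rows = []
    for shuffle in range(n_shuffles):
        shuffled = shuffle_residues(records, rng)
        motifs = extract_motifs(shuffled, params)
        max_support = max(motif_support(motifs, shuffled).values(), default=0)
        rows.append((shuffle, len(motifs), max_support))
    return pd.DataFrame(rows, columns=["shuffle", "n_motifs", "max_support"])
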