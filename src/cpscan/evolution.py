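"""Evolutionary analyses in CP space.

Four questions are answered from the raw CP hit table plus taxonomy
metadata:

* **Kingdom statistics** — which fraction of all CPs is observed in each
  analysis group (Bacteria/Eukarya/Archaea/Mitochondria), and which
  fraction of those is specific to that group alone.
* **Origin classification** — under the tree-of-life topology in which
  Bacteria is an outgroup of Archaea and Eukarya, each CP's presence set
  over the three kingdoms (mitochondria excluded) maps to an origin label:
  all three kingdoms, the joint Archaea+Eukarya node, a single kingdom, or
  the Bacteria+Eukarya set.
* **Mitochondrial enrichment** — per family, CPs hitting only one kingdom
  within the family's nuclear sequences are "kingdom-specific"; a
  hypergeometric test asks whether the CPs that also hit the family's
  mitochondrial sequences are enriched in each kingdom-specific list, with
  Benjamini–Hochberg FDR control across the full family x kingdom grid.
* **Class signatures and shared origins** — CPs that occur preferentially
  in one structural class across at least ``min_families`` families, and
  CPs exclusively shared by a chosen subset of same-class families with an
  exhaustive same-size-subset null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .corpus import GROUPS, KINGDOMS, SequenceRecord

ORIGIN_LABELS = ("ALL3", "AE", "B_only", "A_only", "E_only", "BE", "other")

_ORIGIN_MAP = {
    frozenset(KINGDOMS): "ALL3",
    frozenset({"Archaea", "Eukarya"}): "AE",
    frozenset({"Bacteria"}): "B_only",
    frozenset({"Archaea"}): "A_only",
    frozenset({"Eukarya"}): "E_only",
    frozenset({"Bacteria", "Eukarya"}): "BE",
    frozenset({"Bacteria", "Archaea"}): "other",
}


def _record_maps(records: Sequence[SequenceRecord]):
    group_of = {r.id: r.group for r in records}
    family_of = {r.id: r.family for r in records}
    return group_of, family_of


def _check_hits(hits: pd.DataFrame, known_ids: set[str]) -> None:
    unknown = set(hits["seq_id"]) - known_ids
    if unknown:
        raise KeyError(f"hits reference unknown sequence ids: {sorted(unknown)[:5]}")


def kingdom_cp_stats(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    all_cps: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-group CP presence and specificity percentages.

    For every analysis group: the number of proteins, the percentage of all
    CPs observed in the group, and the percentage of the group's observed
    CPs seen nowhere else.
    """
    group_of, _ = _record_maps(records)
    _check_hits(hits, set(group_of))
    cps = sorted(set(all_cps)) if all_cps is not None else sorted(set(hits["cp"]))
    presence: dict[str, set[str]] = {g: set() for g in GROUPS}
    for seq_id, cp in zip(hits["seq_id"], hits["cp"]):
        presence[group_of[seq_id]].add(cp)
    n_proteins = {g: 0 for g in GROUPS}
    for r in records:
        n_proteins[r.group] += 1
    rows = []
    total = len(cps)
    for g in GROUPS:
        observed = presence[g] & set(cps)
        elsewhere = set().union(*(presence[h] for h in GROUPS if h != g))
        specific = observed - elsewhere
        rows.append(
            (
                g,
                n_proteins[g],
                len(observed),
                100.0 * len(observed) / total if total else 0.0,
                len(specific),
                100.0 * len(specific) / len(observed) if observed else 0.0,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_proteins",
            "n_cps_observed",
            "pct_of_all_cps",
            "n_specific_cps",
            "pct_specific",
        ],
    ).set_index("group")


def classify_origin(presence: Iterable[str]) -> str:
    """Map a CP's kingdom presence set to its origin label.

    Mitochondria are excluded from origin sets; the presence set must be a
    non-empty subset of the three kingdoms.
    """
    ps = frozenset(presence)
    if not ps:
        raise ValueError("empty presence set has no origin")
    unknown = ps - set(KINGDOMS)
    if unknown:
        raise ValueError(f"unknown kingdoms in presence set: {sorted(unknown)}")
    return _ORIGIN_MAP[ps]


def origin_distribution(
    hits: pd.DataFrame, records: Sequence[SequenceRecord]
) -> pd.DataFrame:
    """Per-family counts of CPs in each origin set (kingdom hits only)."""
    group_of, family_of = _record_maps(records)
    _check_hits(hits, set(group_of))
    presence: dict[str, set[str]] = {}
    cp_families: dict[str, set[str]] = {}
    for seq_id, cp in zip(hits["seq_id"], hits["cp"]):
        g = group_of[seq_id]
        if g in KINGDOMS:
            presence.setdefault(cp, set()).add(g)
        cp_families.setdefault(cp, set()).add(family_of[seq_id])
    families = sorted({r.family for r in records})
    table = pd.DataFrame(0, index=families, columns=list(ORIGIN_LABELS))
    for cp, ps in presence.items():
        label = classify_origin(ps)
        for fam in cp_families[cp]:
            table.at[fam, label] += 1
    return table


def _family_kingdom_presence(
    hits: pd.DataFrame, records: Sequence[SequenceRecord]
) -> tuple[dict[str, dict[str, set[str]]], dict[str, set[str]]]:
    """Per family: cp -> kingdoms hit on nuclear sequences; and mito CP sets."""
    group_of, family_of = _record_maps(records)
    _check_hits(hits, set(group_of))
    nuclear: dict[str, dict[str, set[str]]] = {}
    mito: dict[str, set[str]] = {}
    for seq_id, cp in zip(hits["seq_id"], hits["cp"]):
        fam = family_of[seq_id]
        g = group_of[seq_id]
        if g == "Mitochondria":
            mito.setdefault(fam, set()).add(cp)
        else:
            nuclear.setdefault(fam, {}).setdefault(cp, set()).add(g)
    return nuclear, mito


def family_kingdom_specific_cps(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    family: str,
    kingdom: str,
) -> list[str]:
    """CPs hitting the family's nuclear sequences in exactly one kingdom.

    The same CP may well occur in other kingdoms within *other* families;
    specificity is judged within the named family only.
    """
    if kingdom not in KINGDOMS:
        raise ValueError(f"kingdom must be one of {KINGDOMS}, got {kingdom!r}")
    families = {r.family for r in records}
    if family not in families:
        raise ValueError(f"unknown family {family!r}")
    nuclear, _mito = _family_kingdom_presence(hits, records)
    cp_kingdoms = nuclear.get(family, {})
    return sorted(cp for cp, ks in cp_kingdoms.items() if ks == {kingdom})


def family_taxon_specific_cps(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    family: str,
    taxon: str,
) -> list[str]:
    """CPs whose nuclear hits in the family fall only on one taxon's sequences.

    The optional header taxon tag supports sub-kingdom analyses (for
    instance restricting a bacterial signal to one bacterial class) without
    consulting any external species list.  Records without a taxon tag
    count as their own (unnamed) taxon.
    """
    families = {r.family for r in records}
    if family not in families:
        raise ValueError(f"unknown family {family!r}")
    taxon_of = {r.id: (r.taxon or "") for r in records}
    in_family = {r.id for r in records if r.family == family and r.group != "Mitochondria"}
    _check_hits(hits, {r.id for r in records})
    cp_taxa: dict[str, set[str]] = {}
    for seq_id, cp in zip(hits["seq_id"], hits["cp"]):
        if seq_id in in_family:
            cp_taxa.setdefault(cp, set()).add(taxon_of[seq_id])
    return sorted(cp for cp, taxa in cp_taxa.items() if taxa == {taxon})


@dataclass(frozen=True)
class EnrichmentResult:
    """One family x kingdom hypergeometric enrichment test."""

    family: str
    kingdom: str
    population: int  # N: CPs hitting the family's nuclear sequences
    successes: int  # K: kingdom-specific CPs among them
    sample: int  # n: mito-hitting CPs drawn from the population
    sample_successes: int  # k
    p: float
    q: float | None = None
    enriched: bool | None = None


def mito_enrichment(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    fdr: float = 0.01,
    universe: str = "nuclear",
) -> tuple[pd.DataFrame, list[str]]:
    """Kingdom enrichment of each family's mitochondrial CPs.

    For every family with mitochondrial sequences and every kingdom: the
    urn holds the CPs hitting the family's nuclear sequences (``N``), of
    which the kingdom-specific ones are successes (``K``); the draw is the
    set of CPs hitting the family's mitochondrial sequences that also hit
    its nuclear sequences (``n``), with ``k`` of them kingdom-specific.
    The upper-tail hypergeometric p-values are BH-adjusted across the whole
    family x kingdom grid; a test is enriched iff ``q < fdr``.

    ``universe="all"`` widens the urn to every CP hitting the family
    (mitochondrial-only CPs included).  Families without mitochondrial
    sequences are skipped and returned in the second element.
    """
    if universe not in ("nuclear", "all"):
        raise ValueError(f"universe must be 'nuclear' or 'all', got {universe!r}")
    nuclear, mito = _family_kingdom_presence(hits, records)
    families = sorted({r.family for r in records})
    mito_families = sorted({r.family for r in records if r.group == "Mitochondria"})
    skipped = [f for f in families if f not in mito_families]

    results: list[EnrichmentResult] = []
    for family in mito_families:
        cp_kingdoms = nuclear.get(family, {})
        mito_cps = mito.get(family, set())
        if universe == "nuclear":
            population = set(cp_kingdoms)
            sample = mito_cps & population
        else:
            population = set(cp_kingdoms) | mito_cps
            sample = mito_cps
        for kingdom in KINGDOMS:
            specific = {
                cp for cp, ks in cp_kingdoms.items() if ks == {kingdom}
            } & population
            n_pop, n_succ = len(population), len(specific)
            n_sample, k = len(sample), len(sample & specific)
            p = float(hypergeom.sf(k - 1, n_pop, n_succ, n_sample)) if n_pop else 1.0
            results.append(
                EnrichmentResult(family, kingdom, n_pop, n_succ, n_sample, k, p)
            )

    df = pd.DataFrame(
        [
            (r.family, r.kingdom, r.population, r.successes, r.sample,
             r.sample_successes, r.p)
            for r in results
        ],
        columns=["family", "kingdom", "N", "K", "n", "k", "p"],
    )
    if len(df):
        _rej, q, _a, _b = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["q"] = q
        df["enriched"] = df["q"] < fdr
    else:
        df["q"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df, skipped


@dataclass(frozen=True)
class ClassSignature:
    """A CP occurring preferentially in one structural class."""

    cp: str
    preferred_class: str
    families_I: int
    occurrences_I: int
    families_II: int
    occurrences_II: int


def _class_of(records: Sequence[SequenceRecord], class_map: Mapping[str, str] | None):
    out: dict[str, str] = {}
    for r in records:
        label = r.class_label
        if class_map is not None and r.family in class_map:
            label = class_map[r.family]
        if label not in ("I", "II"):
            raise ValueError(f"family {r.family!r} has no class I/II label")
        prev = out.setdefault(r.family, label)
        if prev != label:
            raise ValueError(f"family {r.family!r} maps to both classes")
    return out


def class_signatures(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    class_map: Mapping[str, str] | None = None,
    min_families: int = 6,
    max_other_families: int = 2,
    stop_list: Sequence[str] = ("KMSKS", "HIGH"),
) -> list[ClassSignature]:
    """CPs that preferentially occur in one class, across many families.

    A CP qualifies for class X when it appears in at least ``min_families``
    class-X families, in at most ``max_other_families`` families of the
    other class, and its other-class occurrences number at most
    ``max(3, 5%)`` of its total occurrences.  CPs containing a stop-list
    motif (known class signatures) are omitted.
    """
    family_class = _class_of(records, class_map)
    _group_of, family_of = _record_maps(records)
    _check_hits(hits, set(family_of))
    fam_sets: dict[str, dict[str, set[str]]] = {}
    occ: dict[str, dict[str, int]] = {}
    for seq_id, cp in zip(hits["seq_id"], hits["cp"]):
        cls = family_class[family_of[seq_id]]
        fam_sets.setdefault(cp, {"I": set(), "II": set()})[cls].add(family_of[seq_id])
        occ.setdefault(cp, {"I": 0, "II": 0})
        occ[cp][cls] += 1

    signatures: list[ClassSignature] = []
    for cp in sorted(fam_sets):
        if any(stop in cp for stop in stop_list):
            continue
        n_fam = {c: len(fam_sets[cp][c]) for c in ("I", "II")}
        n_occ = occ[cp]
        total = n_occ["I"] + n_occ["II"]
        for cls, other in (("I", "II"), ("II", "I")):
            if (
                n_fam[cls] >= min_families
                and n_fam[other] <= max_other_families
                and n_occ[other] <= max(3, 0.05 * total)
            ):
                signatures.append(
                    ClassSignature(
                        cp=cp,
                        preferred_class=cls,
                        families_I=n_fam["I"],
                        occurrences_I=n_occ["I"],
                        families_II=n_fam["II"],
                        occurrences_II=n_occ["II"],
                    )
                )
    return signatures


@dataclass(frozen=True)
class ExclusiveSharedResult:
    """CPs exclusive to a family subset, with the exhaustive subset null."""

    subset: tuple[str, ...]
    cps: tuple[str, ...]
    subset_counts: Mapping[frozenset, int]  # every same-size same-class subset

    @property
    def max_other(self) -> int:
        others = [
            v for k, v in self.subset_counts.items() if k != frozenset(self.subset)
        ]
        return max(others) if others else 0


def exclusive_shared_cps(
    hits: pd.DataFrame,
    records: Sequence[SequenceRecord],
    family_subset: Sequence[str],
    class_map: Mapping[str, str] | None = None,
) -> ExclusiveSharedResult:
    """CPs hitting every family of the subset and no other family.

    The null is computed exhaustively: the count of exclusive-shared CPs
    for every equal-size subset of the same structural class.
    """
    subset = tuple(sorted(set(family_subset)))
    if len(subset) < 2:
        raise ValueError("family_subset must contain at least 2 families")
    family_class = _class_of(records, class_map)
    missing = [f for f in subset if f not in family_class]
    if missing:
        raise ValueError(f"unknown families: {missing}")
    classes = {family_class[f] for f in subset}
    if len(classes) != 1:
        raise ValueError(f"family_subset spans both classes: {sorted(classes)}")
    cls = classes.pop()

    _group_of, family_of = _record_maps(records)
    _check_hits(hits, set(family_of))
    cp_families: dict[str, set[str]] = {}
    for seq_id, cp in zip(hits["seq_id"], hits["cp"]):
        cp_families.setdefault(cp, set()).add(family_of[seq_id])

    class_families = sorted(f for f, c in family_class.items() if c == cls)
    counts: dict[frozenset, int] = {}
    for combo in combinations(class_families, len(subset)):
        key = frozenset(combo)
        counts[key] = sum(1 for fams in cp_families.values() if fams == key)
    target = frozenset(subset)
    cps = tuple(sorted(cp for cp, fams in cp_families.items() if fams == target))
    return ExclusiveSharedResult(subset=subset, cps=cps, subset_counts=counts)
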