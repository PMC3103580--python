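"""Corpus I/O, taxonomy metadata and redundancy reduction.

Protein sequences travel in a self-contained FASTA dialect whose header
carries all the metadata the downstream analyses need::

    >id|family|kingdom|organelle[|taxon]

with ``kingdom`` one of Bacteria/Eukarya/Archaea and ``organelle`` one of
``nuclear``/``mito``.  The pair (kingdom, organelle) defines the four
analysis groups: the three kingdoms plus Mitochondria as a separate group.

Redundancy reduction mirrors the usual strain-collapse step of comparative
protein studies: pairwise local-alignment identity, single-linkage
clustering at a 90% threshold within each family, and one representative
per cluster (the member with maximal average identity to the rest).
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")

KINGDOMS = ("Bacteria", "Eukarya", "Archaea")
GROUPS = KINGDOMS + ("Mitochondria",)
ORGANELLES = ("nuclear", "mito")
CLASS_LABELS = ("I", "II", "unknown")


class CorpusError(ValueError):
    """Malformed corpus input (header, residues or metadata)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its taxonomy metadata."""

    id: str
    family: str
    kingdom: str
    organelle: str
    residues: str
    class_label: str = "unknown"
    taxon: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise CorpusError(f"record {self.id!r}: empty residue string")
        if self.kingdom not in KINGDOMS:
            raise CorpusError(
                f"record {self.id!r}: kingdom {self.kingdom!r} not in {KINGDOMS}"
            )
        if self.organelle not in ORGANELLES:
            raise CorpusError(
                f"record {self.id!r}: organelle {self.organelle!r} not in {ORGANELLES}"
            )
        if self.class_label not in CLASS_LABELS:
            raise CorpusError(
                f"record {self.id!r}: class_label {self.class_label!r} not in {CLASS_LABELS}"
            )
        bad = set(self.residues) - _AA_SET - {"X"}
        if bad:
            raise CorpusError(
                f"record {self.id!r}: residues outside the 20-letter alphabet: "
                f"{''.join(sorted(bad))}"
            )

    @property
    def group(self) -> str:
        """Analysis group: Mitochondria if organellar, else the kingdom."""
        return "Mitochondria" if self.organelle == "mito" else self.kingdom

    def header(self) -> str:
        parts = [self.id, self.family, self.kingdom, self.organelle]
        if self.taxon:
            parts.append(self.taxon)
        return "|".join(parts)


def _parse_header(header: str, index: int) -> dict:
    parts = header.split("|")
    if len(parts) not in (4, 5):
        raise CorpusError(
            f"record {index}: header {header!r} must have 4 or 5 '|'-separated "
            "fields (id|family|kingdom|organelle[|taxon])"
        )
    if any(not p for p in parts[:4]):
        raise CorpusError(f"record {index}: header {header!r} has an empty field")
    fields = dict(id=parts[0], family=parts[1], kingdom=parts[2], organelle=parts[3])
    if len(parts) == 5:
        fields["taxon"] = parts[4]
    return fields


def read_corpus(
    path: str | Path,
    class_map: Mapping[str, str] | None = None,
    map_ambiguous: bool = False,
) -> list[SequenceRecord]:
    """Parse the FASTA dialect into SequenceRecords, preserving file order.

    Parameters
    ----------
    class_map
        Optional family -> class label ("I"/"II") mapping; families missing
        from the map get ``"unknown"``.  The header dialect itself does not
        carry the class.
    map_ambiguous
        If True, ambiguous residue codes (B, J, O, U, X, Z) are mapped to
        ``X`` (which never matches a motif); otherwise they are rejected.
    """
    records: list[SequenceRecord] = []
    for index, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        fields = _parse_header(rec.id, index)
        residues = str(rec.seq).upper()
        if map_ambiguous:
            residues = "".join(
                "X" if c in AMBIGUOUS_RESIDUES else c for c in residues
            )
        if class_map is not None:
            fields["class_label"] = class_map.get(fields["family"], "unknown")
        try:
            records.append(SequenceRecord(residues=residues, **fields))
        except CorpusError as exc:
            raise CorpusError(f"record {index}: {exc}") from exc
    return records


def write_corpus(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records in the FASTA dialect, wrapped at `width` columns."""
    seqio_records = [
        SeqRecord(Seq(r.residues), id=r.header(), description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqio_records)


# ---------------------------------------------------------------------------
# Pairwise identity and redundancy clustering
# ---------------------------------------------------------------------------

_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Local-alignment sequence identity between two residue strings.

    The best Smith–Waterman local alignment under BLOSUM62 (gap open 11,
    extend 1) is computed; identity is the number of identical aligned
    columns divided by the length of the shorter sequence, so a short
    perfect local match between long unrelated sequences scores low.
    Returns 0.0 when no positive-scoring local alignment exists.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    # canonical argument order makes the result exactly symmetric even when
    # co-optimal alignments with different match counts exist
    x, y = (a, b) if a <= b else (b, a)
    alignments = _aligner().align(x, y)
    if alignments.score <= 0:
        return 0.0
    best = alignments[0]
    matches = 0
    for (sx, ex), (sy, _ey) in zip(best.aligned[0], best.aligned[1]):
        for i in range(ex - sx):
            if x[sx + i] == y[sy + i]:
                matches += 1
    return matches / min(len(a), len(b))


def _prescreen_identity_bound(a: str, b: str) -> float:
    """Cheap upper-estimate of identity from a semi-global edit distance.

    Aligns the shorter sequence within the longer one (edlib "HW" mode);
    1 - d/len(shorter) tracks the alignment identity closely for the
    near-duplicate pairs redundancy reduction cares about.
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
    return 1.0 - d / len(query)


# margin by which the prescreen over-admits before the exact alignment runs
_PRESCREEN_MARGIN = 0.15


@dataclass(frozen=True)
class RedundancyClustering:
    """Single-linkage identity clustering of a corpus, per family.

    ``clusters`` maps the representative id of each cluster to the sorted
    tuple of member ids (representatives belong to their own clusters).
    """

    clusters: Mapping[str, tuple[str, ...]]
    identity_threshold: float

    @property
    def representatives(self) -> list[str]:
        return sorted(self.clusters)

    def representative_records(
        self, records: Sequence[SequenceRecord]
    ) -> list[SequenceRecord]:
        reps = set(self.representatives)
        return [r for r in records if r.id in reps]

    def cluster_of(self, record_id: str) -> str:
        for rep, members in self.clusters.items():
            if record_id in members:
                return rep
        raise KeyError(record_id)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def reduce_redundancy(
    records: Sequence[SequenceRecord],
    threshold: float = 0.90,
    prescreen: bool = True,
) -> RedundancyClustering:
    """Cluster near-duplicate sequences within each family.

    Edges join pairs with identity >= `threshold`; single-linkage components
    are the clusters.  The representative of a cluster is the member with
    the maximal average identity to the other members, ties broken by the
    lexicographically smallest id.  Clustering is computed within each
    family independently.
    """
    if not records:
        raise ValueError("reduce_redundancy requires at least one record")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise CorpusError("duplicate sequence ids in corpus")

    by_family: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_family.setdefault(r.family, []).append(r)

    clusters: dict[str, tuple[str, ...]] = {}
    for family in sorted(by_family):
        members = sorted(by_family[family], key=lambda r: r.id)
        uf = _UnionFind(r.id for r in members)
        identity_cache: dict[tuple[str, str], float] = {}

        def ident(ra: SequenceRecord, rb: SequenceRecord) -> float:
            key = (ra.id, rb.id) if ra.id < rb.id else (rb.id, ra.id)
            if key not in identity_cache:
                identity_cache[key] = pairwise_identity(ra.residues, rb.residues)
            return identity_cache[key]

        for i, ra in enumerate(members):
            for rb in members[i + 1:]:
                if prescreen:
                    bound = _prescreen_identity_bound(ra.residues, rb.residues)
                    if bound < threshold - _PRESCREEN_MARGIN:
                        continue
                if ident(ra, rb) >= threshold:
                    uf.union(ra.id, rb.id)

        components: dict[str, list[SequenceRecord]] = {}
        for r in members:
            components.setdefault(uf.find(r.id), []).append(r)
        for component in components.values():
            component.sort(key=lambda r: r.id)
            if len(component) == 1:
                rep = component[0].id
            else:
                best: tuple[float, str] | None = None
                for r in component:
                    avg = sum(ident(r, o) for o in component if o.id != r.id) / (
                        len(component) - 1
                    )
                    # prefer higher average identity; ties -> smaller id
                    key = (-avg, r.id)
                    if best is None or key < best:
                        best = key
                        rep = r.id
            clusters[rep] = tuple(r.id for r in component)
    return RedundancyClustering(clusters=clusters, identity_threshold=threshold)


def write_clustering(clustering: RedundancyClustering, path: str | Path) -> None:
    """Write a clustering report TSV: cluster_id, member_id, representative_flag."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\trepresentative_flag\n")
        for rep in clustering.representatives:
            for member in clustering.clusters[rep]:
                fh.write(f"{rep}\t{member}\t{int(member == rep)}\n")
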