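"""End-to-end orchestration: corpus -> CP space.

``build_cp_space`` chains the standard steps: per-family redundancy
reduction, per-family motif extraction on the non-redundant sets,
unification with substring pruning, exhaustive hit location of every CP on
every (non-redundant) sequence, overlap merging and the family x feature
matrix.  The result object carries every intermediate product the
downstream analyses need.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .corpus import (
    RedundancyClustering,
    SequenceRecord,
    read_corpus,
    reduce_redundancy,
    write_clustering,
    write_corpus,
)
from .mex import MexParams, extract_motifs
from .space import (
    CommonPeptide,
    FeatureMatrix,
    build_feature_matrix,
    locate_hits,
    merge_overlaps,
    read_cp_list,
    write_cp_list,
)


@dataclass(frozen=True)
class CPSpace:
    """All products of the CP-space construction for one corpus."""

    records: tuple[SequenceRecord, ...]  # non-redundant corpus
    clustering: RedundancyClustering | None
    per_family_motifs: Mapping[str, frozenset[str]]
    cps: tuple[CommonPeptide, ...]
    hits: pd.DataFrame
    features: pd.DataFrame
    merged_registry: Mapping[str, int]
    matrix: FeatureMatrix

    @property
    def families(self) -> list[str]:
        return sorted({r.family for r in self.records})

    @property
    def cp_strings(self) -> list[str]:
        return [cp.motif for cp in self.cps]


def build_cp_space(
    records: Sequence[SequenceRecord],
    mex_params: MexParams | None = None,
    identity_threshold: float = 0.90,
    reduce: bool = True,
) -> CPSpace:
    """Construct the CP space of a corpus.

    Motifs are extracted per family from the redundancy-reduced sequences;
    the unified, substring-pruned CP set is then searched on every
    non-redundant sequence regardless of source family.
    """
    if not records:
        raise ValueError("build_cp_space requires a non-empty corpus")
    mex_params = mex_params or MexParams()
    clustering: RedundancyClustering | None = None
    if reduce:
        clustering = reduce_redundancy(records, threshold=identity_threshold)
        nr_records = tuple(clustering.representative_records(records))
    else:
        nr_records = tuple(records)

    by_family: dict[str, list[SequenceRecord]] = {}
    for r in nr_records:
        by_family.setdefault(r.family, []).append(r)
    per_family = {
        fam: frozenset(extract_motifs(members, mex_params))
        for fam, members in sorted(by_family.items())
    }
    cps = tuple(unify(per_family))
    hits = locate_hits(cps, nr_records)
    features, registry = merge_overlaps(hits, nr_records)
    matrix = build_feature_matrix(features, nr_records)
    return CPSpace(
        records=nr_records,
        clustering=clustering,
        per_family_motifs=per_family,
        cps=cps,
        hits=hits,
        features=features,
        merged_registry=registry,
        matrix=matrix,
    )


def unify(per_family: Mapping[str, frozenset[str]]) -> list[CommonPeptide]:
    from .space import unify_and_prune

    return unify_and_prune(per_family)


def save_space(space: CPSpace, out_dir: str | Path) -> None:
    """Persist a CP space as plain-text files in a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus(space.records, out / "nr.fa")
    if space.clustering is not None:
        write_clustering(space.clustering, out / "clusters.tsv")
    write_cp_list(space.cps, out / "cps.tsv")
    space.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    space.features.to_csv(out / "features.tsv", sep="\t", index=False)
    space.matrix.values.to_csv(out / "matrix.tsv", sep="\t")
    with open(out / "matrix_triplets.tsv", "w") as fh:
        fh.write("family\tfeature\tvalue\n")
        values = space.matrix.values
        for fam in values.index:
            row = values.loc[fam]
            for feat, value in row[row > 0].items():
                fh.write(f"{fam}\t{feat}\t{value:g}\n")
    with open(out / "merged.tsv", "w") as fh:
        fh.write("feature\tn_occurrences\n")
        for feat in sorted(space.merged_registry):
            fh.write(f"{feat}\t{space.merged_registry[feat]}\n")


def load_space(
    space_dir: str | Path, class_map: Mapping[str, str] | None = None
) -> CPSpace:
    """Reload the parts of a saved space the downstream commands need."""
    out = Path(space_dir)
    records = tuple(read_corpus(out / "nr.fa", class_map=class_map))
    cps = tuple(read_cp_list(out / "cps.tsv"))
    hits = pd.read_csv(out / "hits.tsv", sep="\t")
    features = pd.read_csv(out / "features.tsv", sep="\t")
    matrix = build_feature_matrix(features, records)
    merged_rows = features.loc[features["is_merged"], "feature"]
    registry = {feat: int(n) for feat, n in merged_rows.value_counts().items()}
    return CPSpace(
        records=records,
        clustering=None,
        per_family_motifs={},
        cps=cps,
        hits=hits,
        features=features,
        merged_registry=registry,
        matrix=matrix,
    )
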