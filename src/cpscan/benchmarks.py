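"""Planted-truth benchmark designs exercising every pipeline stage.

Each function builds a :class:`~cpscan.synthetic.SynthSpec` whose planted
structure makes one analysis answerable against ground truth:

* :func:`recovery_spec` — motif-extraction recall and false positives:
  ten families of 100 sequences x 300 residues over a uniform background;
  eight families carry two planted motifs each (insertion probabilities
  0.5 and 0.7), two families are left unplanted.
* :func:`evolution_spec` — class signatures, mitochondrial enrichment and
  exclusive shared CPs: seven class-I and seven class-II families of 40
  sequences x 250 residues; one motif spans each class, five motifs are
  exclusive to a four-family class-I quartet, and one family carries a
  block of motifs restricted to Bacteria+Mitochondria (with
  Eukarya-restricted and Eukarya+Archaea decoys), the design that should
  light up Bacteria — and only Bacteria — in the enrichment test.  Sites
  are planted inside the class/quartet/anchor motifs so prevalent CPs
  overlap annotated positions, while a block of sub-prevalent decoy motifs
  in one class-II family fills the overlap urn with CPs that never touch
  a site.
* :func:`similarity_spec` — a planted correlated family pair: two of six
  families share a block of ten motifs on top of private motifs.
* :func:`cross_family_specs` — two independently processed corpora (a
  multi-family one and a single-family analog corpus) sharing two planted
  motifs at high prevalence.

Motif strings are drawn at random from the supplied seed under two
constraints — no motif contains another and no two motifs share a 5-mer —
so planted signals never collide with each other.  Sequence counts and
insertion probabilities are fixed design choices; the seed only moves the
random residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import AMINO_ACIDS
from .synthetic import (
    CloneGroupSpec,
    FamilySpec,
    PlantedMotif,
    SiteSpec,
    SynthSpec,
)

ALL_GROUPS = frozenset({"Bacteria", "Eukarya", "Archaea", "Mitochondria"})
_DEFAULT_MIX = {"Bacteria": 0.55, "Eukarya": 0.20, "Archaea": 0.15, "Mitochondria": 0.10}


def random_motifs(rng: np.random.Generator, lengths: list[int]) -> list[str]:
    """Random motif strings with no substring containment or shared 5-mers."""
    motifs: list[str] = []
    used_kmers: set[str] = set()
    for length in lengths:
        for _attempt in range(1000):
            m = "".join(rng.choice(list(AMINO_ACIDS), size=length))
            kmers = {m[i : i + 5] for i in range(length - 4)}
            if kmers & used_kmers:
                continue
            motifs.append(m)
            used_kmers |= kmers
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw non-colliding motifs")
    return motifs


@dataclass(frozen=True)
class RecoveryDesign:
    spec: SynthSpec
    planted_families: tuple[str, ...]
    unplanted_families: tuple[str, ...]
    motifs_by_family: dict[str, tuple[str, ...]]


def recovery_spec(
    seed: int,
    n_families: int = 10,
    n_planted_families: int = 8,
    n_sequences: int = 100,
    length_mean: float = 300.0,
) -> RecoveryDesign:
    """Planted-motif recovery benchmark (see module docstring)."""
    rng = np.random.default_rng(seed)
    families = tuple(
        FamilySpec(
            label=f"F{i + 1:02d}",
            class_label="I" if i < n_families // 2 else "II",
            n_sequences=n_sequences,
            length_mean=length_mean,
            length_sd=20.0,
        )
        for i in range(n_families)
    )
    planted = tuple(f.label for f in families[:n_planted_families])
    unplanted = tuple(f.label for f in families[n_planted_families:])
    lengths = [int(rng.integers(6, 9)) for _ in range(2 * len(planted))]
    strings = random_motifs(rng, lengths)
    motifs = []
    by_family: dict[str, tuple[str, ...]] = {}
    for i, fam in enumerate(planted):
        pair = (strings[2 * i], strings[2 * i + 1])
        by_family[fam] = pair
        for m, prob in zip(pair, (0.5, 0.7)):
            motifs.append(
                PlantedMotif(
                    motif=m,
                    target_families=frozenset({fam}),
                    target_kingdoms=ALL_GROUPS,
                    insertion_prob=prob,
                )
            )
    spec = SynthSpec(
        families=families,
        kingdom_mix={f.label: dict(_DEFAULT_MIX) for f in families},
        motifs=tuple(motifs),
        seed=int(rng.integers(2**31)),
    )
    return RecoveryDesign(
        spec=spec,
        planted_families=planted,
        unplanted_families=unplanted,
        motifs_by_family=by_family,
    )


@dataclass(frozen=True)
class EvolutionDesign:
    spec: SynthSpec
    class_I_signature: str
    class_II_signature: str
    quartet: tuple[str, ...]
    quartet_motifs: tuple[str, ...]
    mito_family: str
    bacteria_mito_motifs: tuple[str, ...]
    eukarya_motifs: tuple[str, ...]
    eukarya_archaea_motifs: tuple[str, ...]
    anchor_motifs: tuple[str, ...]  # planted in every mito_family sequence
    decoy_motifs: tuple[str, ...]  # sub-prevalent, no sites: urn background


def evolution_spec(seed: int, n_sequences: int = 40) -> EvolutionDesign:
    """Class-signature / enrichment / exclusive-shared benchmark."""
    rng = np.random.default_rng(seed)
    class_I = tuple(f"I{i + 1}" for i in range(7))
    class_II = tuple(f"H{i + 1}" for i in range(7))
    families = tuple(
        FamilySpec(label=f, class_label=cls, n_sequences=n_sequences,
                   length_mean=250.0, length_sd=15.0)
        for cls, labels in (("I", class_I), ("II", class_II))
        for f in labels
    )
    quartet = class_I[3:7]
    mito_family = class_I[0]
    decoy_family = class_II[-1]

    lengths = [7, 7] + [6] * 5 + [6] * 2 + [6] * 12 + [6] * 6 + [6] * 12 + [6] * 60
    strings = random_motifs(rng, lengths)
    sig_I, sig_II = strings[0], strings[1]
    quartet_motifs = tuple(strings[2:7])
    anchors = tuple(strings[7:9])
    bm_motifs = tuple(strings[9:21])
    e_motifs = tuple(strings[21:27])
    ea_motifs = tuple(strings[27:39])
    decoys = tuple(strings[39:99])

    # group-restricted motifs sit at p=0.55: well below the >50%-of-family
    # prevalence bar (their eligible subset is ~60% of the family) yet far
    # above the extractor's support floor
    motifs: list[PlantedMotif] = [
        PlantedMotif(sig_I, frozenset(class_I), ALL_GROUPS, 0.8),
        PlantedMotif(sig_II, frozenset(class_II), ALL_GROUPS, 0.8),
    ]
    motifs += [
        PlantedMotif(m, frozenset(quartet), ALL_GROUPS, 0.65) for m in quartet_motifs
    ]
    motifs += [
        PlantedMotif(m, frozenset({mito_family}), ALL_GROUPS, 1.0) for m in anchors
    ]
    motifs += [
        PlantedMotif(m, frozenset({mito_family}),
                     frozenset({"Bacteria", "Mitochondria"}), 0.55)
        for m in bm_motifs
    ]
    motifs += [
        PlantedMotif(m, frozenset({mito_family}), frozenset({"Eukarya"}), 0.55)
        for m in e_motifs
    ]
    motifs += [
        PlantedMotif(m, frozenset({mito_family}),
                     frozenset({"Eukarya", "Archaea"}), 0.55)
        for m in ea_motifs
    ]
    # a block of clearly sub-prevalent motifs in one class-II family keeps
    # the site-overlap urn rich in CPs that never touch a site
    motifs += [
        PlantedMotif(m, frozenset({decoy_family}), ALL_GROUPS, 0.3)
        for m in decoys
    ]
    # annotated residues sit inside the class, quartet and anchor motifs
    sites = tuple(
        SiteSpec(motif_index=i, offsets=(2,)) for i in range(2)
    ) + tuple(
        SiteSpec(motif_index=i, offsets=(1,)) for i in range(2, 9)
    )
    mix = {f.label: dict(_DEFAULT_MIX) for f in families}
    mix[mito_family] = {
        "Bacteria": 0.35, "Eukarya": 0.25, "Archaea": 0.10, "Mitochondria": 0.30
    }
    spec = SynthSpec(
        families=families,
        kingdom_mix=mix,
        motifs=tuple(motifs),
        sites=sites,
        seed=int(rng.integers(2**31)),
    )
    return EvolutionDesign(
        spec=spec,
        class_I_signature=sig_I,
        class_II_signature=sig_II,
        quartet=quartet,
        quartet_motifs=quartet_motifs,
        mito_family=mito_family,
        bacteria_mito_motifs=bm_motifs,
        eukarya_motifs=e_motifs,
        eukarya_archaea_motifs=ea_motifs,
        anchor_motifs=anchors,
        decoy_motifs=decoys,
    )


@dataclass(frozen=True)
class SimilarityDesign:
    spec: SynthSpec
    correlated_pair: tuple[str, str]
    shared_motifs: tuple[str, ...]


def similarity_spec(seed: int, n_sequences: int = 30) -> SimilarityDesign:
    """Planted correlated family pair among six families."""
    rng = np.random.default_rng(seed)
    labels = tuple(f"S{i + 1}" for i in range(6))
    families = tuple(
        FamilySpec(label=f, class_label="I" if i < 3 else "II",
                   n_sequences=n_sequences, length_mean=200.0, length_sd=10.0)
        for i, f in enumerate(labels)
    )
    pair = (labels[0], labels[1])
    strings = random_motifs(rng, [6] * (10 + 5 * len(labels)))
    shared = tuple(strings[:10])
    motifs = [
        PlantedMotif(m, frozenset(pair), ALL_GROUPS, 0.8) for m in shared
    ]
    for i, fam in enumerate(labels):
        private = strings[10 + 5 * i : 15 + 5 * i]
        motifs += [
            PlantedMotif(m, frozenset({fam}), ALL_GROUPS, 0.8) for m in private
        ]
    spec = SynthSpec(
        families=families,
        kingdom_mix={f.label: dict(_DEFAULT_MIX) for f in families},
        motifs=tuple(motifs),
        seed=int(rng.integers(2**31)),
    )
    return SimilarityDesign(spec=spec, correlated_pair=pair, shared_motifs=shared)


@dataclass(frozen=True)
class CrossFamilyDesign:
    spec_a: SynthSpec
    spec_b: SynthSpec
    shared_motifs: tuple[str, ...]


def cross_family_specs(seed: int) -> CrossFamilyDesign:
    """Two corpora sharing two highly prevalent planted motifs.

    Corpus A has three families of 60 sequences; corpus B is a
    single-family analog corpus of 120 sequences.  Two motifs are planted
    in one A family (p=0.6) and in B (p=0.6), comfortably above the
    20-distinct-sequence prevalence filter; each corpus also carries
    private motifs.
    """
    rng = np.random.default_rng(seed)
    strings = random_motifs(rng, [6, 6] + [6] * 6)
    shared = tuple(strings[:2])
    private_a, private_b = strings[2:5], strings[5:8]
    fams_a = tuple(
        FamilySpec(label=f"T{i + 1}", class_label="II", n_sequences=60,
                   length_mean=220.0, length_sd=12.0)
        for i in range(3)
    )
    fam_b = (FamilySpec(label="birA", class_label="II", n_sequences=120,
                        length_mean=220.0, length_sd=12.0),)
    motifs_a = [
        PlantedMotif(m, frozenset({"T1"}), ALL_GROUPS, 0.6) for m in shared
    ] + [
        PlantedMotif(m, frozenset({f"T{i + 1}"}), ALL_GROUPS, 0.7)
        for i, m in enumerate(private_a)
    ]
    motifs_b = [
        PlantedMotif(m, frozenset({"birA"}), ALL_GROUPS, 0.6) for m in shared
    ] + [
        PlantedMotif(m, frozenset({"birA"}), ALL_GROUPS, 0.7) for m in private_b
    ]
    spec_a = SynthSpec(
        families=fams_a,
        kingdom_mix={f.label: dict(_DEFAULT_MIX) for f in fams_a},
        motifs=tuple(motifs_a),
        seed=int(rng.integers(2**31)),
    )
    spec_b = SynthSpec(
        families=fam_b,
        kingdom_mix={"birA": dict(_DEFAULT_MIX)},
        motifs=tuple(motifs_b),
        seed=int(rng.integers(2**31)),
    )
    return CrossFamilyDesign(spec_a=spec_a, spec_b=spec_b, shared_motifs=shared)


def clone_spec(seed: int, group_size: int = 4, mutation_rate: float = 0.02) -> SynthSpec:
    """A small corpus with one clone group, for redundancy-reduction checks."""
    rng = np.random.default_rng(seed)
    families = (
        FamilySpec(label="C1", class_label="I", n_sequences=6,
                   length_mean=300.0, length_sd=0.0),
    )
    return SynthSpec(
        families=families,
        kingdom_mix={"C1": dict(_DEFAULT_MIX)},
        clone_groups=(CloneGroupSpec("C1", group_size, mutation_rate),),
        seed=int(rng.integers(2**31)),
    )
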