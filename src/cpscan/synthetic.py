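"""Synthetic protein-family corpora with planted ground truth.

The generator emulates the structure of a multi-family enzyme corpus:
several families split into two structural classes, sequences assigned to
the four analysis groups (Bacteria/Eukarya/Archaea/Mitochondria),
near-duplicate clone groups standing in for strains of one species, and
deterministic motifs planted with controlled family/group specificity.
Backgrounds are i.i.d. residues from a configurable composition (uniform
by default), so planted motifs are the only deterministic signal; motif
planting *replaces* background residues, keeping each sequence at its
drawn length.  Site annotations are emitted at fixed offsets inside chosen
planted motifs, so site-overlap statistics have a planted truth too.

Everything is driven by a single integer seed: the same spec and seed
produce byte-identical FASTA, truth and site files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus import AMINO_ACIDS, GROUPS, SequenceRecord

_AA = np.array(list(AMINO_ACIDS))


class SpecError(ValueError):
    """Invalid synthetic-corpus specification; the message names the field."""


@dataclass(frozen=True)
class PlantedMotif:
    """A deterministic motif planted into eligible sequences.

    Eligibility requires the sequence's family in ``target_families`` and
    its analysis group in ``target_kingdoms``; each eligible sequence then
    carries the motif with probability ``insertion_prob`` at a uniformly
    drawn (or fixed) non-overlapping offset.
    """

    motif: str
    target_families: frozenset[str]
    target_kingdoms: frozenset[str]
    insertion_prob: float = 1.0
    position_mode: str = "uniform"  # "uniform" | "fixed"
    fixed_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.motif) < 5:
            raise SpecError(f"motif: {self.motif!r} shorter than 5 residues")
        bad = set(self.motif) - set(AMINO_ACIDS)
        if bad:
            raise SpecError(
                f"motif: {self.motif!r} uses non-canonical residues "
                f"{''.join(sorted(bad))}"
            )
        if not self.target_families:
            raise SpecError("target_families: must be non-empty")
        if not self.target_kingdoms:
            raise SpecError("target_kingdoms: must be non-empty")
        unknown = set(self.target_kingdoms) - set(GROUPS)
        if unknown:
            raise SpecError(f"target_kingdoms: unknown groups {sorted(unknown)}")
        if not 0.0 <= self.insertion_prob <= 1.0:
            raise SpecError(f"insertion_prob: {self.insertion_prob} not in [0, 1]")
        if self.position_mode not in ("uniform", "fixed"):
            raise SpecError(f"position_mode: {self.position_mode!r}")


@dataclass(frozen=True)
class FamilySpec:
    label: str
    class_label: str  # "I" | "II"
    n_sequences: int
    length_mean: float
    length_sd: float

    def __post_init__(self) -> None:
        if self.class_label not in ("I", "II"):
            raise SpecError(f"class_label: {self.class_label!r} not in ('I', 'II')")
        if self.n_sequences < 0:
            raise SpecError(f"n_sequences: {self.n_sequences} negative")
        if self.length_mean <= 0 or self.length_sd < 0:
            raise SpecError("length_mean/length_sd: must be positive / non-negative")


@dataclass(frozen=True)
class CloneGroupSpec:
    """A group of near-duplicate sequences derived from one template."""

    family: str
    group_size: int
    mutation_rate: float

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise SpecError(f"group_size: {self.group_size} must be >= 2")
        # two clones each mutated at rate m differ at <= 2m of positions in
        # expectation; m <= 0.05 keeps expected pairwise identity >= 0.9
        if not 0.0 <= self.mutation_rate <= 0.05:
            raise SpecError(
                f"mutation_rate: {self.mutation_rate} not in [0, 0.05] "
                "(expected pairwise clone identity must stay >= 0.9)"
            )


@dataclass(frozen=True)
class SiteSpec:
    """Emit site annotations at offsets inside a planted motif."""

    motif_index: int
    offsets: tuple[int, ...]
    site_type: str = "binding"
    ligand: str = "LIG"
    priority: int = 1

    def __post_init__(self) -> None:
        if self.site_type not in ("catalytic", "binding"):
            raise SpecError(f"site_type: {self.site_type!r}")
        if not self.offsets:
            raise SpecError("offsets: must be non-empty")


@dataclass(frozen=True)
class SynthSpec:
    families: tuple[FamilySpec, ...]
    kingdom_mix: Mapping[str, Mapping[str, float]]  # family -> group -> proportion
    motifs: tuple[PlantedMotif, ...] = ()
    clone_groups: tuple[CloneGroupSpec, ...] = ()
    sites: tuple[SiteSpec, ...] = ()
    background_freqs: tuple[float, ...] = tuple([1.0 / 20] * 20)
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [f.label for f in self.families]
        if len(set(labels)) != len(labels):
            raise SpecError("families: duplicate labels")
        for fam in self.families:
            mix = self.kingdom_mix.get(fam.label)
            if mix is None:
                raise SpecError(f"kingdom_mix: missing family {fam.label!r}")
            unknown = set(mix) - set(GROUPS)
            if unknown:
                raise SpecError(f"kingdom_mix[{fam.label!r}]: unknown groups {sorted(unknown)}")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise SpecError(
                    f"kingdom_mix[{fam.label!r}]: proportions sum to "
                    f"{sum(mix.values())}, not 1"
                )
            if any(v < 0 for v in mix.values()):
                raise SpecError(f"kingdom_mix[{fam.label!r}]: negative proportion")
        if len(self.background_freqs) != 20:
            raise SpecError("background_freqs: need 20 values")
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise SpecError("background_freqs: must sum to 1")
        if any(f < 0 for f in self.background_freqs):
            raise SpecError("background_freqs: negative frequency")
        for cg in self.clone_groups:
            if cg.family not in labels:
                raise SpecError(f"clone_groups: unknown family {cg.family!r}")
        for site in self.sites:
            if not 0 <= site.motif_index < len(self.motifs):
                raise SpecError(f"sites: motif_index {site.motif_index} out of range")
            motif = self.motifs[site.motif_index].motif
            if any(not 0 <= off < len(motif) for off in site.offsets):
                raise SpecError(
                    f"sites: offsets {site.offsets} outside motif {motif!r}"
                )
        if self.motifs:
            min_len = self.min_length
            for fam in self.families:
                if fam.length_mean < min_len:
                    raise SpecError(
                        f"families[{fam.label!r}].length_mean: {fam.length_mean} "
                        f"< longest motif + 10 = {min_len}"
                    )

    @property
    def min_length(self) -> int:
        longest = max((len(m.motif) for m in self.motifs), default=0)
        return longest + 10


@dataclass(frozen=True)
class Occurrence:
    seq_id: str
    start: int
    end: int
    motif: str
    motif_index: int
    seq_length: int


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth: motif spans, clone memberships, site rows."""

    occurrences: tuple[Occurrence, ...]
    clone_groups: tuple[tuple[str, tuple[str, ...]], ...]  # (group_id, member ids)
    sites: tuple[tuple[str, int, str, str, int], ...]  # site TSV rows

    def occurrences_of(self, motif_index: int) -> list[Occurrence]:
        return [o for o in self.occurrences if o.motif_index == motif_index]

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.sites),
            columns=["seq_id", "position", "site_type", "ligand", "priority"],
        )


def _draw_background(rng: np.random.Generator, length: int, freqs) -> np.ndarray:
    return rng.choice(20, size=length, p=freqs)


def _plant(
    rng: np.random.Generator,
    seq: np.ndarray,
    motif: str,
    occupied: list[tuple[int, int]],
    position_mode: str,
    fixed_offset: int,
) -> int | None:
    """Overwrite background residues with the motif; returns the offset."""
    m = len(motif)
    if position_mode == "fixed":
        starts = [fixed_offset] if fixed_offset + m <= len(seq) else []
    else:
        starts = list(range(len(seq) - m + 1))
    free = [
        s
        for s in starts
        if all(s + m <= a or s >= b for a, b in occupied)
    ]
    if not free:
        return None
    start = int(free[rng.integers(len(free))])
    seq[start : start + m] = [AMINO_ACIDS.index(c) for c in motif]
    occupied.append((start, start + m))
    return start


def generate(
    spec: SynthSpec,
) -> tuple[list[SequenceRecord], TruthRecord, pd.DataFrame]:
    """Generate the corpus, its planted truth and the site table.

    Deterministic for a fixed spec (same seed twice gives byte-identical
    output).  Clone-group members are derived from a freshly generated
    template by i.i.d. substitutions at the group's mutation rate; truth
    spans are recorded only where the planted motif survived intact.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.background_freqs)
    group_names = list(GROUPS)
    records: list[SequenceRecord] = []
    occurrences: list[Occurrence] = []
    clone_members: list[tuple[str, tuple[str, ...]]] = []
    min_len = spec.min_length

    def draw_length(fam: FamilySpec) -> int:
        return max(min_len, int(round(rng.normal(fam.length_mean, fam.length_sd))))

    def make_sequence(fam: FamilySpec, seq_id: str, group: str):
        length = draw_length(fam)
        seq = _draw_background(rng, length, freqs)
        occupied: list[tuple[int, int]] = []
        occs: list[tuple[int, int]] = []  # (motif_index, start)
        for mi, pm in enumerate(spec.motifs):
            if fam.label not in pm.target_families or group not in pm.target_kingdoms:
                continue
            if pm.insertion_prob < 1.0 and rng.random() >= pm.insertion_prob:
                continue
            start = _plant(rng, seq, pm.motif, occupied, pm.position_mode, pm.fixed_offset)
            if start is not None:
                occs.append((mi, start))
        return seq, occs

    def register(fam: FamilySpec, seq_id: str, group: str, seq: np.ndarray, occs):
        kingdom = "Eukarya" if group == "Mitochondria" else group
        organelle = "mito" if group == "Mitochondria" else "nuclear"
        residues = "".join(_AA[seq])
        records.append(
            SequenceRecord(
                id=seq_id,
                family=fam.label,
                kingdom=kingdom,
                organelle=organelle,
                residues=residues,
                class_label=fam.class_label,
            )
        )
        for mi, start in occs:
            motif = spec.motifs[mi].motif
            if residues[start : start + len(motif)] == motif:
                occurrences.append(
                    Occurrence(seq_id, start, start + len(motif), motif, mi, len(seq))
                )

    for fam in spec.families:
        mix = spec.kingdom_mix[fam.label]
        probs = np.array([mix.get(g, 0.0) for g in group_names])
        for j in range(fam.n_sequences):
            group = group_names[int(rng.choice(4, p=probs))]
            seq_id = f"{fam.label}_{j:04d}"
            seq, occs = make_sequence(fam, seq_id, group)
            register(fam, seq_id, group, seq, occs)
        for gi, cg in enumerate(spec.clone_groups):
            if cg.family != fam.label:
                continue
            group = group_names[int(rng.choice(4, p=probs))]
            template, occs = make_sequence(fam, "", group)
            member_ids = []
            for k in range(cg.group_size):
                seq_id = f"{fam.label}_cg{gi}_{k:02d}"
                member_ids.append(seq_id)
                if k == 0:
                    seq = template.copy()
                else:
                    seq = template.copy()
                    mask = rng.random(len(seq)) < cg.mutation_rate
                    n_mut = int(mask.sum())
                    if n_mut:
                        # shift by 1..19 mod 20: uniform over the other residues
                        shift = rng.integers(1, 20, size=n_mut)
                        seq[mask] = (seq[mask] + shift) % 20
                register(fam, seq_id, group, seq, occs)
            clone_members.append((f"{fam.label}_cg{gi}", tuple(member_ids)))

    site_rows: list[tuple[str, int, str, str, int]] = []
    for site in spec.sites:
        for occ in occurrences:
            if occ.motif_index != site.motif_index:
                continue
            for off in site.offsets:
                site_rows.append(
                    (occ.seq_id, occ.start + off, site.site_type, site.ligand,
                     site.priority)
                )
    truth = TruthRecord(
        occurrences=tuple(occurrences),
        clone_groups=tuple(clone_members),
        sites=tuple(site_rows),
    )
    return records, truth, truth.sites_frame()


# ---------------------------------------------------------------------------
# Truth file round trip
# ---------------------------------------------------------------------------

_TRUTH_HEADER = [
    "kind", "seq_id", "start", "end", "motif", "motif_index", "seq_length",
    "group_id", "position", "site_type", "ligand", "priority",
]


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    """Write the truth record as a single TSV with a `kind` discriminator."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_HEADER)
        for o in truth.occurrences:
            writer.writerow(
                ["occurrence", o.seq_id, o.start, o.end, o.motif, o.motif_index,
                 o.seq_length, "", "", "", "", ""]
            )
        for group_id, members in truth.clone_groups:
            for m in members:
                writer.writerow(
                    ["clone", m, "", "", "", "", "", group_id, "", "", "", ""]
                )
        for seq_id, pos, site_type, ligand, priority in truth.sites:
            writer.writerow(
                ["site", seq_id, "", "", "", "", "", "", pos, site_type, ligand,
                 priority]
            )


def read_truth(path: str | Path) -> TruthRecord:
    """Read a truth TSV back, enforcing the span invariants.

    Raises ValueError with the offending line number for malformed rows or
    spans falling outside their sequence.
    """
    occurrences: list[Occurrence] = []
    clone_map: dict[str, list[str]] = {}
    sites: list[tuple[str, int, str, str, int]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _TRUTH_HEADER:
            raise ValueError(f"{path}:1: unexpected truth header {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_TRUTH_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_TRUTH_HEADER)} fields")
            kind = row[0]
            try:
                if kind == "occurrence":
                    occ = Occurrence(
                        seq_id=row[1], start=int(row[2]), end=int(row[3]),
                        motif=row[4], motif_index=int(row[5]), seq_length=int(row[6]),
                    )
                    if not 0 <= occ.start < occ.end <= occ.seq_length:
                        raise ValueError(
                            f"span [{occ.start}, {occ.end}) outside sequence of "
                            f"length {occ.seq_length}"
                        )
                    if occ.end - occ.start != len(occ.motif):
                        raise ValueError("span length does not match motif length")
                    occurrences.append(occ)
                elif kind == "clone":
                    clone_map.setdefault(row[7], []).append(row[1])
                elif kind == "site":
                    sites.append((row[1], int(row[8]), row[9], row[10], int(row[11])))
                else:
                    raise ValueError(f"unknown kind {kind!r}")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return TruthRecord(
        occurrences=tuple(occurrences),
        clone_groups=tuple((g, tuple(m)) for g, m in clone_map.items()),
        sites=tuple(sites),
    )


# ---------------------------------------------------------------------------
# YAML spec loading
# ---------------------------------------------------------------------------


def load_spec(path: str | Path) -> SynthSpec:
    """Load a SynthSpec from a YAML config (see docs for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        families = tuple(FamilySpec(**f) for f in raw["families"])
        motifs = tuple(
            PlantedMotif(
                motif=m["motif"],
                target_families=frozenset(m["target_families"]),
                target_kingdoms=frozenset(m["target_kingdoms"]),
                insertion_prob=m.get("insertion_prob", 1.0),
                position_mode=m.get("position_mode", "uniform"),
                fixed_offset=m.get("fixed_offset", 0),
            )
            for m in raw.get("motifs", [])
        )
        clone_groups = tuple(CloneGroupSpec(**c) for c in raw.get("clone_groups", []))
        sites = tuple(
            SiteSpec(
                motif_index=s["motif_index"],
                offsets=tuple(s["offsets"]),
                site_type=s.get("site_type", "binding"),
                ligand=s.get("ligand", "LIG"),
                priority=s.get("priority", 1),
            )
            for s in raw.get("sites", [])
        )
        background = tuple(raw.get("background_freqs", [1.0 / 20] * 20))
        return SynthSpec(
            families=families,
            kingdom_mix=raw["kingdom_mix"],
            motifs=motifs,
            clone_groups=clone_groups,
            sites=sites,
            background_freqs=background,
            seed=int(raw.get("seed", 0)),
        )
    except KeyError as exc:
        raise SpecError(f"missing field {exc.args[0]!r} in spec file {path}") from exc


def class_map_of(spec: SynthSpec) -> dict[str, str]:
    """Family -> structural class mapping implied by the spec."""
    return {f.label: f.class_label for f in spec.families}
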