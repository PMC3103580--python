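"""Prevalence, site-overlap statistics and cross-corpus sharing."""

from __future__ import annotations

import random
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from cpscan.corpus import AMINO_ACIDS, SequenceRecord
from cpscan.sites import (
    cross_family_shared,
    hamming1_groups,
    hit_site_distance,
    overlap_significance,
    prevalent_cps,
    read_sites,
    select_annotated_sequences,
    shuffle_control,
    shuffle_residues,
    site_overlap,
    write_sites,
)


def _rec(id, residues="ACDEFGHIKLMNPQRSTVWY", family="F"):
    return SequenceRecord(id=id, family=family, kingdom="Bacteria",
                          organelle="nuclear", residues=residues)


def _hits(rows):
    return pd.DataFrame(rows, columns=["seq_id", "cp", "start", "end"])


def _sites(rows):
    return pd.DataFrame(
        rows, columns=["seq_id", "position", "site_type", "ligand", "priority"]
    )


class TestPrevalentCps:
    RECORDS = [_rec(f"s{i}") for i in range(4)]

    def test_three_of_four_is_prevalent(self):
        hits = _hits([(f"s{i}", "ACDEF", 0, 5) for i in range(3)])
        assert prevalent_cps(hits, self.RECORDS) == ["ACDEF"]

    def test_exactly_half_is_not_prevalent(self):
        hits = _hits([(f"s{i}", "ACDEF", 0, 5) for i in range(2)])
        assert prevalent_cps(hits, self.RECORDS) == []

    def test_stop_list_removes_containing_cps(self):
        hits = _hits([(f"s{i}", "ACDEF", 0, 5) for i in range(3)])
        assert prevalent_cps(hits, self.RECORDS, stop_list=["CDE"]) == []

    def test_repeated_hits_on_one_sequence_count_once(self):
        hits = _hits([("s0", "ACDEF", 0, 5), ("s0", "ACDEF", 7, 12)])
        assert prevalent_cps(hits, self.RECORDS) == []

    def test_matches_membership_recount(self, evolution_space):
        space = evolution_space
        records = list(space.records)
        got = set(prevalent_cps(space.hits, records))
        family_of = {r.id: r.family for r in records}
        sizes: dict[str, int] = {}
        for r in records:
            sizes[r.family] = sizes.get(r.family, 0) + 1
        carriers: dict[str, dict[str, set[str]]] = {}
        for seq_id, cp in zip(space.hits["seq_id"], space.hits["cp"]):
            carriers.setdefault(cp, {}).setdefault(family_of[seq_id],
                                                   set()).add(seq_id)
        expected = {
            cp for cp, fams in carriers.items()
            if any(len(s) > 0.5 * sizes[f] for f, s in fams.items())
        }
        assert got == expected


class TestHitSiteDistance:
    @pytest.mark.parametrize(
        "span,pos,expected",
        [
            ((10, 15), 12, 0),   # inside
            ((10, 15), 10, 0),   # first residue
            ((10, 15), 14, 0),   # last residue of half-open span
            ((10, 15), 15, 0),   # adjacent right: zero residues between
            ((10, 15), 17, 2),   # two residues beyond the end
            ((10, 15), 9, 0),    # adjacent left
            ((10, 15), 7, 2),
        ],
    )
    def test_distance_values(self, span, pos, expected):
        assert hit_site_distance(*span, pos) == expected

    def test_exhaustive_pairwise_oracle(self):
        rng = random.Random(0)
        seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(60))
        rec = _rec("s", seq)
        spans = [(rng.randrange(50), rng.randrange(3, 8)) for _ in range(6)]
        rows = [("s", seq[a:min(a + l, 60)], a, min(a + l, 60)) for a, l in spans]
        rows = [r for r in rows if r[3] > r[2]]
        positions = [rng.randrange(60) for _ in range(5)]
        sites = _sites([("s", p, "binding", "X", 1) for p in positions])
        report = site_overlap(_hits(rows), [rec], sites, max_dist=3,
                              restrict_to_priority=False)
        for cp in set(r[1] for r in rows):
            expected = min(
                hit_site_distance(s, e, p)
                for (_sid, c, s, e) in rows if c == cp
                for p in positions
            )
            got = report.table.set_index("cp").at[cp, "min_distance"]
            assert got == expected

    def test_invariant_to_hit_order(self):
        rec = _rec("s", "ACDEFGHIKLMNPQRSTVWY")
        sites = _sites([("s", 8, "binding", "X", 1)])
        rows = [("s", "ACDEF", 0, 5), ("s", "HIKLM", 6, 11)]
        a = site_overlap(_hits(rows), [rec], sites)
        b = site_overlap(_hits(rows[::-1]), [rec], sites)
        assert a.table.equals(b.table)


class TestSiteOverlap:
    def test_classification_thresholds(self):
        rec = _rec("s", "ACDEFGHIKLMNPQRSTVWY")
        rows = [("s", "ACDEF", 0, 5)]
        for pos, label in [(2, "exact"), (7, "vicinity"), (12, "none")]:
            sites = _sites([("s", pos, "binding", "X", 1)])
            report = site_overlap(_hits(rows), [rec], sites, max_dist=3)
            assert report.table.at[0, "classification"] == label

    def test_unknown_sequence_rejected(self):
        sites = _sites([("ghost", 2, "binding", "X", 1)])
        with pytest.raises(KeyError, match="ghost"):
            site_overlap(_hits([("s", "ACDEF", 0, 5)]), [_rec("s")], sites)

    def test_out_of_bounds_position_rejected(self):
        sites = _sites([("s", 99, "binding", "X", 1)])
        with pytest.raises(ValueError, match="99"):
            site_overlap(_hits([]), [_rec("s")], sites)

    def test_highest_priority_sequence_selected_per_family(self):
        records = [_rec("a"), _rec("b")]
        sites = _sites([("a", 2, "binding", "X", 2), ("b", 2, "binding", "X", 1)])
        assert select_annotated_sequences(sites, records) == {"F": "b"}
        # a CP hitting only the lower-priority sequence drops out
        report = site_overlap(_hits([("a", "ACDEF", 0, 5)]), records, sites)
        assert report.table.empty

    def test_sites_tsv_round_trip(self, tmp_path):
        sites = _sites([("s", 2, "binding", "ATP", 1), ("s", 9, "catalytic", "Mg", 2)])
        path = tmp_path / "sites.tsv"
        write_sites(sites, path)
        assert read_sites(path, [_rec("s")]).equals(sites)


class TestOverlapSignificance:
    def _report(self, classifications):
        table = pd.DataFrame(
            [(f"CP{i:02d}", 0 if c == "exact" else 5, c)
             for i, c in enumerate(classifications)],
            columns=["cp", "min_distance", "classification"],
        )
        from cpscan.sites import OverlapReport

        return OverlapReport(table=table, max_dist=3, selected_sequences={})

    def test_textbook_value(self):
        report = self._report(["exact"] * 10 + ["none"] * 10)
        prevalent = [f"CP{i:02d}" for i in range(5)]  # all five exact
        stats = overlap_significance(report, prevalent)
        assert stats["p"] == pytest.approx(comb(10, 5) / comb(20, 5))

    def test_zero_successes_in_urn_gives_p_one(self):
        report = self._report(["none"] * 8)
        stats = overlap_significance(report, ["CP00"])
        assert stats["K"] == 0 and stats["p"] == 1.0

    def test_vicinity_mode_counts_both_labels(self):
        report = self._report(["exact", "vicinity", "none", "none"])
        stats = overlap_significance(report, ["CP00", "CP01"], mode="vicinity")
        assert (stats["K"], stats["k"]) == (2, 2)

    def test_matches_exhaustive_enumeration_small_urn(self):
        report = self._report(["exact"] * 4 + ["none"] * 6)
        prevalent = ["CP00", "CP01", "CP04", "CP05", "CP06"]
        stats = overlap_significance(report, prevalent)
        # enumerate all 5-element draws from the 10-CP urn
        total = comb(10, 5)
        labels = [1] * 4 + [0] * 6
        count = sum(
            1 for draw in combinations(range(10), 5)
            if sum(labels[i] for i in draw) >= stats["k"]
        )
        assert stats["p"] == pytest.approx(count / total)

    def test_planted_sites_inside_prevalent_motifs_significant(
        self, evolution_space, evolution_corpus
    ):
        _records, _truth, sites = evolution_corpus
        records = list(evolution_space.records)
        prevalent = prevalent_cps(evolution_space.hits, records)
        report = site_overlap(evolution_space.hits, records, sites)
        stats = overlap_significance(report, prevalent)
        assert stats["p"] < 1e-4


class TestCrossFamilyShared:
    def _corpus(self, n, residues_fn, family="F"):
        return [
            _rec(f"{family}{i}", residues_fn(i), family=family) for i in range(n)
        ]

    def test_full_inclusion_counts_as_shared(self):
        pad = "WYWYWYWYWY"
        recs_a = self._corpus(3, lambda i: pad + "GILIE" + pad, family="A")
        recs_b = self._corpus(3, lambda i: pad + "GILIEK" + pad, family="B")
        table = cross_family_shared(["GILIE"], ["GILIEK"], recs_a, recs_b,
                                    min_seqs=2)
        assert list(table["match"]) == ["GILIE"]
        assert bool(table["kept"].iloc[0])

    def test_one_mutation_apart_not_shared_but_grouped(self):
        table = cross_family_shared(["GILIE"], ["GILVE"], [], [], min_seqs=0)
        assert table.empty
        assert hamming1_groups(["GILIE", "GILVE", "GILTE", "LRAAL"]) == [
            ["GILIE", "GILTE", "GILVE"], ["LRAAL"],
        ]

    def test_symmetric_match_strings(self):
        cps_a, cps_b = ["GILIE", "AAAAAC"], ["GILIEK", "CAAAAA"]
        recs = self._corpus(2, lambda i: "GILIEK" + "W" * 5 + "CAAAAAC")
        t_ab = cross_family_shared(cps_a, cps_b, recs, recs, min_seqs=1)
        t_ba = cross_family_shared(cps_b, cps_a, recs, recs, min_seqs=1)
        assert list(t_ab["match"]) == list(t_ba["match"])

    def test_min_seqs_filter_uses_both_corpora(self):
        pad = "WYWYWYWYWY"
        recs_a = self._corpus(5, lambda i: pad + "GILIE" + pad, family="A")
        recs_b = self._corpus(2, lambda i: pad + "GILIE" + pad, family="B")
        table = cross_family_shared(["GILIE"], ["GILIE"], recs_a, recs_b,
                                    min_seqs=3)
        assert not bool(table["kept"].iloc[0])
        assert (table["n_seqs_a"].iloc[0], table["n_seqs_b"].iloc[0]) == (5, 2)


class TestShuffleControl:
    def test_shuffling_conserves_length_and_composition(self):
        rng = np.random.default_rng(0)
        records = [_rec("a", "ACDEFGHIKL" * 3), _rec("b", "WWWYYYVVVM")]
        shuffled = shuffle_residues(records, rng)
        for rec, s in zip(records, shuffled):
            assert len(s) == len(rec.residues)
            assert sorted(s) == sorted(rec.residues)

    def test_deterministic_given_seed(self):
        records = [_rec(f"s{i}", "ACDEFGHIKLMNPQRSTVWY" * 3) for i in range(4)]
        a = shuffle_control(records, n_shuffles=3, seed=5)
        b = shuffle_control(records, n_shuffles=3, seed=5)
        assert a.equals(b)

    def test_single_letter_sequences_unchanged_by_shuffling(self):
        records = [_rec(f"s{i}", "A" * 40) for i in range(5)]
        table = shuffle_control(records, n_shuffles=4, seed=1)
        assert table["n_motifs"].nunique() == 1
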