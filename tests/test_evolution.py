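"""Kingdom statistics, origin labels, enrichment and class signatures."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cpscan.corpus import SequenceRecord
from cpscan.evolution import (
    class_signatures,
    classify_origin,
    exclusive_shared_cps,
    family_kingdom_specific_cps,
    kingdom_cp_stats,
    mito_enrichment,
    origin_distribution,
)


def _rec(id, family="F", kingdom="Bacteria", organelle="nuclear", cls="I"):
    return SequenceRecord(id=id, family=family, kingdom=kingdom,
                          organelle=organelle, residues="ACDEFGHIKL",
                          class_label=cls)


def _hits(rows):
    """(seq_id, cp) rows with dummy spans."""
    return pd.DataFrame(
        [(s, c, 0, len(c)) for s, c in rows],
        columns=["seq_id", "cp", "start", "end"],
    )


class TestKingdomStats:
    RECORDS = [
        _rec("b", kingdom="Bacteria"),
        _rec("e", kingdom="Eukarya"),
        _rec("a", kingdom="Archaea"),
        _rec("m", kingdom="Eukarya", organelle="mito"),
    ]

    def test_ubiquitous_cp_is_present_everywhere_specific_nowhere(self):
        hits = _hits([(s, "KMSKS") for s in "beam"])
        stats = kingdom_cp_stats(hits, self.RECORDS)
        assert (stats["pct_of_all_cps"] == 100.0).all()
        assert (stats["pct_specific"] == 0.0).all()

    def test_single_group_cp_counts_as_specific(self):
        hits = _hits([("b", "KMSKS"), ("b", "WQHRK"), ("e", "WQHRK")])
        stats = kingdom_cp_stats(hits, self.RECORDS)
        assert stats.at["Bacteria", "pct_of_all_cps"] == 100.0
        assert stats.at["Bacteria", "pct_specific"] == 50.0
        assert stats.at["Eukarya", "pct_specific"] == 0.0
        assert stats.at["Archaea", "n_cps_observed"] == 0

    def test_matches_set_algebra_recount_on_random_assignment(self):
        rng = np.random.default_rng(0)
        records = [
            _rec(f"s{i}",
                 kingdom=rng.choice(["Bacteria", "Eukarya", "Archaea"]),
                 organelle=rng.choice(["nuclear", "mito"]))
            for i in range(30)
        ]
        cps = [f"CP{j:02d}AB"[:5] + "AAAAA" for j in range(8)]
        cps = [f"MOTIF{j}" for j in range(8)]
        rows = [
            (r.id, cp) for r in records for cp in cps if rng.random() < 0.3
        ]
        if not rows:
            rows = [(records[0].id, cps[0])]
        stats = kingdom_cp_stats(_hits(rows), records)
        group_of = {r.id: r.group for r in records}
        presence = {}
        for seq_id, cp in rows:
            presence.setdefault(cp, set()).add(group_of[seq_id])
        all_cps = {cp for _s, cp in rows}
        for g in stats.index:
            observed = {cp for cp, gs in presence.items() if g in gs}
            specific = {cp for cp, gs in presence.items() if gs == {g}}
            assert stats.at[g, "n_cps_observed"] == len(observed)
            assert stats.at[g, "n_specific_cps"] == len(specific)
            if observed:
                assert stats.at[g, "pct_specific"] == pytest.approx(
                    100 * len(specific) / len(observed)
                )


class TestClassifyOrigin:
    @pytest.mark.parametrize(
        "presence,label",
        [
            ({"Bacteria", "Eukarya", "Archaea"}, "ALL3"),
            ({"Archaea", "Eukarya"}, "AE"),
            ({"Bacteria"}, "B_only"),
            ({"Archaea"}, "A_only"),
            ({"Eukarya"}, "E_only"),
            ({"Bacteria", "Eukarya"}, "BE"),
            ({"Bacteria", "Archaea"}, "other"),
        ],
    )
    def test_presence_set_maps_to_origin_label(self, presence, label):
        assert classify_origin(presence) == label

    def test_empty_or_unknown_presence_rejected(self):
        with pytest.raises(ValueError):
            classify_origin(set())
        with pytest.raises(ValueError):
            classify_origin({"Mitochondria"})

    def test_origin_distribution_excludes_mitochondrial_hits(self):
        records = [
            _rec("b", kingdom="Bacteria"),
            _rec("m", kingdom="Eukarya", organelle="mito"),
        ]
        hits = _hits([("b", "KMSKS"), ("m", "KMSKS")])
        table = origin_distribution(hits, records)
        assert table.at["F", "B_only"] == 1


class TestFamilyKingdomSpecific:
    RECORDS = [
        _rec("fb", family="F", kingdom="Bacteria"),
        _rec("fa", family="F", kingdom="Archaea"),
        _rec("fm", family="F", kingdom="Eukarya", organelle="mito"),
        _rec("ga", family="G", kingdom="Archaea"),
    ]

    def test_specific_within_family_despite_other_family_hits(self):
        # the CP also hits Archaea — but only in family G
        hits = _hits([("fb", "KMSKS"), ("ga", "KMSKS")])
        assert family_kingdom_specific_cps(hits, self.RECORDS, "F", "Bacteria") == [
            "KMSKS"
        ]

    def test_two_kingdom_cp_excluded(self):
        hits = _hits([("fb", "KMSKS"), ("fa", "KMSKS")])
        assert family_kingdom_specific_cps(hits, self.RECORDS, "F", "Bacteria") == []

    def test_mitochondrial_hits_do_not_define_specificity(self):
        hits = _hits([("fb", "KMSKS"), ("fm", "KMSKS")])
        assert family_kingdom_specific_cps(hits, self.RECORDS, "F", "Bacteria") == [
            "KMSKS"
        ]

    def test_taxon_specific_cps_keyed_on_header_tag(self):
        from cpscan.evolution import family_taxon_specific_cps
        from dataclasses import replace

        records = [
            replace(self.RECORDS[0], taxon="Rickettsia"),
            replace(self.RECORDS[1], taxon="Halo"),
            self.RECORDS[3],
        ]
        hits = _hits([("fb", "KMSKS"), ("fb", "WQHRK"), ("fa", "WQHRK")])
        assert family_taxon_specific_cps(hits, records, "F", "Rickettsia") == [
            "KMSKS"
        ]


class TestMitoEnrichment:
    def _design(self):
        """Family with 3 bacterial, 2 eukaryal nuclear and 2 mito sequences."""
        records = [
            _rec("b1"), _rec("b2"), _rec("b3"),
            _rec("e1", kingdom="Eukarya"), _rec("e2", kingdom="Eukarya"),
            _rec("m1", kingdom="Eukarya", organelle="mito"),
            _rec("m2", kingdom="Eukarya", organelle="mito"),
        ]
        rows = []
        # 4 Bacteria-specific CPs, all hitting mito too
        for j in range(4):
            rows += [("b1", f"BSPEC{j}"), ("m1", f"BSPEC{j}")]
        # 5 Eukarya-specific CPs, none hitting mito
        for j in range(5):
            rows += [("e1", f"ESPEC{j}")]
        # 1 nonspecific CP hitting mito
        rows += [("b2", "SHARE0"), ("e2", "SHARE0"), ("m2", "SHARE0")]
        return records, _hits(rows)

    def test_bookkeeping_and_hypergeometric_value(self):
        records, hits = self._design()
        table, skipped = mito_enrichment(hits, records)
        row = table[(table.family == "F") & (table.kingdom == "Bacteria")].iloc[0]
        assert (row.N, row.K, row.n, row.k) == (10, 4, 5, 4)
        expected = comb(4, 4) * comb(6, 1) / comb(10, 5)
        assert row.p == pytest.approx(expected)
        erow = table[(table.family == "F") & (table.kingdom == "Eukarya")].iloc[0]
        assert (erow.K, erow.k) == (5, 0)
        assert erow.p == pytest.approx(1.0)
        assert skipped == []

    def test_degenerate_all_success_urn_has_p_one(self):
        records = [_rec("b1"), _rec("m1", kingdom="Eukarya", organelle="mito")]
        hits = _hits([("b1", "KMSKS"), ("m1", "KMSKS")])
        table, _ = mito_enrichment(hits, records)
        row = table[(table.kingdom == "Bacteria")].iloc[0]
        assert (row.N, row.K, row.n, row.k) == (1, 1, 1, 1)
        assert row.p == 1.0

    def test_textbook_hypergeometric_example(self):
        from scipy.stats import hypergeom

        assert hypergeom.sf(3, 10, 5, 4) == pytest.approx(5 / 210)

    def test_upper_tail_matches_exhaustive_enumeration(self):
        """Oracle: P(X >= k) by enumerating all draws for small urns."""
        from scipy.stats import hypergeom

        for N, K, n in [(10, 5, 4), (12, 7, 6), (8, 3, 5), (12, 12, 4)]:
            items = [1] * K + [0] * (N - K)
            total = comb(N, n)
            for k in range(0, n + 1):
                count = sum(
                    1 for draw in combinations(range(N), n)
                    if sum(items[i] for i in draw) >= k
                )
                assert hypergeom.sf(k - 1, N, K, n) == pytest.approx(count / total)

    def test_bh_adjustment_matches_hand_computation(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042])
        _rej, q, _a, _b = multipletests(p, method="fdr_bh")
        assert np.allclose(q, [0.005, 0.02, 0.042, 0.042, 0.042])

    def test_families_without_mitochondria_are_skipped(self):
        records = [_rec("b1", family="X")]
        hits = _hits([("b1", "KMSKS")])
        table, skipped = mito_enrichment(hits, records)
        assert table.empty
        assert skipped == ["X"]

    def test_planted_bacterial_mito_design_enriched(self, evolution_space,
                                                    evolution_design):
        table, _ = mito_enrichment(evolution_space.hits,
                                   list(evolution_space.records))
        fam = evolution_design.mito_family
        bac = table[(table.family == fam) & (table.kingdom == "Bacteria")].iloc[0]
        euk = table[(table.family == fam) & (table.kingdom == "Eukarya")].iloc[0]
        assert bool(bac.enriched) and bac.q < 0.01
        assert not bool(euk.enriched)


class TestClassSignatures:
    def _records(self):
        out = []
        for i in range(7):
            out.append(_rec(f"i{i}", family=f"I{i}", cls="I"))
            out.append(_rec(f"h{i}", family=f"H{i}", cls="II"))
        return out

    def test_cp_across_seven_class_I_families_qualifies(self):
        hits = _hits([(f"i{i}", "WQHRK") for i in range(7)])
        sigs = class_signatures(hits, self._records())
        assert [(s.cp, s.preferred_class) for s in sigs] == [("WQHRK", "I")]
        assert sigs[0].families_I == 7 and sigs[0].families_II == 0

    def test_balanced_cp_is_no_signature(self):
        hits = _hits(
            [(f"i{i}", "WQHRK") for i in range(6)]
            + [(f"h{i}", "WQHRK") for i in range(6)]
        )
        assert class_signatures(hits, self._records()) == []

    def test_stop_list_motifs_excluded(self):
        hits = _hits([(f"i{i}", "AKMSKSL") for i in range(7)])
        assert class_signatures(hits, self._records()) == []
        kept = class_signatures(hits, self._records(), stop_list=())
        assert [s.cp for s in kept] == ["AKMSKSL"]

    def test_minor_other_class_presence_tolerated(self):
        hits = _hits(
            [(f"i{i}", "WQHRK") for i in range(7)] * 10  # 70 class-I occurrences
            + [("h0", "WQHRK")]
        )
        sigs = class_signatures(hits, self._records())
        assert [s.preferred_class for s in sigs] == ["I"]

    def test_unlabelled_family_rejected(self):
        records = [_rec("x", family="X", cls="unknown")]
        with pytest.raises(ValueError, match="class"):
            class_signatures(_hits([("x", "WQHRK")]), records)

    def test_planted_signatures_recovered(self, evolution_space,
                                          evolution_design):
        sigs = class_signatures(evolution_space.hits,
                                list(evolution_space.records))
        by_class = {s.preferred_class: s.cp for s in sigs}
        assert by_class["I"] == evolution_design.class_I_signature
        assert by_class["II"] == evolution_design.class_II_signature


class TestExclusiveShared:
    def _records(self):
        return [
            _rec(f"s{i}", family=f"F{i}", cls="I") for i in range(4)
        ] + [_rec("h0", family="H0", cls="II")]

    def test_cps_present_in_every_family_of_full_subset(self):
        rows = [(f"s{i}", "WQHRK") for i in range(4)]
        res = exclusive_shared_cps(_hits(rows), self._records(),
                                   [f"F{i}" for i in range(4)])
        assert res.cps == ("WQHRK",)

    def test_partial_coverage_excluded(self):
        rows = [(f"s{i}", "WQHRK") for i in range(3)]
        res = exclusive_shared_cps(_hits(rows), self._records(),
                                   [f"F{i}" for i in range(4)])
        assert res.cps == ()
        # but the triple itself has it
        res3 = exclusive_shared_cps(_hits(rows), self._records(),
                                    ["F0", "F1", "F2"])
        assert res3.cps == ("WQHRK",)

    def test_outside_hit_breaks_exclusivity(self):
        rows = [(f"s{i}", "WQHRK") for i in range(4)] + [("h0", "WQHRK")]
        # h0 is class II, so the quartet cannot include it; CP not exclusive
        res = exclusive_shared_cps(_hits(rows), self._records(),
                                   [f"F{i}" for i in range(4)])
        assert res.cps == ()

    def test_mixed_class_subset_rejected(self):
        with pytest.raises(ValueError, match="class"):
            exclusive_shared_cps(_hits([("s0", "WQHRK")]), self._records(),
                                 ["F0", "H0"])

    def test_planted_quartet_recovered_exactly(self, evolution_space,
                                               evolution_design):
        res = exclusive_shared_cps(
            evolution_space.hits, list(evolution_space.records),
            evolution_design.quartet,
        )
        assert sorted(res.cps) == sorted(evolution_design.quartet_motifs)
        assert res.max_other <= 1
        assert len(res.subset_counts) == comb(7, 4)
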