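"""Alignment, LCA assignment, exclusivity, collation and filtering."""

import numpy as np
import pytest

from sedadna._seq import revcomp
from sedadna.classify import (
    Hit,
    assign_read,
    checklist_filter,
    classify_reads,
    collate_profile,
    exclusive_confirm,
    hits_from_sam,
    hits_from_tsv,
    hits_to_sam,
    hits_to_tsv,
    match_read,
    subtract_control_taxa,
)
from sedadna.classify import Assignment
from sedadna.simulate import DamageModel, make_reference_db, make_taxonomy
from sedadna.taxdb import ReferenceDB, RefSeq


class TestMatchRead:
    def test_exact_substring_single_hit(self, db_5pct):
        genome = db_5pct.entries[0].sequence
        read = genome[100:160]
        hits = match_read(read, db_5pct, 0)
        exact = [h for h in hits if h.mismatches == 0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.seq_id, h.start, h.strand) == (db_5pct.entries[0].seq_id, 100, "+")
        assert h.identity == 1.0

    def test_reverse_complement_hits_minus_strand(self, db_5pct):
        genome = db_5pct.entries[0].sequence
        read = revcomp(genome[200:260])
        hits = [h for h in match_read(read, db_5pct, 0) if h.mismatches == 0]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].start == 200

    def test_three_mismatches_beyond_slack_empty(self, db_5pct):
        genome = db_5pct.entries[0].sequence
        read = list(genome[300:360])
        for i in (5, 25, 45):
            read[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[i]]
        read = "".join(read)
        hits = [
            h
            for h in match_read(read, db_5pct, 2)
            if h.seq_id == db_5pct.entries[0].seq_id
        ]
        assert hits == []

    def test_parameter_and_format_errors(self, db_5pct):
        with pytest.raises(ValueError, match="below minimum"):
            match_read("ACGT", db_5pct, 0)
        with pytest.raises(ValueError, match="max_mismatches"):
            match_read("A" * 40, db_5pct, 4)
        with pytest.raises(ValueError, match="non-ACGTN"):
            match_read("ACGTX" * 8, db_5pct, 0)

    def test_n_never_matches(self):
        db = ReferenceDB([RefSeq("g", 1, "ACGT" * 20)])
        read = "N" + "ACGT" * 10 + "CGT"  # N over an A position
        hits = match_read(read[:40], db, 0)
        assert all(h.mismatches > 0 for h in hits) or hits == []


class TestAssignRead:
    def _hit(self, taxon, mm, read_len=50):
        return Hit("r1", f"ref_{taxon}", taxon, 0, "+", mm, read_len)

    def test_congener_perfect_hits_lca_to_genus(self, taxonomy_2f):
        a = assign_read([self._hit(4, 0), self._hit(5, 0)], taxonomy_2f)
        assert a.taxon_id == 3  # genus of species 4 and 5
        assert a.n_perfect_hits == 2 and a.n_taxa_hit == 2

    def test_imperfect_hit_discarded(self, taxonomy_2f):
        a = assign_read([self._hit(4, 0), self._hit(7, 1)], taxonomy_2f)
        assert a.taxon_id == 4

    def test_only_imperfect_hits_unassigned(self, taxonomy_2f):
        assert assign_read([self._hit(4, 1), self._hit(5, 2)], taxonomy_2f) is None
        assert assign_read([], taxonomy_2f) is None

    def test_assignment_is_ancestor_of_every_perfect_taxon(self, taxonomy_2f, rng):
        species = [4, 5, 7, 8, 11, 12, 14, 15]
        for _ in range(50):
            k = int(rng.integers(1, 5))
            taxa = rng.choice(species, size=k, replace=False)
            hits = [self._hit(int(t), 0) for t in taxa]
            a = assign_read(hits, taxonomy_2f)
            for t in taxa:
                assert taxonomy_2f.is_ancestor_or_self(a.taxon_id, int(t))


class TestEndToEnd:
    def test_lineage_recovery_no_cross_family(self, db_5pct, taxonomy_2f, clean_reads):
        reads, truth = clean_reads
        assignments, unassigned = classify_reads(reads, db_5pct, taxonomy_2f, 2)
        truth_of = dict(zip(truth.read_id, truth.taxon_id))
        n_lineage = 0
        for a in assignments:
            true_sp = truth_of[a.read_id]
            true_family = taxonomy_2f.ancestor_at_rank(true_sp, "family")
            a_family = taxonomy_2f.ancestor_at_rank(a.taxon_id, "family")
            if a_family is not None:
                assert a_family == true_family  # zero cross-family
            if taxonomy_2f.is_ancestor_or_self(a.taxon_id, true_sp):
                n_lineage += 1
        assert n_lineage / len(reads) >= 0.99
        assert len(assignments) + len(unassigned) == len(reads)

    def test_duplicate_reads_assigned_identically(self, db_5pct, taxonomy_2f):
        genome = db_5pct.entries[0].sequence
        from sedadna.simulate import Read

        reads = [Read("a", genome[10:60]), Read("b", genome[10:60])]
        assignments, _ = classify_reads(reads, db_5pct, taxonomy_2f, 0)
        assert len(assignments) == 2
        assert assignments[0].taxon_id == assignments[1].taxon_id


class TestExclusiveConfirm:
    def test_unique_read_confirmed(self, db_5pct):
        # species 4's genome diverges ~5% from its congener: most 60-mers
        # carry >=3 differences and are exclusive
        genome = db_5pct.sequences_of(4)[0].sequence
        confirmed = [
            exclusive_confirm(genome[i : i + 60], 4, db_5pct, slack=2)
            for i in range(0, 300, 60)
        ]
        assert any(confirmed)

    def test_shared_read_rejected(self):
        tax = make_taxonomy(1, 1, 2)
        db = make_reference_db(tax, 500, 0.0, seed=1)  # identical congeners
        read = db.sequences_of(4)[0].sequence[50:110]
        assert not exclusive_confirm(read, 4, db, slack=2)
        assert not exclusive_confirm(read, 5, db, slack=2)

    def test_imperfect_focal_placement_rejected(self, db_5pct):
        genome = db_5pct.sequences_of(4)[0].sequence
        read = list(genome[100:160])
        read[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[30]]
        assert not exclusive_confirm("".join(read), 4, db_5pct, slack=2)

    def test_mutual_exclusivity_over_planted_reads(self, db_5pct, clean_reads):
        reads, _ = clean_reads
        taxa = db_5pct.taxa()
        for r in list(reads)[:300]:
            confirmed = [t for t in taxa if exclusive_confirm(r.sequence, t, db_5pct, 2)]
            assert len(confirmed) <= 1


class TestCollation:
    def _assignments(self, pairs):
        return [Assignment(f"r{i}", t, 1, 1) for i, t in enumerate(pairs)]

    def test_stated_rule_genus_and_family(self, taxonomy_2f):
        # 10 reads to species 4 (genus 3), 2 reads to family 2
        assigns = self._assignments([4] * 10 + [2] * 2)
        samples = {a.read_id: "S1" for a in assigns}
        genus = collate_profile(assigns, taxonomy_2f, "genus", samples)
        assert genus.counts.loc[3, "S1"] == 10
        assert int(genus.above_rank["S1"]) == 2
        family = collate_profile(assigns, taxonomy_2f, "family", samples)
        assert family.counts.loc[2, "S1"] == 12
        assert int(family.above_rank.sum()) == 0

    def test_root_assignment_excluded_everywhere(self, taxonomy_2f):
        assigns = self._assignments([1])
        samples = {"r0": "S1"}
        for rank in ("family", "genus", "species"):
            m = collate_profile(assigns, taxonomy_2f, rank, samples)
            assert m.total() == 0 and int(m.above_rank.sum()) == 1

    def test_empty_assignments_empty_matrix(self, taxonomy_2f):
        m = collate_profile([], taxonomy_2f, "genus", {})
        assert m.total() == 0 and len(m.counts) == 0

    def test_conservation_ledger_balances(self, db_5pct, taxonomy_2f, clean_reads):
        reads, _ = clean_reads
        assignments, unassigned = classify_reads(reads, db_5pct, taxonomy_2f, 2)
        samples = {r.read_id: f"S{int(r.read_id[1:]) % 3}" for r in reads}
        m = collate_profile(assignments, taxonomy_2f, "genus", samples)
        assert m.total() + int(m.above_rank.sum()) + len(unassigned) == len(reads)

    def test_unknown_sample_raises(self, taxonomy_2f):
        with pytest.raises(KeyError, match="sample"):
            collate_profile(self._assignments([4]), taxonomy_2f, "genus", {})


class TestFilters:
    def _matrix(self, taxonomy, data, samples):
        import pandas as pd

        assigns, mapping = [], {}
        i = 0
        for (taxon, sample), n in data.items():
            for _ in range(n):
                assigns.append(Assignment(f"r{i}", taxon, 1, 1))
                mapping[f"r{i}"] = sample
                i += 1
        return collate_profile(assigns, taxonomy, "genus", mapping)

    def test_control_subtraction_removes_whole_rows(self, taxonomy_2f):
        m = self._matrix(taxonomy_2f, {(4, "S1"): 100, (7, "S1"): 50}, ["S1"])
        ctrl = self._matrix(taxonomy_2f, {(7, "C1"): 1}, ["C1"])
        out = subtract_control_taxa(m, [ctrl])
        assert 3 in out.counts.index  # genus of species 4 retained
        assert 6 not in out.counts.index  # genus of species 7 removed
        assert any("control-subtraction" in line for line in out.log)

    def test_empty_controls_unchanged(self, taxonomy_2f):
        m = self._matrix(taxonomy_2f, {(4, "S1"): 10}, ["S1"])
        out = subtract_control_taxa(m, [])
        assert out.counts.equals(m.counts)

    def test_controls_covering_everything_empty_matrix(self, taxonomy_2f):
        m = self._matrix(taxonomy_2f, {(4, "S1"): 10}, ["S1"])
        ctrl = self._matrix(taxonomy_2f, {(4, "C1"): 2}, ["C1"])
        assert subtract_control_taxa(m, [ctrl]).counts.empty

    def test_rank_mismatch_rejected(self, taxonomy_2f):
        m = self._matrix(taxonomy_2f, {(4, "S1"): 10}, ["S1"])
        bad = collate_profile(
            [Assignment("r0", 4, 1, 1)], taxonomy_2f, "family", {"r0": "C1"}
        )
        with pytest.raises(ValueError, match="rank"):
            subtract_control_taxa(m, [bad])

    def test_checklist_drops_off_list_regardless_of_count(self, taxonomy_2f):
        m = self._matrix(taxonomy_2f, {(4, "S1"): 1000, (7, "S1"): 10}, ["S1"])
        out = checklist_filter(m, {"Genus_1_2"}, taxonomy_2f, min_reads=1)
        assert 3 not in out.counts.index  # Genus_1_1 off checklist, dropped
        assert 6 in out.counts.index
        assert any("Genus_1_1" in line for line in out.log)

    def test_min_reads_zeroes_cells_and_min_samples_drops_rows(self, taxonomy_2f):
        m = self._matrix(
            taxonomy_2f, {(4, "S1"): 2, (4, "S2"): 5, (7, "S1"): 2, (7, "S2"): 2}, None
        )
        out = checklist_filter(
            m, {"Genus_1_1", "Genus_1_2"}, taxonomy_2f, min_reads=3, min_samples=1
        )
        assert out.counts.loc[3, "S1"] == 0 and out.counts.loc[3, "S2"] == 5
        assert 6 not in out.counts.index  # both cells zeroed -> row dropped

    def test_permissive_settings_leave_matrix_unchanged(self, taxonomy_2f):
        m = self._matrix(taxonomy_2f, {(4, "S1"): 5, (7, "S1"): 5}, ["S1"])
        out = checklist_filter(
            m, {"Genus_1_1", "Genus_1_2"}, taxonomy_2f, min_reads=1, min_samples=1
        )
        assert out.counts.equals(m.counts)


class TestHitIO:
    def test_tsv_round_trip(self, db_5pct, tmp_path):
        genome = db_5pct.entries[0].sequence
        hits = match_read(genome[50:110], db_5pct, 2, read_id="rx")
        hits_to_tsv(hits, tmp_path / "h.tsv")
        assert hits_from_tsv(tmp_path / "h.tsv") == hits

    def test_sam_round_trip_with_nm_tag(self, db_5pct, tmp_path):
        genome = db_5pct.entries[0].sequence
        reads = {"rx": revcomp(genome[50:110])}
        hits = match_read(reads["rx"], db_5pct, 2, read_id="rx")
        hits_to_sam(hits, db_5pct, reads, tmp_path / "h.sam")
        back = hits_from_sam(tmp_path / "h.sam", db_5pct)
        assert sorted(back, key=lambda h: (h.seq_id, h.start)) == sorted(
            hits, key=lambda h: (h.seq_id, h.start)
        )
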