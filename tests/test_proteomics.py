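import math
from fractions import Fraction
from itertools import combinations

import pytest

from altorf import proteomics as px


class TestBuildSearchFasta:
    def test_sizes(self):
        entries = px.build_search_fasta(
            {"r1": "MKA", "r2": "MRP"}, {"a1": "MAA", "a2": "MCC", "a3": "MDD"},
            {"c1": "MEE"})
        assert len(entries) == 12
        assert sum(1 for e in entries if e.kind == "decoy") == 6

    def test_decoy_is_reversal(self):
        entries = px.build_search_fasta({"r1": "MKAV"}, {}, {})
        decoy = [e for e in entries if e.kind == "decoy"][0]
        assert decoy.sequence == "VAKM"
        assert decoy.source_id == "r1"
        assert decoy.id == "REV_r1"

    def test_reversal_is_involution(self):
        entries = px.build_search_fasta({"r1": "MKAVQ"}, {}, {})
        decoy = [e for e in entries if e.kind == "decoy"][0]
        assert decoy.sequence[::-1] == "MKAVQ"

    def test_id_collision_errors(self):
        with pytest.raises(ValueError, match="collision"):
            px.build_search_fasta({"x": "MK"}, {"x": "MR"}, {})


class TestDigestTryptic:
    def test_no_missed_cleavages(self):
        peps = {p.sequence for p in px.digest_tryptic("MKAAARPK", 0, 1, 40)}
        assert peps == {"MK", "AAAR", "PK"}  # trypsin/P cleaves before proline

    def test_two_missed_cleavages(self):
        peps = {p.sequence for p in px.digest_tryptic("MKAAARPK", 2, 1, 40)}
        assert peps == {"MK", "AAAR", "PK", "MKAAAR", "AAARPK", "MKAAARPK"}

    def test_no_cleavage_sites(self):
        (pep,) = px.digest_tryptic("MAAAW", 2, 1, 40)
        assert (pep.sequence, pep.start, pep.end) == ("MAAAW", 1, 5)

    def test_length_filter(self):
        peps = {p.sequence for p in px.digest_tryptic("MKAAARPK", 2, 6, 40)}
        assert peps == {"MKAAAR", "AAARPK", "MKAAARPK"}

    def test_coordinates_and_missed_counts(self):
        by_seq = {p.sequence: p for p in px.digest_tryptic("MKAAARPK", 2, 1, 40)}
        assert (by_seq["AAAR"].start, by_seq["AAAR"].end) == (3, 6)
        assert by_seq["MKAAARPK"].missed_cleavages == 2

    def test_mc0_fragments_concatenate_to_protein(self):
        protein = "MKTTRAAAPKWWKLLR"
        frags = px.digest_tryptic(protein, 0, 1, 10**6)
        assert "".join(p.sequence for p in sorted(frags, key=lambda p: p.start)) == protein


def _db(**proteins):
    ref = {k: v for k, v in proteins.items() if k.startswith("r")}
    alt = {k: v for k, v in proteins.items() if k.startswith("a")}
    return px.build_search_fasta(ref, alt, {})


class TestMapPeptides:
    def test_unique_peptide(self):
        db = _db(r1="MKAVLLRTESTK", a1="MSSSPER")
        m = px.map_peptides([px.PeptideObservation("AVLLR")], db)
        (obs,) = m.observations
        assert obs.assigned_proteins == {"r1"}
        assert obs.is_unique

    def test_shared_peptide_two_groups_not_unique(self):
        db = _db(r1="MKAVLLRTESTK", r2="MRAVLLRWWWK")
        m = px.map_peptides(
            [px.PeptideObservation("AVLLR"), px.PeptideObservation("TESTK"),
             px.PeptideObservation("WWWK")], db)
        shared = next(o for o in m.observations if o.sequence == "AVLLR")
        assert shared.assigned_proteins == {"r1", "r2"}
        assert not shared.is_unique

    def test_identical_peptide_sets_grouped(self):
        db = _db(r1="MKAVLLRTESTK", r2="MKAVLLRTESTK")
        m = px.map_peptides([px.PeptideObservation("AVLLR")], db)
        (obs,) = m.observations
        assert obs.assigned_proteins == {"r1", "r2"}
        assert obs.is_unique            # one group of two indistinguishable proteins
        assert m.groups == {"r1": ("r1", "r2")}

    def test_nontryptic_match_rejected(self):
        db = _db(r1="MKAVLLRTESTK")
        m = px.map_peptides([px.PeptideObservation("VLLR")], db)
        (obs,) = m.observations
        assert obs.assigned_proteins == frozenset()

    def test_initiator_met_cleaved_nterm_allowed(self):
        db = _db(r1="MSSSPERAAAK")
        m = px.map_peptides([px.PeptideObservation("SSSPER")], db)
        (obs,) = m.observations
        assert obs.assigned_proteins == {"r1"}

    def test_cterm_must_be_tryptic_or_protein_end(self):
        db = _db(r1="MKAVLLWRTESTK")
        m = px.map_peptides([px.PeptideObservation("AVLLW")], db)
        assert m.observations[0].assigned_proteins == frozenset()
        m2 = px.map_peptides([px.PeptideObservation("TESTK")], db)
        assert m2.observations[0].assigned_proteins == {"r1"}

    def test_decoy_only_match_flagged_and_excluded(self):
        db = _db(r1="MKAVLLR")
        # the decoy sequence is RLLVAKM; its tryptic peptide LLVAKM matches no forward entry
        m = px.map_peptides([px.PeptideObservation("LLVAKM")], db)
        (obs,) = m.observations
        assert obs.assigned_proteins == frozenset()
        assert obs.decoy_only

    def test_planted_assignments_recovered(self):
        from altorf.synthetic import PlantedDetection, generate_peptide_table
        import random

        rng = random.Random(5)
        proteins = {
            f"a{i}": "M" + "".join(rng.choices("ACDEFGHILNPQSTVWY", k=30)) + "K"
            for i in range(4)
        }
        db = px.build_search_fasta({}, proteins, {})
        plan = [PlantedDetection(f"a{i}", n_peptides=1) for i in range(4)]
        observations, _ = generate_peptide_table(db, plan, seed=9)
        m = px.map_peptides(observations, db)
        assigned = sorted(p for o in m.observations for p in o.assigned_proteins)
        assert assigned == sorted(proteins)


class TestFilterIdentifications:
    def _s(self, pep, unique):
        return px.DetectionSummary("p", n_unique_peptides=unique, pep_score=pep)

    def test_boundary_inside(self):
        assert px.filter_identifications([self._s(0.049, 1)])

    def test_boundary_rejected_strict(self):
        assert px.filter_identifications([self._s(0.05, 1)]) == []

    def test_no_unique_rejected(self):
        assert px.filter_identifications([self._s(0.01, 0)]) == []

    def test_missing_pep_rejected(self):
        assert px.filter_identifications([self._s(None, 3)]) == []


class TestComputeCoverage:
    def _pep(self, start, end):
        return px.Peptide("X" * (end - start + 1), start, end, 0)

    def test_union_arithmetic(self):
        assert px.compute_coverage("A" * 10, [self._pep(1, 5), self._pep(4, 8)]) == 80.0

    def test_no_peptides(self):
        assert px.compute_coverage("A" * 10, []) == 0.0

    def test_full_span(self):
        assert px.compute_coverage("A" * 10, [self._pep(1, 10)]) == 100.0

    def test_duplication_and_order_invariant(self):
        peps = [self._pep(1, 5), self._pep(4, 8)]
        base = px.compute_coverage("A" * 10, peps)
        assert px.compute_coverage("A" * 10, peps * 3) == base
        assert px.compute_coverage("A" * 10, list(reversed(peps))) == base

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            px.compute_coverage("A" * 10, [self._pep(5, 11)])


class TestValidateTis:
    def _obs(self, acetyl):
        return px.PeptideObservation("STEAK", is_nterm_acetylated=acetyl)

    def test_met_cleavage_rule(self):
        assert px.validate_tis("MSTEAKWWW", [(self._obs(True), 2)])

    def test_internal_acetylation_rejected(self):
        assert not px.validate_tis("MSTEAKWWW", [(self._obs(True), 5)])

    def test_position_one(self):
        assert px.validate_tis("STEAKWWW", [(self._obs(True), 1)])

    def test_acetylation_required(self):
        assert not px.validate_tis("STEAKWWW", [(self._obs(False), 1)])

    def test_position_two_without_met_rejected(self):
        assert not px.validate_tis("WSTEAK", [(self._obs(True), 2)])


class TestCoexpression:
    GENE = {"r1": "GA", "a1": "GA", "r2": "GB", "a3": "GC"}
    KIND = {"r1": "reference", "a1": "alternative", "r2": "reference",
            "a3": "alternative"}

    def _det(self, pid, intensity=10.0):
        return px.DetectionSummary(pid, mean_intensity=intensity)

    def test_gene_with_both_included_with_intensities(self):
        out = px.coexpression_genes(
            [self._det("r1", 10.0), self._det("a1", 4.0)], self.GENE, self.KIND)
        assert out == [px.CoexpressedGene("GA", 10.0, 4.0)]

    def test_gene_with_only_one_kind_excluded(self):
        assert px.coexpression_genes([self._det("r2")], self.GENE, self.KIND) == []
        assert px.coexpression_genes([self._det("a3")], self.GENE, self.KIND) == []

    def test_planted_k_coexpressed(self):
        gene = {}
        kind = {}
        dets = []
        for i in range(7):
            gene[f"r{i}"] = gene[f"a{i}"] = f"G{i}"
            kind[f"r{i}"] = "reference"
            kind[f"a{i}"] = "alternative"
            dets.append(self._det(f"r{i}"))
            if i < 3:  # plant exactly 3 co-expressed genes
                dets.append(self._det(f"a{i}"))
        out = px.coexpression_genes(dets, gene, kind)
        assert [g.gene_symbol for g in out] == ["G0", "G1", "G2"]


def brute_force_overlap_tail(n_a, n_b, k, universe):
    """Exact P(X >= k) by enumerating all C(universe, n_b) draws (rationals)."""
    population = range(universe)
    fixed = set(range(n_a))
    hits = total = 0
    for draw in combinations(population, n_b):
        total += 1
        if len(fixed.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


class TestOverlapEnrichment:
    def test_k_zero_is_one(self):
        assert px.overlap_enrichment(2, 2, 0, 10) == 1.0

    def test_exact_small_case(self):
        assert px.overlap_enrichment(2, 2, 2, 10) == pytest.approx(1 / 45, rel=1e-12)

    def test_forced_full_overlap(self):
        assert px.overlap_enrichment(5, 5, 5, 5) == 1.0

    @pytest.mark.parametrize("universe", [8, 11])
    def test_matches_brute_force_enumeration(self, universe):
        for n_a in range(0, universe + 1, 3):
            for n_b in range(1, universe + 1, 3):
                for k in range(max(0, n_a + n_b - universe), min(n_a, n_b) + 1):
                    expected = brute_force_overlap_tail(n_a, n_b, k, universe)
                    got = px.overlap_enrichment(n_a, n_b, k, universe)
                    assert got == pytest.approx(float(expected), rel=1e-10), (
                        n_a, n_b, k, universe)

    def test_monotone_nonincreasing_in_k(self):
        values = [px.overlap_enrichment(12, 9, k, 40) for k in range(10)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_extreme_tail_in_log_space(self):
        p = px.overlap_enrichment(129, 45, 14, 83886)
        assert 0 < p < 1e-20
        assert math.isfinite(math.log10(p))

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            px.overlap_enrichment(2, 2, 3, 10)
        with pytest.raises(ValueError):
            px.overlap_enrichment(11, 2, 1, 10)
        with pytest.raises(ValueError):
            px.overlap_enrichment(9, 9, 0, 10)  # overlap of at least 8 is forced
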