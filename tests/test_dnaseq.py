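"""Exact-match gRNA search, presence/design matrices, anomaly classification."""

import numpy as np
import pandas as pd
import pytest

from yeastgates.circuit_model import parse_strain_label
from yeastgates.dnaseq import (
    EXPECTED,
    UNEXPECTED_ABSENCE,
    UNEXPECTED_PRESENCE,
    AnomalyMatrix,
    GRNALibrary,
    PresenceMatrix,
    build_design_matrix,
    build_results_matrix,
    coverage_estimate,
    design_compatibility,
    find_anomalies,
    read_fasta_reads,
    reverse_complement,
    search_grna,
)


def _strain(label, grnas):
    return parse_strain_label(label).with_grnas(grnas)


class TestSearch:
    def test_direct_substring(self):
        assert search_grna(["TTACGTACGTTT"], "ACGTACGT") == 1

    def test_reverse_complement_hit(self):
        grna = "ACGTAACCGG"
        read = "TT" + reverse_complement(grna) + "AA"
        assert search_grna([read], grna) == 1

    def test_miss(self):
        assert search_grna(["AAAAAAAAAA"], "CCCC") == 0

    def test_ambiguous_bases_never_match(self):
        with pytest.raises(ValueError):
            search_grna(["AAAA"], "ANC")  # N in the gRNA is an error
        assert search_grna(["AACNGG"], "ACGG") == 0  # N in read mismatches

    def test_min_hits_threshold(self):
        reads = ["TTAAACCC", "GGAAACCCT"]
        assert search_grna(reads, "AAACCC", min_hits=2) == 1
        assert search_grna(reads, "AAACCC", min_hits=3) == 0

    def test_matches_naive_double_loop_oracle(self, rng):
        bases = np.array(list("ACGT"))
        grna = "".join(rng.choice(bases, 8))
        rc = reverse_complement(grna)
        reads = []
        for i in range(1000):
            read = "".join(rng.choice(bases, 30))
            if i % 7 == 0:  # plant an insertion
                pos = int(rng.integers(0, 22))
                read = read[:pos] + grna + read[pos + 8:]
            reads.append(read)

        def naive(read, pat):
            for i in range(len(read) - len(pat) + 1):
                if all(read[i + j] == pat[j] for j in range(len(pat))):
                    return True
            return False

        expect = int(any(naive(r, grna) or naive(r, rc) for r in reads))
        assert search_grna(reads, grna) == expect
        # per-read agreement too
        for r in reads:
            assert search_grna([r], grna) == int(naive(r, grna) or naive(r, rc))

    def test_invariant_under_reverse_complementing_reads(self, rng):
        bases = np.array(list("ACGT"))
        grna = "".join(rng.choice(bases, 10))
        reads = ["".join(rng.choice(bases, 40)) for _ in range(50)]
        reads[13] = reads[13][:5] + grna + reads[13][15:]
        rc_reads = [reverse_complement(r) for r in reads]
        assert search_grna(reads, grna) == search_grna(rc_reads, grna)


class TestLibrary:
    def test_validation(self):
        with pytest.raises(ValueError):
            GRNALibrary({"r1": ""})
        with pytest.raises(ValueError):
            GRNALibrary({"r1": "ACGN"})

    def test_fasta_round_trip(self, tmp_path):
        lib = GRNALibrary({"r1": "ACGT", "r2": "GGCC"})
        p = tmp_path / "lib.fasta"
        lib.to_fasta(p)
        again = GRNALibrary.from_fasta(p)
        assert again.entries == lib.entries


LIB = GRNALibrary({"r1": "ACGTACGTAC", "r2": "GGGGCCCCAA", "r3": "TTTTAAAACC"})


class TestMatrices:
    def test_results_row_matches_design_when_reads_cover(self):
        strain = _strain("AND11", {"r1", "r3"})
        reads = ["TT" + LIB["r1"] + "GG", "AA" + LIB["r3"] + "CC"]
        res = build_results_matrix({"AND11": reads}, LIB)
        des = build_design_matrix([strain], LIB)
        assert res.table.loc["AND11"].equals(des.table.loc["AND11"])

    def test_empty_read_set_flagged_not_zero_filled(self):
        res = build_results_matrix({"AND11": []}, LIB)
        assert res.missing_rows == ("AND11",)
        assert "AND11" not in res.table.index

    def test_design_matrix_set_membership_oracle(self, rng):
        strains = [
            _strain(lab, set(rng.choice(["r1", "r2", "r3"], rng.integers(0, 4), replace=False)))
            for lab in ("AND00", "OR11", "XOR10", "WT")
        ]
        mat = build_design_matrix(strains, LIB)
        for s in strains:
            for g in LIB:
                assert mat.table.loc[s.label, g] == int(g in s.grnas)

    def test_empty_part_list_gives_zero_row(self):
        mat = build_design_matrix([_strain("WT", set())], LIB)
        assert mat.table.loc["WT"].sum() == 0

    def test_identical_designs_identical_rows(self):
        a = _strain("AND00", {"r1"})
        b = _strain("AND01", {"r1"})
        mat = build_design_matrix([a, b], LIB)
        assert mat.table.loc["AND00"].equals(mat.table.loc["AND01"])

    def test_unknown_grna_in_design_is_error(self):
        with pytest.raises(KeyError, match="r99"):
            build_design_matrix([_strain("AND00", {"r99"})], LIB)

    def test_non_binary_cells_rejected(self):
        with pytest.raises(ValueError):
            PresenceMatrix(pd.DataFrame({"r1": [2]}, index=["s"]), role="results")


class TestAnomalies:
    def _mat(self, rows, role):
        return PresenceMatrix(
            pd.DataFrame(rows, columns=["r1", "r2", "r3"], index=["s1", "s2"]),
            role=role,
        )

    def test_identical_matrices_no_anomalies(self):
        d = self._mat([[1, 0, 1], [0, 1, 0]], "design")
        r = self._mat([[1, 0, 1], [0, 1, 0]], "results")
        assert find_anomalies(d, r).n_anomalies == 0

    def test_classification_directions(self):
        d = self._mat([[1, 0, 0], [0, 0, 0]], "design")
        r = self._mat([[0, 1, 0], [0, 0, 0]], "results")
        a = find_anomalies(d, r).table
        assert a.loc["s1", "r1"] == UNEXPECTED_ABSENCE
        assert a.loc["s1", "r2"] == UNEXPECTED_PRESENCE
        assert a.loc["s1", "r3"] == EXPECTED

    def test_random_matrices_match_elementwise_oracle(self, rng):
        strains = [f"s{i}" for i in range(24)]
        grnas = [f"r{i}" for i in range(13)]
        d = pd.DataFrame(rng.integers(0, 2, (24, 13)), index=strains, columns=grnas)
        r = pd.DataFrame(rng.integers(0, 2, (24, 13)), index=strains, columns=grnas)
        a = find_anomalies(PresenceMatrix(d, "design"), PresenceMatrix(r, "results"))
        n_abs = n_pres = 0
        for s in strains:
            for g in grnas:
                if d.loc[s, g] == 1 and r.loc[s, g] == 0:
                    n_abs += 1
                elif d.loc[s, g] == 0 and r.loc[s, g] == 1:
                    n_pres += 1
        assert (a.table == UNEXPECTED_ABSENCE).to_numpy().sum() == n_abs
        assert (a.table == UNEXPECTED_PRESENCE).to_numpy().sum() == n_pres
        # swapping roles swaps the two anomaly classes
        swapped = find_anomalies(PresenceMatrix(r, "design"), PresenceMatrix(d, "results"))
        assert (swapped.table == UNEXPECTED_ABSENCE).to_numpy().sum() == n_pres

    def test_shape_mismatch_is_error(self):
        d = self._mat([[1, 0, 0], [0, 0, 0]], "design")
        r = PresenceMatrix(
            pd.DataFrame([[1, 0]], columns=["r1", "r2"], index=["s1"]), "results"
        )
        with pytest.raises(ValueError):
            find_anomalies(d, r)

    def test_counts_by_strain_and_grna(self):
        d = self._mat([[1, 1, 0], [0, 0, 0]], "design")
        r = self._mat([[0, 1, 1], [0, 0, 0]], "results")
        a = find_anomalies(d, r)
        by_strain = a.counts_by_strain()
        assert by_strain.loc["s1", "unexpected_absence"] == 1
        assert by_strain.loc["s1", "unexpected_presence"] == 1
        assert a.counts_by_grna().loc["r1", "unexpected_absence"] == 1


class TestCompatibility:
    def test_all_candidates_require_missing_grna(self):
        # every design needs r1, but r1 (and r9) are absent from the observation
        observed = {"r1": 0, "r6": 1, "r9": 0}
        candidates = [
            _strain("XOR00", {"r1", "r6"}),
            _strain("XOR01", {"r1", "r9"}),
            _strain("XOR10", {"r1"}),
        ]
        assert design_compatibility(observed, candidates) == []

    def test_exact_match_candidate_compatible(self):
        observed = {"r1": 1, "r2": 0, "r3": 1}
        cand = _strain("AND11", {"r1", "r3"})
        assert design_compatibility(observed, [cand]) == [cand]
        assert design_compatibility(observed, [cand], strict=True) == [cand]

    def test_strict_mode_rejects_extra_observed(self):
        observed = {"r1": 1, "r2": 1, "r3": 0}
        cand = _strain("AND11", {"r1"})
        assert design_compatibility(observed, [cand]) == [cand]
        assert design_compatibility(observed, [cand], strict=True) == []

    def test_unique_satisfiable_candidate_found(self, rng):
        grnas = [f"r{i}" for i in range(1, 16)]
        candidates = []
        for i in range(15):
            req = set(rng.choice(grnas, 4, replace=False)) | {f"r{i + 1}"}
            candidates.append(_strain("XOR00", frozenset(req)))
        target = candidates[7]
        observed = {g: int(g in target.grnas) for g in grnas}
        hits = design_compatibility(observed, candidates, strict=True)
        assert hits == [target]

    def test_empty_candidate_list(self):
        assert design_compatibility({"r1": 1}, []) == []


class TestCoverage:
    def test_arithmetic(self):
        reads = {"s1": ["A" * 100] * 1000, "s2": []}
        cov = coverage_estimate(reads, 100_000)
        assert cov["s1"] == pytest.approx(1.0)
        assert cov["s2"] == 0.0

    def test_matches_base_count_oracle(self, rng):
        reads = {"s": ["A" * int(rng.integers(50, 150)) for _ in range(100)]}
        total = sum(len(r) for r in reads["s"])
        assert coverage_estimate(reads, 12345)["s"] == pytest.approx(total / 12345)

    def test_bad_genome_size(self):
        with pytest.raises(ValueError):
            coverage_estimate({}, 0)


def test_read_fasta_reads(tmp_path):
    p = tmp_path / "reads.fasta"
    p.write_text(">a\nACGT\n>b\nGGTT\n")
    assert read_fasta_reads(p) == ["ACGT", "GGTT"]
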