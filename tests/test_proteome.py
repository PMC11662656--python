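"""Proteome scanning, PUN-protein classification and density ranking."""

import numpy as np
import pytest

from punscan.motif import MotifMatch, ProteinRecord, scan_sequence
from punscan.proteome import (
    ECOLI_RULE,
    PunCallRule,
    classify_protein,
    max_motifs_in_window,
    rank_by_density,
    scan_proteome,
)

from conftest import oracle_max_in_window


def spans_to_matches(spans, pid="p"):
    return [MotifMatch(pid, s, e, "K" * (e - s)) for s, e in spans]


class TestMaxMotifsInWindow:
    @pytest.mark.parametrize(
        "spans,window,expected",
        [
            ([(0, 6), (70, 76), (140, 146)], 150, 3),
            ([(0, 6), (145, 151)], 150, 1),  # second span ends past the window
            ([], 150, 0),
            ([(0, 6)], 150, 1),
            ([(0, 6), (144, 150)], 150, 2),  # exactly fits
        ],
    )
    def test_examples(self, spans, window, expected):
        assert max_motifs_in_window(spans_to_matches(spans), window) == expected

    def test_equals_bruteforce_on_random_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n = int(rng.integers(0, 10))
            starts = np.sort(rng.choice(500, size=n, replace=False)) if n else []
            spans, last_end = [], -1
            for s in starts:
                if s <= last_end:
                    continue
                e = s + int(rng.integers(6, 16))
                spans.append((int(s), e))
                last_end = e
            window = int(rng.integers(20, 200))
            for mode in ("span", "start"):
                got = max_motifs_in_window(spans_to_matches(spans), window, mode)
                assert got == oracle_max_in_window(spans, window, 600, mode)

    def test_start_mode_is_at_least_span_mode(self):
        spans = [(0, 6), (140, 152)]
        m = spans_to_matches(spans)
        assert max_motifs_in_window(m, 150, "start") >= max_motifs_in_window(m, 150, "span")


class TestClassification:
    def test_default_rule_positive(self):
        spans = [(0, 6), (50, 56), (100, 106), (200, 206), (300, 306)]
        prof = classify_protein("p", 400, spans_to_matches(spans))
        assert prof.motif_count == 5 and prof.max_in_window == 3 and prof.is_pun

    def test_cluster_clause_fails(self):
        spans = [(i * 200, i * 200 + 6) for i in range(5)]
        prof = classify_protein("p", 1200, spans_to_matches(spans))
        assert prof.motif_count == 5 and prof.max_in_window == 1 and not prof.is_pun

    def test_ecoli_rule_no_cluster_requirement(self):
        spans = [(0, 6), (300, 306), (600, 606)]
        prof = classify_protein("p", 700, spans_to_matches(spans), ECOLI_RULE)
        assert prof.is_pun
        assert not classify_protein("p", 700, spans_to_matches(spans[:2]), ECOLI_RULE).is_pun

    def test_adding_a_motif_never_unmakes_a_pun_protein(self):
        rng = np.random.default_rng(5)
        rule = PunCallRule()
        for _ in range(200):
            n = int(rng.integers(0, 9))
            starts = sorted(rng.choice(400, size=n, replace=False) * 2) if n else []
            spans, last = [], -1
            for s in starts:
                if s <= last:
                    continue
                spans.append((int(s), int(s) + 6))
                last = int(s) + 6
            before = classify_protein("p", 900, spans_to_matches(spans), rule).is_pun
            extra = spans + [(850, 856)]
            after = classify_protein("p", 900, spans_to_matches(extra), rule).is_pun
            assert not (before and not after)

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            PunCallRule(window_aa=5)
        with pytest.raises(ValueError):
            PunCallRule(min_motifs=2, cluster_min=3)
        with pytest.raises(ValueError):
            PunCallRule(cluster_mode="middle")


class TestScanProteome:
    def test_profiles_preserve_order_and_match_per_record_scans(self, tmp_path):
        records = [
            ProteinRecord("A1", "", "KAKKAK" + "G" * 40),
            ProteinRecord("B2", "", "G" * 50),
            ProteinRecord("C3", "", ("KAKKAK" + "GGG") * 5 + "G" * 30),
        ]
        profiles, summary = scan_proteome(records)
        assert [p.protein_id for p in profiles] == ["A1", "B2", "C3"]
        assert summary.n_proteins == 3
        for rec, prof in zip(records, profiles):
            assert prof.motif_count == len(scan_sequence(rec))

    def test_concatenated_fasta_equals_union_of_records(self, tmp_path):
        from punscan.io import read_fasta, write_fasta

        records = [
            ProteinRecord("X1", "", "KAKKAKDDD" * 3 + "G" * 20),
            ProteinRecord("X2", "", "ADEG" * 25),
        ]
        f = tmp_path / "two.fasta"
        write_fasta(records, f)
        profiles_file, _ = scan_proteome(f)
        profiles_mem, _ = scan_proteome(records)
        assert [(p.protein_id, p.motif_count) for p in profiles_file] == [
            (p.protein_id, p.motif_count) for p in profiles_mem
        ]

    def test_duplicate_ids_deduplicated_with_warning(self):
        records = [
            ProteinRecord("D", "", "G" * 30),
            ProteinRecord("D", "", "A" * 30),
        ]
        with pytest.warns(UserWarning, match="duplicate"):
            profiles, _ = scan_proteome(records)
        assert [p.protein_id for p in profiles] == ["D", "D.2"]

    def test_empty_fasta_errors(self, tmp_path):
        f = tmp_path / "empty.fasta"
        f.write_text("")
        with pytest.raises(ValueError):
            scan_proteome(f)


class TestRanking:
    def _profile(self, pid, length, n_motifs):
        spans = [(i * 20, i * 20 + 6) for i in range(n_motifs)]
        return classify_protein(pid, length, spans_to_matches(spans, pid))

    def test_density_ordering_and_tiebreaks(self):
        profiles = [
            self._profile("low", 400, 5),
            self._profile("hi", 200, 8),
            self._profile("tie_b", 300, 6),
            self._profile("tie_a", 300, 6),
            self._profile("not_pun", 300, 2),
        ]
        table = rank_by_density(profiles)
        assert list(table["protein_id"]) == ["hi", "tie_a", "tie_b", "low"]
        assert table.index.tolist() == [1, 2, 3, 4]
        assert table.loc[1, "density_per_100aa"] == pytest.approx(4.0)

    def test_empty_when_no_pun_proteins(self):
        assert rank_by_density([self._profile("x", 300, 1)]).empty
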