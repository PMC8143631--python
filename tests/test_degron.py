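"""Degron scanner, PWM similarity, disorder annotation, and hit filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import apcscreen as apc
from apcscreen.degron import (
    DegronHit,
    consensus_class,
    disorder_heuristic,
    filter_hits,
)
from apcscreen.motifs import AMINO_ACIDS, MOTIF_TEMPLATES

from test_simulate import brute_force_motif_scan

sequences = st.text(alphabet=AMINO_ACIDS + "X", min_size=0, max_size=80)


class TestScanMotifs:
    def test_ken_box(self):
        hits = apc.scan_motifs("AAKENAA", ["KEN"])
        assert [(h.start, h.end, h.matched_seq) for h in hits] == [(3, 5, "KEN")]

    def test_minimal_and_extended_dbox_nesting(self):
        hits = apc.scan_motifs("ARVALHEQSNG", ["D_min", "D_ext"])
        spans = {(h.degron_class, h.start, h.end) for h in hits}
        assert spans == {("D_min", 2, 5), ("D_ext", 2, 10)}
        d_min = next(h for h in hits if h.degron_class == "D_min")
        assert d_min.matched_seq == "RVAL"
        assert d_min.nested_in_ext

    def test_irs2_like_extended_dbox_at_972(self, irs2_like_sequence):
        hits = apc.scan_motifs(irs2_like_sequence, ["D_ext"])
        assert any(h.start == 972 and h.end == 980 for h in hits)

    def test_empty_sequence(self):
        assert apc.scan_motifs("", ["KEN", "D_min"]) == []

    def test_x_never_matches_anchors(self):
        assert apc.scan_motifs("XENAA", ["KEN"]) == []
        # but X is tolerated at wildcard positions
        hits = apc.scan_motifs("RXXL", ["D_min"])
        assert len(hits) == 1

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError):
            apc.scan_motifs("KEN1", ["KEN"])

    def test_overlapping_hits_all_reported(self):
        hits = apc.scan_motifs("RRALLL", ["D_min"])  # RxxL at 1-4 and 2-5
        assert {(h.start, h.end) for h in hits} == {(1, 4), (2, 5)}

    @given(sequences)
    def test_agrees_with_exhaustive_window_matcher(self, seq):
        for cls in ("D_min", "D_ext", "KEN"):
            got = [(h.start, h.end) for h in apc.scan_motifs(seq, [cls])]
            assert got == brute_force_motif_scan(seq, cls)

    @given(sequences)
    def test_reversal_symmetry(self, seq):
        """Hit count is invariant under reversing both sequence and pattern."""
        for cls in ("D_min", "D_ext", "KEN"):
            length, anchors = MOTIF_TEMPLATES[cls]
            rev_anchors = {length - 1 - off: res for off, res in anchors.items()}
            n_fwd = len(apc.scan_motifs(seq, [cls]))
            rev = seq[::-1]
            n_rev = sum(
                all(rev[i + off] == res for off, res in rev_anchors.items())
                for i in range(len(rev) - length + 1)
            )
            assert n_fwd == n_rev


def pwm_oracle_score(seq: str, refs: list[str]) -> float:
    """Independent direct log-odds summation (pseudocount 1, background 1/20)."""
    length = len(refs[0])
    total_min = 0.0
    per_pos = []
    for pos in range(length):
        counts = {a: 1 for a in AMINO_ACIDS}
        for r in refs:
            counts[r[pos]] += 1
        tot = sum(counts.values())
        lods = {a: np.log(20 * counts[a] / tot) for a in AMINO_ACIDS}
        per_pos.append(lods)
        total_min += min(lods.values())

    def raw(s):
        return sum(per_pos[i][s[i]] for i in range(length))

    best = max(raw(r) for r in refs)
    return (raw(seq) - total_min) / (best - total_min)


class TestSimilarityScore:
    def test_reference_sequence_scores_one(self):
        refs = apc.load_reference_degrons()
        for cls, seqs in refs.items():
            best = max(apc.similarity_score(s, seqs) for s in seqs)
            assert best == pytest.approx(1.0)

    def test_worst_possible_sequence_scores_zero(self):
        refs = ["RAALSDIGN", "RTVLEDLSN"]
        # W appears in no reference at any position -> column minimum everywhere
        assert apc.similarity_score("WWWWWWWWW", refs) == pytest.approx(0.0)

    def test_matches_independent_pwm_oracle(self):
        refs = apc.load_reference_degrons()["D_ext"]
        for probe in ("RAALSDIGN", "RHMLAAAGN", "KKKKKKKKK", "RTVLSDLGN"):
            expected = np.clip(pwm_oracle_score(probe, refs), 0, 1)
            assert apc.similarity_score(probe, refs) == pytest.approx(float(expected))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apc.similarity_score("KEN", ["RAALSDIGN"])

    @given(st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=9))
    def test_score_bounded(self, seq):
        refs = apc.load_reference_degrons()["D_ext"]
        assert 0.0 <= apc.similarity_score(seq, refs) <= 1.0


class TestDisorder:
    def test_constant_track(self):
        hit = DegronHit("P", "D_ext", 10, 18, "RAALSDIGN")
        out = apc.annotate_disorder(hit, np.full(30, 0.68))
        assert out.disorder == pytest.approx(0.68)

    def test_two_residue_average(self):
        hit = DegronHit("P", "KEN", 1, 2, "KE")
        assert apc.annotate_disorder(hit, np.array([0.0, 1.0])).disorder == 0.5

    def test_missing_coverage_raises(self):
        hit = DegronHit("P", "KEN", 5, 7, "KEN")
        with pytest.raises(KeyError):
            apc.annotate_disorder(hit, np.full(6, 0.5))

    def test_series_track_one_based(self):
        track = pd.Series([0.2, 0.4, 0.6], index=[1, 2, 3])
        hit = DegronHit("P", "KEN", 2, 3, "EN")
        assert apc.annotate_disorder(hit, track).disorder == pytest.approx(0.5)

    def test_heuristic_in_unit_interval(self):
        track = disorder_heuristic("MKKRSSPQEGGAAWILVFMMM")
        assert track.shape == (21,)
        assert ((track >= 0) & (track <= 1)).all()


class TestFilterHits:
    def _hit(self, similarity, disorder):
        return DegronHit("P1", "D_ext", 1, 9, "RAALSDIGN",
                         similarity=similarity, disorder=disorder)

    def test_table_row_like_hit_passes(self):
        out = filter_hits([self._hit(0.87, 0.68)])
        assert out[0].passes
        assert out[0].consensus_class == "medium"

    def test_boundaries_inclusive(self):
        assert filter_hits([self._hit(0.75, 0.4)])[0].passes
        assert not filter_hits([self._hit(0.7499, 0.4)])[0].passes
        assert not filter_hits([self._hit(0.75, 0.399)])[0].passes

    def test_secreted_protein_fails(self):
        loc = pd.DataFrame(
            {"protein": ["P1"], "intracellular": [True], "secreted": [True]}
        )
        assert not filter_hits([self._hit(0.99, 0.9)], loc)[0].passes

    def test_missing_localization_warns_and_assumes_intracellular(self, caplog):
        loc = pd.DataFrame(
            {"protein": ["OTHER"], "intracellular": [True], "secreted": [False]}
        )
        with caplog.at_level("WARNING"):
            out = filter_hits([self._hit(0.9, 0.6)], loc)
        assert out[0].passes
        assert "localization" in caplog.text

    def test_unannotated_hit_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([DegronHit("P", "KEN", 1, 3, "KEN")])

    @pytest.mark.parametrize(
        "similarity,expected",
        [(0.95, "high"), (0.9, "high"), (0.8, "medium"), (0.74, "low")],
    )
    def test_consensus_classes(self, similarity, expected):
        assert consensus_class(similarity) == expected


class TestScanProteome:
    def test_planted_degron_recall_is_complete(self):
        seqs, tracks, loc, truth = apc.simulate_proteome(
            60, planted_degrons=[("D_ext", 20), ("KEN", 20)], seed=8
        )
        hits = apc.scan_proteome(seqs, tracks, loc)
        found = {
            (r["protein"], r["degron_class"], r["start"], r["end"])
            for _, r in hits.iterrows()
        }
        for _, row in truth.planted.iterrows():
            assert (row["protein"], row["degron_class"], row["start"], row["end"]) in found

    def test_custom_motif_class_scaffold(self):
        from apcscreen.motifs import register_motif_class

        register_motif_class("ABBA_custom", 4, {0: "F", 3: "E"})
        try:
            hits = apc.scan_motifs("AFXYEA", ["ABBA_custom"])
            assert [(h.start, h.end) for h in hits] == [(2, 5)]
        finally:
            MOTIF_TEMPLATES.pop("ABBA_custom")
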