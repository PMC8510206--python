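"""Consensus screening: thresholds, Venn regions, MoA stratification,
ranking, property summaries."""

import itertools

import numpy as np
import pytest

from pepscreen import screening as sc

# The four published predictor score rows for the synthesized candidates.
TABLE1 = [
    sc.PredictorScores("TTMICLTCAR", 1.05, 0.997, 0.515, 0.766, True, True),   # CTP-ori
    sc.PredictorScores("TTGICLTCCR", 1.58, 0.997, 0.538, 0.674, True, True),   # CTP-rds
    sc.PredictorScores("VTFVLIAAK", 1.28, 0.875, 0.558, 0.787, False, False),  # C-ori
    sc.PredictorScores("FTFVLLAAK", 1.62, 0.943, 0.506, 0.541, False, False),  # C-rds
]


def _mk(peptide, a, i, r, s, toxic=False, cpp=False):
    return sc.PredictorScores(peptide, a, i, r, s, toxic, cpp)


# ---------------------------------------------------------------------------
# call_predictors

def test_published_candidate_rows_are_all_consensus():
    for row in TABLE1:
        v = sc.call_predictors(row)
        assert v.anticp_pos and v.iacp_pos and v.mlacp_pos and v.consensus_acp


def test_all_zero_scores_negative():
    v = sc.call_predictors(_mk("AAAAA", 0.0, 0.0, 0.0, 0.0))
    assert not (v.anticp_pos or v.iacp_pos or v.mlacp_pos or v.consensus_acp)


def test_thresholds_are_strict():
    """'over 1.00' / 'over 0.5' means strictly greater: boundary scores fail."""
    v = sc.call_predictors(_mk("AAAAA", 1.00, 0.6, 0.6, 0.6))
    assert not v.anticp_pos and v.iacp_pos and v.mlacp_pos
    assert not v.consensus_acp
    assert not sc.call_predictors(_mk("AAAAA", 1.5, 0.5, 0.6, 0.6)).iacp_pos
    assert not sc.call_predictors(_mk("AAAAA", 1.5, 0.6, 0.5, 0.6)).mlacp_pos


def test_mlacp_needs_both_probabilities():
    assert not sc.call_predictors(_mk("AAAAA", 1.5, 0.9, 0.9, 0.3)).mlacp_pos
    assert not sc.call_predictors(_mk("AAAAA", 1.5, 0.9, 0.3, 0.9)).mlacp_pos


def test_probability_out_of_range_rejected():
    with pytest.raises(ValueError):
        _mk("AAAAA", 1.0, 1.2, 0.5, 0.5)


def test_monotonicity_raising_scores_never_flips_positive_to_negative(rng):
    for _ in range(200):
        base = _mk("PEPTIDE", *(rng.normal(0.8, 0.5), *np.clip(rng.normal(0.5, 0.2, 3), 0, 1)))
        bumped = sc.PredictorScores(
            base.peptide,
            base.anticp_svm + rng.uniform(0, 1),
            min(1.0, base.iacp_prob + rng.uniform(0, 0.5)),
            min(1.0, base.mlacp_rf + rng.uniform(0, 0.5)),
            min(1.0, base.mlacp_svm + rng.uniform(0, 0.5)),
            base.toxic,
            base.cpp,
        )
        v0, v1 = sc.call_predictors(base), sc.call_predictors(bumped)
        for attr in ("anticp_pos", "iacp_pos", "mlacp_pos", "consensus_acp"):
            assert not (getattr(v0, attr) and not getattr(v1, attr))


# ---------------------------------------------------------------------------
# Venn regions

def _verdict(pep, a, i, m):
    return sc.ScreenVerdict(pep, a, i, m, a and i and m, "none" if (a and i and m) else None)


def test_venn_all_triple_positive():
    verdicts = [_verdict(f"p{k}", True, True, True) for k in range(3)]
    counts = sc.venn_counts(verdicts)
    assert counts["111"] == 3 and counts["consensus"] == 3
    assert all(counts[k] == 0 for k in counts if set(k) <= {"0", "1"} and k != "111")


def test_venn_eight_peptides_cover_every_region_once():
    verdicts = []
    k = 0
    for a, i, m in itertools.product([False, True], repeat=3):
        verdicts.append(_verdict(f"p{k}", a, i, m))
        k += 1
    counts = sc.venn_counts(verdicts)
    for key in counts:
        if set(key) <= {"0", "1"}:
            assert counts[key] == 1
    assert counts["anticp_total"] == 4 and counts["union"] == 7


def test_venn_random_table_matches_set_algebra(rng):
    verdicts, A, B, C = [], set(), set(), set()
    for k in range(500):
        a, i, m = rng.random(3) < 0.4
        name = f"p{k}"
        verdicts.append(_verdict(name, bool(a), bool(i), bool(m)))
        if a: A.add(name)
        if i: B.add(name)
        if m: C.add(name)
    counts = sc.venn_counts(verdicts)
    assert counts["anticp_total"] == len(A)
    assert counts["consensus"] == len(A & B & C)
    assert counts["110"] == len((A & B) - C)
    assert counts["001"] == len(C - A - B)
    # inclusion-exclusion identity
    union = len(A) + len(B) + len(C) - len(A & B) - len(A & C) - len(B & C) + len(A & B & C)
    assert counts["union"] == union == len(A | B | C)


def test_venn_rejects_duplicate_peptides():
    v = _verdict("same", True, False, False)
    with pytest.raises(ValueError):
        sc.venn_counts([v, v])


# ---------------------------------------------------------------------------
# mode of action

def test_moa_assignment():
    assert sc.call_predictors(TABLE1[0]).moa_category == "both"
    assert sc.call_predictors(TABLE1[2]).moa_category == "none"


def test_moa_partition_and_overlapping_totals(rng):
    verdicts = []
    tally = {c: 0 for c in sc.MOA_CATEGORIES}
    for k in range(10):
        toxic, cpp = bool(rng.random() < 0.5), bool(rng.random() < 0.5)
        cat = ("both" if toxic and cpp else "toxic_only" if toxic
               else "cpp_only" if cpp else "none")
        tally[cat] += 1
        verdicts.append(sc.ScreenVerdict(f"p{k}", True, True, True, True, cat))
    counts = sc.classify_moa(verdicts)
    for c in sc.MOA_CATEGORIES:
        assert counts[c] == tally[c]
    assert counts["consensus"] == 10
    assert counts["toxic_total"] == tally["toxic_only"] + tally["both"]
    assert counts["cpp_total"] == tally["cpp_only"] + tally["both"]
    # overlap identity: toxic + cpp - both + none == consensus
    assert (counts["toxic_total"] + counts["cpp_total"] - counts["both"]
            + counts["none"]) == counts["consensus"]


def test_moa_requires_flags_for_consensus_peptides():
    bad = sc.ScreenVerdict("p", True, True, True, True, None)
    with pytest.raises(ValueError):
        sc.classify_moa([bad])


# ---------------------------------------------------------------------------
# ranking

def test_rank_by_svm_score():
    a, b = _mk("AAA", 1.5, 0.5, 0.5, 0.5), _mk("CCC", 1.2, 0.9, 0.9, 0.9)
    assert [s.peptide for s in sc.rank_candidates([a, b])] == ["AAA", "CCC"]


def test_rank_tie_broken_by_mean_of_other_scores():
    a = _mk("AAA", 1.5, 0.5, 0.5, 0.5)
    b = _mk("CCC", 1.5, 0.9, 0.9, 0.9)
    assert [s.peptide for s in sc.rank_candidates([a, b])] == ["CCC", "AAA"]


def test_rank_published_c_group_order():
    c_ori, c_rds = TABLE1[2], TABLE1[3]
    assert [s.peptide for s in sc.rank_candidates([c_ori, c_rds])] == [
        "FTFVLLAAK",  # 1.62
        "VTFVLIAAK",  # 1.28
    ]


def test_rank_is_permutation_invariant(rng):
    rows = [
        _mk(f"P{k}", float(rng.normal(1, 0.5)), *np.clip(rng.random(3), 0, 1))
        for k in range(20)
    ]
    ref = [s.peptide for s in sc.rank_candidates(rows)]
    for _ in range(5):
        perm = list(rows)
        rng.shuffle(perm)
        assert [s.peptide for s in sc.rank_candidates(perm)] == ref


# ---------------------------------------------------------------------------
# property summary

def test_property_summary_two_peptides_split():
    s = sc.property_summary(["KKKKK", "DDDDD"])
    assert s.charge_pct["cationic"] == 50.0 and s.charge_pct["anionic"] == 50.0
    assert sum(s.charge_pct.values()) == 100.0


def test_property_summary_single_peptide():
    s = sc.property_summary(["VTFVLIAAK"])
    assert s.charge_pct["cationic"] == 100.0
    assert s.hydro_pct["hydrophobic"] == 100.0
    assert s.length_pct["5-20"] == 100.0


def test_property_summary_empty_flagged():
    assert sc.property_summary([]).empty


def test_property_summary_hand_tally(rng):
    from tests.conftest import random_peptide

    peps = list({random_peptide(rng) for _ in range(30)})
    s = sc.property_summary(peps)
    from pepscreen.properties import compute_properties

    cationic = sum(compute_properties(p).charge_class == "cationic" for p in peps)
    assert s.charge_pct["cationic"] == round(100.0 * cationic / len(peps), 1)


# ---------------------------------------------------------------------------
# TSV I/O

def test_scores_tsv_roundtrip(tmp_path):
    path = tmp_path / "scores.tsv"
    path.write_text(
        "peptide\tanticp_svm\tiacp_prob\tmlacp_rf\tmlacp_svm\ttoxic\tcpp\n"
        "VTFVLIAAK\t1.28\t0.875\t0.558\t0.787\t0\t0\n"
    )
    rows = sc.read_scores_tsv(path)
    assert rows[0] == TABLE1[2]


def test_scores_tsv_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("peptide\tanticp_svm\nAAA\t1.0\n")
    with pytest.raises(ValueError, match="missing column"):
        sc.read_scores_tsv(path)
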