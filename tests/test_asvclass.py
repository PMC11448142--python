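"""ASV affiliation: local alignment, threshold semantics, aggregation, and
community summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from ampliscope.asvclass import (
    Scoring,
    Thresholds,
    clade_ratio,
    classify_all,
    classify_asv,
    local_align,
    summarize_groups,
)
from ampliscope.refdb import ReferenceDB, ReferenceRecord

from _oracles import local_align_score
from conftest import random_dna


def test_identical_sequences_align_perfectly():
    hit = local_align("q", "A" * 50 + "CGT" * 17, "s", "A" * 50 + "CGT" * 17)
    assert hit.identity == 1.0
    assert hit.align_len == 101
    assert hit.score == 202


def test_ten_substitutions_in_hundred_give_identity_090():
    rng = np.random.default_rng(4)
    subject = random_dna(rng, 100)
    q = list(subject)
    # substitutions >= 2 from the ends and >= 3 apart: full-length optimal
    for pos in range(5, 100, 10):  # 10 positions: 5, 15, ..., 95
        q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
    query = "".join(q)
    hit = local_align("q", query, "s", subject)
    assert hit.score == local_align_score(query, subject) == 90 * 2 - 10 * 3
    assert hit.align_len == 100
    assert hit.identity == pytest.approx(0.90)


def test_disjoint_alphabets_no_usable_hit():
    hit = local_align("q", "A" * 40, "s", "C" * 40)
    assert hit.align_len == 0 and hit.identity == 0.0


def test_score_matches_quadratic_dp_oracle_on_random_pairs():
    rng = np.random.default_rng(23)
    for _ in range(40):
        a = random_dna(rng, int(rng.integers(20, 60)))
        b = random_dna(rng, int(rng.integers(20, 60)))
        hit = local_align("q", a, "s", b)
        assert hit.score == local_align_score(a, b), (a, b)


def test_bitscore_formula():
    s = Scoring()
    assert s.bitscore(200) == pytest.approx((0.625 * 200 - math.log(0.41)) / math.log(2))


@pytest.fixture
def small_refdb():
    rng = np.random.default_rng(77)
    return ReferenceDB([
        ReferenceRecord("refA", random_dna(rng, 500), "cladeA"),
        ReferenceRecord("refB", random_dna(rng, 500), "cladeB"),
        ReferenceRecord("refO", random_dna(rng, 500), "other_cu_mmo"),
    ])


def test_exact_slice_is_affiliated_and_aggregated(small_refdb):
    expected_len = 200
    asv = small_refdb.get("refA").sequence[100:300]
    res = classify_asv("a1", asv, small_refdb, expected_len)
    assert res.category == "cladeA"
    assert res.best_ref == "refA"
    assert res.aggregated_ref == "refA"
    assert res.identity == 1.0 and res.cover_fraction == 1.0


def _mutate(seq, n_sub, rng):
    # evenly spaced, away from ends, >= 3 apart: measured identity is exact
    s = list(seq)
    L = len(s)
    for j in range(n_sub):
        pos = 2 + int((j + 0.5) * (L - 5) / n_sub)
        s[pos] = sorted(set("ACGT") - {s[pos]})[int(rng.integers(3))]
    return "".join(s)


def test_identity_band_affiliated_but_not_aggregated(small_refdb):
    rng = np.random.default_rng(1)
    expected_len = 200
    base = small_refdb.get("refB").sequence[50:250]
    asv = _mutate(base, 40, rng)  # identity 0.80
    res = classify_asv("a1", asv, small_refdb, expected_len)
    assert res.category == "cladeB"
    assert res.identity == pytest.approx(0.80)
    assert res.aggregated_ref is None


@pytest.mark.parametrize(
    "n_sub,expected_cat,expected_agg",
    [
        (20, "cladeA", "refA"),   # identity 0.90 -> aggregated (boundary inclusive)
        (50, "cladeA", None),     # identity 0.75 -> affiliated only
        (51, "unknown", None),    # identity 0.745 < 0.75
    ],
)
def test_identity_thresholds_are_step_functions(small_refdb, n_sub, expected_cat, expected_agg):
    rng = np.random.default_rng(2)
    expected_len = 200
    base = small_refdb.get("refA").sequence[100:300]
    asv = _mutate(base, n_sub, rng)
    res = classify_asv("a1", asv, small_refdb, expected_len)
    assert res.category == expected_cat
    assert res.aggregated_ref == expected_agg


@pytest.mark.parametrize(
    "slice_len,expected_cat",
    [
        (131, "unaligned"),  # 131/400 = 0.3275 < 0.33
        (132, "unknown"),    # 132/400 = 0.33, boundary inclusive -> aligned but short
        (264, "cladeA"),     # 264/400 = 0.66, boundary inclusive -> affiliated
    ],
)
def test_cover_thresholds_are_step_functions(small_refdb, slice_len, expected_cat):
    expected_len = 400
    asv = small_refdb.get("refA").sequence[10:10 + slice_len]
    res = classify_asv("a1", asv, small_refdb, expected_len)
    assert res.category == expected_cat
    if expected_cat == "unaligned":
        assert res.best_ref is None


def test_tie_break_is_deterministic():
    seq = "ACGT" * 50
    db = ReferenceDB([
        ReferenceRecord("z_ref", seq, "cladeB"),
        ReferenceRecord("a_ref", seq, "cladeA"),
    ])
    res = classify_asv("a1", seq[:120], db, 120)
    assert res.best_ref == "a_ref"  # lexicographically smallest on exact tie


def test_empty_refdb_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        classify_asv("a1", "ACGT" * 30, ReferenceDB([]), 100)


def test_aggregation_never_beats_best_bitscore(small_refdb):
    rng = np.random.default_rng(3)
    expected_len = 200
    for _ in range(10):
        ref = small_refdb.records[int(rng.integers(3))]
        start = int(rng.integers(0, 300))
        asv = _mutate(ref.sequence[start:start + 200], int(rng.integers(0, 15)), rng)
        res = classify_asv("a", asv, small_refdb, expected_len)
        if res.aggregated_ref is not None:
            assert res.aggregated_ref == res.best_ref


# ---------------------------------------------------------------------------
# abundance summaries


def _abund(rows):
    return pd.DataFrame(rows, columns=["sample_id", "asv_id", "read_count"])


def _affil(cats):
    return pd.DataFrame(
        [{"asv_id": a, "category": c, "best_ref": None, "identity": 1.0,
          "cover_fraction": 1.0, "bitscore": 0.0, "aggregated_ref": None}
         for a, c in cats.items()]
    )


def test_clade_ratio_single_sample():
    abund = _abund([("s1", "a1", 400), ("s1", "b1", 100)])
    affil = _affil({"a1": "cladeA", "b1": "cladeB"})
    per_sample, mean = clade_ratio(abund, affil)
    assert per_sample["s1"] == 4.0 and mean == 4.0


def test_clade_ratio_mean_over_samples():
    abund = _abund([
        ("s1", "a1", 200), ("s1", "b1", 100),
        ("s2", "a1", 600), ("s2", "b1", 100),
    ])
    affil = _affil({"a1": "cladeA", "b1": "cladeB"})
    per_sample, mean = clade_ratio(abund, affil)
    assert per_sample["s1"] == 2.0 and per_sample["s2"] == 6.0
    assert mean == 4.0


def test_zero_cladeB_sample_excluded_with_warning():
    abund = _abund([("s1", "a1", 10), ("s2", "a1", 5), ("s2", "b1", 5)])
    affil = _affil({"a1": "cladeA", "b1": "cladeB"})
    with pytest.warns(UserWarning, match="zero clade B"):
        per_sample, mean = clade_ratio(abund, affil)
    assert math.isinf(per_sample["s1"])
    assert mean == 1.0


def test_ratio_matches_direct_recomputation_on_random_tables():
    rng = np.random.default_rng(6)
    cats = {f"x{i}": ["cladeA", "cladeB", "AOB", "unknown"][i % 4] for i in range(12)}
    affil = _affil(cats)
    rows = [
        (f"s{j}", a, int(rng.integers(1, 50)))
        for j in range(4) for a in cats
    ]
    abund = _abund(rows)
    per_sample, mean = clade_ratio(abund, affil)
    # independent recomputation
    for j in range(4):
        a = sum(c for s, x, c in rows if s == f"s{j}" and cats[x] == "cladeA")
        b = sum(c for s, x, c in rows if s == f"s{j}" and cats[x] == "cladeB")
        assert per_sample[f"s{j}"] == pytest.approx(a / b)


def test_summarize_groups_fractions_and_counts():
    abund = _abund([
        ("s1", "a1", 75), ("s1", "b1", 25),
        ("s2", "a1", 10), ("s2", "a2", 10),
    ])
    affil = _affil({"a1": "cladeA", "a2": "cladeA", "b1": "cladeB"})
    rel, counts = summarize_groups(abund, affil)
    assert rel.loc["s1", "cladeA"] == 0.75
    assert rel.loc["s1", "cladeB"] == 0.25
    assert rel.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])
    assert counts["cladeA"] == 2 and counts["cladeB"] == 1
    assert counts.sum() == len(affil)


def test_unknown_asv_in_abundance_is_an_error():
    abund = _abund([("s1", "mystery", 5)])
    affil = _affil({"a1": "cladeA"})
    with pytest.raises(ValueError, match="mystery"):
        clade_ratio(abund, affil)


def test_classify_all_returns_one_row_per_asv(small_refdb):
    asvs = [
        ("a1", small_refdb.get("refA").sequence[0:200]),
        ("a2", small_refdb.get("refB").sequence[100:300]),
    ]
    df = classify_all(asvs, small_refdb, 200)
    assert list(df["asv_id"]) == ["a1", "a2"]
    assert list(df["category"]) == ["cladeA", "cladeB"]
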