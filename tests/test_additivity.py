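"""Site classification, the 1-bp-indel superposition test, pair scoring and
parentage calling, checked against independent per-column oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridtrace import iupac
from hybridtrace.additivity import (
    ParentageConfig,
    RibotypePanel,
    SiteLabel,
    Verdict,
    classify_sites,
    constant_additive_positions,
    hamming_distance,
    infer_parentage,
    score_pair,
    shifted_superposition,
)
from hybridtrace.errors import AlignmentGeometryError, ValidationError

SYMBOLS = sorted(iupac.CODES) + ["-"]


def oracle_label(q: str, a: str, b: str) -> SiteLabel:
    """Independent truth table for one column, written directly from the
    label definitions using raw base sets."""
    table = {
        "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
        "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
        "K": {"G", "T"}, "M": {"A", "C"},
        "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
        "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
    }
    inv = {frozenset(v): k for k, v in table.items()}
    if "-" in (q, a, b) or q == "N":
        return SiteLabel.GAPPED
    if a == b:
        return SiteLabel.INVARIANT if q == a else SiteLabel.RESIDUAL
    if q == inv[frozenset(table[a] | table[b])]:
        return SiteLabel.ADDITIVE
    if q == a:
        return SiteLabel.PARENT_A
    if q == b:
        return SiteLabel.PARENT_B
    return SiteLabel.RESIDUAL


def test_classify_sites_matches_truth_table_over_all_symbol_triples():
    triples = list(itertools.product(SYMBOLS, repeat=3))
    query = "".join(t[0] for t in triples)
    pa = "".join(t[1] for t in triples)
    pb = "".join(t[2] for t in triples)
    result = classify_sites(query, pa, pb)
    assert len(result) == len(triples)
    for site, (q, a, b) in zip(result, triples):
        assert site.label is oracle_label(q, a, b), (q, a, b)
        assert (site.observed, site.parent_a, site.parent_b) == (q, a, b)


def test_classify_sites_on_random_long_triples():
    rng = np.random.default_rng(2024)
    syms = np.array(SYMBOLS)
    for _ in range(20):
        q, a, b = ("".join(rng.choice(syms, size=650)) for _ in range(3))
        for site in classify_sites(q, a, b):
            i = site.position - 1
            assert site.label is oracle_label(q[i], a[i], b[i])


def test_classify_sites_trivial_and_length_mismatch():
    assert all(s.label is SiteLabel.INVARIANT for s in classify_sites("ACGT", "ACGT", "ACGT"))
    with pytest.raises(AlignmentGeometryError):
        classify_sites("ACG", "ACGT", "ACGT")


def test_classify_sites_additive_example_g_against_a():
    # parents differing G vs A, query showing the union R
    [site] = classify_sites("R", "G", "A")
    assert site.label is SiteLabel.ADDITIVE


def test_classify_sites_constructed_ten_column_case():
    # parents differ at cols 7 (G/T) and 8 (T/C); query: union at 7, parental
    # dropout at 8, a residual G at the monomorphic col 2
    pa = "ACGTACGTAG"
    pb = "ACGTACTCAG"
    qq = "AGGTACKTAG"
    labels = [s.label for s in classify_sites(qq, pa, pb)]
    expected = [
        SiteLabel.INVARIANT, SiteLabel.RESIDUAL, SiteLabel.INVARIANT, SiteLabel.INVARIANT,
        SiteLabel.INVARIANT, SiteLabel.INVARIANT, SiteLabel.ADDITIVE, SiteLabel.PARENT_A,
        SiteLabel.INVARIANT, SiteLabel.INVARIANT,
    ]
    assert labels == expected
    assert labels == [oracle_label(qq[i], pa[i], pb[i]) for i in range(10)]


# --- shifted superposition --------------------------------------------------


def build_shifted_query(parent_short: str, parent_long: str) -> str:
    """Construct the exact shifted-superposition consensus: both templates
    emit one base per trace position, so downstream of the gap column g the
    query shows union(long[i], short[i+1]) (1-based aligned columns)."""
    g = parent_short.index("-") + 1
    length = len(parent_long)
    out = []
    for col in range(1, length + 1):
        if col < g:
            out.append(iupac.union(parent_long[col - 1], parent_short[col - 1]))
        elif col < length:
            out.append(iupac.union(parent_long[col - 1], parent_short[col]))
        else:
            out.append(parent_long[col - 1])
    return "".join(out)


def test_shift_consistent_for_exact_superposition_query():
    parent_long = "ACGGTCATTGCA"
    parent_short = "ACG-TCATTGCA"
    query = build_shifted_query(parent_short, parent_long)
    res = shifted_superposition(query, parent_short, parent_long)
    assert res is not None
    assert res.indel_position == 4
    assert res.shift_consistent
    assert res.n_shift_explained == res.n_testable == len(parent_long) - 4  # cols 4..11


def test_degenerate_self_offset_region_is_consistent():
    # parents identical except the gap, and self-offset-identical downstream
    parent_long = "ACGAAAAAAA"
    parent_short = "ACG-AAAAAA"
    res = shifted_superposition(parent_long, parent_short, parent_long)
    assert res.shift_consistent
    assert res.n_shift_explained == res.n_testable


def test_corrupted_downstream_query_is_inconsistent():
    rng = np.random.default_rng(5)
    parent_long = "".join(rng.choice(list("ACGT"), size=120))
    parent_short = parent_long[:29] + "-" + parent_long[30:]
    query = list(build_shifted_query(parent_short, parent_long))
    # corrupt 30% of downstream columns with a symbol missing a required base
    downstream = list(range(30, 119))
    for i in rng.choice(downstream, size=len(downstream) * 3 // 10, replace=False):
        required = iupac.base_set(query[i])
        query[i] = sorted(set("ACGT") - required)[0] if required != set("ACGT") else "A"
    res = shifted_superposition("".join(query), parent_short, parent_long, tau_noise=0.05)
    assert not res.shift_consistent


def test_no_single_indel_returns_none_and_query_gap_raises():
    assert shifted_superposition("ACGT", "ACGT", "ACGT") is None  # no indel
    assert shifted_superposition("ACGT", "A--T", "ACGT") is None  # 2-column gap
    with pytest.raises(AlignmentGeometryError):
        shifted_superposition("AC-T", "AC-T", "ACGT")


# --- pair scoring ------------------------------------------------------------


def test_score_pair_counts_exact_f1_construction():
    rng = np.random.default_rng(11)
    pa = list(rng.choice(list("ACGT"), size=200))
    pb = list(pa)
    diff_cols = rng.choice(200, size=20, replace=False)
    for i in diff_cols:
        pb[i] = sorted(set("ACGT") - {pa[i]})[0]
    query = "".join(iupac.union(a, b) for a, b in zip(pa, pb))
    score = score_pair(query, "".join(pa), "".join(pb))
    assert score.n_additive == 20
    assert score.n_residual == 0
    assert score.n_parent_only == 0
    assert sorted(score.additive_positions) == sorted(int(i) + 1 for i in diff_cols)


def test_score_pair_query_identical_to_one_parent():
    pa = "ACGTACGT"
    pb = "ACGAACGA"
    score = score_pair(pa, pa, pb)
    assert score.n_additive == 0
    assert score.n_residual == 0
    assert score.n_parent_only == 2  # the two columns where the parents differ


def test_score_pair_symmetric_under_label_swap():
    rng = np.random.default_rng(3)
    syms = list("ACGTRYSWKMBDHV")
    for _ in range(10):
        q, a, b = ("".join(rng.choice(syms, size=80)) for _ in range(3))
        s_ab = score_pair(q, a, b)
        s_ba = score_pair(q, b, a)
        for attr in ("n_additive", "n_residual", "n_parent_only", "n_invariant", "n_gapped"):
            assert getattr(s_ab, attr) == getattr(s_ba, attr)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_score_pair_counts_partition_alignment_length(seed):
    rng = np.random.default_rng(seed)
    syms = SYMBOLS
    q, a, b = ("".join(rng.choice(syms, size=60)) for _ in range(3))
    s = score_pair(q, a, b)
    assert s.n_additive + s.n_residual + s.n_parent_only + s.n_invariant + s.n_gapped == 60


def test_score_pair_attaches_consistent_indel_shift():
    parent_long = "ACGGTCATTGCAGGTCAA"
    parent_short = "ACG-TCATTGCAGGTCAA"
    query = build_shifted_query(parent_short, parent_long)
    score = score_pair(query, parent_short, parent_long)
    assert score.indel_shift is not None
    assert score.indel_shift.shift_consistent
    # the shift explains the downstream region, so nothing is residual
    assert score.n_residual == 0


# --- parentage ----------------------------------------------------------------


def _toy_panel(rng, n_species=4, length=300, n_diff=12):
    """Panel of single-base ribotypes with designated differing columns."""
    anc = rng.choice(list("ACGT"), size=length)
    entries = []
    for si, sp in enumerate(["circinatus", "fluitans", "kauffmannii", "aquatilis"][:n_species]):
        row = list(anc)
        cols = rng.choice(length, size=n_diff, replace=False)
        for i in cols:
            row[i] = sorted(set("ACGT") - {row[i]})[rng.integers(0, 3)]
        entries.append((sp, "r1", "".join(row)))
    return RibotypePanel(entries)


def test_species_call_for_panel_member_and_near_variant():
    rng = np.random.default_rng(21)
    panel = _toy_panel(rng)
    sp, rid, seq = panel.entries[2]
    call = infer_parentage("x", seq, panel)
    assert call.verdict is Verdict.SPECIES
    assert call.species_match == (f"{sp}|{rid}", 0)
    # two private mutations stay below tau_species
    variant = list(seq)
    variant[5] = sorted(set("ACGT") - {variant[5]})[0]
    variant[50] = sorted(set("ACGT") - {variant[50]})[0]
    call = infer_parentage("x", "".join(variant), panel)
    assert call.verdict is Verdict.SPECIES
    assert call.species_match[1] == 2


def test_f1_recovery_on_constructed_union():
    rng = np.random.default_rng(22)
    panel = _toy_panel(rng)
    (_, _, s1), (_, _, s2) = panel.entries[0], panel.entries[1]
    query = "".join(iupac.union(a, b) for a, b in zip(s1, s2))
    call = infer_parentage("f1", query, panel)
    assert call.verdict is Verdict.F1_HYBRID
    assert call.best_pair.species_pair == ("circinatus", "fluitans")
    assert call.best_pair.n_residual == 0


def test_threeway_detection_with_engineered_extra_sites():
    rng = np.random.default_rng(23)
    panel = _toy_panel(rng, length=600, n_diff=20)
    by_sp = {sp: seq for sp, _, seq in panel.entries}
    p1, p2, p3 = by_sp["circinatus"], by_sp["fluitans"], by_sp["kauffmannii"]
    query = [iupac.union(a, b) for a, b in zip(p1, p2)]
    eligible = [
        i for i in range(600)
        if iupac.base_set(p3[i]) - (iupac.base_set(p1[i]) | iupac.base_set(p2[i]))
    ]
    chosen = rng.choice(eligible, size=6, replace=False)
    for i in chosen:
        query[i] = iupac.union(query[i], p3[i])
    call = infer_parentage("tw", "".join(query), panel)
    assert call.verdict is Verdict.COMPLEX_HYBRID
    top_name, top_explained = call.third_parent_candidates[0]
    trio = {call.best_pair.species_a, call.best_pair.species_b, top_name.split("|")[0]}
    assert trio == {"circinatus", "fluitans", "kauffmannii"}
    # when the true pair is ranked first, the third parent explains every residual
    if call.best_pair.species_pair == ("circinatus", "fluitans"):
        assert set(call.residual_positions) == {int(i) + 1 for i in chosen}
        assert top_explained == 6


def test_unresolved_when_no_pair_is_additive():
    panel = RibotypePanel([("a", "r1", "AAAA"), ("b", "r1", "AAAA")])
    call = infer_parentage("q", "TTTT", panel)
    assert call.verdict is Verdict.UNRESOLVED


def test_parentage_rejects_misaligned_query_and_uses_ribotype_variants():
    rng = np.random.default_rng(29)
    panel = _toy_panel(rng)
    with pytest.raises(AlignmentGeometryError):
        infer_parentage("q", "ACGT", panel)


def test_hamming_distance_skips_gap_columns():
    assert hamming_distance("AC-T", "ACG-") == 0
    assert hamming_distance("ACGT", "ACGA") == 1


# --- constant additive positions ---------------------------------------------


def test_constant_additive_positions_is_the_intersection():
    pa = "AAAAAAAAAAAA"
    pb = "AATATAAATAAA"  # parents differ at cols 3, 5, 9
    q1 = list(pa)
    q2 = list(pa)
    for col in (3, 5):
        q1[col - 1] = "W"
    for col in (3, 9):
        q2[col - 1] = "W"
    assert constant_additive_positions(["".join(q1)], pa, pb) == [3, 5]
    assert constant_additive_positions(["".join(q1), "".join(q2)], pa, pb) == [3]
    with pytest.raises(ValidationError):
        constant_additive_positions([], pa, pb)


def test_constant_additive_core_recovered_from_group():
    rng = np.random.default_rng(31)
    length = 400
    anc = rng.choice(list("ACGT"), size=length)
    pa = list(anc)
    pb = list(anc)
    core = sorted(rng.choice(length, size=12, replace=False))
    for i in core:
        pb[i] = sorted(set("ACGT") - {pb[i]})[0]
    pa, pb = "".join(pa), "".join(pb)
    group = []
    other_cols = [i for i in range(length) if i not in core]
    for k in range(4):
        row = [iupac.union(a, b) for a, b in zip(pa, pb)]
        # private residual sites must not enter the constant core
        for i in rng.choice(other_cols, size=3, replace=False):
            row[i] = iupac.union(row[i], sorted(set("ACGT") - iupac.base_set(row[i]))[0])
        group.append("".join(row))
    assert constant_additive_positions(group, pa, pb) == [i + 1 for i in core]
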