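import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rtcp.alphabets import canonical_alphabets, reduce_sequence
from rtcp.features import (
    PSSMatrix,
    FeatureVector,
    PSSMParseError,
    parse_pssm_ascii,
    sigmoid_scale,
    pssm_feature,
    tripeptide_composition,
    tripeptide_labels,
    assemble_rtcp,
    amino_acid_composition,
    fit_reducer,
    apply_reducer,
    PSSM_COLUMNS,
)
from rtcp.synthetic import format_pssm_ascii


# ---------------------------------------------------------------- PSSM parsing


def _ascii_pssm(rows, residues, extra_cols=0):
    letters = "  ".join(PSSM_COLUMNS)
    lines = ["", "Last position-specific scoring matrix computed", f"   {letters}   {letters}"]
    for i, (res, row) in enumerate(zip(residues, rows), start=1):
        fields = " ".join(str(v) for v in row) + ("  0" * extra_cols)
        lines.append(f"{i:5d} {res}  {fields}")
    return "\n".join(lines) + "\n"


def test_parse_well_formed_three_rows():
    rows = [[1] * 20, [0] * 20, [-2] * 20]
    m = parse_pssm_ascii(_ascii_pssm(rows, "MKV", extra_cols=22))
    assert m.scores.shape == (3, 20)
    assert m.residues == "MKV"
    assert np.all(m.scores[2] == -2)


def test_parse_keeps_only_log_odds_block():
    # 44 numeric fields per row: 20 log-odds + 20 percentages + 2 stats
    rows = [list(range(20)), list(range(20))]
    m = parse_pssm_ascii(_ascii_pssm(rows, "AC", extra_cols=22))
    assert np.array_equal(m.scores, np.array([list(range(20))] * 2, dtype=float))


def test_parse_empty_body_raises():
    with pytest.raises(PSSMParseError):
        parse_pssm_ascii(_ascii_pssm([], ""))


def test_parse_short_row_names_line():
    letters = "  ".join(PSSM_COLUMNS)
    bad = "\n".join(["", "header", f"   {letters}   {letters}", "    1 A  1 2 3"])
    with pytest.raises(PSSMParseError, match="line"):
        parse_pssm_ascii(bad)


def test_pssmatrix_row_residue_mismatch():
    with pytest.raises(ValueError):
        PSSMatrix("p", "AC", np.zeros((3, 20)))


def test_format_parse_round_trip():
    rng = np.random.default_rng(3)
    scores = np.round(rng.normal(0, 2, size=(7, 20)))
    m = PSSMatrix("p1", "ACDEFGH", scores)
    back = parse_pssm_ascii(format_pssm_ascii(m), "p1")
    assert back.residues == m.residues
    assert np.array_equal(back.scores, m.scores)


# ---------------------------------------------------------------- sigmoid/PSSM


def test_sigmoid_values():
    assert sigmoid_scale(0.0) == 0.5
    assert math.isclose(sigmoid_scale(math.log(3)), 0.75, rel_tol=1e-12)


@given(st.floats(-500, 500))
def test_sigmoid_symmetry_and_range(a):
    s = sigmoid_scale(a)
    assert 0.0 <= s <= 1.0
    assert math.isclose(s, 1.0 - sigmoid_scale(-a), abs_tol=1e-12)


def test_pssm_feature_zero_matrix():
    m = PSSMatrix("p", "AAAAA", np.zeros((5, 20)))
    f = pssm_feature(m)
    assert len(f) == 20
    assert np.allclose(f.values, 0.5)


def test_pssm_feature_two_row_average():
    scores = np.vstack([np.zeros(20), np.full(20, math.log(3))])
    f = pssm_feature(PSSMatrix("p", "AC", scores))
    assert np.allclose(f.values, 0.625)


def test_pssm_feature_row_permutation_invariant():
    rng = np.random.default_rng(5)
    scores = rng.normal(0, 2, size=(30, 20))
    perm = rng.permutation(30)
    f1 = pssm_feature(PSSMatrix("p", "A" * 30, scores))
    f2 = pssm_feature(PSSMatrix("p", "A" * 30, scores[perm]))
    assert np.allclose(f1.values, f2.values)
    assert np.all((f1.values > 0) & (f1.values < 1))


# ---------------------------------------------------------------- tripeptides


def brute_force_tc(reduced, k):
    counts = {}
    for i in range(len(reduced) - 2):
        counts[tuple(reduced[i : i + 3])] = counts.get(tuple(reduced[i : i + 3]), 0) + 1
    vec = np.zeros(k**3)
    for (x, y, z), c in counts.items():
        vec[x * k * k + y * k + z] = c / (len(reduced) - 2)
    return vec


def test_tripeptide_constant_sequence():
    f = tripeptide_composition([0, 0, 0, 0], 7)
    assert f.values[0] == 1.0
    assert f.values.sum() == 1.0
    assert len(f) == 343


def test_tripeptide_alternating_two_symbols():
    f = tripeptide_composition([0, 1, 0, 1], 2)
    labels = dict(zip(f.schema, f.values))
    assert labels["0-1-0"] == 0.5
    assert labels["1-0-1"] == 0.5
    assert f.values.sum() == 1.0


def test_raw_amino_acid_tripeptide_space_is_8000():
    assert len(tripeptide_labels(20)) == 8000


@given(
    st.integers(2, 8).flatmap(
        lambda k: st.tuples(
            st.just(k), st.lists(st.integers(0, k - 1), min_size=3, max_size=120)
        )
    )
)
def test_tripeptide_matches_brute_force(case):
    k, reduced = case
    f = tripeptide_composition(reduced, k)
    assert np.allclose(f.values, brute_force_tc(reduced, k), atol=1e-12)
    assert abs(f.values.sum() - 1.0) < 1e-9


def test_tripeptide_too_short_raises():
    with pytest.raises(ValueError):
        tripeptide_composition([0, 1], 2)


# ---------------------------------------------------------------- RTCP


@pytest.mark.parametrize("name", sorted(canonical_alphabets()))
def test_rtcp_length_is_k_cubed_plus_20(name):
    alpha = canonical_alphabets()[name]
    seq = "ACDEFGHIKLMNPQRSTVWY" * 2
    rtc = tripeptide_composition(reduce_sequence(seq, alpha), alpha.size, "p")
    pf = pssm_feature(PSSMatrix("p", seq, np.zeros((len(seq), 20))))
    combined = assemble_rtcp(rtc, pf)
    assert len(combined) == alpha.size**3 + 20
    # tripeptide labels first, then the 20 pssm columns
    assert combined.schema[-20:] == tuple(f"pssm_{c}" for c in PSSM_COLUMNS)
    assert combined.schema[: alpha.size**3] == rtc.schema


def test_rtcp_532_for_eight_letter_alphabet():
    alpha = canonical_alphabets()["ST_CP"]
    assert alpha.size**3 + 20 == 532


def test_assemble_rejects_id_mismatch():
    a = FeatureVector("p1", np.zeros(8), tuple(f"t{i}" for i in range(8)))
    b = FeatureVector("p2", np.zeros(20), tuple(f"pssm_{c}" for c in PSSM_COLUMNS))
    with pytest.raises(ValueError):
        assemble_rtcp(a, b)


# ---------------------------------------------------------------- composition


def test_amino_acid_composition():
    f = amino_acid_composition("AAAA")
    assert f.values[0] == 1.0 and f.values[1:].sum() == 0.0
    g = amino_acid_composition("HQVHQV")
    nz = dict(zip(g.schema, g.values))
    assert math.isclose(nz["aac_H"], 1 / 3) and math.isclose(nz["aac_V"], 1 / 3)
    assert len(g) == 20
    with pytest.raises(ValueError):
        amino_acid_composition("X")


# ---------------------------------------------------------------- reducer


def test_reducer_default_width_80():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(120, 532))
    r = fit_reducer(X)
    assert apply_reducer(r, X).shape == (120, 80)
    assert np.allclose(r.components @ r.components.T, np.eye(80), atol=1e-8)


def test_reducer_exact_subspace_reconstruction():
    rng = np.random.default_rng(1)
    basis = rng.normal(size=(3, 40))
    X = rng.normal(size=(50, 3)) @ basis + 5.0
    r = fit_reducer(X, 3)
    Z = apply_reducer(r, X)
    Xhat = Z @ r.components + r.mean
    assert np.allclose(Xhat, X, atol=1e-8)


def test_reducer_first_axis_on_diagonal_line():
    t = np.linspace(-1, 1, 30)
    X = np.column_stack([t, t])
    r = fit_reducer(X, 1)
    assert np.allclose(np.abs(r.components[0]), 1 / np.sqrt(2), atol=1e-10)
    assert r.components[0, np.argmax(np.abs(r.components[0]))] > 0


def test_reducer_dimension_guard():
    with pytest.raises(ValueError):
        fit_reducer(np.zeros((10, 5)), 9)
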