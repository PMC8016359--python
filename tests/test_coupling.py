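import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pgksite as pg
from pgksite.coupling import (
    CouplingError,
    N_ALPHA,
    conditional_frame,
    conditioning_neighbor,
    marginal_frame,
)
from pgksite.windowing import ALPHABET, NEGATIVE, POSITIVE, PeptideWindow
from conftest import brute_force_tables


def test_hand_counted_conditional_probabilities(toy_windows):
    """P(A|R)=2/3 and P(C|R)=1/3 at position 1 of the ARKAR/ARKRA/CRKAR toy."""
    cond, marg = pg.fit_tables(toy_windows, zeta=2)
    a, c, r = ALPHABET.index("A"), ALPHABET.index("C"), ALPHABET.index("R")
    assert cond[1][a, r] == pytest.approx(2 / 3)
    assert cond[1][c, r] == pytest.approx(1 / 3)
    assert cond[1][:, r].sum() == pytest.approx(1.0)
    # marginal at position 2 (left centre-adjacent): all three have R
    assert marg[2][r] == pytest.approx(1.0)


def test_single_window_gives_degenerate_tables():
    cond, marg = pg.fit_tables([PeptideWindow("P", 3, "ARKAR")], zeta=2)
    observed = cond[1][cond[1] > 0]
    assert np.allclose(observed, 1.0)
    assert marg[2].sum() == pytest.approx(1.0)


def test_conditional_table_enumerates_441_pairs(toy_windows):
    cond, _ = pg.fit_tables(toy_windows, zeta=2)
    assert all(t.shape == (21, 21) and t.size == 441 for t in cond.values())


def test_empty_subset_warns_and_zero_fills():
    with pytest.warns(UserWarning, match="empty subset"):
        cond, marg = pg.fit_tables([], zeta=2)
    assert all(not t.any() for t in cond.values())
    assert all(not m.any() for m in marg.values())


@given(
    n_windows=st.integers(min_value=1, max_value=20),
    zeta=st.integers(min_value=2, max_value=3),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(deadline=None, max_examples=25, derandomize=True)
def test_fit_tables_matches_brute_force_oracle(n_windows, zeta, seed):
    """Vectorised counting agrees exactly with a nested-loop enumeration."""
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(n_windows):
        flank = rng.choice(list(ALPHABET), size=2 * zeta)
        residues = "".join(flank[:zeta]) + "K" + "".join(flank[zeta:])
        windows.append(PeptideWindow(f"P{i}", zeta + 1, residues))
    cond, marg = pg.fit_tables(windows, zeta)
    ref_cond, ref_marg = brute_force_tables(windows, zeta)
    for p in ref_cond:
        np.testing.assert_allclose(cond[p], ref_cond[p], atol=1e-12)
    for p in ref_marg:
        np.testing.assert_allclose(marg[p], ref_marg[p], atol=1e-12)


def test_normalization_over_observed_conditioners(small_enriched_dataset):
    _, dataset = small_enriched_dataset
    model = pg.fit_model(dataset)
    for tables in (model.positive_conditional, model.negative_conditional):
        for table in tables.values():
            col_sums = table.sum(axis=0)
            observed = col_sums > 0
            np.testing.assert_allclose(col_sums[observed], 1.0, atol=1e-12)
    for tables in (model.positive_marginal, model.negative_marginal):
        for m in tables.values():
            assert m.sum() == pytest.approx(1.0, abs=1e-12)


def test_fit_model_requires_both_classes(toy_windows):
    ds = pg.WindowDataset(windows=toy_windows, zeta=2)
    with pytest.raises(CouplingError, match="both classes"):
        pg.fit_model(ds)


def test_identical_subsets_encode_to_zero(toy_windows):
    mirrored = [
        PeptideWindow(w.protein_id, w.position, w.residues, NEGATIVE)
        for w in toy_windows
    ]
    ds = pg.WindowDataset(windows=toy_windows + mirrored, zeta=2)
    model = pg.fit_model(ds)
    X, _ = pg.encode_dataset(ds, model)
    np.testing.assert_allclose(X, 0.0, atol=1e-12)


def test_encode_component_is_table_difference(toy_dataset):
    model = pg.fit_model(toy_dataset)
    w = toy_dataset.windows[0]  # ARKAR (positives sort first only by id)
    assert w.residues == "ARKAR"
    vec = pg.encode_window(w, model)
    a, r = ALPHABET.index("A"), ALPHABET.index("R")
    expected = (
        model.positive_conditional[1][a, r] - model.negative_conditional[1][a, r]
    )
    assert vec[0] == pytest.approx(expected)
    assert vec.shape == (4,)
    assert np.all(np.abs(vec) <= 1.0)


def test_feature_dimension_is_28_at_default_zeta():
    spec = pg.SyntheticSpec(
        n_proteins=6, length_range=(200, 260), n_pos_sites=10, n_neg_sites=20,
        seed=3,
    )
    ds = pg.generate(spec)
    wd = pg.build_dataset(ds.proteins, ds.annotations, zeta=14)
    model = pg.fit_model(wd)
    X, y = pg.encode_dataset(wd, model)
    assert X.shape == (30, 28)
    assert model.feature_dim == 28
    assert np.all(np.abs(X) <= 1.0)


def test_encoding_is_deterministic(toy_dataset):
    m1 = pg.fit_model(toy_dataset)
    m2 = pg.fit_model(toy_dataset)
    X1, _ = pg.encode_dataset(toy_dataset, m1)
    X2, _ = pg.encode_dataset(toy_dataset, m2)
    np.testing.assert_array_equal(X1, X2)


def test_conditioning_direction_points_at_center():
    # left flank conditions on the right-hand neighbour, right flank on the left
    assert conditioning_neighbor(1, 14) == 2
    assert conditioning_neighbor(13, 14) == 14
    assert conditioning_neighbor(16, 14) == 15
    assert conditioning_neighbor(28, 14) == 27
    with pytest.raises(CouplingError):
        conditioning_neighbor(14, 14)


def test_export_shapes_and_round_trip(tmp_path, toy_dataset):
    model = pg.fit_model(toy_dataset)
    cond_f = conditional_frame(model)
    marg_f = marginal_frame(model)
    # zeta=2: one conditional position per flank per subset, 441 pair rows
    assert cond_f.shape == (441, 4)
    assert marg_f.shape == (21, 4)

    pc, pm = tmp_path / "cond.csv", tmp_path / "marg.csv"
    pg.export_tables(model, pc, pm)
    loaded = pg.load_tables(pc, pm)
    assert loaded.zeta == model.zeta
    assert loaded.n_pos == model.n_pos and loaded.n_neg == model.n_neg
    for p in model.positive_conditional:
        np.testing.assert_allclose(
            loaded.positive_conditional[p], model.positive_conditional[p]
        )
    for p in model.negative_marginal:
        np.testing.assert_allclose(
            loaded.negative_marginal[p], model.negative_marginal[p]
        )
    # encodings survive the round trip bit-for-bit
    X1, _ = pg.encode_dataset(toy_dataset, model)
    X2, _ = pg.encode_dataset(toy_dataset, loaded)
    np.testing.assert_allclose(X1, X2, atol=1e-15)


def test_default_zeta_export_has_26_conditional_positions():
    spec = pg.SyntheticSpec(
        n_proteins=6, length_range=(200, 260), n_pos_sites=10, n_neg_sites=20,
        seed=3,
    )
    ds = pg.generate(spec)
    wd = pg.build_dataset(ds.proteins, ds.annotations, zeta=14)
    model = pg.fit_model(wd)
    frame = conditional_frame(model)
    positive_cols = [c for c in frame.columns if c.startswith("positive:")]
    assert len(positive_cols) == 26  # 13 left + 13 right
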