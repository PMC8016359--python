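import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pgksite as pg
from pgksite.evaluation import EvaluationError, cv_result_to_dict
from conftest import brute_force_auc


def test_confusion_hand_cases():
    t = [1, 1, 1, 1, -1, -1, -1, -1, -1, -1]
    p = [1, 1, 1, -1, 1, -1, -1, -1, -1, -1]
    c = pg.confusion(t, p)
    assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 5)
    perfect = pg.confusion([1] * 3 + [-1] * 5, [1] * 3 + [-1] * 5)
    assert (perfect.tp, perfect.fp, perfect.tn, perfect.fn) == (3, 0, 5, 0)
    allpos = pg.confusion([1] * 3 + [-1] * 5, [1] * 8)
    assert (allpos.fp, allpos.fn) == (5, 0)


def test_confusion_length_mismatch():
    with pytest.raises(EvaluationError, match="mismatch"):
        pg.confusion([1, -1], [1])


def test_metrics_hand_computed_values():
    rep = pg.metrics(pg.ConfusionCounts(tp=3, fn=1, fp=1, tn=5))
    assert rep.sn == pytest.approx(0.75)
    assert rep.sp == pytest.approx(5 / 6)
    assert rep.precision == pytest.approx(0.75)
    assert rep.acc == pytest.approx(0.8)
    assert rep.mcc == pytest.approx(14 / 24)


def test_metrics_perfect_and_degenerate():
    perfect = pg.metrics(pg.ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
    assert (perfect.sn, perfect.sp, perfect.precision, perfect.acc, perfect.mcc) == (
        1.0, 1.0, 1.0, 1.0, 1.0,
    )
    inverted = pg.metrics(pg.ConfusionCounts(tp=0, fp=6, tn=0, fn=4))
    assert inverted.mcc == pytest.approx(-1.0)
    degenerate = pg.metrics(pg.ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
    assert degenerate.precision == 0.0
    assert degenerate.mcc == 0.0


def test_metrics_agree_with_sklearn_mcc():
    from sklearn.metrics import matthews_corrcoef

    rng = np.random.default_rng(0)
    for _ in range(20):
        t = rng.choice([1, -1], size=50)
        p = rng.choice([1, -1], size=50)
        if len(set(t)) < 2:
            continue
        rep = pg.metrics(pg.confusion(t, p))
        assert rep.mcc == pytest.approx(matthews_corrcoef(t, p), abs=1e-12)


def test_roc_auc_known_values():
    assert pg.roc_auc([1, 1, -1, -1], [0.9, 0.8, 0.2, 0.1]) == 1.0
    assert pg.roc_auc([1, -1, 1, -1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    assert pg.roc_auc([1, -1, 1, -1], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(0.75)


def test_roc_auc_rejects_single_class():
    with pytest.raises(EvaluationError, match="both classes"):
        pg.roc_auc([1, 1], [0.1, 0.2])


@given(
    n=st.integers(min_value=2, max_value=200),
    seed=st.integers(min_value=0, max_value=10_000),
    tie_prob=st.floats(min_value=0.0, max_value=0.9),
)
@settings(deadline=None, max_examples=40, derandomize=True)
def test_roc_auc_matches_all_pairs_concordance(n, seed, tie_prob):
    """Rank-based AUC equals brute-force pair counting, ties weighing half."""
    rng = np.random.default_rng(seed)
    labels = rng.choice([1, -1], size=n)
    if len(set(labels.tolist())) < 2:
        labels[0], labels[1] = 1, -1
    scores = rng.standard_normal(n)
    tied = rng.random(n) < tie_prob
    scores[tied] = np.round(scores[tied])  # force score collisions
    assert pg.roc_auc(labels, scores) == pytest.approx(
        brute_force_auc(labels, scores), abs=1e-12
    )


def test_roc_points_cover_unit_square():
    pts = pg.roc_points([1, -1, 1, -1], [0.9, 0.8, 0.7, 0.6])
    fpr = [p[0] for p in pts]
    tpr = [p[1] for p in pts]
    assert fpr[0] == 0.0 and fpr[-1] == 1.0
    assert tpr[-1] == 1.0


def _separated_dataset(zeta=3, n_pos=30, n_neg=90, seed=0):
    spec = pg.SyntheticSpec(
        n_proteins=30, length_range=(150, 250), n_pos_sites=n_pos,
        n_neg_sites=n_neg, zeta=zeta,
        enrichment=pg.motif_enrichment(zeta, 8.0),  # near-deterministic motif
        seed=seed,
    )
    ds = pg.generate(spec)
    return pg.build_dataset(ds.proteins, ds.annotations, zeta=zeta)


@pytest.mark.parametrize("protocol", ["paper", "nested"])
def test_separated_dataset_scores_perfectly(protocol):
    wd = _separated_dataset()
    cfg = pg.CVConfig(folds=5, repeats=2, protocol=protocol, seed=0)
    res = pg.repeated_cv(wd, cfg, hyperparams=pg.HyperParams())
    assert res.mean.acc == pytest.approx(1.0)
    assert res.mean.auc == pytest.approx(1.0)
    assert res.mean.mcc == pytest.approx(1.0)


def test_each_repeat_partitions_the_dataset():
    """Every sample is scored exactly once per repeat (fold partition)."""
    from sklearn.model_selection import StratifiedKFold

    wd = _separated_dataset()
    y = np.array([1 if w.label == "positive" else -1 for w in wd.windows])
    for r in range(3):
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=7 + r)
        seen = np.zeros(len(y), dtype=int)
        for _, test_idx in skf.split(np.zeros(len(y)), y):
            seen[test_idx] += 1
        assert (seen == 1).all()


def test_repeated_cv_deterministic_given_seed():
    wd = _separated_dataset(seed=4)
    cfg = pg.CVConfig(folds=4, repeats=2, protocol="nested", seed=9)
    r1 = pg.repeated_cv(wd, cfg, hyperparams=pg.HyperParams())
    r2 = pg.repeated_cv(wd, cfg, hyperparams=pg.HyperParams())
    assert r1.mean == r2.mean
    assert r1.per_repeat == r2.per_repeat


def test_per_repeat_hyperparams_are_honoured():
    wd = _separated_dataset(seed=5)
    hps = [pg.HyperParams(C=1.0, gamma=0.5), pg.HyperParams(C=4.0, gamma=0.25)]
    cfg = pg.CVConfig(
        folds=4, repeats=2, protocol="paper", seed=0, per_repeat_hyperparams=hps
    )
    res = pg.repeated_cv(wd, cfg)
    assert res.hyperparams == hps


def test_grid_selection_inside_repeat():
    wd = _separated_dataset(seed=6)
    cfg = pg.CVConfig(folds=4, repeats=1, protocol="paper", seed=0)
    res = pg.repeated_cv(
        wd, cfg, C_grid=[1.0, 2.0], gamma_grid=[0.5, 0.25]
    )
    assert len(res.hyperparams) == 1
    assert res.hyperparams[0].C in (1.0, 2.0)


def test_paper_protocol_leaks_relative_to_nested():
    """Full-dataset feature fitting inflates AUC versus nested refitting.

    Statistical tendency over seeds on data with class-distinct coupling
    structure, not a per-seed guarantee.
    """
    deltas = []
    for s in range(20):
        spec = pg.SyntheticSpec(
            n_proteins=16, length_range=(120, 180), n_pos_sites=15,
            n_neg_sites=120, zeta=3,
            enrichment=pg.motif_enrichment(3, 1.0),
            first_order_coupling=0.1, seed=40 + s,
        )
        ds = pg.generate(spec)
        wd = pg.build_dataset(ds.proteins, ds.annotations, zeta=3)
        cfg_p = pg.CVConfig(folds=3, repeats=1, protocol="paper", seed=s)
        cfg_n = pg.CVConfig(folds=3, repeats=1, protocol="nested", seed=s)
        auc_p = pg.repeated_cv(wd, cfg_p, hyperparams=pg.HyperParams()).mean.auc
        auc_n = pg.repeated_cv(wd, cfg_n, hyperparams=pg.HyperParams()).mean.auc
        deltas.append(auc_p - auc_n)
    assert np.mean(deltas) > 0


def test_independent_test_resubstitution_is_perfect():
    wd = _separated_dataset(seed=8)
    report, scores = pg.independent_test(wd, wd, pg.HyperParams())
    assert report.acc == 1.0 and report.mcc == 1.0 and report.auc == 1.0
    assert len(scores) == len(wd)


def test_independent_test_warns_on_protein_overlap():
    wd = _separated_dataset(seed=8)
    with pytest.warns(UserWarning, match="shares"):
        pg.independent_test(wd, wd, pg.HyperParams())


def test_report_writers_round_trip(tmp_path):
    import json

    wd = _separated_dataset(seed=9)
    cfg = pg.CVConfig(folds=4, repeats=2, protocol="nested", seed=0)
    res = pg.repeated_cv(wd, cfg, hyperparams=pg.HyperParams())
    payload = cv_result_to_dict(res)
    path = tmp_path / "report.json"
    pg.evaluation.write_json_report(payload, path)
    loaded = json.loads(path.read_text())
    assert loaded["mean"]["acc"] == pytest.approx(res.mean.acc)
    assert len(loaded["per_repeat"]) == 2

    tsv = tmp_path / "report.tsv"
    pg.evaluation.write_tsv_report({"mean": res.mean}, tsv)
    header, row = tsv.read_text().strip().split("\n")
    assert header.split("\t")[0] == "name"
    assert row.split("\t")[0] == "mean"
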