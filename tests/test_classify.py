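import warnings

import numpy as np
import pytest

import flankact as fa
from flankact import classify as cl
from flankact.io import GeneModel, InsertionEvent


def smith_waterman(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    """Quadratic DP oracle for local alignment with linear gap cost."""
    H = np.zeros((len(a) + 1, len(b) + 1))
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    return float(H.max())


def test_similarity_identical_sequences(rng):
    seq = "".join(rng.choice(list("ACGT"), size=100))
    scores = fa.similarity_scores([seq, seq])
    assert np.allclose(scores, [100.0, 100.0])


def test_similarity_outlier_is_minimum(rng):
    gc_rich = [
        "".join(rng.choice(list("GC"), size=80)) for _ in range(4)
    ]
    outlier = "A" * 80
    scores = fa.similarity_scores(gc_rich + [outlier])
    assert np.argmin(scores) == 4


def test_similarity_matches_dp_oracle(rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(5)]
    scores = fa.similarity_scores(seqs)
    n = len(seqs)
    expected = np.zeros(n)
    for i in range(n):
        expected[i] = np.mean(
            [smith_waterman(seqs[i], seqs[j]) for j in range(n) if j != i]
        )
    assert np.allclose(scores, expected)


def test_similarity_errors():
    with pytest.raises(ValueError):
        fa.similarity_scores([])
    with pytest.raises(ValueError):
        fa.similarity_scores(["ACGT"])


def test_build_training_subsets_reference_bookkeeping():
    """190 positives + 90 negatives -> two 180-record subsets, 10 dropped."""
    pos = [f"p{i:03d}" for i in range(190)]
    scores = np.arange(190, dtype=float)
    neg = [f"n{i:03d}" for i in range(90)]
    split = fa.build_training_subsets(pos, scores, neg, group_size=90)
    assert len(split.subset_ids(1)) == 180
    assert len(split.subset_ids(2)) == 180
    assert len(split.dropped) == 10
    assert set(split.subset1_pos).isdisjoint(split.subset2_pos)


def test_build_training_subsets_sort_split_and_ties():
    pos = ["a", "b", "c", "d"]
    scores = np.array([9.0, 7.0, 5.0, 3.0])
    split = fa.build_training_subsets(pos, scores, ["n1", "n2"], group_size=2)
    assert split.subset1_pos == ["a", "b"]
    assert split.subset2_pos == ["c", "d"]

    tied = fa.build_training_subsets(
        ["b", "a", "d", "c"], np.array([5.0, 5.0, 5.0, 5.0]), ["n1"], group_size=2
    )
    assert tied.subset1_pos == ["a", "b"]  # lexicographic tie-break

    with pytest.raises(ValueError):
        fa.build_training_subsets(["a"], np.array([1.0]), ["n"], group_size=2)


def test_enumerate_combos():
    combos = fa.enumerate_combos()
    assert len(combos) == 15
    assert len(set(combos)) == 15
    sizes = [len(c) for c in combos]
    assert sizes == [1] * 4 + [2] * 6 + [3] * 4 + [4]


def test_train_layer_two_perfect_column(rng):
    n = 40
    y = np.array([1] * 20 + [0] * 20)
    X = np.zeros((n, 8))
    X[:, 0] = y + rng.normal(0, 0.01, n)
    gnb = fa.train_layer_two(X, y, frozenset({"ngram"}))
    cols = cl.combo_columns(frozenset({"ngram"}))
    pred = gnb.predict(X[:, cols])
    assert (pred == y).mean() == 1.0
    with pytest.raises(ValueError):
        fa.train_layer_two(X, np.ones(n), frozenset({"ngram"}))


def test_gnb_duplicate_column_ranking_consistent(rng):
    """Duplicated Gaussian input columns preserve the prediction ranking."""
    from sklearn.naive_bayes import GaussianNB

    n = 60
    y = np.array([1] * 30 + [0] * 30)
    x = rng.normal(y, 1.0)
    one = GaussianNB().fit(x[:, None], y)
    two = GaussianNB().fit(np.column_stack([x, x]), y)
    p1 = one.predict_proba(x[:, None])[:, 1]
    p2 = two.predict_proba(np.column_stack([x, x]))[:, 1]
    assert np.array_equal(np.argsort(p1), np.argsort(p2))


def test_layer_one_count_and_shapes(tiny_model):
    assert len(tiny_model.layer_one) == 8
    assert set(tiny_model.layer_one) == set(cl.ADMISSIBLE_PAIRS)
    trained = [m for m in tiny_model.layer_one.values() if not m.skipped]
    assert len(trained) == 8


def test_layer_one_training_determinism(small_records, reduced_table, small_study):
    """Same seed twice: identical decision values on held-out records."""
    _, recs, labs = small_records
    lib = fa.synthetic_motif_library(seed=small_study.spec.seed)
    cfg = fa.RunConfig(seed=77)
    train, held = recs[:32], recs[32:]
    labs_train = labs[:32]
    out = []
    for _ in range(2):
        enc = fa.Encoder(lib, reduced_table, cfg)
        m = fa.TwoLayerModel(encoder=enc, config=cfg, seed=77)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(train, labs_train)
        out.append(m.predict_proba(held))
    assert np.array_equal(out[0], out[1])


def test_separable_toy_training_accuracy(rng):
    """A linearly separable 2-feature design is learnt perfectly."""
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    y = np.array([1] * 20 + [0] * 20)
    X = np.column_stack([y * 10.0 + rng.normal(0, 0.1, 40), rng.normal(size=40)])
    pipe = Pipeline([("s", StandardScaler()), ("svc", SVC(kernel="rbf", C=8.0))])
    pipe.fit(X, y)
    assert (pipe.predict(X) == y).mean() == 1.0


def test_two_layer_predictions_and_combo(tiny_model, small_records):
    rids, recs, labs = small_records
    proba = tiny_model.predict_proba(recs)
    assert proba.shape == (len(recs),)
    assert np.all((proba >= 0) & (proba <= 1))
    # planted signal: the selected combo must involve a sequence feature
    assert tiny_model.combo & {"ngram", "motif"}
    # self-consistency on a planted study separates the classes
    assert fa.auc_score(proba, labs) > 0.9


def test_layer_two_input_dimension_invariant(tiny_model):
    full = cl.combo_columns(frozenset(cl.FEATURES))
    for combo in fa.enumerate_combos():
        assert len(cl.combo_columns(combo)) <= len(full)
    assert tiny_model.integrator.n_features_in_ == len(
        cl.combo_columns(tiny_model.combo)
    )


def test_missing_region_emits_half(tiny_model, small_records):
    _, recs, _ = small_records
    rs = recs[0]
    crippled = fa.RegionSequences(
        gene_id=rs.gene_id, line_id=rs.line_id, ups1k=rs.ups1k,
        distance_seq="", middle="", distance_bp=1, location_class="US",
    )
    matrices = tiny_model.encoder.encode_study([crippled])
    missing = {
        pair: np.array([True])
        for pair in cl.ADMISSIBLE_PAIRS
        if pair[0] in ("DISTANCE", "MIDDLE")
    }
    out = cl.layer_one_outputs(
        tiny_model.layer_one, matrices, tiny_model.masks,
        np.array([0.8]), tiny_model.config.weighting, missing,
    )
    assert out.shape == (1, 8)
    for col, pair in enumerate(cl.ADMISSIBLE_PAIRS):
        if pair[0] != "UPS1K":
            assert out[0, col] == 0.5


def test_predict_flanking_genes_window(tiny_model, small_study):
    genes = small_study.genes
    gene = genes[0]
    ins = InsertionEvent("q", gene.chrom, gene.tls + 500)
    table = fa.predict_flanking_genes(
        tiny_model, small_study.genome, genes, ins, window_bp=600
    )
    assert list(table.columns) == [
        "gene_id", "chrom", "tls", "distance_bp", "location_class", "label",
        "confidence",
    ]
    assert gene.gene_id in set(table.gene_id)
    # closed window boundary: distance exactly == window is included
    boundary = fa.predict_flanking_genes(
        tiny_model, small_study.genome, [gene], ins, window_bp=500
    )
    assert len(boundary) == 1
    # too-small window: empty table
    empty = fa.predict_flanking_genes(
        tiny_model, small_study.genome, [gene], ins, window_bp=10
    )
    assert empty.empty


def test_full_system_protocols(small_records, reduced_table, small_study):
    """Similarity-grouped subsets, protocol table and selection score."""
    rids, recs, labs = small_records
    records = dict(zip(rids, recs))
    label_map = dict(zip(rids, labs))
    lib = fa.synthetic_motif_library(seed=small_study.spec.seed)
    cfg = fa.RunConfig(seed=5)
    enc = fa.Encoder(lib, reduced_table, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fa.train_full_system(records, label_map, enc, cfg)
    protocols = set(result.protocol.protocol)
    assert protocols == {"cross_validation", "self_consistency", "exchange_testing"}
    assert set(result.protocol.model) == {"subset1", "subset2"}
    assert result.selected in ("subset1", "subset2")
    # self-consistency should not trail cross-validation on a planted study
    for name in ("subset1", "subset2"):
        sub = result.protocol.set_index(["model", "protocol"])
        self_acc = sub.loc[(name, "self_consistency"), "Acc(%)"]
        cv_acc = sub.loc[(name, "cross_validation"), "Acc(%)"]
        assert self_acc >= cv_acc - 1e-9


def test_full_system_leakage_guard(small_records, reduced_table, small_study):
    rids, recs, labs = small_records
    records = dict(zip(rids, recs))
    label_map = dict(zip(rids, labs))
    lib = fa.synthetic_motif_library(seed=small_study.spec.seed)
    enc = fa.Encoder(lib, reduced_table, fa.RunConfig(seed=5))
    with pytest.raises(ValueError, match="overlap"):
        fa.train_full_system(
            records, label_map, enc, fa.RunConfig(seed=5),
            test_records={rids[0]: recs[0]}, test_labels={rids[0]: labs[0]},
        )
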