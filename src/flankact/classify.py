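"""Two-layer stacked classifier for flanking-gene activation.

Layer 1: one RBF-kernel SVM with Platt probability calibration per
admissible (region, feature) pair -- UPS1K carries all four encodings,
DISTANCE and MIDDLE carry N-gram and NPC only, eight models in total.
Each model sees pattern-masked (N-gram/Motif), distance-weighted,
z-standardized features.

Layer 2: a Gaussian naive-Bayes integrator over the layer-1 activation
probabilities of one feature combination; all 15 non-empty combinations of
the four features are swept by stratified cross-validation on out-of-fold
layer-1 outputs and the best combination (highest AUC) is kept.

Training-set construction follows the similarity-grouping protocol: the
positive records are ranked by mean pairwise local-alignment score, split
into two equal groups, and each group is merged with the shared negatives
into a balanced subset; the two subset models are then compared with the
overfitting-aware selection score (cross-validation x exchange-testing /
self-consistency, summed over AUC, Sn and Sp).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import evaluate as ev
from .config import RunConfig
from .distance import DistanceLogisticModel, activation_probability, fit_distance_logistic
from .features import (
    MOTIF_CHANNELS,
    NGRAM_DIM,
    MotifScanner,
    PatternMask,
    cgi_names,
    count_ngrams,
    detect_cpg_islands,
    encode_cgi,
    encode_motifs,
    encode_npc,
    motif_names,
    ngram_names,
    npc_names,
    select_patterns,
)
from .io import GeneModel, GenomeAssembly, InsertionEvent, MotifLibrary, PropertyTable
from .regions import RegionSequences, extract_regions

logger = logging.getLogger("flankact")

FEATURES = ("ngram", "motif", "npc", "cgi")
ADMISSIBLE_PAIRS: tuple[tuple[str, str], ...] = (
    ("UPS1K", "ngram"),
    ("UPS1K", "motif"),
    ("UPS1K", "npc"),
    ("UPS1K", "cgi"),
    ("DISTANCE", "ngram"),
    ("DISTANCE", "npc"),
    ("MIDDLE", "ngram"),
    ("MIDDLE", "npc"),
)
# pattern masks are fitted for these keys (raw count columns)
MASKED_KEYS = ("UPS1K:ngram", "DISTANCE:ngram", "MIDDLE:ngram", "UPS1K:motif")


# ---------------------------------------------------------------------------
# encoding records


class Encoder:
    """Turns RegionSequences into the eight per-pair feature vectors."""

    def __init__(
        self,
        library: MotifLibrary,
        reduced_table: PropertyTable,
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        self.library = library
        self.reduced_table = reduced_table
        self.scanner = MotifScanner(library, self.config.motif_p_threshold)

    def encode_record(self, rs: RegionSequences) -> dict[tuple[str, str], np.ndarray]:
        out: dict[tuple[str, str], np.ndarray] = {}
        for region, feature in ADMISSIBLE_PAIRS:
            seq = getattr(rs, {"UPS1K": "ups1k", "DISTANCE": "distance_seq", "MIDDLE": "middle"}[region])
            if feature == "ngram":
                out[(region, feature)] = count_ngrams(seq)
            elif feature == "npc":
                if len(seq) < 2:
                    out[(region, feature)] = None  # missing region
                else:
                    out[(region, feature)] = encode_npc(seq, self.reduced_table)
            elif feature == "motif":
                occs = self.scanner.scan(seq)
                if self.config.motif_dis_mode == "tls":
                    anchor = len(seq) + 1  # TLS sits just 3' of UPS1K
                else:
                    anchor = len(seq) + 1 + rs.distance_bp  # insertion junction
                out[(region, feature)] = encode_motifs(
                    occs, self.library, len(seq), anchor
                )
            else:  # cgi
                islands = detect_cpg_islands(seq)
                out[(region, feature)] = encode_cgi(
                    islands, seq, max(len(seq), 1), len(seq) + 1
                )
        return out

    def dim(self, pair: tuple[str, str]) -> int:
        feature = pair[1]
        if feature == "ngram":
            return NGRAM_DIM
        if feature == "motif":
            return 6 * len(self.library)
        if feature == "npc":
            return 16 * self.reduced_table.values.shape[1]
        return 5

    def encode_study(
        self, records: list[RegionSequences]
    ) -> dict[tuple[str, str], np.ndarray]:
        """Stack per-record vectors into (n x d) matrices per pair.

        Records with a missing region contribute zero rows there."""
        per_record = [self.encode_record(r) for r in records]
        out = {}
        for pair in ADMISSIBLE_PAIRS:
            dim = self.dim(pair)
            rows = [
                pr[pair] if pr[pair] is not None else np.zeros(dim)
                for pr in per_record
            ]
            out[pair] = np.vstack(rows) if rows else np.empty((0, dim))
        return out

    def feature_names(self, pair: tuple[str, str]) -> list[str]:
        region, feature = pair
        if feature == "ngram":
            return [f"{region}:{n}" for n in ngram_names()]
        if feature == "motif":
            return [f"{region}:{n}" for n in motif_names(self.library)]
        if feature == "npc":
            return [f"{region}:{n}" for n in npc_names(self.reduced_table)]
        return [f"{region}:{n}" for n in cgi_names()]


# ---------------------------------------------------------------------------
# similarity grouping and subset construction


def similarity_scores(positive_seqs: list[str]) -> np.ndarray:
    """Mean pairwise local-alignment score of each record against the rest.

    Scoring: match +1, mismatch -1, gap -2 (linear).
    """
    from Bio import Align

    if not positive_seqs:
        raise ValueError("no positive sequences given")
    n = len(positive_seqs)
    if n < 2:
        raise ValueError("need at least 2 positives for similarity grouping")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(positive_seqs[i], positive_seqs[j])
            mat[i, j] = mat[j, i] = s
    return mat.sum(axis=1) / (n - 1)


@dataclass
class SubsetSplit:
    subset1_pos: list[str]  # record ids
    subset2_pos: list[str]
    negatives: list[str]
    dropped: list[str]
    scores: dict[str, float]

    def subset_ids(self, which: int) -> list[str]:
        pos = self.subset1_pos if which == 1 else self.subset2_pos
        return pos + self.negatives


def build_training_subsets(
    positive_ids: list[str],
    scores: np.ndarray,
    negative_ids: list[str],
    group_size: int,
) -> SubsetSplit:
    """Rank positives by similarity score and split into two equal groups.

    The top ``group_size`` positives form subset 1, the next ``group_size``
    subset 2; extras are dropped (logged by id).  Each subset shares the
    full negative set, so both are balanced at ``group_size`` a side.
    Ties at the boundary are broken by record-id lexicographic order.
    """
    if len(positive_ids) < 2 * group_size:
        raise ValueError(
            f"need at least {2 * group_size} positives, have {len(positive_ids)}"
        )
    order = sorted(
        range(len(positive_ids)), key=lambda i: (-scores[i], positive_ids[i])
    )
    ranked = [positive_ids[i] for i in order]
    split = SubsetSplit(
        subset1_pos=ranked[:group_size],
        subset2_pos=ranked[group_size : 2 * group_size],
        negatives=list(negative_ids),
        dropped=ranked[2 * group_size :],
        scores={positive_ids[i]: float(scores[i]) for i in range(len(positive_ids))},
    )
    if split.dropped:
        logger.info("similarity grouping dropped %d positives: %s",
                    len(split.dropped), ",".join(split.dropped))
    return split


def balance_negatives(
    positive_ids: list[str],
    negative_ids: list[str],
    ratio: float,
    seed: int,
) -> list[str]:
    """Seeded subsample of negatives to reach the requested P/N ratio."""
    target = int(round(len(positive_ids) / ratio))
    if target >= len(negative_ids):
        return list(negative_ids)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negative_ids), size=target, replace=False)
    return [negative_ids[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# layer 1


@dataclass
class LayerOneModel:
    region: str
    feature: str
    scaler: StandardScaler | None
    svc: SVC | None
    keep_cols: np.ndarray | None  # non-constant column indices after masking
    best_params: dict | None
    skipped: bool = False
    skip_reason: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.region, self.feature)


def _prepare_pair_matrix(
    pair: tuple[str, str],
    X: np.ndarray,
    masks: dict[str, PatternMask],
    weights: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Mask (N-gram/Motif), then apply the distance weighting."""
    region, feature = pair
    key = f"{region}:{feature}"
    if key in masks:
        mask = masks[key].mask
        if feature == "motif":
            mask = np.repeat(mask, len(MOTIF_CHANNELS))
        X = X[:, mask]
    if mode == "multiply":
        X = X * weights[:, None]
    elif mode == "append":
        X = np.hstack([X, weights[:, None]])
    return X


def train_layer_one(
    matrices: dict[tuple[str, str], np.ndarray],
    labels: np.ndarray,
    masks: dict[str, PatternMask],
    weights: np.ndarray,
    config: RunConfig,
    seed: int,
) -> tuple[dict[tuple[str, str], LayerOneModel], np.ndarray]:
    """Fit the eight layer-1 SVMs and return out-of-fold probabilities.

    Returns (models, oof) where ``oof`` is an (n x 8) matrix of stacked
    out-of-fold activation probabilities in ADMISSIBLE_PAIRS order; skipped
    models contribute a constant 0.5 column.

    The stacking outputs are leakage-free: inside each outer fold the
    pattern mask is refitted on the fold's training records only, so the
    out-of-fold probabilities (which drive layer-2 training and combination
    selection) reflect genuine generalization of the masked encodings.  The
    frozen ``masks`` fitted on the full training set are used only for the
    final deployed models.
    """
    y = labels.astype(int)
    n = len(y)
    models: dict[tuple[str, str], LayerOneModel] = {}
    oof = np.full((n, len(ADMISSIBLE_PAIRS)), 0.5)
    cv_outer = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=seed
    )
    cv_inner = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=seed
    )
    outer_splits = list(cv_outer.split(np.zeros(n), y))
    param_grid = {
        "svc__C": list(config.svm_c_grid),
        "svc__gamma": list(config.svm_gamma_grid),
    }
    for col, pair in enumerate(ADMISSIBLE_PAIRS):
        X = _prepare_pair_matrix(pair, matrices[pair], masks, weights, config.weighting)
        keep = np.nonzero(X.std(axis=0) > 0)[0]
        if keep.size < X.shape[1]:
            logger.warning(
                "%s:%s: dropped %d constant feature columns",
                pair[0], pair[1], X.shape[1] - keep.size,
            )
        if keep.size == 0:
            logger.warning("%s:%s: all columns constant; model skipped", *pair)
            models[pair] = LayerOneModel(
                *pair, None, None, None, None, skipped=True,
                skip_reason="all feature columns constant",
            )
            continue
        Xk = X[:, keep]
        pipe = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed))]
        )
        search = GridSearchCV(
            pipe, param_grid, scoring="roc_auc", cv=cv_inner, n_jobs=None
        )
        search.fit(Xk, y)
        best = {
            "C": search.best_params_["svc__C"],
            "gamma": search.best_params_["svc__gamma"],
        }

        def _make_pipe():
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svc", SVC(kernel="rbf", probability=True,
                                random_state=seed, **best)),
                ]
            )

        raw = matrices[pair]
        key = f"{pair[0]}:{pair[1]}"
        for train_idx, test_idx in outer_splits:
            if key in masks:
                fold_masks = {
                    key: _fit_single_mask(pair, raw[train_idx], y[train_idx],
                                          config.alpha)
                }
            else:
                fold_masks = {}
            Xf = _prepare_pair_matrix(pair, raw, fold_masks, weights,
                                      config.weighting)
            fold_keep = np.nonzero(Xf[train_idx].std(axis=0) > 0)[0]
            if fold_keep.size == 0:
                continue  # fold column stays at the 0.5 default
            fold_pipe = _make_pipe()
            fold_pipe.fit(Xf[np.ix_(train_idx, fold_keep)], y[train_idx])
            oof[test_idx, col] = fold_pipe.predict_proba(
                Xf[np.ix_(test_idx, fold_keep)]
            )[:, 1]
        final_pipe = _make_pipe()
        final_pipe.fit(Xk, y)
        models[pair] = LayerOneModel(
            region=pair[0],
            feature=pair[1],
            scaler=final_pipe.named_steps["scale"],
            svc=final_pipe.named_steps["svc"],
            keep_cols=keep,
            best_params=best,
        )
    return models, oof


def layer_one_outputs(
    models: dict[tuple[str, str], LayerOneModel],
    matrices: dict[tuple[str, str], np.ndarray],
    masks: dict[str, PatternMask],
    weights: np.ndarray,
    mode: str,
    missing: dict[tuple[str, str], np.ndarray] | None = None,
) -> np.ndarray:
    """Calibrated activation probability per layer-1 model, fixed pair order.

    ``missing`` optionally maps pair -> boolean row mask of records whose
    region sequence was absent; those entries emit 0.5.
    """
    n = len(weights)
    out = np.full((n, len(ADMISSIBLE_PAIRS)), 0.5)
    for col, pair in enumerate(ADMISSIBLE_PAIRS):
        m = models[pair]
        if m.skipped:
            continue
        X = _prepare_pair_matrix(pair, matrices[pair], masks, weights, mode)
        X = X[:, m.keep_cols]
        proba = m.svc.predict_proba(m.scaler.transform(X))[:, 1]
        if missing and pair in missing:
            proba = np.where(missing[pair], 0.5, proba)
        out[:, col] = proba
    return out


# ---------------------------------------------------------------------------
# layer 2


def enumerate_combos() -> list[frozenset[str]]:
    """All 15 non-empty feature subsets: singletons, pairs, triples, quad."""
    combos = []
    for size in range(1, len(FEATURES) + 1):
        for combo in itertools.combinations(FEATURES, size):
            combos.append(frozenset(combo))
    return combos


def combo_columns(combo: frozenset[str]) -> list[int]:
    return [i for i, (_, feat) in enumerate(ADMISSIBLE_PAIRS) if feat in combo]


GNB_VAR_SMOOTHING = 0.01  # inputs are probabilities; bounds posterior sharpness


def _fit_gnb(X: np.ndarray, y: np.ndarray) -> GaussianNB:
    gnb = GaussianNB(var_smoothing=GNB_VAR_SMOOTHING)
    gnb.fit(X, y)
    # degenerate (constant) inputs: floor the variance so posteriors reduce
    # to the class priors instead of NaN
    gnb.var_ = np.maximum(gnb.var_, 1e-12)
    return gnb


def train_layer_two(
    layer1_outputs: np.ndarray, labels: np.ndarray, combo: frozenset[str]
) -> GaussianNB:
    """Gaussian naive Bayes over the layer-1 columns of ``combo``."""
    y = labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("layer-2 training needs both classes")
    return _fit_gnb(layer1_outputs[:, combo_columns(combo)], y)


def gnb_log_odds(gnb: GaussianNB, X: np.ndarray) -> np.ndarray:
    """Class-1 vs class-0 joint log-likelihood difference (unbounded score)."""
    z = np.log(gnb.class_prior_[1]) - np.log(gnb.class_prior_[0])
    for j in range(X.shape[1]):
        for cls, sign in ((1, 1.0), (0, -1.0)):
            mu, var = gnb.theta_[cls, j], gnb.var_[cls, j]
            z = z + sign * (
                -0.5 * np.log(2 * np.pi * var)
                - 0.5 * (X[:, j] - mu) ** 2 / var
            )
    return z


def _combo_cv_report(
    oof: np.ndarray, y: np.ndarray, combo: frozenset[str], folds: int, seed: int
) -> ev.EvaluationReport:
    cols = combo_columns(combo)

    def fit_score(train_idx, test_idx):
        gnb = _fit_gnb(oof[np.ix_(train_idx, cols)], y[train_idx])
        return gnb.predict_proba(oof[np.ix_(test_idx, cols)])[:, 1]

    return ev.kfold_cv(y, fit_score, k=folds, seed=seed)


# ---------------------------------------------------------------------------
# the two-layer model


@dataclass
class TwoLayerModel:
    encoder: Encoder
    config: RunConfig
    seed: int
    distance_model: DistanceLogisticModel = field(default_factory=DistanceLogisticModel)
    masks: dict[str, PatternMask] = field(default_factory=dict)
    layer_one: dict[tuple[str, str], LayerOneModel] = field(default_factory=dict)
    combo: frozenset[str] = frozenset(FEATURES)
    integrator: GaussianNB | None = None
    calibrator: object | None = None  # 1-D logistic over integrator log-odds
    combo_reports: dict[frozenset[str], ev.EvaluationReport] = field(default_factory=dict)
    cv_report: ev.EvaluationReport | None = None
    training_ids: list[str] = field(default_factory=list)

    layer_one_order = ADMISSIBLE_PAIRS

    @property
    def motif_library(self) -> MotifLibrary:
        return self.encoder.library

    # -- training ----------------------------------------------------------

    def fit(self, records: list[RegionSequences], labels) -> "TwoLayerModel":
        y = _binary(labels)
        distances = np.array([r.distance_bp for r in records], dtype=float)
        if self.config.refit_distance:
            try:
                self.distance_model = fit_distance_logistic(distances, y)
            except ValueError as exc:
                logger.warning("distance logistic not refit (%s); using default", exc)
                self.distance_model = DistanceLogisticModel(
                    self.config.beta0, self.config.beta1
                )
        else:
            self.distance_model = DistanceLogisticModel(
                self.config.beta0, self.config.beta1
            )
        weights = activation_probability(self.distance_model, distances)
        matrices = self.encoder.encode_study(records)
        self.masks = fit_pattern_masks(matrices, y, self.config.alpha)
        self.layer_one, oof = train_layer_one(
            matrices, y, self.masks, weights, self.config, self.seed
        )
        self.combo_reports = {}
        for combo in enumerate_combos():
            self.combo_reports[combo] = _combo_cv_report(
                oof, y, combo, self.config.cv_folds, self.seed
            )
        self.combo = max(
            enumerate_combos(),
            key=lambda c: (
                np.nan_to_num(self.combo_reports[c].auc),
                np.nan_to_num(self.combo_reports[c].acc),
                -len(c),
            ),
        )
        self.cv_report = self.combo_reports[self.combo]
        # the integrator learns from the trained layer-1 models' outputs on
        # the training records (so its per-column orientation always matches
        # the deployed models); its log-odds are then recalibrated against
        # the leakage-free out-of-fold scores, which are distributed like
        # unseen-data scores
        l1_self = layer_one_outputs(
            self.layer_one, matrices, self.masks, weights, self.config.weighting
        )
        cols = combo_columns(self.combo)
        self.integrator = train_layer_two(l1_self, y, self.combo)
        z_oof = gnb_log_odds(self.integrator, oof[:, cols])
        self.calibrator = LogisticRegression(C=1e3, max_iter=1000)
        self.calibrator.fit(z_oof[:, None], y)
        self.training_ids = [f"{r.gene_id}|{r.line_id}" for r in records]
        return self

    # -- prediction --------------------------------------------------------

    def predict_proba(self, records: list[RegionSequences]) -> np.ndarray:
        distances = np.array([r.distance_bp for r in records], dtype=float)
        weights = activation_probability(self.distance_model, distances)
        matrices = self.encoder.encode_study(records)
        missing = {}
        for pair in ADMISSIBLE_PAIRS:
            region = pair[0]
            if region == "UPS1K":
                continue
            attr = "distance_seq" if region == "DISTANCE" else "middle"
            absent = np.array([len(getattr(r, attr)) < 2 for r in records])
            if absent.any():
                missing[pair] = absent
        l1 = layer_one_outputs(
            self.layer_one, matrices, self.masks, weights,
            self.config.weighting, missing,
        )
        z = gnb_log_odds(self.integrator, l1[:, combo_columns(self.combo)])
        return self.calibrator.predict_proba(z[:, None])[:, 1]

    def predict(self, records: list[RegionSequences]) -> np.ndarray:
        proba = self.predict_proba(records)
        return np.where(proba >= 0.5, "Ac", "NAc")


def _fit_single_mask(
    pair: tuple[str, str], raw: np.ndarray, y: np.ndarray, alpha: float
) -> PatternMask:
    X = raw
    if pair[1] == "motif":
        X = X[:, :: len(MOTIF_CHANNELS)]
    return select_patterns(X, y, alpha=alpha)


def fit_pattern_masks(
    matrices: dict[tuple[str, str], np.ndarray],
    y: np.ndarray,
    alpha: float,
) -> dict[str, PatternMask]:
    """Welch-t pattern masks for the N-gram regions and the motif counts.

    The motif mask is computed on the per-motif occurrence-count channel and
    selects whole motifs (all six channels follow the motif's mask entry).
    """
    masks: dict[str, PatternMask] = {}
    for key in MASKED_KEYS:
        region, feature = key.split(":")
        X = matrices[(region, feature)]
        if feature == "motif":
            X = X[:, :: len(MOTIF_CHANNELS)]  # the 'number' channel per motif
        masks[key] = select_patterns(X, y, alpha=alpha)
    return masks


def _binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return (arr == "Ac").astype(int)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# model selection across subsets


@dataclass
class FullSystemResult:
    model_s1: TwoLayerModel
    model_s2: TwoLayerModel
    split: SubsetSplit
    protocol: pd.DataFrame
    score_s1: ev.ModelSelectionScore
    score_s2: ev.ModelSelectionScore
    selected: str  # "subset1" or "subset2"

    @property
    def final_model(self) -> TwoLayerModel:
        return self.model_s1 if self.selected == "subset1" else self.model_s2


def train_full_system(
    records: dict[str, RegionSequences],
    labels: dict[str, str],
    encoder: Encoder,
    config: RunConfig | None = None,
    test_records: dict[str, RegionSequences] | None = None,
    test_labels: dict[str, str] | None = None,
    group_size: int | None = None,
) -> FullSystemResult:
    """Similarity-grouped two-subset training with Eq-style model selection.

    ``records``/``labels`` are keyed by record id.  The positives are split
    by similarity score into two groups of ``group_size`` (default: the
    balanced size implied by the negative count and P/N ratio); each group
    plus the shared negatives trains one TwoLayerModel.  The model with the
    higher selection score wins (ties: higher cross-validation AUC).
    """
    config = config or RunConfig()
    pos_ids = sorted(rid for rid, lab in labels.items() if lab == "Ac")
    neg_ids = sorted(rid for rid, lab in labels.items() if lab == "NAc")
    neg_ids = balance_negatives(pos_ids, neg_ids, config.pn_ratio, config.seed)
    if group_size is None:
        group_size = min(len(neg_ids), len(pos_ids) // 2)
    scores = similarity_scores([records[rid].ups1k for rid in pos_ids])
    split = build_training_subsets(pos_ids, scores, neg_ids, group_size)

    if test_records:
        overlap = set(test_records) & set(records)
        if overlap:
            raise ValueError(
                f"independent test set overlaps training records: {sorted(overlap)[:5]}"
            )

    models = []
    for which in (1, 2):
        ids = split.subset_ids(which)
        recs = [records[rid] for rid in ids]
        labs = [labels[rid] for rid in ids]
        m = TwoLayerModel(encoder=encoder, config=config, seed=config.seed)
        m.fit(recs, labs)
        models.append((ids, recs, labs, m))

    reports: dict[tuple[str, str], ev.EvaluationReport] = {}
    sel_scores = []
    for idx, (ids, recs, labs, m) in enumerate(models):
        name = f"subset{idx + 1}"
        other = models[1 - idx]
        cv = m.cv_report
        self_rep = ev.full_report(m.predict_proba(recs), _binary(labs))
        ex_rep = ev.full_report(m.predict_proba(other[1]), _binary(other[2]))
        reports[(name, "cross_validation")] = cv
        reports[(name, "self_consistency")] = self_rep
        reports[(name, "exchange_testing")] = ex_rep
        if test_records:
            t_ids = sorted(test_records)
            t_recs = [test_records[rid] for rid in t_ids]
            t_labs = [test_labels[rid] for rid in t_ids]
            reports[(name, "independent_testing")] = ev.full_report(
                m.predict_proba(t_recs), _binary(t_labs)
            )
        sel_scores.append(ev.model_selection_score(cv, ex_rep, self_rep))

    if (sel_scores[0].total, np.nan_to_num(models[0][3].cv_report.auc)) >= (
        sel_scores[1].total, np.nan_to_num(models[1][3].cv_report.auc)
    ):
        selected = "subset1"
    else:
        selected = "subset2"
    if sel_scores[1].total > sel_scores[0].total:
        selected = "subset2"
    return FullSystemResult(
        model_s1=models[0][3],
        model_s2=models[1][3],
        split=split,
        protocol=ev.protocol_table(reports),
        score_s1=sel_scores[0],
        score_s2=sel_scores[1],
        selected=selected,
    )


# ---------------------------------------------------------------------------
# prediction over flanking genes


def predict_flanking_genes(
    model: TwoLayerModel,
    genome: GenomeAssembly,
    genes: list[GeneModel],
    insertion: InsertionEvent,
    window_bp: int | None = None,
) -> pd.DataFrame:
    """Predict activation for every gene with TLS within ``window_bp`` of the
    insertion (closed interval), on the insertion's chromosome."""
    window = window_bp if window_bp is not None else model.config.window_bp
    if window <= 0:
        raise ValueError("window_bp must be positive")
    in_window = [
        g
        for g in genes
        if g.chrom == insertion.chrom and abs(g.tls - insertion.position) <= window
    ]
    cols = ["gene_id", "chrom", "tls", "distance_bp", "location_class", "label", "confidence"]
    if not in_window:
        logger.info("no genes within %d bp of %s:%d", window, insertion.chrom,
                    insertion.position)
        return pd.DataFrame(columns=cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recs = [extract_regions(genome, g, insertion) for g in in_window]
    proba = model.predict_proba(recs)
    rows = []
    for g, r, p in zip(in_window, recs, proba):
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "tls": g.tls,
                "distance_bp": r.distance_bp,
                "location_class": r.location_class,
                "label": "Ac" if p >= 0.5 else "NAc",
                "confidence": float(p),
            }
        )
    return pd.DataFrame(rows, columns=cols)
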