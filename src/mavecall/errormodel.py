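"""Classifier-based sequencing-error correction.

A negative-control (NC) library of the non-mutagenized template captures
the background error process. True variants are spiked into the NC
alignments with :mod:`mavecall.sim`, the caller is re-run, and each call is
labeled by truth-VCF membership. Binary classifiers are trained on the
caller's quality features and used to strip predicted errors from real
call sets.

The truth set is *balanced*: variants are sampled (SNP fraction 0.25 by
default, frequencies drawn from a mutagenized library's empirical
distribution) until their cumulative component-mismatch count (SNP = 1,
di = 2, tri = 3) reaches the NC library's false-positive mismatch count.
"""

from __future__ import annotations

import math
import os
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .call import CallFilters, VariantCall
from .refdata import TranscriptReference
from .synthdata import SUBSTITUTION_CLASSES, substitution_class

LABEL_TRUE = "true_variant"
LABEL_ERROR = "error"

#: component mismatches per variant type
COMPONENTS = {"SNP": 1, "di_nt_MNP": 2, "tri_nt_MNP": 3}

AMPLICON_FEATURES = [
    "log10_frequency",
    "variant_type",
    "matches_signature",
    "substitution",
    "upstream_nt",
    "downstream_nt",
    "r1_median_bq",
    "r2_median_bq",
    "r2_median_read_pos",
    "r2_median_nm",
]

RACE_EXTRA_FEATURES = [
    "r1_bq_plus", "r1_bq_minus", "r2_bq_plus", "r2_bq_minus",
    "r2_read_pos_plus", "r2_read_pos_minus", "r2_nm_plus", "r2_nm_minus",
    "strand_count_diff",
]

_CATEGORIES = {
    "variant_type": ["SNP", "di_nt_MNP", "tri_nt_MNP"],
    "substitution": list(SUBSTITUTION_CLASSES),
    "upstream_nt": list("ACGT"),
    "downstream_nt": list("ACGT"),
}


def _lower_median(values) -> float:
    s = sorted(values)
    return float(s[(len(s) - 1) // 2]) if s else math.nan


def features_from_calls(
    calls: list[VariantCall], ref: TranscriptReference, method: str = "amplicon"
) -> pd.DataFrame:
    """Caller quality features, one row per variant call.

    RACE-like libraries add strand-specific BQ/read-position/edit-distance
    features plus the sample-strand count difference; strata with zero
    observations yield NaN (imputed downstream by per-feature median
    rough-fix).
    """
    rows = []
    for call in calls:
        ann = call.annotation
        pos0 = ann.pos - 1
        first_mismatch = next(
            i for i, (r, a) in enumerate(zip(ann.ref_allele, ann.alt_allele)) if r != a
        )
        subst = substitution_class(
            ann.ref_allele[first_mismatch], ann.alt_allele[first_mismatch]
        )
        row = dict(
            pos=ann.pos,
            ref=ann.ref_allele,
            alt=ann.alt_allele,
            log10_frequency=math.log10(call.frequency),
            variant_type=ann.variant_type,
            matches_signature=int(call.matches_signature),
            substitution=subst,
            upstream_nt=ref.sequence[pos0 - 1] if pos0 > 0 else "A",
            downstream_nt=(
                ref.sequence[pos0 + len(ann.ref_allele)]
                if pos0 + len(ann.ref_allele) < len(ref.sequence)
                else "A"
            ),
            r1_median_bq=call.summaries["R1BQ"],
            r2_median_bq=call.summaries["R2BQ"],
            r2_median_read_pos=call.summaries["R2RP"],
            r2_median_nm=call.summaries["R2NM"],
        )
        if method == "race_like":
            obs = [o for c in call.components for o in c.observations]
            for strand, tag in (("+", "plus"), ("-", "minus")):
                sel = [o for o in obs if o.sample_strand == strand]
                row[f"r1_bq_{tag}"] = _lower_median([o.r1_bq for o in sel])
                row[f"r2_bq_{tag}"] = _lower_median([o.r2_bq for o in sel])
                row[f"r2_read_pos_{tag}"] = _lower_median([o.r2_read_pos for o in sel])
                row[f"r2_nm_{tag}"] = _lower_median([o.r2_nm for o in sel])
            row["strand_count_diff"] = abs(
                call.strand_counts.get("+", 0) - call.strand_counts.get("-", 0)
            )
        rows.append(row)
    cols = ["pos", "ref", "alt"] + AMPLICON_FEATURES
    if method == "race_like":
        cols += RACE_EXTRA_FEATURES
    return pd.DataFrame(rows, columns=cols)


def encode_features(table: pd.DataFrame, feature_columns: list[str] | None = None):
    """One-hot encode categoricals into a numeric design matrix.

    With ``feature_columns`` given (scoring time), the design is reindexed
    to that schema and scoring refuses on mismatch.
    """
    df = table.drop(columns=[c for c in ("pos", "ref", "alt", "label") if c in table])
    for col, cats in _CATEGORIES.items():
        if col in df:
            df[col] = pd.Categorical(df[col], categories=cats)
    design = pd.get_dummies(df, dtype=float)
    # median rough-fix for strand-specific NAs
    design = design.fillna(design.median(numeric_only=True)).fillna(0.0)
    if feature_columns is not None:
        missing = set(feature_columns) - set(design.columns)
        extra = set(design.columns) - set(feature_columns)
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch; missing={sorted(missing)} extra={sorted(extra)}"
            )
        design = design[feature_columns]
    return design


@dataclass
class ModelBundle:
    model: object
    feature_columns: list[str]
    model_kind: str
    seed: int
    cutoff: float = 0.5
    metadata: dict = field(default_factory=dict)

    def predict_error_probability(self, features: pd.DataFrame) -> np.ndarray:
        design = encode_features(features, self.feature_columns)
        proba = self.model.predict_proba(design.to_numpy())
        error_idx = list(self.model.classes_).index(LABEL_ERROR)
        return proba[:, error_idx]

    def save(self, path: str) -> str:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str) -> "ModelBundle":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class CvReport:
    fold_accuracies: list[float]
    feature_importances: pd.Series | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def count_false_positive_mismatches(nc_calls: list[VariantCall]) -> int:
    """Total component mismatches across NC calls (SNP=1, di=2, tri=3)."""
    return sum(COMPONENTS[c.annotation.variant_type] for c in nc_calls)


def build_balanced_truthset(
    nc_calls: list[VariantCall],
    mut_calls: list[VariantCall],
    ref: TranscriptReference,
    window: tuple[int, int],
    seed: int,
    snp_proportion: float = 0.25,
    per_variant_margin: int = 10,
):
    """Sample spike-in specs until component mismatches match the NC FP count.

    Frequencies are resampled from the mutagenized library's empirical
    variant-frequency distribution (calls below 0.3). Raises on an empty NC
    call set — there is nothing to balance against.
    """
    from .synthdata import random_variant_specs

    target = count_false_positive_mismatches(nc_calls)
    if target <= 0:
        raise ValueError("NC library has no false-positive mismatches to balance against")
    frequencies = [c.frequency for c in mut_calls if c.frequency < 0.3]
    if not frequencies:
        frequencies = [1e-3]

    rng = np.random.default_rng(seed)
    # draw generously, then walk the list landing exactly on the target
    pool = random_variant_specs(
        ref, window, n_variants=2 * target + 8, seed=seed,
        snp_proportion=snp_proportion, margin=per_variant_margin,
        frequencies=frequencies,
    )
    rng.shuffle(pool)
    chosen = []
    remaining = target
    for spec in pool:
        size = len(spec.ref_allele)
        if size > remaining:
            continue
        chosen.append(spec)
        remaining -= size
        if remaining == 0:
            break
    if remaining != 0:
        raise RuntimeError("could not balance the truth set exactly; widen the window")
    return chosen


def generate_training_dataset(
    nc_bam: str,
    truthset,
    ref: TranscriptReference,
    window: tuple[int, int],
    out_dir: str,
    seed: int,
    filters: CallFilters | None = None,
    method: str = "amplicon",
    aligner_config=None,
    max_frequency: float = 0.3,
) -> pd.DataFrame:
    """sim-edit the truth set into NC alignments, re-call, and label.

    Calls are labeled ``true_variant`` iff present in the truth VCF; calls
    outside the target window or with frequency >= ``max_frequency`` are
    excluded. Training runs the caller at min_count 1 so singleton errors
    are represented.
    """
    from . import sim as sim_mod
    from .call import run_call

    filters = filters or CallFilters(min_count=1, min_bq=30, max_nm=10, signature="NNK")
    os.makedirs(out_dir, exist_ok=True)
    truth, fq1, fq2, truth_vcf = sim_mod.run_sim(
        list(truthset), nc_bam, ref, os.path.join(out_dir, "sim"), seed=seed
    )
    truth_keys = {t.spec.key for t in truth if t.realized_count > 0}
    result = run_call(
        ref, os.path.join(out_dir, "call"), fastq_r1=fq1, fastq_r2=fq2,
        filters=filters, method=method, aligner_config=aligner_config,
    )
    wstart, wend = window
    kept = [
        c for c in result.calls
        if c.frequency < max_frequency and wstart <= c.annotation.pos - 1 < wend
    ]
    table = features_from_calls(kept, ref, method=method)
    table["label"] = [
        LABEL_TRUE if c.key in truth_keys else LABEL_ERROR for c in kept
    ]
    return table


_BASE_MODELS = {
    "rf": lambda seed: RandomForestClassifier(random_state=seed, n_jobs=1),
    "gbm": lambda seed: GradientBoostingClassifier(random_state=seed),
    "glm_elasticnet": lambda seed: Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(
                solver="saga", l1_ratio=0.5, max_iter=5000, random_state=seed,
            )),
        ]
    ),
    "knn": lambda seed: Pipeline(
        [("scale", StandardScaler()), ("clf", KNeighborsClassifier())]
    ),
    "svc": lambda seed: Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)),
        ]
    ),
}

_GRIDS = {
    "rf": [{"max_features": f} for f in ("sqrt", 0.5)],
    "gbm": [{"learning_rate": lr} for lr in (0.05, 0.1)],
    "glm_elasticnet": [{"clf__C": c} for c in (0.1, 1.0, 10.0)],
    "knn": [{"clf__n_neighbors": k} for k in (3, 5, 11)],
    "svc": [{"clf__estimator__C": c} for c in (0.5, 1.0, 5.0)],
}


def _fit_with_tuning(model_kind: str, X, y, seed: int):
    """Tune hyperparameters on 20% of the data, then refit on all of it."""
    base = _BASE_MODELS[model_kind](seed)
    grid = _GRIDS[model_kind]
    if len(grid) > 1 and len(np.unique(y)) > 1:
        X_fit, X_tune, y_fit, y_tune = train_test_split(
            X, y, test_size=0.2, random_state=seed, stratify=y
        )
        best, best_acc = None, -1.0
        for params in grid:
            m = _BASE_MODELS[model_kind](seed)
            m.set_params(**params)
            m.fit(X_fit, y_fit)
            acc = float(np.mean(m.predict(X_tune) == y_tune))
            if acc > best_acc:
                best, best_acc = params, acc
        base.set_params(**best)
    base.fit(X, y)
    return base


def _knn_select_features(X: pd.DataFrame, y, seed: int, k_range=(3, 10)) -> list[str]:
    """Greedy forward selection of 3-10 design columns scored by 5-fold CV."""
    from sklearn.model_selection import cross_val_score

    selected: list[str] = []
    candidates = list(X.columns)
    best_overall: tuple[float, list[str]] = (-1.0, [])
    while len(selected) < k_range[1] and candidates:
        scored = []
        for col in candidates:
            cols = selected + [col]
            m = _BASE_MODELS["knn"](seed)
            acc = cross_val_score(
                m, X[cols].to_numpy(), y,
                cv=StratifiedKFold(5, shuffle=True, random_state=seed),
            ).mean()
            scored.append((acc, col))
        scored.sort(reverse=True)
        acc, col = scored[0]
        selected.append(col)
        candidates.remove(col)
        if len(selected) >= k_range[0] and acc > best_overall[0]:
            best_overall = (acc, list(selected))
    return best_overall[1] or selected[: k_range[0]]


def train_and_evaluate(
    examples: pd.DataFrame,
    model_kind: str = "rf",
    seed: int = 0,
    n_folds: int = 10,
    cutoff: float = 0.5,
) -> tuple[ModelBundle, CvReport]:
    """Nested k-fold CV (default 10): within each fold 20% of the training
    split tunes hyperparameters; accuracy is measured on the held-out fold.
    The final model is refit on all examples. kNN additionally selects
    3-10 features by greedy forward selection under 5-fold CV. Random
    forests report mean-decrease-in-accuracy (permutation) importances.
    """
    if model_kind not in _BASE_MODELS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    y = examples["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    design = encode_features(examples)
    feature_columns = list(design.columns)
    X = design.to_numpy()

    if model_kind == "knn":
        cols = _knn_select_features(design, y, seed)
        design = design[cols]
        feature_columns = cols
        X = design.to_numpy()

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_acc = []
    for fold_i, (tr, te) in enumerate(skf.split(X, y)):
        model = _fit_with_tuning(model_kind, X[tr], y[tr], seed + fold_i)
        fold_acc.append(float(np.mean(model.predict(X[te]) == y[te])))

    final = _fit_with_tuning(model_kind, X, y, seed)
    importances = None
    if model_kind == "rf":
        perm = permutation_importance(
            final, X, y, n_repeats=5, random_state=seed, scoring="accuracy"
        )
        importances = pd.Series(
            perm.importances_mean, index=feature_columns
        ).sort_values(ascending=False)

    bundle = ModelBundle(
        model=final,
        feature_columns=feature_columns,
        model_kind=model_kind,
        seed=seed,
        cutoff=cutoff,
        metadata=dict(n_examples=len(y), n_folds=n_folds),
    )
    return bundle, CvReport(fold_accuracies=fold_acc, feature_importances=importances)


def score_and_filter(
    calls: list[VariantCall],
    features: pd.DataFrame,
    bundle: ModelBundle,
    cutoff: float | None = None,
) -> tuple[list[VariantCall], np.ndarray]:
    """Remove calls whose predicted-error probability exceeds the cutoff."""
    cutoff = bundle.cutoff if cutoff is None else cutoff
    probs = bundle.predict_error_probability(features)
    kept = [c for c, p in zip(calls, probs) if p <= cutoff]
    return kept, probs


def replicate_aware_filter(
    replicate_calls: list[list[VariantCall]],
    replicate_features: list[pd.DataFrame],
    bundle: ModelBundle,
    cutoff: float | None = None,
) -> list[list[VariantCall]]:
    """Drop a variant only when predicted an error in ALL replicates."""
    cutoff = bundle.cutoff if cutoff is None else cutoff
    verdicts: dict[tuple[int, str, str], list[bool]] = {}
    for calls, feats in zip(replicate_calls, replicate_features):
        probs = bundle.predict_error_probability(feats)
        for c, p in zip(calls, probs):
            verdicts.setdefault(c.key, []).append(p > cutoff)
    doomed = {k for k, v in verdicts.items() if v and all(v)}
    return [[c for c in calls if c.key not in doomed] for calls in replicate_calls]
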