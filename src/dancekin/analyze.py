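"""Post-hoc analyses: similarity embedding, feature importance, fingerprints.

* :func:`lsa_embed` — latent-semantic-analysis style truncated SVD of the
  z-scored genre x feature matrix, placing each genre in a low-dimensional
  similarity space.
* :func:`feature_importance` — Shapley-value attribution (exact subset
  enumeration for small feature sets, permutation sampling otherwise) or
  permutation importance measured as log-loss increase.
* :func:`genre_fingerprint` — a genre's per-feature means and within-genre
  feature correlation matrix.
* :func:`compare_confusions` — per-class accuracy comparison of two
  classification reports (e.g. model vs. human observers).

Shapley values here are computed directly from the model's prediction
function against a background sample, so they satisfy the local-accuracy
property: per instance, attributions sum to the prediction minus the
background-mean prediction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classify import ClassificationReport, EnsembleModel, multiclass_log_loss
from .errors import ConfigError, DataError, LabelError, SchemaError
from .features import FeatureMatrix

__all__ = [
    "EmbeddingResult",
    "ImportanceReport",
    "GenreFingerprint",
    "ConfusionComparison",
    "genre_feature_table",
    "lsa_embed",
    "shapley_values",
    "feature_importance",
    "genre_fingerprint",
    "compare_confusions",
    "save_feature_violin_plot",
    "save_fingerprint_heatmap",
    "save_embedding_plot",
    "save_confusion_heatmap",
]


# ---------------------------------------------------------------------------
# LSA similarity embedding
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingResult:
    coordinates: dict[str, np.ndarray]  # genre -> (k,) coordinates
    singular_values: np.ndarray         # all singular values, non-increasing
    loadings: np.ndarray                # (k, n_features) orthonormal directions
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {
            "coordinates": {g: c.tolist() for g, c in self.coordinates.items()},
            "singular_values": self.singular_values.tolist(),
            "loadings": self.loadings.tolist(),
            "feature_names": list(self.feature_names),
        }


def genre_feature_table(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-genre mean feature vectors as a genre x feature DataFrame."""
    df = matrix.to_dataframe()
    if df["genre"].isna().any():
        raise LabelError("genre table requires labeled rows")
    return df.drop(columns=["sequence_id", "tier"]).groupby("genre").mean().sort_index()


def lsa_embed(genre_table: pd.DataFrame, k: int = 3) -> EmbeddingResult:
    """Truncated SVD of the column-standardized genre x feature matrix.

    Each feature column is z-scored (population SD; zero-variance columns
    are left centered at 0), then the matrix is factored and each genre's
    coordinates are the first ``k`` left singular vectors scaled by their
    singular values.  Component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    A = genre_table.to_numpy(dtype=float)
    n_genres, n_features = A.shape
    if k >= min(n_genres, n_features):
        raise ConfigError(
            f"k={k} must be smaller than min(n_genres, n_features)={min(n_genres, n_features)}"
        )
    center = A.mean(axis=0)
    scale = A.std(axis=0)
    safe_scale = np.where(scale > 0, scale, 1.0)
    Z = (A - center) / safe_scale
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign convention
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = U[:, :k] * S[:k]
    return EmbeddingResult(
        coordinates={g: coords[i] for i, g in enumerate(genre_table.index)},
        singular_values=S,
        loadings=Vt[:k],
        feature_names=tuple(genre_table.columns),
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Shapley values and feature importance
# ---------------------------------------------------------------------------

EXACT_SHAPLEY_MAX_FEATURES = 12


def _coalition_value(predict_fn, x, background, mask_indices) -> float:
    """E over background rows of f(row with features in the coalition from x)."""
    hybrid = background.copy()
    if mask_indices:
        hybrid[:, mask_indices] = x[list(mask_indices)]
    return float(np.mean(predict_fn(hybrid)))


def shapley_values(
    predict_fn,
    x: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 30,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Shapley attribution of ``predict_fn(x)`` over its input features.

    ``predict_fn`` maps an ``(m, n_features)`` array to ``m`` scalars.
    Missing features are marginalized by substituting background-sample
    values.  With at most 12 features every coalition is enumerated and
    the result is exact; otherwise permutation sampling with
    ``n_permutations`` draws is used.  Returns ``(phi, base_value)`` with
    ``base_value + sum(phi) == E_background f`` + f(x) decomposition, i.e.
    ``sum(phi) = f(x) - base_value`` (exactly for enumeration).
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    n = x.shape[0]
    rng = rng or np.random.default_rng(0)
    base_value = _coalition_value(predict_fn, x, background, ())
    phi = np.zeros(n)

    if n <= EXACT_SHAPLEY_MAX_FEATURES:
        values: dict[frozenset, float] = {}
        for size in range(n + 1):
            for subset in itertools.combinations(range(n), size):
                values[frozenset(subset)] = _coalition_value(predict_fn, x, background, subset)
        fact = math.factorial
        for j in range(n):
            others = [i for i in range(n) if i != j]
            for size in range(n):
                w = fact(size) * fact(n - size - 1) / fact(n)
                for subset in itertools.combinations(others, size):
                    s = frozenset(subset)
                    phi[j] += w * (values[s | {j}] - values[s])
        return phi, base_value

    for _ in range(n_permutations):
        order = rng.permutation(n)
        mask: list[int] = []
        prev = base_value
        for j in order:
            mask.append(int(j))
            cur = _coalition_value(predict_fn, x, background, tuple(mask))
            phi[j] += cur - prev
            prev = cur
    return phi / n_permutations, base_value


@dataclass
class ImportanceReport:
    global_importance: dict[str, float]
    per_class: dict[str, dict[str, float]]
    method: str
    feature_names: tuple[str, ...] = ()

    def ranking(self) -> list[str]:
        return sorted(self.global_importance, key=self.global_importance.get, reverse=True)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "global": self.global_importance,
            "per_class": self.per_class,
        }


def feature_importance(
    model: EnsembleModel,
    X: FeatureMatrix,
    method: str = "permutation",
    seed: int = 0,
    n_repeats: int = 10,
    max_instances: int = 30,
    background_size: int = 100,
    n_permutations: int = 30,
) -> ImportanceReport:
    """Global and per-class feature importance for a fitted model.

    ``permutation``: mean increase in log loss over ``n_repeats`` shuffles
    of each feature column (labels required).  ``shapley``: mean |Shapley
    value| over instances and classes, with per-class signed means.
    Both are deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    names = X.feature_names
    if names != tuple(model.feature_names):
        raise SchemaError("feature matrix does not match the model's registry")

    if method == "permutation":
        labels = X.labels()
        if any(lab is None for lab in labels):
            raise LabelError("permutation importance requires labeled rows")
        Xa = X.X()
        labels_arr = np.asarray(labels)
        proba_base = model.predict_proba(Xa)
        base = multiclass_log_loss(labels, proba_base, model.class_labels)
        base_c = {
            c: multiclass_log_loss(
                labels_arr[labels_arr == c], proba_base[labels_arr == c], model.class_labels
            )
            for c in model.class_labels
            if (labels_arr == c).any()
        }
        global_imp: dict[str, float] = {}
        per_class: dict[str, dict[str, float]] = {c: {} for c in model.class_labels}
        for j, name in enumerate(names):
            increases = []
            class_increases = {c: [] for c in model.class_labels}
            for _ in range(n_repeats):
                Xp = Xa.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                proba = model.predict_proba(Xp)
                increases.append(
                    multiclass_log_loss(labels, proba, model.class_labels) - base
                )
                for c in model.class_labels:
                    m = labels_arr == c
                    if m.any():
                        class_increases[c].append(
                            multiclass_log_loss(labels_arr[m], proba[m], model.class_labels)
                            - base_c[c]
                        )
            global_imp[name] = float(np.mean(increases))
            for c in model.class_labels:
                per_class[c][name] = float(np.mean(class_increases[c])) if class_increases[c] else 0.0
        return ImportanceReport(global_imp, per_class, "permutation", names)

    if method == "shapley":
        Xa = X.X()
        bg_idx = rng.choice(len(Xa), size=min(background_size, len(Xa)), replace=False)
        background = Xa[bg_idx]
        inst_idx = rng.choice(len(Xa), size=min(max_instances, len(Xa)), replace=False)
        abs_sum = np.zeros(len(names))
        per_class_sum = {c: np.zeros(len(names)) for c in model.class_labels}
        for k, c in enumerate(model.class_labels):
            predict_fn = lambda rows, _k=k: model.predict_proba(rows)[:, _k]
            for i in inst_idx:
                phi, _ = shapley_values(
                    predict_fn, Xa[i], background, n_permutations=n_permutations, rng=rng
                )
                abs_sum += np.abs(phi)
                per_class_sum[c] += phi
        n_terms = len(inst_idx) * len(model.class_labels)
        global_imp = dict(zip(names, (abs_sum / n_terms).tolist()))
        per_class = {
            c: dict(zip(names, (per_class_sum[c] / len(inst_idx)).tolist()))
            for c in model.class_labels
        }
        return ImportanceReport(global_imp, per_class, "shapley", names)

    raise ConfigError(f"unknown importance method {method!r}")


# ---------------------------------------------------------------------------
# Genre fingerprints
# ---------------------------------------------------------------------------


@dataclass
class GenreFingerprint:
    """A genre's per-feature means plus its feature-correlation matrix.

    Correlations involving zero-variance features, or computed from fewer
    than 3 rows, are flagged undefined (NaN entries + listed by name).
    """

    genre: str
    mean_vector: dict[str, float]
    correlation: pd.DataFrame
    undefined_features: tuple[str, ...]
    n_rows: int


def genre_fingerprint(matrix: FeatureMatrix, genre: str) -> GenreFingerprint:
    rows = [r for r in matrix.rows if r.genre == genre]
    if not rows:
        raise LabelError(f"no rows for genre {genre!r}")
    names = matrix.feature_names
    data = np.array([r.as_array(names) for r in rows])
    means = dict(zip(names, data.mean(axis=0).tolist()))
    corr = pd.DataFrame(np.nan, index=list(names), columns=list(names))
    if len(rows) >= 3:
        variances = data.std(axis=0)
        defined = variances > 0
        undefined = tuple(n for n, d in zip(names, defined) if not d)
        if defined.sum() >= 1:
            sub = np.corrcoef(data[:, defined], rowvar=False)
            sub = np.atleast_2d(sub)
            di = [i for i, d in enumerate(defined) if d]
            for a, ia in enumerate(di):
                for b, ib in enumerate(di):
                    corr.iloc[ia, ib] = np.clip(sub[a, b], -1.0, 1.0)
    else:
        undefined = tuple(names)
    return GenreFingerprint(
        genre=genre,
        mean_vector=means,
        correlation=corr,
        undefined_features=undefined,
        n_rows=len(rows),
    )


# ---------------------------------------------------------------------------
# Confusion comparison
# ---------------------------------------------------------------------------


@dataclass
class ConfusionComparison:
    class_labels: tuple[str, ...]
    per_class_accuracy_a: dict[str, float]
    per_class_accuracy_b: dict[str, float]
    rank_correlation: float
    disagreements: list[tuple[str, float]]  # (class, |acc_a - acc_b|), descending

    def to_dict(self) -> dict:
        return {
            "class_labels": list(self.class_labels),
            "per_class_accuracy_a": self.per_class_accuracy_a,
            "per_class_accuracy_b": self.per_class_accuracy_b,
            "rank_correlation": self.rank_correlation,
            "disagreements": [list(d) for d in self.disagreements],
        }


def compare_confusions(a: ClassificationReport, b: ClassificationReport) -> ConfusionComparison:
    """Compare two reports' per-class accuracies (diagonal / row support).

    Returns the two accuracy vectors, their Spearman rank correlation, and
    the classes ordered by absolute disagreement (ties broken by class
    order; classes with zero difference are omitted).
    """
    if a.class_labels != b.class_labels:
        raise SchemaError("reports must share a class vocabulary")

    def per_class_acc(rep: ClassificationReport) -> np.ndarray:
        cm = np.asarray(rep.confusion, dtype=float)
        totals = cm.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(totals > 0, np.diag(cm) / totals, np.nan)
        return acc

    acc_a, acc_b = per_class_acc(a), per_class_acc(b)
    valid = ~(np.isnan(acc_a) | np.isnan(acc_b))
    if valid.sum() >= 2:
        rho = float(spearmanr(acc_a[valid], acc_b[valid]).statistic)
        if math.isnan(rho):  # zero-variance vectors (e.g. identical perfect reports)
            rho = 1.0 if np.allclose(acc_a[valid], acc_b[valid]) else 0.0
    else:
        rho = float("nan")
    diffs = np.abs(acc_a - acc_b)
    disagreements = [
        (c, float(d))
        for c, d in sorted(
            zip(a.class_labels, diffs), key=lambda cd: -cd[1] if not math.isnan(cd[1]) else 0
        )
        if not math.isnan(d) and d > 0
    ]
    return ConfusionComparison(
        class_labels=a.class_labels,
        per_class_accuracy_a=dict(zip(a.class_labels, acc_a.tolist())),
        per_class_accuracy_b=dict(zip(b.class_labels, acc_b.tolist())),
        rank_correlation=rho,
        disagreements=disagreements,
    )


# ---------------------------------------------------------------------------
# Optional plot files (matplotlib loaded lazily)
# ---------------------------------------------------------------------------


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def save_feature_violin_plot(matrix: FeatureMatrix, feature: str, path) -> None:
    """Violin plot of one feature's distribution across genres."""
    plt = _pyplot()
    df = matrix.to_dataframe()
    genres = sorted(g for g in df["genre"].dropna().unique())
    data = [df.loc[df["genre"] == g, feature].to_numpy() for g in genres]
    fig, ax = plt.subplots(figsize=(1 + 0.8 * len(genres), 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(genres) + 1), genres, rotation=45, ha="right")
    ax.set_ylabel(feature)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_fingerprint_heatmap(fingerprint: GenreFingerprint, path) -> None:
    """Heatmap of a genre's feature-correlation matrix (undefined = blank)."""
    plt = _pyplot()
    corr = fingerprint.correlation.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(np.ma.masked_invalid(corr), vmin=-1, vmax=1, cmap="coolwarm")
    names = list(fingerprint.correlation.columns)
    ax.set_xticks(range(len(names)), names, rotation=90, fontsize=6)
    ax.set_yticks(range(len(names)), names, fontsize=6)
    ax.set_title(f"{fingerprint.genre} (n={fingerprint.n_rows})")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_embedding_plot(result: EmbeddingResult, path) -> None:
    """3-D scatter of the genre similarity embedding."""
    plt = _pyplot()
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for genre, coords in result.coordinates.items():
        c = np.pad(coords, (0, max(0, 3 - len(coords))))
        ax.scatter(c[0], c[1], c[2])
        ax.text(c[0], c[1], c[2], genre, fontsize=7)
    ax.set_xlabel("component 1")
    ax.set_ylabel("component 2")
    ax.set_zlabel("component 3")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def save_confusion_heatmap(report: ClassificationReport, path) -> None:
    """Row-normalized confusion-matrix heatmap."""
    plt = _pyplot()
    cm = np.asarray(report.confusion, dtype=float)
    totals = cm.sum(axis=1, keepdims=True)
    norm = np.divide(cm, totals, out=np.zeros_like(cm), where=totals > 0)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(norm, vmin=0, vmax=1, cmap="viridis")
    labels = list(report.class_labels)
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
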