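"""Per-data-type binary text classifiers for paper triage.

Each of the eight automatically triaged data types (allele sequence change,
anatomic expression, genetic / physical / regulatory interactions, allele,
RNAi and transgene-overexpression phenotypes) gets an independent binary
classifier over the paper's full text.  The model class is a linear
max-margin classifier (L2-regularized hinge loss) over bag-of-words
features, tf-idf weighted by default.  A paper is flagged positive when the
decision margin is strictly greater than zero; flags pre-populate the
author form's checkboxes, so no probability calibration is needed.

Tokens are lowercased and split on non-alphanumeric characters except
internal hyphens, so nematode gene symbols like ``lin-3`` survive as single
features.  The trained model is fully described by its vocabulary, weight
vector, bias and idf vector and serializes to portable JSON; prediction
needs nothing but that file.
"""

from __future__ import annotations

import json
import math
import random
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Article, ValidationError

__all__ = [
    "DataTypeLabel",
    "LabeledCorpus",
    "ClassifierModel",
    "DataTypeFlags",
    "tokenize",
    "build_vocabulary",
    "featurize",
    "train",
    "classify",
    "classify_all",
    "evaluate_holdout",
]


class DataTypeLabel(str, Enum):
    """The eight automatically classified data types."""

    ALLELE_SEQUENCE_CHANGE = "allele_sequence_change"
    ANATOMIC_EXPRESSION = "anatomic_expression"
    GENETIC_INTERACTIONS = "genetic_interactions"
    PHYSICAL_INTERACTIONS = "physical_interactions"
    REGULATORY_INTERACTIONS = "regulatory_interactions"
    ALLELE_PHENOTYPE = "allele_phenotype"
    RNAI_PHENOTYPE = "rnai_phenotype"
    TRANSGENE_OVEREXPRESSION_PHENOTYPE = "transgene_overexpression_phenotype"


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase tokens; splits on non-alphanumerics except internal hyphens."""
    return _TOKEN_RE.findall(text.lower())


def _article_text(article: Article) -> str:
    return f"{article.title}\n{article.abstract}\n{article.body}"


@dataclass(frozen=True)
class LabeledCorpus:
    """Articles with a complete boolean label map per record."""

    records: tuple[tuple[Article, Mapping[DataTypeLabel, bool]], ...]

    def __post_init__(self) -> None:
        for article, labels in self.records:
            missing = [l for l in DataTypeLabel if l not in labels]
            if missing:
                raise ValidationError(
                    f"record {article.paper_id!r} lacks labels: "
                    f"{[m.value for m in missing]}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def split(self, label: DataTypeLabel) -> tuple[list[Article], np.ndarray]:
        articles = [a for a, _ in self.records]
        y = np.array([bool(labels[label]) for _, labels in self.records])
        return articles, y


@dataclass
class ClassifierModel:
    """A trained linear classifier for one data type.

    ``weights`` is aligned to ``vocabulary`` (token -> feature index);
    ``idf`` is present for the tf-idf scheme and absent for raw counts.
    """

    label: DataTypeLabel
    vocabulary: dict[str, int]
    weights: np.ndarray
    bias: float
    feature_scheme: str = "tfidf"
    idf: np.ndarray | None = None
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.idf is not None:
            self.idf = np.asarray(self.idf, dtype=float)
        if self.weights.shape != (len(self.vocabulary),):
            raise ValidationError(
                f"weights length {self.weights.shape} does not match "
                f"vocabulary size {len(self.vocabulary)}"
            )
        if not np.all(np.isfinite(self.weights)) or not math.isfinite(self.bias):
            raise ValidationError("model parameters must be finite")
        if self.feature_scheme not in ("counts", "tfidf"):
            raise ValidationError(
                f"unknown feature scheme {self.feature_scheme!r}"
            )
        if self.feature_scheme == "tfidf" and self.idf is None:
            raise ValidationError("tfidf scheme requires an idf vector")

    def save(self, path: str | Path) -> None:
        payload = {
            "label": self.label.value,
            "vocabulary": self.vocabulary,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_scheme": self.feature_scheme,
            "idf": None if self.idf is None else self.idf.tolist(),
            "training_meta": self.training_meta,
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, sort_keys=True), "utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text("utf-8"))
        return cls(
            label=DataTypeLabel(payload["label"]),
            vocabulary=payload["vocabulary"],
            weights=np.array(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            feature_scheme=payload["feature_scheme"],
            idf=None
            if payload.get("idf") is None
            else np.array(payload["idf"], dtype=float),
            training_meta=payload.get("training_meta", {}),
        )


@dataclass(frozen=True)
class DataTypeFlags:
    """Per-label (flag, margin) pairs; flag is True iff margin > 0."""

    flags: Mapping[DataTypeLabel, tuple[bool, float]]

    def __post_init__(self) -> None:
        for label, (flag, margin) in self.flags.items():
            if flag != (margin > 0):
                raise ValidationError(
                    f"{label.value}: flag inconsistent with margin {margin}"
                )

    def flag(self, label: DataTypeLabel) -> bool:
        return self.flags[label][0]

    def as_bool_map(self) -> dict[DataTypeLabel, bool]:
        return {label: fm[0] for label, fm in self.flags.items()}


def build_vocabulary(
    articles: Sequence[Article], min_df: int = 2
) -> tuple[dict[str, int], np.ndarray]:
    """Vocabulary (min document frequency filter) and smoothed idf vector.

    idf(t) = ln((1 + n) / (1 + df(t))) + 1, the smoothed convention that
    keeps weights finite for terms present in every document.
    """
    df: dict[str, int] = {}
    for article in articles:
        for token in set(tokenize(_article_text(article))):
            df[token] = df.get(token, 0) + 1
    kept = sorted(t for t, d in df.items() if d >= min_df)
    vocabulary = {t: i for i, t in enumerate(kept)}
    n = len(articles)
    idf = np.array(
        [math.log((1 + n) / (1 + df[t])) + 1.0 for t in kept], dtype=float
    )
    return vocabulary, idf


def featurize(
    article: Article,
    vocabulary: Mapping[str, int],
    feature_scheme: str = "tfidf",
    idf: np.ndarray | None = None,
) -> np.ndarray:
    """Bag-of-words vector over title+abstract+body.

    Out-of-vocabulary tokens are ignored.  Under tf-idf, counts are
    reweighted by the stored idf and L2-normalized (zero vectors stay zero).
    """
    vec = np.zeros(len(vocabulary), dtype=float)
    for token in tokenize(_article_text(article)):
        idx = vocabulary.get(token)
        if idx is not None:
            vec[idx] += 1.0
    if feature_scheme == "tfidf":
        if idf is None:
            raise ValidationError("tfidf featurization requires idf")
        vec *= idf
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
    return vec


def train(
    corpus: LabeledCorpus,
    label: DataTypeLabel,
    hyperparams: Mapping[str, object] | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit an L2-regularized hinge-loss linear classifier for one label.

    Hyperparameters: ``C`` (inverse regularization, default 1.0),
    ``min_df`` (vocabulary document-frequency floor, default 2),
    ``feature_scheme`` ("tfidf" default, or "counts").  Deterministic for a
    fixed corpus and seed.
    """
    from sklearn.svm import LinearSVC

    hp = dict(hyperparams or {})
    C = float(hp.pop("C", 1.0))
    min_df = int(hp.pop("min_df", 2))
    feature_scheme = str(hp.pop("feature_scheme", "tfidf"))
    if hp:
        raise ValidationError(f"unknown hyperparameters: {sorted(hp)}")

    articles, y = corpus.split(label)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"corpus has a single class for label {label.value!r} "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    vocabulary, idf = build_vocabulary(articles, min_df=min_df)
    X = np.stack(
        [
            featurize(
                a,
                vocabulary,
                feature_scheme,
                idf if feature_scheme == "tfidf" else None,
            )
            for a in articles
        ]
    )
    svm = LinearSVC(C=C, random_state=seed, max_iter=20000)
    svm.fit(X, y.astype(int))
    return ClassifierModel(
        label=label,
        vocabulary=vocabulary,
        weights=svm.coef_.ravel().astype(float),
        bias=float(svm.intercept_[0]),
        feature_scheme=feature_scheme,
        idf=idf if feature_scheme == "tfidf" else None,
        training_meta={
            "n_pos": n_pos,
            "n_neg": n_neg,
            "seed": int(seed),
            "hyperparameters": {
                "C": C,
                "min_df": min_df,
                "feature_scheme": feature_scheme,
            },
        },
    )


def classify(article: Article, model: ClassifierModel) -> tuple[bool, float]:
    """(flag, margin) for one article; flag = margin > 0 (ties negative)."""
    vec = featurize(article, model.vocabulary, model.feature_scheme, model.idf)
    margin = float(vec @ model.weights + model.bias)
    return margin > 0, margin


def evaluate_holdout(
    corpus: LabeledCorpus,
    label: DataTypeLabel,
    test_fraction: float = 0.25,
    seed: int = 0,
    hyperparams: Mapping[str, object] | None = None,
) -> float:
    """Held-out accuracy for one label under a stratified random split.

    Records are split per class with a seeded shuffle so both classes are
    represented on each side; the model is trained on the training side
    only (vocabulary included) and scored on the held-out side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must be in (0, 1)")
    rng = random.Random(seed)
    pos = [r for r in corpus.records if r[1][label]]
    neg = [r for r in corpus.records if not r[1][label]]
    rng.shuffle(pos)
    rng.shuffle(neg)
    n_pos_test = max(1, int(round(len(pos) * test_fraction)))
    n_neg_test = max(1, int(round(len(neg) * test_fraction)))
    test = pos[:n_pos_test] + neg[:n_neg_test]
    training = pos[n_pos_test:] + neg[n_neg_test:]
    model = train(LabeledCorpus(tuple(training)), label, hyperparams, seed)
    correct = sum(
        1
        for article, labels in test
        if classify(article, model)[0] == bool(labels[label])
    )
    return correct / len(test)


def classify_all(
    article: Article, models: Mapping[DataTypeLabel, ClassifierModel]
) -> DataTypeFlags:
    """One (flag, margin) per data type; all eight models must be present.

    Papers negative for every label still yield a complete record.
    """
    missing = [l for l in DataTypeLabel if l not in models]
    if missing:
        raise ValidationError(
            f"missing models for labels: {[m.value for m in missing]}"
        )
    return DataTypeFlags(
        {label: classify(article, models[label]) for label in DataTypeLabel}
    )
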