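"""ATC-class assay classification on embedding features.

Assays are labeled through the approved drugs (development phase 4) tested in
them: the level-2 prefixes (first three characters) of the drugs' WHO ATC
codes map to problem classes, and an assay is kept only when that mapping is
unambiguous — exactly one class. Four standard problems are provided:

* ``cidal_binary`` — cidal/cytotoxic drug classes (antineoplastics L01,
  antibacterials J01/J02/J04, antivirals J05, antiprotozoals/anthelmintics
  P01/P02/P03) vs everything else;
* ``nervous_binary`` — any nervous-system drug (ATC anatomical group N);
* ``top5_multiclass`` — antiepileptics N03, psycholeptics N05, antineoplastics
  L01, antidiabetics A10, and anti-inflammatory drugs (the C01/M01/M02/S01
  combination carried by indomethacin, the standard reference drug of
  inflammation models);
* ``nervous_subclass`` — N01…N06 therapeutic subgroups.

Cross-validation supports two 10-fold splits: random over assays, and random
over source documents (all assays curated from one publication share a fold,
which prevents near-duplicate leakage and is the stricter, more honest
estimate). The classifier is a 200-tree random forest with balanced class
weights; the out-of-bag estimate comes from a fit on the full labeled set.

Per-class phrase enrichment uses a one-sided Fisher exact test on the 2x2
presence/absence table, computed through the hypergeometric tail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

logger = logging.getLogger(__name__)

__all__ = [
    "ClassProblem",
    "PROBLEMS",
    "assign_class_labels",
    "FoldAssignment",
    "make_folds",
    "ClassificationReport",
    "cross_validate_rf",
    "fisher_greater_p",
    "enriched_phrases",
]


@dataclass(frozen=True)
class ClassProblem:
    """A labeling problem: class name -> set of ATC level-2 prefixes.

    One class may be the catch-all "*" collecting every prefix not claimed by
    another class (used by the binary problems). Explicit code sets must be
    pairwise disjoint.
    """

    name: str
    classes: Mapping[str, frozenset[str]]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for cls, prefixes in self.classes.items():
            for p in prefixes:
                if p == "*":
                    continue
                if p in seen:
                    raise ValueError(
                        f"{self.name}: prefix {p} in both {seen[p]} and {cls}"
                    )
                seen[p] = cls

    def map_prefix(self, prefix: str) -> str | None:
        catch_all = None
        for cls, prefixes in self.classes.items():
            if "*" in prefixes:
                catch_all = cls
            if prefix in prefixes:
                return cls
        return catch_all

    @property
    def class_names(self) -> list[str]:
        return sorted(self.classes)


def _p(*codes: str) -> frozenset[str]:
    return frozenset(codes)


#: the four built-in classification problems
PROBLEMS: dict[str, ClassProblem] = {
    "cidal_binary": ClassProblem(
        "cidal_binary",
        {
            "cidal": _p("L01", "J01", "J02", "J04", "J05", "P01", "P02", "P03"),
            "non_cidal": _p("*"),
        },
    ),
    "nervous_binary": ClassProblem(
        "nervous_binary",
        {
            "nervous": _p("N01", "N02", "N03", "N04", "N05", "N06", "N07"),
            "non_nervous": _p("*"),
        },
    ),
    "top5_multiclass": ClassProblem(
        "top5_multiclass",
        {
            "antiepileptics": _p("N03"),
            "psycholeptics": _p("N05"),
            "antineoplastics": _p("L01"),
            "antidiabetics": _p("A10"),
            "anti_inflammatory": _p("C01", "M01", "M02", "S01"),
        },
    ),
    "nervous_subclass": ClassProblem(
        "nervous_subclass",
        {
            "antiepileptics": _p("N03"),
            "psycholeptics": _p("N05"),
            "analgesics": _p("N02"),
            "psychoanaleptics": _p("N06"),
            "antiparkinsonians": _p("N04"),
            "anaesthetics": _p("N01"),
        },
    ),
}


def assign_class_labels(
    assays,
    compounds,
    links: Sequence[tuple[str, str]] | None,
    problem: ClassProblem,
    approved_phase: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label assays via approved-drug ATC level-2 prefixes.

    Catch-all classes never claim an assay that also maps to an explicit
    class. Returns (labeled, excluded) frames; ``excluded`` carries reason
    codes (no_approved_drug / no_class_code / ambiguous).
    """
    by_id = {c.compound_id: c for c in compounds}
    assay_compounds: dict[str, set[str]] = {a.assay_id: set(a.compound_ids) for a in assays}
    for aid, cid in links or ():
        if aid in assay_compounds:
            assay_compounds[aid].add(cid)

    labeled_rows, excluded_rows = [], []
    explicit_prefixes = {
        p for prefixes in problem.classes.values() for p in prefixes if p != "*"
    }
    for a in assays:
        drugs = [
            by_id[cid] for cid in sorted(assay_compounds[a.assay_id])
            if cid in by_id and by_id[cid].max_phase >= approved_phase
        ]
        drugs = [d for d in drugs if d.atc_codes]
        if not drugs:
            excluded_rows.append((a.assay_id, "no_approved_drug"))
            continue
        prefixes = {code[:3] for d in drugs for code in d.atc_codes}
        explicit = {problem.map_prefix(p) for p in prefixes if p in explicit_prefixes}
        mapped = explicit or {problem.map_prefix(p) for p in prefixes}
        mapped.discard(None)
        if not mapped:
            excluded_rows.append((a.assay_id, "no_class_code"))
        elif len(mapped) > 1:
            excluded_rows.append((a.assay_id, "ambiguous"))
        else:
            labeled_rows.append((a.assay_id, mapped.pop(), a.document_id))
    labeled = pd.DataFrame(labeled_rows, columns=["assay_id", "label", "document_id"])
    excluded = pd.DataFrame(excluded_rows, columns=["assay_id", "reason"])
    return labeled, excluded


@dataclass
class FoldAssignment:
    fold: np.ndarray           # fold index per row of the labeled frame
    split_method: str          # "assay" | "document"
    k: int
    seed: int


def make_folds(
    labeled: pd.DataFrame, method: str = "assay", k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Assign each labeled assay to one of k folds.

    ``assay``: random equal split. ``document``: documents are shuffled and
    partitioned, so same-document assays always share a fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(labeled)
    fold = np.empty(n, dtype=int)
    if method == "assay":
        order = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(order, k)):
            fold[chunk] = f
    elif method == "document":
        docs = np.array(sorted(labeled["document_id"].unique()))
        if len(docs) < k:
            raise ValueError(f"{len(docs)} documents < {k} folds")
        rng.shuffle(docs)
        doc_fold = {d: f for f, chunk in enumerate(np.array_split(docs, k)) for d in chunk}
        fold[:] = [doc_fold[d] for d in labeled["document_id"]]
    else:
        raise ValueError(f"unknown split method {method!r}")
    return FoldAssignment(fold, method, k, seed)


@dataclass
class ClassificationReport:
    problem: str
    split_method: str
    seed: int
    classes: list[str]
    accuracy: float                      # pooled over held-out predictions
    accuracy_mean_over_folds: float
    per_class: pd.DataFrame              # precision/recall/f1/support
    confusion: np.ndarray                # rows = true class, cols = predicted
    oob_score: float | None
    skipped_folds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "problem": self.problem,
            "split_method": self.split_method,
            "seed": self.seed,
            "classes": self.classes,
            "accuracy": self.accuracy,
            "accuracy_mean_over_folds": self.accuracy_mean_over_folds,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.tolist(),
            "oob_score": self.oob_score,
            "skipped_folds": self.skipped_folds,
        }

    def render(self) -> str:
        lines = [
            f"problem={self.problem} split={self.split_method} seed={self.seed}",
            f"accuracy (pooled) = {self.accuracy:.4f}",
            f"accuracy (mean over folds) = {self.accuracy_mean_over_folds:.4f}",
            f"out-of-bag estimate = {self.oob_score:.4f}" if self.oob_score is not None else "",
            self.per_class.round(4).to_string(),
            "confusion matrix (rows true, cols predicted):",
            pd.DataFrame(self.confusion, index=self.classes, columns=self.classes).to_string(),
        ]
        return "\n".join(l for l in lines if l)


def cross_validate_rf(
    X: np.ndarray,
    y: Sequence[str],
    folds: FoldAssignment,
    n_trees: int = 200,
    class_weight: str | None = "balanced",
    seed: int = 0,
    problem_name: str = "",
    compute_oob: bool = True,
) -> ClassificationReport:
    """10-fold cross-validated random forest on assay vectors.

    Fits on k−1 folds, predicts the held-out fold; pooled held-out predictions
    produce the report. A fold whose training part lacks some class is skipped
    with a warning and recorded. The OOB estimate comes from a single fit on
    the full labeled set.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=object)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a classifier")

    y_pred = np.empty(len(y), dtype=object)
    predicted_mask = np.zeros(len(y), dtype=bool)
    fold_accs = []
    skipped = []
    for f in range(folds.k):
        test = folds.fold == f
        train = ~test
        if not test.any():
            continue
        if set(y[train]) != set(classes):
            logger.warning("fold %d lacks some class in training data; skipped", f)
            skipped.append(f)
            continue
        clf = RandomForestClassifier(
            n_estimators=n_trees, class_weight=class_weight, random_state=seed, n_jobs=1
        )
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        y_pred[test] = pred
        predicted_mask |= test
        fold_accs.append(float((pred == y[test]).mean()))

    yt, yp = y[predicted_mask], y_pred[predicted_mask]
    cm = confusion_matrix(yt, yp, labels=classes)
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    prec, rec, f1, support = precision_recall_fscore_support(
        yt, yp, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=classes,
    )

    oob = None
    if compute_oob:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = RandomForestClassifier(
                n_estimators=n_trees, class_weight=class_weight,
                random_state=seed, oob_score=True, n_jobs=1,
            ).fit(X, y)
        oob = float(full.oob_score_)

    return ClassificationReport(
        problem=problem_name,
        split_method=folds.split_method,
        seed=seed,
        classes=classes,
        accuracy=acc,
        accuracy_mean_over_folds=float(np.mean(fold_accs)) if fold_accs else 0.0,
        per_class=per_class,
        confusion=cm,
        oob_score=oob,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# Fisher phrase enrichment
# ---------------------------------------------------------------------------


def fisher_greater_p(a, b, c, d):
    """One-sided Fisher exact p for over-representation on [[a, b], [c, d]].

    a = in-class assays containing the phrase, b = in-class without it,
    c = out-of-class with it, d = out-of-class without it. Computed through
    the hypergeometric survival function; vectorized over array inputs.
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    N = a + b + c + d
    p = hypergeom.sf(a - 1, np.maximum(N, 1), a + c, a + b)
    # empty table: observing nothing is never evidence of enrichment
    return np.where(N == 0, 1.0, p)


def enriched_phrases(
    labels: Mapping[str, str],
    phrase_assays: Mapping[str, set[str]],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Per-class phrase enrichment by one-sided Fisher exact test.

    ``labels`` maps assay_id -> class; ``phrase_assays`` maps phrase -> set of
    assay_ids containing it. Rows are ranked per class by ascending p-value,
    ties broken by descending in-class frequency then lexicographically.
    """
    assay_ids = list(labels)
    n_total = len(assay_ids)
    class_sets: dict[str, set[str]] = {}
    for aid, cls in labels.items():
        class_sets.setdefault(cls, set()).add(aid)

    rows = []
    universe = set(assay_ids)
    for cls, members in sorted(class_sets.items()):
        n_in = len(members)
        for phrase, assays_with in sorted(phrase_assays.items()):
            hits = assays_with & universe
            a = len(hits & members)
            if a == 0:
                continue
            c = len(hits) - a
            b = n_in - a
            d = n_total - n_in - c
            p = float(fisher_greater_p(a, b, c, d))
            rows.append((cls, phrase, a, c, p))
    df = pd.DataFrame(rows, columns=["class", "phrase", "n_in_class", "n_out_class", "p_value"])
    df = df.sort_values(
        ["class", "p_value", "n_in_class", "phrase"],
        ascending=[True, True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.groupby("class", group_keys=False).head(top_k).reset_index(drop=True)
    return df
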