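"""Balanced cross-validation evaluation of bipartite link-prediction methods.

The protocol mirrors standard practice for DPI benchmarks:

1. Every known interaction is a positive sample.  An equal number of
   negatives is drawn uniformly, without replacement, from the non-edges
   (balanced sampling avoids the extreme class imbalance of the grid,
   where positives are well below 1%).
2. Positives are shuffled and split into *k* folds (default 10); the
   negatives are split in parallel, so each fold's test set is balanced.
3. For each fold, the fold's positives are removed from the graph, scores
   are computed on that training graph only (degrees and neighbourhoods
   never see held-out edges), and the top *m* scored test pairs are
   labelled positive, with ``m`` = the fold's positive count.
4. Precision, sensitivity (recall), F1, accuracy are computed from those
   labels; AUC and AUPR from the continuous scores.  The whole procedure is
   repeated for several runs with derived seeds and reported as mean ± std
   over all folds of all runs.

Note an algebraic consequence of the balanced top-m rule: with as many
predicted positives as there are true positives on a balanced test set,
FP = FN and TN = TP, so accuracy, sensitivity and (because precision then
equals TP/m = sensitivity) precision and F1 all coincide fold by fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _curve_auc
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .network import BipartiteGraph, Edge
from .scoring import METHODS, score_method, sort_scores

__all__ = [
    "NegativeSample",
    "CVPlan",
    "FoldPlan",
    "EvalReport",
    "sample_negatives",
    "make_cv_plan",
    "classify_top_ranked",
    "compute_metrics",
    "evaluate_method",
    "sweep_combination",
    "recovery_auc",
]

METRIC_NAMES = ("precision", "sensitivity", "f1", "accuracy", "auc", "aupr")

_SEED_MOD = 2**31 - 1


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt * 7919 + 17) % _SEED_MOD)


# --------------------------------------------------------------------------
# Negative sampling
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NegativeSample:
    """A uniform sample of non-edges with its coverage diagnostic.

    ``drug_coverage`` / ``protein_coverage`` report which fraction of each
    node side appears in at least one sampled pair — a sanity check that a
    balanced negative set still spans the node populations.
    """

    pairs: tuple[Edge, ...]
    drug_coverage: float
    protein_coverage: float


def sample_negatives(g: BipartiteGraph, n: int, seed: int) -> NegativeSample:
    """Draw ``n`` distinct non-edges uniformly at random.

    Reproducible for a given seed.  Raises if ``n`` exceeds the number of
    candidate (non-edge) pairs.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    total = g.n_candidate_pairs
    if n > total:
        raise ValueError(f"cannot sample {n} negatives from {total} candidate pairs")
    rng = np.random.default_rng(seed)
    np_ = g.n_proteins
    edge_lin = {di * np_ + pj for di, pj in g.edge_indices}
    grid = g.n_possible_pairs
    chosen: list[int] = []
    if n == total:
        chosen = [k for k in range(grid) if k not in edge_lin]
    else:
        taken: set[int] = set()
        # rejection sampling; the grid is sparse so acceptance is near 1
        while len(chosen) < n:
            batch = rng.integers(0, grid, size=max(64, 2 * (n - len(chosen))))
            for k in batch:
                k = int(k)
                if k in edge_lin or k in taken:
                    continue
                taken.add(k)
                chosen.append(k)
                if len(chosen) == n:
                    break
    pairs = tuple((g.drugs[k // np_], g.proteins[k % np_]) for k in chosen)
    dcov = len({d for d, _ in pairs}) / g.n_drugs if g.n_drugs else 0.0
    pcov = len({p for _, p in pairs}) / g.n_proteins if g.n_proteins else 0.0
    return NegativeSample(pairs, dcov, pcov)


# --------------------------------------------------------------------------
# Cross-validation plan
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    test_positives: tuple[Edge, ...]
    test_negatives: tuple[Edge, ...]


@dataclass(frozen=True)
class CVPlan:
    """A k-fold split of the positive edges with a parallel negative split."""

    seed: int
    folds: tuple[FoldPlan, ...]
    negatives: NegativeSample

    @property
    def k(self) -> int:
        return len(self.folds)


def make_cv_plan(
    g: BipartiteGraph,
    k: int = 10,
    seed: int = 0,
    negatives: NegativeSample | None = None,
) -> CVPlan:
    """Shuffle positives into ``k`` near-equal folds with balanced negatives.

    Negatives are sampled once (|negatives| = |positives|) and partitioned
    in parallel, so per-fold positive and negative counts match to within
    one.  Pass ``negatives`` to reuse an existing sample across plans.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    positives = g.edges()
    if len(positives) < k:
        raise ValueError(f"need at least k={k} positive edges, have {len(positives)}")
    rng = np.random.default_rng(_derive_seed(seed, 1))
    pos = [positives[i] for i in rng.permutation(len(positives))]
    if negatives is None:
        negatives = sample_negatives(g, len(positives), _derive_seed(seed, 2))
    neg = list(negatives.pairs)
    pos_blocks = [pos[i::k] for i in range(k)]
    neg_blocks = [neg[i::k] for i in range(k)]
    folds = tuple(
        FoldPlan(tuple(pb), tuple(nb)) for pb, nb in zip(pos_blocks, neg_blocks)
    )
    return CVPlan(seed=seed, folds=folds, negatives=negatives)


# --------------------------------------------------------------------------
# Classification and metrics
# --------------------------------------------------------------------------

def classify_top_ranked(scores: pd.DataFrame, m: int) -> pd.DataFrame:
    """Label the ``m`` highest-scored pairs positive, the rest negative.

    Ties are broken deterministically (score descending, then lexicographic
    drug/protein identifiers).  Returns the table with a boolean
    ``predicted`` column, in ranking order.
    """
    if m > len(scores):
        raise ValueError(f"m={m} exceeds the number of scored pairs ({len(scores)})")
    out = sort_scores(scores).copy()
    out["predicted"] = np.arange(len(out)) < m
    return out


def compute_metrics(
    labels: Sequence[bool],
    truth: Sequence[bool],
    scores: Sequence[float],
    curves: bool = False,
) -> dict:
    """Six-way evaluation of one test set.

    ``labels`` are the binary predictions (from :func:`classify_top_ranked`),
    ``truth`` the actual class of each pair, ``scores`` the continuous
    ranking scores.  Threshold metrics come from the labels; AUC and AUPR
    from the scores.  Empty denominators (or a single-class truth vector for
    the curve metrics) yield 0 with a warning.
    """
    labels = np.asarray(labels, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if not (len(labels) == len(truth) == len(scores)):
        raise ValueError("labels, truth and scores must have equal length")

    tp = int(np.sum(labels & truth))
    fp = int(np.sum(labels & ~truth))
    fn = int(np.sum(~labels & truth))
    tn = int(np.sum(~labels & ~truth))

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name}: empty denominator, reporting 0", stacklevel=2)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if (precision + sensitivity) > 0
        else 0.0
    )
    accuracy = _ratio(tp + tn, tp + fp + fn + tn, "accuracy")

    if truth.all() or not truth.any():
        warnings.warn("single-class truth vector; AUC/AUPR reported as 0", stacklevel=2)
        aucv = auprv = 0.0
        roc_pts = pr_pts = None
    else:
        aucv = float(roc_auc_score(truth, scores))
        prec_c, rec_c, _ = precision_recall_curve(truth, scores)
        auprv = float(_curve_auc(rec_c, prec_c))
        roc_pts = pr_pts = None
        if curves:
            fpr, tpr, _ = roc_curve(truth, scores)
            roc_pts = np.column_stack([fpr, tpr])
            pr_pts = np.column_stack([rec_c, prec_c])

    out = {
        "precision": precision,
        "sensitivity": sensitivity,
        "f1": f1,
        "accuracy": accuracy,
        "auc": aucv,
        "aupr": auprv,
    }
    if curves:
        out["roc_points"] = roc_pts
        out["pr_points"] = pr_pts
    return out


# --------------------------------------------------------------------------
# Full evaluation
# --------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-fold metrics plus mean/std aggregates and pooled curve points."""

    method: str
    per_fold: pd.DataFrame  # columns: run, fold, <metrics>
    roc_points: np.ndarray | None = None
    pr_points: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].std(ddof=1)

    def summary_frame(self) -> pd.DataFrame:
        """One-row table of mean and std per metric (Table-style output)."""
        row: dict[str, float] = {"method": self.method}
        for name in METRIC_NAMES:
            row[f"{name}_mean"] = float(self.mean[name])
            row[f"{name}_std"] = float(self.std[name])
        return pd.DataFrame([row])


def _score_fold(
    g_train: BipartiteGraph,
    method: str,
    fold: FoldPlan,
    t: float,
    h: float,
) -> tuple[dict, np.ndarray, np.ndarray]:
    """Metrics for one fold plus (truth, score) arrays for curve pooling."""
    pairs = list(fold.test_positives) + list(fold.test_negatives)
    truth = np.array(
        [True] * len(fold.test_positives) + [False] * len(fold.test_negatives)
    )
    table = score_method(g_train, method, pairs, t=t, h=h)
    truth_map = {pair: tv for pair, tv in zip(pairs, truth)}
    ranked = classify_top_ranked(table, m=len(fold.test_positives))
    ranked["truth"] = [
        truth_map[(d, p)] for d, p in zip(ranked["drug"], ranked["protein"])
    ]
    metrics = compute_metrics(ranked["predicted"], ranked["truth"], ranked["score"])
    return metrics, ranked["truth"].to_numpy(), ranked["score"].to_numpy()


def evaluate_method(
    g: BipartiteGraph,
    method: str,
    k: int = 10,
    seed: int = 0,
    runs: int = 10,
    t: float = 15.0,
    h: float = 30.0,
    resample_negatives: bool = True,
) -> EvalReport:
    """Balanced k-fold cross-validation of one scoring method.

    For each of ``runs`` repetitions a fresh CV plan is drawn from a seed
    derived from ``seed``; with ``resample_negatives=False`` the first
    run's negative sample is reused and only the fold shuffle changes.
    Each fold's positives are removed from the graph before scoring, so all
    degrees are training-graph degrees.  Curve points are pooled over the
    folds of the first run.
    """
    if method.lower() not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    rows = []
    pooled_truth: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    shared_negatives: NegativeSample | None = None
    for run in range(runs):
        run_seed = _derive_seed(seed, 100 + run)
        plan = make_cv_plan(g, k=k, seed=run_seed, negatives=shared_negatives)
        if not resample_negatives and shared_negatives is None:
            shared_negatives = plan.negatives
        for fi, fold in enumerate(plan.folds):
            g_train = g.remove_edges(fold.test_positives)
            res, truth_arr, score_arr = _score_fold(g_train, method, fold, t, h)
            rows.append({"run": run, "fold": fi, **{m: res[m] for m in METRIC_NAMES}})
            if run == 0:
                pooled_truth.append(truth_arr)
                pooled_scores.append(score_arr)
    per_fold = pd.DataFrame(rows)
    truth_all = np.concatenate(pooled_truth)
    scores_all = np.concatenate(pooled_scores)
    roc_pts = pr_pts = None
    if truth_all.any() and not truth_all.all():
        fpr, tpr, _ = roc_curve(truth_all, scores_all)
        roc_pts = np.column_stack([fpr, tpr])
        prec_c, rec_c, _ = precision_recall_curve(truth_all, scores_all)
        pr_pts = np.column_stack([rec_c, prec_c])
    return EvalReport(
        method=method,
        per_fold=per_fold,
        roc_points=roc_pts,
        pr_points=pr_pts,
        params={"k": k, "seed": seed, "runs": runs, "t": t, "h": h},
    )


def sweep_combination(
    g: BipartiteGraph,
    partner: str,
    grid: Iterable[float],
    k: int = 10,
    seed: int = 0,
    runs: int = 3,
) -> pd.DataFrame:
    """Evaluate ``CN + coeff * partner`` over a coefficient grid.

    ``partner`` is ``"dls"`` (coefficient t) or ``"ja"`` (coefficient h).
    Returns one row per coefficient with mean accuracy and F1; the frame's
    ``attrs`` record the accuracy- and F1-optimal coefficients.
    """
    partner = partner.lower()
    if partner not in ("dls", "ja"):
        raise ValueError("partner must be 'dls' or 'ja'")
    grid = list(grid)
    if not grid:
        raise ValueError("coefficient grid is empty")
    method = f"cn+{partner}"
    rows = []
    for coeff in grid:
        rep = evaluate_method(
            g,
            method,
            k=k,
            seed=seed,
            runs=runs,
            t=coeff if partner == "dls" else 15.0,
            h=coeff if partner == "ja" else 30.0,
        )
        rows.append(
            {
                "coeff": float(coeff),
                "accuracy": float(rep.mean["accuracy"]),
                "f1": float(rep.mean["f1"]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["best_accuracy_coeff"] = float(out.loc[out["accuracy"].idxmax(), "coeff"])
    out.attrs["best_f1_coeff"] = float(out.loc[out["f1"].idxmax(), "coeff"])
    return out


def recovery_auc(
    g_train: BipartiteGraph,
    heldout: Sequence[Edge],
    method: str,
    seed: int = 0,
    t: float = 15.0,
    h: float = 30.0,
) -> float:
    """AUC for recovering held-out edges against an equal negative sample.

    Negatives are drawn from pairs that are edges in neither the training
    graph nor the held-out set.  Used with :func:`dlslink.synthetic.planted_graph`
    to check that a scorer finds planted local structure.
    """
    g_full = g_train.add_edges(heldout)
    negs = sample_negatives(g_full, len(heldout), _derive_seed(seed, 3)).pairs
    pairs = list(heldout) + list(negs)
    truth = np.array([True] * len(heldout) + [False] * len(negs))
    table = score_method(g_train, method, pairs, t=t, h=h)
    smap = {(d, p): s for d, p, s in zip(table["drug"], table["protein"], table["score"])}
    scores = np.array([smap[pr] for pr in pairs])
    return float(roc_auc_score(truth, scores))
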