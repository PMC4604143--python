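"""Stepwise forward feature selection and the hyperparameter sweeps.

Training optimizes Mean(Se,PPV) = (Se + PPV)/2 on the training table: false
positives in the SVB class and false negatives in the VB class are weighted
equally, which is what matters under the heavy SVB/VB imbalance.  At each
step every not-yet-selected feature of the 210-element expansion is
temporarily added, the classifier refit, and the feature with the best
criterion kept (ties -> higher Se, then lower feature index); selection
stops when no candidate raises the criterion or Se.  The companion sweeps
cover the cluster count (2..10, bounded by sqrt(210/2)), the LDA/tree class
priors, and the tree pruning levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from beatclass.classifiers import (
    ConditioningError,
    KMeansBeatClassifier,
    TreeModel,
    _encode_labels,
    _se_ppv,
    tree_prune,
)
from beatclass.pipeline import ConfusionCounts

MAX_STEPS_DEFAULT = 150
#: "not deteriorated Mean(Se,PPV)" tolerance in the prior sweep, % points
PRIOR_CRITERION_TOL = 0.5
#: rule-of-thumb cluster-count ceiling: floor(sqrt(n_features / 2))
CLUSTER_COUNT_BOUND = int(np.sqrt(210 / 2))  # = 10


def criterion(counts: ConfusionCounts) -> float:
    """Mean(Se,PPV) in percent; undefined Se or PPV is an error."""
    if counts.tp + counts.fn == 0:
        raise ValueError("Se undefined: no positive (VB) beats")
    if counts.tp + counts.fp == 0:
        raise ValueError("PPV undefined: no beats assigned to VB")
    se = 100.0 * counts.tp / (counts.tp + counts.fn)
    ppv = 100.0 * counts.tp / (counts.tp + counts.fp)
    return (se + ppv) / 2.0


@dataclass
class StepwiseTrace:
    """Per-step record of the forward selection."""

    steps: list[dict] = field(default_factory=list)
    selected: list[int] = field(default_factory=list)
    excluded: list[int] = field(default_factory=list)
    stop_step: int = 0

    @property
    def best(self) -> dict | None:
        return self.steps[self.stop_step - 1] if self.stop_step else None

    def to_json(self) -> str:
        return json.dumps({
            "version": 1, "steps": self.steps, "selected": self.selected,
            "excluded": self.excluded, "stop_step": self.stop_step,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _fit_score(estimator, X, y01):
    """Fit a clone on (X, y) and return (model, se, ppv, crit)."""
    model = clone(estimator)
    model.fit(X, np.where(y01 == 1, "VB", "SVB"))
    pred = _encode_labels(model.predict(X))
    se, ppv = _se_ppv(y01, pred)
    crit = (se + ppv) / 2.0 if se is not None and ppv is not None else None
    return model, se, ppv, crit


def stepwise_select(
    estimator,
    X,
    y,
    max_steps: int = MAX_STEPS_DEFAULT,
    verbose: bool = False,
) -> tuple[object, StepwiseTrace]:
    """Forward feature selection wrapped around any SVB/VB estimator.

    ``estimator`` is an unfitted prototype (cloned per candidate fit).
    Features that raise a ``ConditioningError`` (collinear with the current
    LDA model) are excluded from this and all later steps. Returns the
    model refit on the selected columns — with ``feature_idx_`` attached —
    and the trace.
    """
    X = np.asarray(X, dtype=float)
    y01 = _encode_labels(y)
    if len(np.unique(y01)) < 2:
        raise ValueError("training labels must contain both classes")
    trace = StepwiseTrace()
    best_crit, best_se = -np.inf, -np.inf
    current_model = None
    for step in range(1, max_steps + 1):
        cand_best = None  # (crit, se, -feature, ppv)
        for f in range(X.shape[1]):
            if f in trace.selected or f in trace.excluded:
                continue
            cols = trace.selected + [f]
            try:
                model, se, ppv, crit = _fit_score(estimator, X[:, cols], y01)
            except ConditioningError:
                trace.excluded.append(f)   # collinear: out for good
                continue
            except ValueError:
                continue  # unusable at this step (e.g. k > distinct rows)
            if se is None or ppv is None or crit is None:
                continue
            key = (crit, se, -f)
            if cand_best is None or key > cand_best[0]:
                cand_best = (key, f, se, ppv, crit, model)
        if cand_best is None:
            break
        _, f, se, ppv, crit, model = cand_best
        if crit <= best_crit and se <= best_se:
            break  # no candidate raises criterion nor Se
        trace.selected.append(f)
        trace.steps.append({
            "step": step, "feature": f, "se": se, "ppv": ppv, "criterion": crit,
        })
        trace.stop_step = step
        best_crit = max(best_crit, crit)
        best_se = max(best_se, se)
        current_model = model
        if verbose:
            print(f"step {step}: +F[{f}] crit={crit:.2f} se={se:.2f} ppv={ppv:.2f}")
    if current_model is None:
        raise ValueError("no admissible feature found")
    current_model.feature_idx_ = list(trace.selected)
    return current_model, trace


def sweep_clusters(
    X, y, k_range=range(2, CLUSTER_COUNT_BOUND + 1),
    replicates: int = 10, seed: int | None = 0,
    max_steps: int = MAX_STEPS_DEFAULT,
) -> tuple[int, object, StepwiseTrace]:
    """Stepwise selection per cluster count; best (criterion, Se) wins."""
    best = None
    for k in k_range:
        proto = KMeansBeatClassifier(k=k, replicates=replicates, random_state=seed)
        try:
            model, trace = stepwise_select(proto, X, y, max_steps=max_steps)
        except ValueError:
            continue
        row = trace.best
        key = (row["criterion"], row["se"])
        if best is None or key > best[0]:
            best = (key, k, model, trace)
    if best is None:
        raise ValueError("no cluster count produced a valid model")
    _, k, model, trace = best
    return k, model, trace


def sweep_priors(
    estimator_factory,
    X,
    y,
    prior_grid,
    max_steps: int = MAX_STEPS_DEFAULT,
    stepwise: bool = True,
) -> tuple[tuple[float, float], object, list[dict]]:
    """Evaluate each (SVB, VB) prior pair and apply the selection rule.

    ``estimator_factory(priors)`` returns an unfitted estimator. With
    ``stepwise=False`` (classification tree: the tree self-selects its
    features) the estimator is fit on the full table. The returned pair is
    the first in grid order with Se > PPV whose criterion is within 0.5
    percentage points of the grid maximum; if no pair has Se > PPV, the
    criterion-maximizing pair.
    """
    y01 = _encode_labels(y)
    records = []
    for priors in prior_grid:
        proto = estimator_factory(tuple(priors))
        if stepwise:
            model, trace = stepwise_select(proto, X, y, max_steps=max_steps)
            row = trace.best
            se, ppv, crit = row["se"], row["ppv"], row["criterion"]
        else:
            model, se, ppv, crit = _fit_score(proto, np.asarray(X, dtype=float), y01)
            trace = None
        records.append({
            "priors": tuple(priors), "se": se, "ppv": ppv, "criterion": crit,
            "model": model, "trace": trace,
        })
    max_crit = max(r["criterion"] for r in records)
    chosen = None
    for r in records:
        if r["se"] > r["ppv"] and r["criterion"] >= max_crit - PRIOR_CRITERION_TOL:
            chosen = r
            break
    if chosen is None:
        chosen = max(records, key=lambda r: r["criterion"])
    table = [{k: r[k] for k in ("priors", "se", "ppv", "criterion")} for r in records]
    return chosen["priors"], chosen["model"], table


def prune_scan(tree: TreeModel, X_eval, y_eval) -> pd.DataFrame:
    """Metrics and complexity of the tree at every pruning level.

    Evaluates the pruned tree at each decision-node count from the full
    size down to 1: Se, PPV, Mean(Se,PPV), resubstitution error cost,
    number of distinct features, and total node count.
    """
    X_eval = np.asarray(X_eval, dtype=float)
    y01 = _encode_labels(y_eval)
    rows = []
    pruned = tree
    full = tree.n_decision_nodes
    for target in range(full, 0, -1):
        pruned = tree_prune(pruned, target)
        live = pruned._live_nodes()
        internal = [i for i in live if not pruned.nodes[i].is_leaf]
        if rows and rows[-1]["decision_nodes"] == len(internal):
            continue  # this level was skipped by a multi-node collapse
        pred = pruned.predict01(X_eval)
        se, ppv = _se_ppv(y01, pred)
        crit = (se + ppv) / 2.0 if se is not None and ppv is not None else None
        rows.append({
            "decision_nodes": len(internal),
            "total_nodes": len(live),
            "n_features": len({pruned.nodes[i].feature for i in internal}),
            "se": se, "ppv": ppv, "criterion": crit,
            "error_cost": float(np.mean(pred != y01)),
        })
    return pd.DataFrame(rows)
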