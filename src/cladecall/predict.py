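"""Driver-mutation prediction by clade co-membership.

Clades are labelled by majority vote over their genotyped members; an
unlabelled clone inherits its clade's label with a support fraction
(labelled members agreeing / labelled members).  Ties and empty clades
abstain, and predictions from abstaining clades are UNDETERMINED rather
than guesses.

:func:`predict_refined` formalizes reading sub-clades off the dendrogram:
when a clade's genotyped members disagree, the vote for an unlabelled clone
is taken over the smallest enclosing dendrogram subtree that contains
genotyped clones and yields an untied majority — i.e. the clone is
labelled by its nearest genotyped neighbours in tree topology.  This is
the second-level-cut refinement needed when distinct drivers co-inhabit a
primary clade (e.g. an *MTH1* sub-clade inside a mostly-*SNF3* clade).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from cladecall.cluster import CladeResults, Dendrogram
from cladecall.errors import ConfigurationError

#: Sentinel label for a clade with no genotyped member or a tied vote.
ABSTAIN = "ABSTAIN"

#: Sentinel prediction for clones in an abstaining clade.
UNDETERMINED = "UNDETERMINED"

PREDICTION_COLUMNS = ("clone", "clade", "predicted_class", "support")


@dataclass(frozen=True)
class CladeLabel:
    """Majority label of one clade with its vote counts."""

    label: str
    n_support: int
    n_conflict: int

    @property
    def abstained(self) -> bool:
        return self.label == ABSTAIN


def _majority(votes: Counter) -> tuple[str, int, int]:
    """Return (label, n_support, n_conflict); ABSTAIN on empty or tied vote."""
    total = sum(votes.values())
    if total == 0:
        return ABSTAIN, 0, 0
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return ABSTAIN, ranked[0][1], total - ranked[0][1]
    return ranked[0][0], ranked[0][1], total - ranked[0][1]


def label_clades(
    assignment: pd.Series, labels: Mapping[str, str] | pd.Series
) -> dict[int, CladeLabel]:
    """Majority-vote driver label per clade from the genotyped clones.

    ``labels`` maps clone id to its known mutation class; every labelled
    clone must be present in the clade assignment.
    """
    labels = dict(labels)
    unknown = sorted(set(labels) - set(assignment.index))
    if unknown:
        raise ConfigurationError(
            f"labels refer to clones absent from the assignment: {unknown}"
        )
    out: dict[int, CladeLabel] = {}
    for clade in sorted(assignment.unique()):
        members = assignment.index[assignment == clade]
        votes = Counter(labels[c] for c in members if c in labels)
        label, sup, con = _majority(votes)
        out[int(clade)] = CladeLabel(label, sup, con)
    return out


def predict(
    assignment: pd.Series,
    label_map: Mapping[int, CladeLabel],
    clones: Iterable[str],
) -> pd.DataFrame:
    """Predict each clone's driver as its clade's majority label.

    Returns a DataFrame ``clone clade predicted_class support``; support is
    the agreeing fraction of the clade's labelled members (NaN when the
    clade abstains with no labelled member).
    """
    rows = []
    for clone in clones:
        if clone not in assignment.index:
            raise ConfigurationError(f"clone {clone!r} absent from the assignment")
        clade = int(assignment[clone])
        cl = label_map[clade]
        total = cl.n_support + cl.n_conflict
        if cl.abstained:
            rows.append((clone, clade, UNDETERMINED, float("nan")))
        else:
            rows.append((clone, clade, cl.label, cl.n_support / total))
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))


def _vote_on_subtree(
    dend: Dendrogram, node: int, labels: Mapping[str, str]
) -> tuple[str, int, int]:
    votes = Counter(
        labels[dend.labels[i]]
        for i in dend._subtree_leaves(node)
        if dend.labels[i] in labels
    )
    return _majority(votes)


def predict_refined(
    results: CladeResults,
    labels: Mapping[str, str] | pd.Series,
    clones: Iterable[str],
) -> pd.DataFrame:
    """Dendrogram-guided prediction with sub-clade refinement.

    For each query clone, ascend from its leaf toward its clade's root and
    vote over the first subtree that contains genotyped clones and gives an
    untied majority.  Clades whose genotyped members all agree reduce to the
    plain clade vote; conflicted clades are resolved locally, as a reader of
    the dendrogram would.
    """
    labels = dict(labels)
    dend = results.dendrogram
    assignment = results.assignment
    unknown = sorted(set(labels) - set(assignment.index))
    if unknown:
        raise ConfigurationError(
            f"labels refer to clones absent from the assignment: {unknown}"
        )

    n = dend.n_leaves
    parent: dict[int, int] = {}
    for i, (a, b) in enumerate(dend.merges):
        parent[a] = parent[b] = n + i
    leaf_of = {lab: i for i, lab in enumerate(dend.labels)}

    # root node of each clade's subtree = highest ancestor staying in-clade
    clade_of_leaf = {leaf_of[c]: int(assignment[c]) for c in assignment.index}

    rows = []
    for clone in clones:
        if clone not in assignment.index:
            raise ConfigurationError(f"clone {clone!r} absent from the assignment")
        clade = int(assignment[clone])
        node = leaf_of[clone]
        result = (ABSTAIN, 0, 0)
        while True:
            label, sup, con = _vote_on_subtree(dend, node, labels)
            if label != ABSTAIN:
                result = (label, sup, con)
                break
            in_clade = all(
                clade_of_leaf[leaf] == clade for leaf in dend._subtree_leaves(node)
            )
            if node not in parent or not in_clade:
                result = (label, sup, con)
                break
            nxt = parent[node]
            nxt_leaves = dend._subtree_leaves(nxt)
            if any(clade_of_leaf[leaf] != clade for leaf in nxt_leaves):
                result = (label, sup, con)  # clade root reached; stay abstained
                break
            node = nxt
        label, sup, con = result
        total = sup + con
        if label == ABSTAIN:
            rows.append((clone, clade, UNDETERMINED, float("nan")))
        else:
            rows.append((clone, clade, label, sup / total))
    return pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))


def evaluate(
    predictions: pd.DataFrame,
    truth: Mapping[str, str] | pd.Series,
    count_undetermined: bool = True,
) -> dict:
    """Score predictions against truth labels.

    Returns overall accuracy, per-class accuracy, and the confusion counts.
    UNDETERMINED predictions count as errors by default; with
    ``count_undetermined=False`` they are excluded from the denominator.
    """
    truth = dict(truth)
    missing = sorted(set(predictions["clone"]) - set(truth))
    if missing:
        raise ConfigurationError(f"no truth label for clones: {missing}")

    per_class_hits: Counter = Counter()
    per_class_total: Counter = Counter()
    confusion: Counter = Counter()
    n_correct = 0
    n_scored = 0
    for row in predictions.itertuples(index=False):
        t = truth[row.clone]
        p = row.predicted_class
        confusion[(t, p)] += 1
        if p == UNDETERMINED and not count_undetermined:
            continue
        n_scored += 1
        per_class_total[t] += 1
        if p == t:
            n_correct += 1
            per_class_hits[t] += 1
    return {
        "n": n_scored,
        "n_correct": n_correct,
        "accuracy": n_correct / n_scored if n_scored else float("nan"),
        "per_class_accuracy": {
            c: per_class_hits[c] / per_class_total[c] for c in sorted(per_class_total)
        },
        "confusion": dict(confusion),
    }


def loocv(
    results: CladeResults,
    labels: Mapping[str, str] | pd.Series,
    refined: bool = False,
) -> dict:
    """Leave-one-out accuracy over the genotyped clones.

    Each labelled clone is hidden in turn, clades are re-labelled from the
    remaining genotyped clones (the clustering itself does not depend on
    labels, so it is not recomputed), and the hidden clone is predicted.
    """
    labels = dict(labels)
    preds = []
    for clone in labels:
        held = {c: l for c, l in labels.items() if c != clone}
        if refined:
            pred = predict_refined(results, held, [clone])
        else:
            lmap = label_clades(results.assignment, held)
            pred = predict(results.assignment, lmap, [clone])
        preds.append(pred)
    all_preds = pd.concat(preds, ignore_index=True)
    report = evaluate(all_preds, labels)
    report["predictions"] = all_preds
    return report
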