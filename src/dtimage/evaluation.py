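"""Threshold metrics, AUC and the cross-validated experiment driver.

Threshold metrics from a confusion table:

    Acc = (TP + TN) / (TP + FP + TN + FN)
    Pre = TP / (TP + FP)
    Sen = TP / (TP + FN)
    F1  = 2 * Sen * Pre / (Sen + Pre)

Zero-denominator cases (no predicted positives, no actual positives, or
Pre = Sen = 0) report the affected metric as 0 and set a flag rather than
raising: an all-negative predictor is a legitimate, if degenerate,
experimental outcome.

AUC is the Mann-Whitney rank statistic — the probability that a randomly
chosen positive outscores a randomly chosen negative, ties counted half —
which equals the trapezoidal area under the ROC curve.

Cross-validation trains one classifier per fold on the view-level images
of the k-1 training folds (descriptor cleaning is refit on training rows
only, inside the fold), scores every view of the test fold, votes per
pair, and accumulates confusion counts at two scopes: per view and per
pair after voting.  The headline numbers are the per-pair scope — the
pair is the object the method predicts — with per-view numbers kept for
diagnosis.  Reported values are fold means; per-fold values and the
pooled per-pair scores (for ROC export) are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cnn import ModelConfig, build_model, train
from .drugs import DescriptorMask, DrugDescriptorTable, clean_table
from .ensemble import VoteResult, vote_grouped
from .pairs import FoldAssignment, PairSample, assemble_image_stack, make_folds
from .proteins import MoranDescriptor

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """Raised for undefined metric requests (e.g. single-class AUC)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class MetricReport:
    acc: float
    sen: float
    pre: float
    f1: float
    auc: float | None = None
    scope: str = "per-pair-after-vote"
    flags: tuple[str, ...] = ()
    per_fold: dict = field(default_factory=dict)


def metrics(c: ConfusionCounts, scope: str = "per-pair-after-vote") -> MetricReport:
    """Accuracy, precision, sensitivity and F1 from a confusion table."""
    if c.total == 0:
        raise MetricError("empty confusion table")
    flags = []
    acc = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        pre, _ = 0.0, flags.append("precision_undefined")
    else:
        pre = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        sen, _ = 0.0, flags.append("sensitivity_undefined")
    else:
        sen = c.tp / (c.tp + c.fn)
    if pre + sen == 0:
        f1, _ = 0.0, flags.append("f1_undefined")
    else:
        f1 = 2 * sen * pre / (sen + pre)
    return MetricReport(acc=acc, sen=sen, pre=pre, f1=f1, scope=scope, flags=tuple(flags))


def auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) of the empirical ROC curve, for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr


def confusion_from_predictions(labels, decisions) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    decisions = np.asarray(decisions, dtype=int)
    return ConfusionCounts(
        tp=int(((labels == 1) & (decisions == 1)).sum()),
        fp=int(((labels == 0) & (decisions == 1)).sum()),
        tn=int(((labels == 0) & (decisions == 0)).sum()),
        fn=int(((labels == 1) & (decisions == 0)).sum()),
    )


@dataclass
class CrossValidationReport:
    """Fold-mean metrics at both scopes, plus pooled per-pair predictions."""

    pair_scope: MetricReport
    view_scope: MetricReport
    per_family: dict[str, MetricReport]
    votes: list[VoteResult]
    vote_labels: np.ndarray
    folds: FoldAssignment
    vote_fraction_auc: float | None = None
    skipped_folds: tuple[int, ...] = ()


def _fold_mean(per_fold: list[MetricReport], aucs: list[float], scope: str) -> MetricReport:
    rep = MetricReport(
        acc=float(np.mean([m.acc for m in per_fold])),
        sen=float(np.mean([m.sen for m in per_fold])),
        pre=float(np.mean([m.pre for m in per_fold])),
        f1=float(np.mean([m.f1 for m in per_fold])),
        auc=float(np.mean(aucs)) if aucs else None,
        scope=scope,
        flags=tuple(sorted({f for m in per_fold for f in m.flags})),
    )
    rep.per_fold = {
        "acc": [m.acc for m in per_fold],
        "auc": list(aucs),
    }
    return rep


def cross_validate(
    pairs: list[PairSample],
    table: DrugDescriptorTable,
    proteins: dict[str, MoranDescriptor],
    masks: list[DescriptorMask],
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    side: int | None = None,
    vote_threshold: float = 0.5,
    ensemble_mode: str = "shared",
) -> CrossValidationReport:
    """k-fold cross-validation of the full view-vote pipeline.

    Per fold: refit descriptor cleaning on drugs seen in training pairs,
    assemble training and test image stacks over all views, train the
    classifier, score the test views, vote per pair, and accumulate
    metrics.  A fold whose test pairs are single-class is skipped with a
    warning.

    ``ensemble_mode="shared"`` (default) trains one network on all views;
    ``"per-view"`` trains one network per mask and each model scores only
    its own view — the votes then aggregate across models.
    """
    if ensemble_mode not in ("shared", "per-view"):
        raise ValueError(f"unknown ensemble_mode {ensemble_mode!r}")
    folds = make_folds(pairs, k=k, seed=seed)
    drug_index = table.row_map()
    pair_fold = np.array([folds.fold_of[p.key] for p in pairs])

    fold_pair_metrics: list[MetricReport] = []
    fold_view_metrics: list[MetricReport] = []
    fold_pair_aucs: list[float] = []
    fold_view_aucs: list[float] = []
    all_votes: list[VoteResult] = []
    all_vote_labels: list[int] = []
    all_vote_families: list[str] = []
    skipped: list[int] = []

    for fold in range(k):
        test_pairs = [p for p, f in zip(pairs, pair_fold) if f == fold]
        train_pairs = [p for p, f in zip(pairs, pair_fold) if f != fold]
        test_labels = np.array([p.label for p in test_pairs])
        if len(np.unique(test_labels)) < 2 or len(
            np.unique([p.label for p in train_pairs])
        ) < 2:
            logger.warning("fold %d skipped: a split is single-class", fold)
            skipped.append(fold)
            continue

        train_drugs = sorted({p.drug_id for p in train_pairs})
        cleaned = clean_table(table, train_drugs)

        tr_imgs, tr_labels, _, tr_view_idx = assemble_image_stack(
            train_pairs, cleaned.values, drug_index, masks, proteins, side=side
        )
        te_imgs, te_view_labels, te_pair_idx, te_view_idx = assemble_image_stack(
            test_pairs, cleaned.values, drug_index, masks, proteins, side=side
        )

        if ensemble_mode == "per-view":
            view_scores = np.empty(len(te_imgs))
            for j in range(len(masks)):
                view_config = ModelConfig(
                    **{**config.to_dict(), "seed": config.seed + 131 * fold + j}
                )
                net = build_model(view_config, image_side=tr_imgs.shape[-1])
                sel = tr_view_idx == j
                model = train(net, tr_imgs[sel], tr_labels[sel], view_config)
                out = te_view_idx == j
                view_scores[out] = model.score(te_imgs[out])
        else:
            fold_config = ModelConfig(**{**config.to_dict(), "seed": config.seed + fold})
            net = build_model(fold_config, image_side=tr_imgs.shape[-1])
            model = train(net, tr_imgs, tr_labels, fold_config)
            view_scores = model.score(te_imgs)

        view_conf = confusion_from_predictions(
            te_view_labels, (view_scores >= vote_threshold).astype(int)
        )
        fold_view_metrics.append(metrics(view_conf, scope="per-view"))
        fold_view_aucs.append(auc(view_scores, te_view_labels))

        votes = vote_grouped(view_scores, te_pair_idx, test_pairs, threshold=vote_threshold)
        decisions = [v.decision for v in votes]
        agg = [v.aggregate_score for v in votes]
        pair_conf = confusion_from_predictions(test_labels, decisions)
        fold_pair_metrics.append(metrics(pair_conf, scope="per-pair-after-vote"))
        fold_pair_aucs.append(auc(agg, test_labels))

        all_votes.extend(votes)
        all_vote_labels.extend(test_labels.tolist())
        all_vote_families.extend(p.family for p in test_pairs)

    if not fold_pair_metrics:
        raise MetricError("every fold was skipped; no metrics available")

    vote_labels = np.array(all_vote_labels)
    per_family: dict[str, MetricReport] = {}
    for family in sorted(set(all_vote_families)):
        idx = [i for i, f in enumerate(all_vote_families) if f == family]
        fam_labels = vote_labels[idx]
        fam_dec = [all_votes[i].decision for i in idx]
        rep = metrics(confusion_from_predictions(fam_labels, fam_dec))
        if len(np.unique(fam_labels)) == 2:
            rep.auc = auc([all_votes[i].aggregate_score for i in idx], fam_labels)
        per_family[family] = rep

    vote_frac_auc = auc([v.vote_fraction for v in all_votes], vote_labels)

    return CrossValidationReport(
        pair_scope=_fold_mean(fold_pair_metrics, fold_pair_aucs, "per-pair-after-vote"),
        view_scope=_fold_mean(fold_view_metrics, fold_view_aucs, "per-view"),
        per_family=per_family,
        votes=all_votes,
        vote_labels=vote_labels,
        folds=folds,
        vote_fraction_auc=vote_frac_auc,
        skipped_folds=tuple(skipped),
    )


def write_metrics_tsv(report: CrossValidationReport, path) -> None:
    """Fold-mean metrics at both scopes plus per-family breakdown, as TSV."""
    rows = [("pooled", report.pair_scope), ("pooled", report.view_scope)]
    rows += [(fam, rep) for fam, rep in report.per_family.items()]
    with open(path, "w") as fh:
        fh.write("group\tscope\tacc\tsen\tpre\tf1\tauc\tflags\n")
        for group, rep in rows:
            auc_s = "" if rep.auc is None else f"{rep.auc:.6f}"
            fh.write(
                f"{group}\t{rep.scope}\t{rep.acc:.6f}\t{rep.sen:.6f}\t{rep.pre:.6f}\t"
                f"{rep.f1:.6f}\t{auc_s}\t{','.join(rep.flags)}\n"
            )


def write_roc_csv(report: CrossValidationReport, path) -> None:
    fpr, tpr, thr = roc_points(
        [v.aggregate_score for v in report.votes], report.vote_labels
    )
    with open(path, "w") as fh:
        fh.write("fpr,tpr,threshold\n")
        for f, t, h in zip(fpr, tpr, thr):
            fh.write(f"{f},{t},{h}\n")
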