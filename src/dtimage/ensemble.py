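"""Majority-vote aggregation of per-view predictions.

Every drug-target pair is scored once per augmented view.  A view votes
positive when its positive-class probability reaches the per-view
threshold (default 0.5, the argmax of the two-class output).  The pair is
predicted to interact when AT LEAST HALF of its views vote positive —
with an even view count an exact tie is therefore decided positive; this
literal reading of the rule is asserted by the tests.  The pair's
continuous score, used for ROC/AUC, is the arithmetic mean of the view
probabilities; the positive-vote fraction is also carried so both natural
readings of the ensemble score can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VoteResult:
    drug_id: str
    target_id: str
    per_view_scores: tuple[float, ...]
    votes_positive: int
    n_views: int
    decision: int
    aggregate_score: float

    @property
    def vote_fraction(self) -> float:
        return self.votes_positive / self.n_views


def vote(
    per_view_scores,
    threshold: float = 0.5,
    drug_id: str = "",
    target_id: str = "",
) -> VoteResult:
    """Aggregate one pair's per-view probabilities into a decision.

    decision = 1 iff 2 * votes_positive >= n_views ("at least half").
    """
    scores = np.asarray(per_view_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty per-view score list")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    votes = int((scores >= threshold).sum())
    n = scores.size
    return VoteResult(
        drug_id=drug_id,
        target_id=target_id,
        per_view_scores=tuple(float(s) for s in scores),
        votes_positive=votes,
        n_views=n,
        decision=int(2 * votes >= n),
        aggregate_score=float(scores.mean()),
    )


def vote_grouped(
    scores: np.ndarray,
    pair_index: np.ndarray,
    pairs,
    threshold: float = 0.5,
) -> list[VoteResult]:
    """Vote per pair over a flat per-view score vector.

    ``pair_index[r]`` maps score row r to its pair in ``pairs`` (the layout
    produced by the image-stack assembler).
    """
    results = []
    for i, pair in enumerate(pairs):
        s = scores[pair_index == i]
        results.append(vote(s, threshold, drug_id=pair.drug_id, target_id=pair.target_id))
    return results


def write_predictions_tsv(results: list[VoteResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\ttarget_id\tn_views\tvotes_positive\taggregate_score\tdecision\n")
        for r in results:
            fh.write(
                f"{r.drug_id}\t{r.target_id}\t{r.n_views}\t{r.votes_positive}\t"
                f"{r.aggregate_score:.6f}\t{r.decision}\n"
            )
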