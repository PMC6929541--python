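"""Labeled drug-target pair sets and image-like feature assembly.

Positives come from curated interaction lists; negatives are built by
re-coupling — randomly pairing every drug with every target, removing the
known positives, and sampling uniformly without replacement until the
negative count reaches ratio x positives (default ratio 2, with 1 and 3 as
study variants).

Each pair is replicated across n augmented views (one per descriptor
mask); the replication factor is the smallest n whose total pair count
reaches the 40000-50000 working-set target, or an explicit override.  For
one (pair, view) the masked drug sub-vector (342 entries, ascending column
order) is concatenated with the protein Moran vector (442 entries,
property-major) and reshaped row-major into a 28x28 matrix.  Alternative
geometries must declare their own square side.

Cross-validation folds are stratified by label at the PAIR level, and all
views of one pair share the pair's fold.  The pair is the object of
prediction, so letting different views of one pair straddle
the train/test boundary would leak the answer through the shared protein
block; co-assignment is this package's guard against that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .drugs import DescriptorMask
from .proteins import MoranDescriptor

FAMILIES = ("enzyme", "ion_channel", "gpcr", "nuclear_receptor", "other")


class DatasetConstructionError(ValueError):
    """Raised when a pair set cannot be built as requested."""


class GeometryError(ValueError):
    """Raised when feature lengths do not match the declared image side."""


@dataclass(frozen=True)
class PairSample:
    drug_id: str
    target_id: str
    label: int  # 1 interacting, 0 non-interacting
    family: str = "other"
    origin: str = "listed_positive"  # or "sampled_negative"

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_id, self.target_id)


@dataclass(frozen=True)
class PairImage:
    """One (pair, view): a side x side matrix whose row-major flattening is
    [masked drug sub-vector, protein Moran vector]."""

    drug_id: str
    target_id: str
    view_index: int
    matrix: np.ndarray
    label: int


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: dict[tuple[str, str], int]
    seed: int

    def test_pairs(self, fold: int) -> list[tuple[str, str]]:
        return [key for key, f in self.fold_of.items() if f == fold]


def sample_negatives(
    positives: list[PairSample],
    drugs: list[str],
    targets: list[str],
    ratio: float = 2.0,
    seed: int = 0,
) -> list[PairSample]:
    """Sample round(ratio x |positives|) re-coupled negatives, uniformly
    without replacement, never colliding with a listed positive."""
    if not positives:
        raise DatasetConstructionError("no positive pairs given")
    n_drugs, n_targets = len(drugs), len(targets)
    drug_pos = {d: i for i, d in enumerate(drugs)}
    target_pos = {t: i for i, t in enumerate(targets)}
    pos_codes = set()
    for p in positives:
        if p.drug_id in drug_pos and p.target_id in target_pos:
            pos_codes.add(drug_pos[p.drug_id] * n_targets + target_pos[p.target_id])
    universe = n_drugs * n_targets
    available = universe - len(pos_codes)
    wanted = round(ratio * len(positives))
    if wanted > available:
        max_ratio = available / len(positives)
        raise DatasetConstructionError(
            f"requested {wanted} negatives but only {available} non-positive "
            f"pairs exist (maximum achievable ratio {max_ratio:.3f})"
        )
    rng = np.random.default_rng(seed)
    codes = np.arange(universe)
    mask = np.ones(universe, dtype=bool)
    mask[list(pos_codes)] = False
    chosen = rng.choice(codes[mask], size=wanted, replace=False)
    fam = {(p.drug_id, p.target_id): p.family for p in positives}
    negatives = []
    for code in chosen:
        d, t = drugs[code // n_targets], targets[code % n_targets]
        negatives.append(
            PairSample(d, t, label=0, family=fam.get((d, t), "other"), origin="sampled_negative")
        )
    return negatives


def choose_replication(
    n_pairs: int,
    target_total_low: int = 40000,
    target_total_high: int = 50000,
) -> int:
    """Smallest n >= 1 with n * n_pairs >= target_total_low.

    Small datasets may overshoot target_total_high; the low bound governs.
    """
    if n_pairs < 1:
        raise DatasetConstructionError("n_pairs must be >= 1")
    return max(1, math.ceil(target_total_low / n_pairs))


def assemble_image(
    drug_row: np.ndarray,
    mask: DescriptorMask,
    protein: MoranDescriptor,
    label: int = 0,
    drug_id: str = "",
    side: int | None = None,
) -> PairImage:
    """Assemble one 28x28 (or side x side) image for one (pair, view)."""
    flat = np.concatenate([mask.apply(np.asarray(drug_row, dtype=float)), protein.values])
    n = len(flat)
    if side is None:
        side = math.isqrt(n)
    if side * side != n:
        raise GeometryError(
            f"feature length {len(mask)} + {len(protein)} = {n} does not fill "
            f"a {side}x{side} image"
        )
    return PairImage(
        drug_id=drug_id,
        target_id=protein.target_id,
        view_index=mask.view_index,
        matrix=flat.reshape(side, side),
        label=label,
    )


def assemble_image_stack(
    pairs: list[PairSample],
    drug_rows: np.ndarray,
    drug_index: dict[str, int],
    masks: list[DescriptorMask],
    proteins: dict[str, MoranDescriptor],
    side: int | None = None,
    dtype=np.float32,
):
    """Bulk image assembly for pairs x views.

    Returns ``(images, labels, pair_index, view_index)`` where ``images`` has
    shape (|pairs| * n_views, side, side); entry order is view-major within
    pair so all views of pair i are contiguous.  ``pair_index[r]`` maps image
    row r back to its pair.
    """
    if not pairs:
        raise DatasetConstructionError("no pairs to assemble")
    subset = len(masks[0])
    prot_len = len(next(iter(proteins.values())))
    n = subset + prot_len
    if side is None:
        side = math.isqrt(n)
    if side * side != n:
        raise GeometryError(f"feature length {n} does not fill a {side}x{side} image")
    n_views = len(masks)
    rows = np.array([drug_index[p.drug_id] for p in pairs])
    prot_mat = np.stack([proteins[p.target_id].values for p in pairs]).astype(dtype)
    images = np.empty((len(pairs) * n_views, side, side), dtype=dtype)
    labels = np.repeat([p.label for p in pairs], n_views).astype(np.int64)
    pair_index = np.repeat(np.arange(len(pairs)), n_views)
    view_index = np.tile(np.arange(n_views), len(pairs))
    for j, m in enumerate(masks):
        drug_part = drug_rows[np.ix_(rows, m.column_indices)].astype(dtype)
        flat = np.concatenate([drug_part, prot_mat], axis=1)
        images[j::n_views] = flat.reshape(-1, side, side)
    return images, labels, pair_index, view_index


def make_folds(pairs: list[PairSample], k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified-by-label partition of pairs into k near-equal folds."""
    if k < 2:
        raise DatasetConstructionError("k must be >= 2")
    if len(pairs) < k:
        raise DatasetConstructionError(f"{len(pairs)} pairs cannot fill {k} folds")
    labels = np.array([p.label for p in pairs])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[tuple[str, str], int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(pairs)), labels)):
        for i in test_idx:
            fold_of[pairs[i].key] = fold
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def read_pair_tsv(path) -> list[PairSample]:
    """Read a pair list TSV: drug_id, target_id, family[, label]."""
    pairs: list[PairSample] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("drug_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DatasetConstructionError(f"bad pair TSV row: {line!r}")
            drug_id, target_id, family = parts[0], parts[1], parts[2]
            label = int(parts[3]) if len(parts) > 3 else 1
            key = (drug_id, target_id)
            if key in seen:
                raise DatasetConstructionError(f"duplicate pair {key}")
            seen.add(key)
            origin = "listed_positive" if label == 1 else "sampled_negative"
            pairs.append(PairSample(drug_id, target_id, label, family, origin))
    return pairs


def write_pair_tsv(pairs: list[PairSample], path, with_label: bool = True) -> None:
    with open(path, "w") as fh:
        header = "drug_id\ttarget_id\tfamily"
        fh.write(header + ("\tlabel" if with_label else "") + "\n")
        for p in pairs:
            row = f"{p.drug_id}\t{p.target_id}\t{p.family}"
            fh.write(row + (f"\t{p.label}" if with_label else "") + "\n")
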