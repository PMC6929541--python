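"""Self-contained synthetic fixtures for the whole pipeline.

The generator emulates the four external inputs — amino-acid property
scales, protein FASTA, drug descriptor CSV, and a labeled pair list — with
a planted interaction signal, so every stage and the end-to-end
cross-validated experiment run without downloads.

Construction.  Every drug and every target carries a latent binary
"compatibility" factor (prevalence 0.65 — compatibility classes are not
balanced, which also gives learners a first-order foothold on the
otherwise purely interaction-driven label); a pair interacts iff the
factors match.  The signal is deliberately split across BOTH input
modalities:

* the target factor lives in sequence composition — residues are emitted
  by a two-state Markov chain over a hydrophobic/polar partition whose
  persistence depends on the factor (factor 1: long same-class runs,
  positive lag-1 autocorrelation; factor 0: alternation, negative), so the
  Moran encoder is on the causal path to the label;
* the drug factor lives in a contiguous block of descriptor columns whose
  values are ±signal_strength plus Gaussian noise of sd noise_sd, so the
  random column masks matter.  Because masks are sorted uniform samples, a
  contiguous source block lands at nearly the same image position in
  every view.  Non-signal columns are a low-rank background plus noise
  ("structured" but uninformative).

signal_strength interpolates both channels: 0 gives iid sequences and
pure-noise descriptor columns (labels independent of features, AUC 0.5);
1 gives strongly persistent/alternating chains and unit-gap columns.

A truth manifest records every latent variable for parameter-recovery
tests.  The label is a match (XNOR) of the two factors, so no single
modality suffices — an end-to-end success requires both encoders to work.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .aaindex import AMINO_ACIDS, AAIndexProperty, PropertySet, _AAINDEX_ROW1, _AAINDEX_ROW2
from .cnn import ModelConfig
from .drugs import DrugDescriptorTable, draw_masks
from .pairs import FAMILIES, PairSample
from .proteins import ProteinRecord, encode_all

_HYDROPHOBIC = tuple("AVLIMFWC")
_POLAR = tuple(sorted(set(AMINO_ACIDS) - set(_HYDROPHOBIC)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Geometry and signal parameters of one synthetic study.

    The default ("desk") preset keeps the method's full feature geometry —
    1444-column descriptors, 342-column masks, 34 properties x 13 lags =
    442, 28x28 images — at a dataset size (200 drugs x 100 targets, 2000
    positives, 1:2 negatives) that a single CPU handles.
    """

    n_drugs: int = 200
    n_targets: int = 100
    n_properties: int = 34
    descriptor_width: int = 1444
    subset_size: int = 342
    d_max: int = 13
    image_side: int = 28
    n_positive: int = 2000
    negative_ratio: float = 2.0
    signal_strength: float = 1.0
    noise_sd: float = 0.1
    n_signal_columns: int = 40
    factor_prevalence: float = 0.65
    min_seq_len: int = 100
    max_seq_len: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size > self.descriptor_width:
            raise ValueError("subset_size exceeds descriptor_width")
        if self.subset_size + self.n_properties * self.d_max != self.image_side**2:
            raise ValueError(
                f"geometry violated: {self.subset_size} + {self.n_properties} x "
                f"{self.d_max} != {self.image_side}^2"
            )
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_signal_columns > self.descriptor_width:
            raise ValueError("n_signal_columns exceeds descriptor_width")
        if not 0 < self.factor_prevalence < 1:
            raise ValueError("factor_prevalence must be in (0, 1)")


def small_preset(**overrides) -> SyntheticConfig:
    """A seconds-scale preset with 10x10 images (58 + 6x7 = 100 features)."""
    params = dict(
        n_drugs=40,
        n_targets=25,
        n_properties=6,
        descriptor_width=120,
        subset_size=58,
        d_max=7,
        image_side=10,
        n_positive=150,
        negative_ratio=2.0,
        n_signal_columns=12,
        min_seq_len=60,
        max_seq_len=120,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass
class SyntheticData:
    """In-memory form of one generated study plus its ground truth."""

    config: SyntheticConfig
    properties: list[AAIndexProperty]
    proteins: list[ProteinRecord]
    table: DrugDescriptorTable
    pairs: list[PairSample]
    truth: dict


def _markov_sequence(rng, length: int, persist: float) -> str:
    """Two-state hydrophobic/polar Markov chain; persist = stay probability."""
    states = np.empty(length, dtype=int)
    states[0] = rng.integers(2)
    stay = rng.random(length - 1) < persist
    for i in range(1, length):
        states[i] = states[i - 1] if stay[i - 1] else 1 - states[i - 1]
    out = []
    for s in states:
        pool = _HYDROPHOBIC if s == 1 else _POLAR
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def generate_data(config: SyntheticConfig) -> SyntheticData:
    """Generate one synthetic study in memory (no files written)."""
    root = np.random.SeedSequence(entropy=config.seed)
    rng_prop, rng_seq, rng_desc, rng_pair = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    # property scales: independent Gaussian 20-vectors
    properties = [
        AAIndexProperty(
            accession=f"SYN{m + 1:04d}",
            description=f"synthetic property scale {m + 1}",
            values=dict(zip(AMINO_ACIDS, rng_prop.standard_normal(20).round(3))),
        )
        for m in range(config.n_properties)
    ]

    # targets: latent factor -> Markov persistence
    target_ids = [f"T{i + 1:04d}" for i in range(config.n_targets)]
    # the class asymmetry is itself part of the planted signal: at
    # signal_strength 0 the factors are balanced, so per-entity positive
    # rates carry no information either (clean null)
    prevalence = 0.5 + (config.factor_prevalence - 0.5) * config.signal_strength
    target_factor = (rng_seq.random(config.n_targets) < prevalence).astype(int)
    half_gap = 0.45 * config.signal_strength
    proteins = []
    for tid, g in zip(target_ids, target_factor):
        length = int(rng_seq.integers(config.min_seq_len, config.max_seq_len + 1))
        persist = 0.5 + half_gap if g == 1 else 0.5 - half_gap
        proteins.append(ProteinRecord(tid, _markov_sequence(rng_seq, length, persist)))

    # drugs: latent factor -> signal column block; low-rank background
    drug_ids = [f"D{i + 1:04d}" for i in range(config.n_drugs)]
    drug_factor = (rng_desc.random(config.n_drugs) < prevalence).astype(int)
    width = config.descriptor_width
    rank = min(10, width)
    loadings = rng_desc.standard_normal((config.n_drugs, rank))
    basis = rng_desc.standard_normal((rank, width)) / np.sqrt(rank)
    values = loadings @ basis + 0.5 * rng_desc.standard_normal((config.n_drugs, width))
    start = (width - config.n_signal_columns) // 2
    signal_cols = np.arange(start, start + config.n_signal_columns)
    signal = (2.0 * drug_factor - 1.0)[:, None] * config.signal_strength
    values[:, signal_cols] = signal + config.noise_sd * rng_desc.standard_normal(
        (config.n_drugs, len(signal_cols))
    )
    table = DrugDescriptorTable(
        drug_ids=drug_ids,
        column_names=[f"SD{j + 1:04d}" for j in range(width)],
        values=values,
        cleaning_report={"n_drugs": config.n_drugs, "width": width, "missing_cells": 0,
                         "cleaned": False},
    )

    # pairs: positive iff factors match; negatives from the non-matching rest
    match = drug_factor[:, None] == target_factor[None, :]
    pos_codes = np.flatnonzero(match.ravel())
    neg_codes = np.flatnonzero(~match.ravel())
    if len(pos_codes) < config.n_positive:
        raise ValueError(
            f"only {len(pos_codes)} matching pairs exist; cannot draw "
            f"{config.n_positive} positives"
        )
    n_neg = round(config.negative_ratio * config.n_positive)
    if len(neg_codes) < n_neg:
        raise ValueError(
            f"only {len(neg_codes)} non-matching pairs exist; cannot draw {n_neg} negatives"
        )
    family_of_target = {
        tid: FAMILIES[rng_pair.integers(4)] for tid in target_ids
    }
    chosen_pos = rng_pair.choice(pos_codes, size=config.n_positive, replace=False)
    chosen_neg = rng_pair.choice(neg_codes, size=n_neg, replace=False)
    pairs = []
    for code, label in [(c, 1) for c in chosen_pos] + [(c, 0) for c in chosen_neg]:
        d, t = drug_ids[code // config.n_targets], target_ids[code % config.n_targets]
        pairs.append(
            PairSample(
                d, t, label=label, family=family_of_target[t],
                origin="listed_positive" if label else "sampled_negative",
            )
        )

    truth = {
        "config": asdict(config),
        "drug_factor": {d: int(f) for d, f in zip(drug_ids, drug_factor)},
        "target_factor": {t: int(f) for t, f in zip(target_ids, target_factor)},
        "signal_columns": signal_cols.tolist(),
        "family_of_target": family_of_target,
    }
    return SyntheticData(config, properties, proteins, table, pairs, truth)


def _write_aaindex(properties: list[AAIndexProperty], path) -> None:
    """Write scales in the AAindex1 flat-file dialect."""
    with open(path, "w") as fh:
        for p in properties:
            fh.write(f"H {p.accession}\n")
            fh.write(f"D {p.description}\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T"
                     "     G/W     H/Y     I/V\n")
            for row in (_AAINDEX_ROW1, _AAINDEX_ROW2):
                fh.write("   " + "   ".join(f"{p.values[a]:7.3f}" for a in row) + "\n")
            fh.write("//\n")


def generate(config: SyntheticConfig, outdir) -> dict[str, Path]:
    """Generate a study and write the four input files plus the truth manifest.

    Returns the written paths keyed as ``properties``, ``fasta``,
    ``descriptors``, ``pairs``, ``truth``.
    """
    data = generate_data(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "properties": outdir / "properties.aaindex",
        "fasta": outdir / "proteins.fasta",
        "descriptors": outdir / "descriptors.csv",
        "pairs": outdir / "pairs.tsv",
        "truth": outdir / "truth.json",
    }
    _write_aaindex(data.properties, paths["properties"])
    with open(paths["fasta"], "w") as fh:
        for prot in data.proteins:
            fh.write(f">{prot.target_id} synthetic\n")
            for i in range(0, len(prot.sequence), 60):
                fh.write(prot.sequence[i : i + 60] + "\n")
    with open(paths["descriptors"], "w") as fh:
        fh.write("Name," + ",".join(data.table.column_names) + "\n")
        for i, d in enumerate(data.table.drug_ids):
            fh.write(d + "," + ",".join(repr(float(v)) for v in data.table.values[i]) + "\n")
    from .pairs import write_pair_tsv

    write_pair_tsv(data.pairs, paths["pairs"])
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=1)
    return paths


def desk_model_config(seed: int = 0) -> ModelConfig:
    """The reduced classifier used for desk-scale cross-validation runs.

    A narrower stack (8/16/32 filters, 64-unit hidden layer) trained for
    900 Adam steps of 64 at the standard 0.001 learning rate.  These sizes
    keep a full 10-fold run tractable on one CPU while leaving ample
    capacity for the synthetic studies; adaptive steps shorten the long
    interaction-learning plateau that plain SGD shows on this task.
    """
    return ModelConfig(
        conv_filters=(8, 16, 32),
        fc_units=64,
        batch_size=64,
        optimizer="adam",
        max_iterations=900,
        log_every=100,
        seed=seed,
    )


def run_synthetic_cv(
    config: SyntheticConfig,
    model_config: ModelConfig | None = None,
    n_views: int | None = None,
    k: int = 10,
    seed: int | None = None,
    ensemble_mode: str = "shared",
):
    """Generate a study and cross-validate the full pipeline on it.

    ``n_views`` defaults to the replication factor that lifts the total
    view count into the 40000-50000 working-set band.  Returns the
    cross-validation report.
    """
    from .evaluation import cross_validate
    from .pairs import choose_replication

    seed = config.seed if seed is None else seed
    data = generate_data(config)
    pset = PropertySet(tuple(data.properties), threshold=1.0, provenance={"source": "synthetic"})
    encoded, skipped = encode_all(data.proteins, pset, d_max=config.d_max)
    if skipped:
        raise RuntimeError(f"synthetic proteins failed to encode: {skipped}")
    if n_views is None:
        n_views = choose_replication(len(data.pairs))
    masks = draw_masks(
        n_views, subset_size=config.subset_size, width=config.descriptor_width,
        seed=seed + 1,
    )
    model_config = model_config or desk_model_config(seed=seed)
    return cross_validate(
        data.pairs,
        data.table,
        encoded,
        masks,
        model_config,
        k=k,
        seed=seed + 2,
        side=config.image_side,
        ensemble_mode=ensemble_mode,
    )
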