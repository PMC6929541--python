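"""Protein sequence encoding by Moran autocorrelation descriptors.

A protein of length N is mapped, for each property scale P and each lag
d = 1..d_max, to the autocorrelation statistic

    T(d) = [ (1/(N-d)) * sum_{i=1..N-d} (P_i - Pbar)(P_{i+d} - Pbar) ]
           / [ (1/N)   * sum_{i=1..N-d} (P_i - Pbar)^2 ]

where P_i is the scale value of residue i and Pbar the mean over all N
residues.  Note the denominator: its sum runs to N-d while its prefactor is
1/N.  This is the form implemented by default ("as printed" in the source
method); the textbook Moran variant, whose denominator sums over all N
positions, is available via ``denominator="full"`` but is never used by
default.  The statistic is invariant to affine rescaling of the property
scale, so scales need no standardisation beforehand.

Vectors are laid out property-major: all d_max lags of property 1, then of
property 2, and so on — with 34 properties and d_max = 13 this gives the
442-long target descriptor.  The downstream image assembly depends on this
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .aaindex import AMINO_ACIDS, AAIndexProperty, PropertySet

_VALID = set(AMINO_ACIDS)


class SequenceEncodingError(ValueError):
    """Raised for sequences that cannot be encoded (bad residues, too short)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein target: identifier plus amino-acid sequence."""

    target_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.target_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MoranDescriptor:
    """Fixed-length Moran feature vector for one protein, property-major."""

    target_id: str
    values: np.ndarray
    d_max: int

    def __len__(self) -> int:
        return len(self.values)


def _property_profile(sequence: str, prop: AAIndexProperty) -> np.ndarray:
    """Per-position property values; rejects non-standard residues."""
    bad = [(i, c) for i, c in enumerate(sequence) if c not in _VALID]
    if bad:
        i, c = bad[0]
        raise SequenceEncodingError(
            f"residue {c!r} at position {i + 1} is outside the 20-letter alphabet"
        )
    lut = prop.values
    return np.array([lut[c] for c in sequence], dtype=float)


def moran_term(
    sequence: str,
    prop: AAIndexProperty,
    d: int,
    denominator: str = "as_printed",
) -> float:
    """The lag-d Moran autocorrelation of one property along one sequence.

    ``denominator="as_printed"`` sums (P_i - Pbar)^2 over i = 1..N-d with a
    1/N prefactor; ``"full"`` is the textbook form summing over all N.  A
    zero denominator (property constant over the summed positions) returns
    0: a constant signal has no autocorrelation structure.
    """
    n = len(sequence)
    if not 1 <= d < n:
        raise SequenceEncodingError(f"lag d={d} requires 1 <= d < N={n}")
    p = _property_profile(sequence, prop)
    return float(_moran_lags(p, d, denominator)[-1])


def _moran_lags(p: np.ndarray, d_max: int, denominator: str) -> np.ndarray:
    """All lags 1..d_max of one per-position profile, vectorised."""
    if denominator not in ("as_printed", "full"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    n = len(p)
    centred = p - p.mean()
    sq = centred * centred
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    out = np.empty(d_max)
    for k, d in enumerate(range(1, d_max + 1)):
        num = (centred[: n - d] * centred[d:]).sum() / (n - d)
        den = (csum[n] if denominator == "full" else csum[n - d]) / n
        out[k] = 0.0 if den == 0.0 else num / den
    return out


def encode_protein(
    protein: ProteinRecord,
    props: PropertySet,
    d_max: int = 13,
    denominator: str = "as_printed",
) -> MoranDescriptor:
    """Encode one protein into its |props| x d_max Moran descriptor vector."""
    n = len(protein)
    if n <= d_max:
        raise SequenceEncodingError(
            f"protein {protein.target_id!r} has length {n} <= d_max={d_max}; "
            "cannot be encoded"
        )
    blocks = [
        _moran_lags(_property_profile(protein.sequence, prop), d_max, denominator)
        for prop in props
    ]
    return MoranDescriptor(protein.target_id, np.concatenate(blocks), d_max)


def read_fasta(path) -> list[ProteinRecord]:
    """Read proteins from FASTA; ids are the header token up to whitespace."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    return records


def encode_all(
    proteins: list[ProteinRecord],
    props: PropertySet,
    d_max: int = 13,
    on_error: str = "skip",
) -> tuple[dict[str, MoranDescriptor], list[str]]:
    """Encode a batch; returns (descriptors by id, skipped target ids).

    ``on_error="skip"`` drops unencodable proteins (too short, non-standard
    residues) and reports them; ``"raise"`` propagates the first error.
    """
    out: dict[str, MoranDescriptor] = {}
    skipped: list[str] = []
    for prot in proteins:
        try:
            out[prot.target_id] = encode_protein(prot, props, d_max)
        except SequenceEncodingError:
            if on_error == "raise":
                raise
            skipped.append(prot.target_id)
    return out, skipped


def descriptor_column_names(props: PropertySet, d_max: int = 13) -> list[str]:
    """Column names like ACC0001_d01 ... matching the property-major layout."""
    return [f"{p.accession}_d{d:02d}" for p in props for d in range(1, d_max + 1)]


def write_descriptor_csv(descriptors: dict[str, MoranDescriptor], props: PropertySet, path) -> None:
    """Write Moran descriptors as CSV: target_id plus one column per (property, lag)."""
    d_max = next(iter(descriptors.values())).d_max if descriptors else 13
    names = descriptor_column_names(props, d_max)
    with open(path, "w") as fh:
        fh.write("target_id," + ",".join(names) + "\n")
        for tid in sorted(descriptors):
            vals = ",".join(repr(float(v)) for v in descriptors[tid].values)
            fh.write(f"{tid},{vals}\n")
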