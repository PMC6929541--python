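"""Amino-acid property scales: AAindex1 parsing and decorrelated subset selection.

Protein sequences are encoded through physicochemical property scales taken
from the AAindex1 database, one real value per standard residue type per
scale.  Because many AAindex1 scales are near-duplicates of one another, a
greedy filter retains only a mutually weakly-correlated subset: properties
are ranked by how many other properties they correlate with beyond a
threshold, and scanning from the most-entangled survivor downward, every
later property correlated with a survivor beyond the threshold is dropped.

Correlation is compared as |Pearson r| against the threshold: a strong
negative correlation makes a scale just as redundant as a strong positive
one.  A pair whose |r| equals the threshold exactly is retained; only
strictly larger values trigger removal.  Ties in the exceedance count are
broken lexicographically by accession so the selection is deterministic
across runs and platforms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids in alphabetical one-letter order.  All
#: property vectors are laid out in this order.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Residue order of the AAindex1 ``I`` header: first value row then second.
_AAINDEX_ROW1 = tuple("ARNDCQEGHI")
_AAINDEX_ROW2 = tuple("LKMFPSTWYV")


class AAIndexParseError(ValueError):
    """Raised when an AAindex1 record is malformed."""


class PropertySelectionError(ValueError):
    """Raised when property selection receives unusable input."""


@dataclass(frozen=True)
class AAIndexProperty:
    """One named amino-acid scale: a real value for each of the 20 residues."""

    accession: str
    description: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(
                f"property {self.accession!r} missing residues: {sorted(missing)}"
            )

    @property
    def is_complete(self) -> bool:
        """True when every residue value is finite (no NA placeholders)."""
        return all(np.isfinite(self.values[a]) for a in AMINO_ACIDS)

    def vector(self) -> np.ndarray:
        """The 20 values in amino-acid-alphabetical order."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)


@dataclass(frozen=True)
class PropertySet:
    """An ordered, mutually weakly-correlated selection of property scales."""

    properties: tuple[AAIndexProperty, ...]
    threshold: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.properties)

    def __iter__(self):
        return iter(self.properties)

    @property
    def accessions(self) -> list[str]:
        return [p.accession for p in self.properties]


def parse_aaindex(stream) -> list[AAIndexProperty]:
    """Parse a text stream in the AAindex1 flat-file dialect.

    Each record carries line-type prefixes (``H`` accession, ``D``
    description, ``I`` residue-order header followed by two rows of ten
    values) and ends with ``//``.  Records whose value block contains the
    ``NA`` missing-value marker are returned with ``nan`` entries; callers
    filter on :attr:`AAIndexProperty.is_complete` before selection.

    Parameters
    ----------
    stream
        A text file object or a string containing the flat file.

    Returns
    -------
    list of AAIndexProperty, in file order.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    props: list[AAIndexProperty] = []
    accession = ""
    description = ""
    value_rows: list[list[float]] = []
    expect_values = 0
    seen: set[str] = set()

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if expect_values:
            tokens = line.split()
            row: list[float] = []
            for tok in tokens:
                if tok.upper() in ("NA", "NA."):
                    row.append(float("nan"))
                    continue
                try:
                    row.append(float(tok))
                except ValueError as exc:
                    raise AAIndexParseError(
                        f"record {accession or '<unnamed>'}: non-numeric token "
                        f"{tok!r} at line {lineno}"
                    ) from exc
            if len(row) != 10:
                raise AAIndexParseError(
                    f"record {accession or '<unnamed>'}: expected 10 values, "
                    f"got {len(row)} at line {lineno}"
                )
            value_rows.append(row)
            expect_values -= 1
            continue
        tag = line[0]
        if tag == "H":
            accession = line[1:].strip()
        elif tag == "D":
            description = line[1:].strip()
        elif tag == "I":
            expect_values = 2
            value_rows = []
        elif line.startswith("//"):
            if not accession:
                raise AAIndexParseError(f"record ending at line {lineno} has no accession")
            if len(value_rows) != 2:
                raise AAIndexParseError(
                    f"record {accession}: value block incomplete at line {lineno}"
                )
            if accession in seen:
                raise AAIndexParseError(f"duplicate accession {accession}")
            seen.add(accession)
            values = dict(zip(_AAINDEX_ROW1, value_rows[0]))
            values.update(zip(_AAINDEX_ROW2, value_rows[1]))
            props.append(AAIndexProperty(accession, description, values))
            accession = ""
            description = ""
            value_rows = []
        # other tags (R, A, T, J, C, *) and continuation lines are metadata
    if accession:
        raise AAIndexParseError(f"record {accession} not terminated by //")
    return props


def correlation(p: AAIndexProperty, q: AAIndexProperty) -> float:
    """Pearson correlation of two 20-value scales in residue-alphabetical order."""
    x, y = p.vector(), q.vector()
    if np.std(x) == 0 or np.std(y) == 0:
        raise PropertySelectionError(
            f"correlation undefined: zero-variance property "
            f"({p.accession if np.std(x) == 0 else q.accession})"
        )
    return float(np.corrcoef(x, y)[0, 1])


def select_uncorrelated(
    props: list[AAIndexProperty], threshold: float = 0.5
) -> PropertySet:
    """Greedy decorrelation filter over a list of complete property scales.

    The pass: (1) for each property count how many |r| with the others
    strictly exceed ``threshold``; (2) order by that count descending,
    accession ascending on ties; (3) scan from the top, and for each
    survivor remove every not-yet-removed later property whose |r| with it
    strictly exceeds ``threshold``.

    Incomplete properties (NA residue values) are excluded before counting.
    """
    if not 0 < threshold < 1:
        raise PropertySelectionError(f"threshold must be in (0, 1), got {threshold}")
    usable = [p for p in props if p.is_complete]
    if not usable:
        raise PropertySelectionError("no complete properties to select from")

    vecs = np.array([p.vector() for p in usable])
    stds = vecs.std(axis=1)
    if np.any(stds == 0):
        bad = usable[int(np.argmin(stds))].accession
        raise PropertySelectionError(f"zero-variance property {bad}")
    corr = np.abs(np.atleast_2d(np.corrcoef(vecs)))
    np.fill_diagonal(corr, 0.0)

    exceed = (corr > threshold).sum(axis=1)
    order = sorted(range(len(usable)), key=lambda i: (-exceed[i], usable[i].accession))

    removed = np.zeros(len(usable), dtype=bool)
    survivors: list[int] = []
    for rank, i in enumerate(order):
        if removed[i]:
            continue
        survivors.append(i)
        for j in order[rank + 1 :]:
            if not removed[j] and corr[i, j] > threshold:
                removed[j] = True

    retained = tuple(usable[i] for i in survivors)
    provenance = {
        "input_count": len(props),
        "complete_count": len(usable),
        "threshold": threshold,
        "ordering": "exceedance count desc, accession asc",
        "retained_count": len(retained),
    }
    return PropertySet(retained, threshold, provenance)


def write_property_csv(pset: PropertySet, path) -> None:
    """Write a selected PropertySet as CSV with a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(
            "# selected amino-acid property scales; "
            + "; ".join(f"{k}={v}" for k, v in pset.provenance.items())
            + "\n"
        )
        fh.write("accession," + ",".join(AMINO_ACIDS) + "\n")
        for p in pset.properties:
            vals = ",".join(repr(float(p.values[a])) for a in AMINO_ACIDS)
            fh.write(f"{p.accession},{vals}\n")


def read_property_csv(path) -> PropertySet:
    """Read a PropertySet written by :func:`write_property_csv`."""
    props: list[AAIndexProperty] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("accession,"):
                continue
            parts = line.rstrip("\n").split(",")
            if len(parts) != 21:
                raise AAIndexParseError(f"bad property CSV row: {line!r}")
            values = {a: float(v) for a, v in zip(AMINO_ACIDS, parts[1:])}
            props.append(AAIndexProperty(parts[0], "", values))
    return PropertySet(tuple(props), threshold=float("nan"), provenance={"source": str(path)})
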