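"""Target-site representation and coordinate arithmetic for homing endonucleases.

A LAGLIDADG homing endonuclease (LHE) recognition site is a ~20 bp DNA
sequence. Positions are conventionally labelled with signed integers
relative to the central cleavage point: ``-L/2 .. -1`` for the 5' half and
``+1 .. +L/2`` for the 3' half, with no position 0. Differences between two
sites are described as mismatch labels such as ``-10G-8A`` (position -10 is
a G, position -8 an A, in the variant site).

Internally everything uses 0-based half-open indices; the signed labels are
a display/interchange convention and the mapping between the two is a
bijection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AlphabetError",
    "CoordinateError",
    "LengthMismatchError",
    "Mismatch",
    "MismatchSet",
    "PositionLabel",
    "SubstrateRecord",
    "TargetSite",
    "apply_mismatches",
    "build_substrate",
    "contains_site",
    "hamming",
    "index_to_label",
    "label_to_index",
    "mismatches",
    "reverse_complement",
]

DNA_BASES = "ACGT"
# IUPAC one-letter ambiguity codes; allowed only in genomic scans, where
# they always count as mismatches.
IUPAC_BASES = "ACGTNRYSWKMBDHV"

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


class AlphabetError(ValueError):
    """A sequence contains symbols outside the accepted alphabet."""


class LengthMismatchError(ValueError):
    """Two sites that must have equal length do not."""


class CoordinateError(ValueError):
    """A signed position label is 0 or outside the valid range for a site."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise LengthMismatchError(f"length {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def label_to_index(value: int, length: int) -> int:
    """Map a signed position label to a 0-based index.

    Labels run -L/2 .. -1, +1 .. +L/2 with no zero; -L/2 maps to index 0
    and +L/2 to index L-1.
    """
    half = length // 2
    if value == 0:
        raise CoordinateError("position 0 is not a valid label")
    if not -half <= value <= half:
        raise CoordinateError(f"label {value:+d} outside [-{half}, +{half}]")
    return value + half if value < 0 else value + half - 1


def index_to_label(idx: int, length: int) -> int:
    """Inverse of :func:`label_to_index`."""
    half = length // 2
    if not 0 <= idx < length:
        raise CoordinateError(f"index {idx} outside [0, {length})")
    return idx - half if idx < half else idx - half + 1


@dataclass(frozen=True, order=True)
class PositionLabel:
    """Signed, zero-free position label within a site of even length."""

    value: int

    def __post_init__(self) -> None:
        if self.value == 0:
            raise CoordinateError("position 0 is not a valid label")

    def to_index(self, length: int) -> int:
        return label_to_index(self.value, length)

    @classmethod
    def from_index(cls, idx: int, length: int) -> "PositionLabel":
        return cls(index_to_label(idx, length))

    def __str__(self) -> str:
        return f"{self.value:+d}"


@dataclass(frozen=True)
class TargetSite:
    """A nuclease recognition sequence.

    Sequences are normalized to uppercase; only A/C/G/T are accepted and the
    length must be even (the coordinate system is symmetric around the
    central cleavage point).
    """

    name: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2 or len(seq) % 2 != 0:
            raise ValueError(
                f"site {self.name!r}: length must be even and >= 2, got {len(seq)}"
            )
        bad = set(seq) - set(DNA_BASES)
        if bad:
            raise AlphabetError(
                f"site {self.name!r}: invalid symbols {sorted(bad)} (only A/C/G/T)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, label: int) -> str:
        """Reference base at a signed position label."""
        return self.sequence[label_to_index(label, self.length)]

    def labels(self) -> list[int]:
        """All signed labels, 5' to 3'."""
        return [index_to_label(i, self.length) for i in range(self.length)]


# Mismatch label grammar. The field prints a Unicode minus in figures and
# labels positive positions with an explicit "+"; we accept "-", Unicode
# minus, "+" and bare digits (treated as positive) and always emit ASCII
# with explicit signs.
_LABEL_TOKEN = re.compile(r"([+\-−]?\d+)([A-Z])")


@dataclass(frozen=True)
class Mismatch:
    """One variant base at a signed position."""

    position: int
    base: str

    def __post_init__(self) -> None:
        if self.position == 0:
            raise CoordinateError("position 0 is not a valid label")
        if self.base not in IUPAC_BASES:
            raise AlphabetError(f"invalid variant base {self.base!r}")

    def __str__(self) -> str:
        return f"{self.position:+d}{self.base}"


@dataclass(frozen=True)
class MismatchSet:
    """An ordered set of (position, variant base) differences from a site.

    The label string round-trips: ``"-10G-8A"`` <-> entries
    ``[(-10, G), (-8, A)]``.
    """

    entries: tuple[Mismatch, ...]
    relative_to: str = ""

    def __post_init__(self) -> None:
        positions = [e.position for e in self.entries]
        if any(b >= a for a, b in zip(positions[1:], positions)):
            raise ValueError(f"positions must be strictly increasing: {positions}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def label(self) -> str:
        """ASCII mismatch-label string, e.g. ``-10G-8A`` or ``+4T+8G``."""
        return "".join(str(e) for e in self.entries)

    @classmethod
    def parse(cls, text: str, relative_to: str = "") -> "MismatchSet":
        """Parse a mismatch-label string (ASCII or Unicode minus; bare
        numbers are positive)."""
        norm = text.replace("−", "-").strip()
        if norm == "":
            return cls(entries=(), relative_to=relative_to)
        pos = 0
        entries = []
        for m in _LABEL_TOKEN.finditer(norm):
            if m.start() != pos:
                raise ValueError(f"cannot parse mismatch label {text!r}")
            entries.append(Mismatch(int(m.group(1)), m.group(2)))
            pos = m.end()
        if pos != len(norm) or not entries:
            raise ValueError(f"cannot parse mismatch label {text!r}")
        return cls(entries=tuple(entries), relative_to=relative_to)


def mismatches(a: TargetSite, b: TargetSite) -> MismatchSet:
    """Differences between two equal-length sites, labelled with *b*'s bases.

    The entry count equals the Hamming distance between the two sequences.
    """
    if a.length != b.length:
        raise LengthMismatchError(
            f"{a.name} has length {a.length}, {b.name} has {b.length}"
        )
    entries = tuple(
        Mismatch(index_to_label(i, a.length), y)
        for i, (x, y) in enumerate(zip(a.sequence, b.sequence))
        if x != y
    )
    return MismatchSet(entries=entries, relative_to=a.name)


def apply_mismatches(site: TargetSite, m: MismatchSet) -> TargetSite:
    """Construct the variant site carrying exactly the given mismatches."""
    seq = list(site.sequence)
    for e in m:
        if e.base not in DNA_BASES:
            raise AlphabetError(f"cannot apply ambiguous base {e.base!r}")
        idx = label_to_index(e.position, site.length)
        if seq[idx] == e.base:
            raise ValueError(
                f"entry {e} equals the reference base at {e.position:+d}; not a mismatch"
            )
        seq[idx] = e.base
    name = site.name if len(m) == 0 else f"{site.name}_{m.label}"
    return replace(site, name=name, sequence="".join(seq))


@dataclass(frozen=True)
class SubstrateRecord:
    """A double-stranded oligo substrate: the recognition site centered
    between primer-binding flanks (default 16 bp per side, 52 bp total for
    a 20 bp site), with end labels for cleavage detection."""

    sequence: str
    site_span: tuple[int, int]
    flank_length: int
    labels: tuple[str, str] = ("5'-biotin", "3'-AlexaFluor647")

    def __post_init__(self) -> None:
        start, end = self.site_span
        site_len = end - start
        if len(self.sequence) != 2 * self.flank_length + site_len:
            raise ValueError("substrate length must be 2*flank + site length")
        if start != self.flank_length:
            raise ValueError("site must be centered between the flanks")

    @property
    def site_sequence(self) -> str:
        start, end = self.site_span
        return self.sequence[start:end]


def build_substrate(
    site: TargetSite, flank_length: int = 16, seed: int = 0
) -> SubstrateRecord:
    """Build a cleavage substrate with pseudo-random flanks.

    The actual primer-binding flank sequences are immaterial to the assays
    modelled here; only their length matters, so they are drawn
    deterministically from the seed.
    """
    if flank_length < 0:
        raise ValueError("flank_length must be >= 0")
    rng = np.random.default_rng(seed)
    bases = np.array(list(DNA_BASES))
    left = "".join(rng.choice(bases, size=flank_length))
    right = "".join(rng.choice(bases, size=flank_length))
    return SubstrateRecord(
        sequence=left + site.sequence + right,
        site_span=(flank_length, flank_length + site.length),
        flank_length=flank_length,
    )


def contains_site(composite: str, site: TargetSite) -> tuple[int, int] | None:
    """Leftmost exact occurrence of a site within a composite sequence, as a
    half-open interval, or None if absent."""
    idx = composite.upper().find(site.sequence)
    if idx < 0:
        return None
    return (idx, idx + site.length)
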