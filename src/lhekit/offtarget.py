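"""Genome-wide scanning for near-match nuclease cleavage sites.

Every window of target length on either strand whose Hamming distance to
the target is at most ``k_max`` is reported, annotated with its mismatch
labels and, when a specificity profile is supplied, a tolerance prediction
from the combination rule (every constituent single mismatch must be
individually tolerated).

The scan is a vectorized exact sliding comparison — no seeding heuristics —
so its output is definitionally complete for the chosen ``k_max``.
Ambiguity codes (N etc.) in the genome always count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sites import (
    Mismatch,
    MismatchSet,
    TargetSite,
    index_to_label,
    reverse_complement,
)
from .specificity import SpecificityProfile, predict_tolerance

__all__ = ["OfftargetHit", "annotate", "scan"]


@dataclass(frozen=True)
class OfftargetHit:
    """A genomic near-match of the target site.

    ``site_sequence`` is given in target orientation (reverse-complemented
    for minus-strand hits), so its mismatch labels read directly against
    the target.
    """

    chrom: str
    start: int
    end: int
    strand: str
    site_sequence: str
    mismatch_set: MismatchSet
    n_mismatches: int
    prediction: str = "unknown"
    per_mismatch_r: tuple[float, ...] | None = None

    @property
    def name(self) -> str:
        return self.mismatch_set.label or "exact"


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# every other symbol keeps code 255 and can never match an A/C/G/T target


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_mismatch_counts(codes: np.ndarray, target_codes: np.ndarray) -> np.ndarray:
    """Hamming distance of every length-L window against the target."""
    L = len(target_codes)
    n_win = len(codes) - L + 1
    counts = np.zeros(n_win, dtype=np.int32)
    for j in range(L):
        counts += codes[j : j + n_win] != target_codes[j]
    return counts


def _mismatch_set(candidate: str, target: TargetSite) -> MismatchSet:
    entries = tuple(
        Mismatch(index_to_label(i, target.length), c if c in "ACGTNRYSWKMBDHV" else "N")
        for i, (c, t) in enumerate(zip(candidate.upper(), target.sequence))
        if c != t
    )
    return MismatchSet(entries=entries, relative_to=target.name)


def scan(
    genome: dict[str, str], target: TargetSite, k_max: int
) -> list[OfftargetHit]:
    """Report every window within ``k_max`` mismatches on either strand.

    Hits are sorted by (chrom, start, strand). A window matching on both
    strands is reported once per strand — each orientation is a distinct
    binding mode. Overlapping windows are all reported.
    """
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if not genome:
        raise ValueError("genome is empty")
    L = target.length
    fwd = _encode(target.sequence)
    rev = _encode(reverse_complement(target.sequence))
    hits: list[OfftargetHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        if len(seq) < L:
            continue
        codes = _encode(seq)
        for strand, tcodes in (("+", fwd), ("-", rev)):
            counts = _window_mismatch_counts(codes, tcodes)
            for start in np.flatnonzero(counts <= k_max):
                start = int(start)
                window = seq[start : start + L]
                cand = window if strand == "+" else reverse_complement(window)
                mset = _mismatch_set(cand, target)
                hits.append(
                    OfftargetHit(
                        chrom=chrom,
                        start=start,
                        end=start + L,
                        strand=strand,
                        site_sequence=cand,
                        mismatch_set=mset,
                        n_mismatches=len(mset),
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def annotate(
    hits: list[OfftargetHit], profile: SpecificityProfile
) -> list[OfftargetHit]:
    """Attach tolerance predictions from a one-off profile to scan hits.

    Zero-mismatch hits are always tolerated; multi-mismatch hits follow the
    combination rule (all constituent single mismatches tolerated).
    """
    if hits and profile.site.length != len(hits[0].site_sequence):
        raise ValueError("profile site length does not match hit length")
    out = []
    for h in hits:
        pred = predict_tolerance(h.mismatch_set, profile)
        out.append(
            replace(
                h,
                prediction="tolerated" if pred.tolerated else "not_tolerated",
                per_mismatch_r=pred.per_entry_r,
            )
        )
    return out
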