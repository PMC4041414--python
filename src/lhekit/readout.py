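"""Amplicon-read classification and disruption/HDR/NHEJ rate estimation.

After a nuclease cleaves its genomic target, mutagenic end joining (NHEJ)
leaves small insertions/deletions concentrated at the cleavage point —
for LAGLIDADG enzymes, within the central four bases of the recognition
site — while homology-directed repair (HDR) converts the locus to a donor
template. Each sequenced amplicon read is therefore classified as:

* ``HDR``    — every donor-signature base matches and no indel touches the
  cut window;
* ``NHEJ``   — at least one indel's reference footprint intersects the cut
  window;
* ``intact`` — neither (substitutions alone never count as disruption,
  because sequencing/PCR error would inflate rates);
* ``fail``   — the read could not be aligned confidently.

Rates over non-failed reads are reported with Wilson 95% confidence
intervals, which behave sensibly at the small read counts (tens of clones)
typical of cloned-amplicon sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from statsmodels.stats.proportion import proportion_confint

from .sites import reverse_complement

__all__ = [
    "AlignParams",
    "AlignmentResult",
    "AmpliconRef",
    "DisruptionSummary",
    "FoldChange",
    "Indel",
    "ReadCall",
    "align_read",
    "classify_read",
    "classify_reads",
    "fold_change",
    "summarize",
]


@dataclass(frozen=True)
class AmpliconRef:
    """Reference amplicon with the recognition-site and cut-window spans.

    ``cut_window`` defaults to the central four bases of the site (the
    positions -2,-1,+1,+2 straddling the cleavage point), where LHE-induced
    deletions concentrate. ``donor_signature`` lists (reference index,
    expected base) pairs that distinguish an HDR-converted read.
    """

    sequence: str
    site_span: tuple[int, int]
    cut_window: tuple[int, int] | None = None
    donor_signature: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        s0, s1 = self.site_span
        if not (0 <= s0 < s1 <= len(seq)):
            raise ValueError("site_span outside amplicon")
        if self.cut_window is None:
            center = (s0 + s1) // 2
            object.__setattr__(self, "cut_window", (center - 2, center + 2))
        c0, c1 = self.cut_window
        if not (s0 <= c0 < c1 <= s1):
            raise ValueError("cut_window must lie within site_span")
        object.__setattr__(self, "donor_signature", tuple(self.donor_signature))


@dataclass(frozen=True)
class AlignParams:
    """Global affine-gap alignment parameters (fixed for determinism)."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    min_read_length: int = 50
    score_floor_per_base: float = 0.0  # mean per-read-base score below this -> fail


@dataclass(frozen=True)
class Indel:
    """An indel in reference coordinates, reported at its left-aligned
    (canonical) placement. ``amb_end`` is the exclusive end of the
    rightmost equivalent placement, so [start, amb_end) is the full
    equivalence footprint used for cut-window intersection — this makes
    classification invariant to where a homopolymer indel was placed."""

    kind: str  # "ins" | "del"
    start: int  # reference coordinate (for ins: inserted before ref[start])
    length: int
    inserted: str = ""
    amb_end: int = -1

    def __post_init__(self) -> None:
        if self.amb_end < 0:
            object.__setattr__(
                self, "amb_end", self.start + (self.length if self.kind == "del" else 0)
            )


@dataclass
class AlignmentResult:
    score: float
    orientation: str  # "+" if the read aligned as given, "-" if reverse-complemented
    indels: list[Indel]
    ref_to_read_base: dict[int, str]
    failed: bool = False


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _left_align_deletion(ref: str, start: int, length: int) -> int:
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_align_insertion(ref: str, start: int, inserted: str) -> tuple[int, str]:
    while start > 0 and inserted and inserted[-1] == ref[start - 1]:
        inserted = ref[start - 1] + inserted[:-1]
        start -= 1
    return start, inserted


def _right_extent_deletion(ref: str, start: int, length: int) -> int:
    """Exclusive end of the rightmost placement equivalent to deleting
    ref[start:start+length]."""
    s = start
    while s + length < len(ref) and ref[s] == ref[s + length]:
        s += 1
    return s + length


def _right_extent_insertion(ref: str, start: int, inserted: str) -> int:
    """Rightmost reference position at which the same insertion could be
    placed."""
    s, t = start, inserted
    while t and s < len(ref) and t[0] == ref[s]:
        t = t[1:] + ref[s]
        s += 1
    return s


def _extract(alignment, ref: str, read: str) -> tuple[list[Indel], dict[int, str]]:
    """Indels (left-aligned) and per-reference-base read calls from one
    global alignment."""
    ref_blocks, read_blocks = alignment.aligned
    indels: list[Indel] = []
    ref_to_read: dict[int, str] = {}
    prev_r, prev_q = 0, 0
    boundaries = list(zip(ref_blocks, read_blocks)) + [
        ((len(ref), len(ref)), (len(read), len(read)))
    ]
    for (r0, r1), (q0, q1) in boundaries:
        dr, dq = r0 - prev_r, q0 - prev_q
        if dq > 0:
            s, ins = _left_align_insertion(ref, prev_r, read[prev_q : prev_q + dq])
            indels.append(
                Indel("ins", s, dq, ins, amb_end=_right_extent_insertion(ref, s, ins))
            )
        if dr > 0:
            s = _left_align_deletion(ref, prev_r, dr)
            indels.append(
                Indel("del", s, dr, amb_end=_right_extent_deletion(ref, s, dr))
            )
        for i in range(r1 - r0):
            ref_to_read[r0 + i] = read[q0 + i]
        prev_r, prev_q = r1, q1
    return indels, ref_to_read


def align_read(
    read: str, ref: AmpliconRef, params: AlignParams = AlignParams()
) -> AlignmentResult:
    """Globally align a read against the amplicon, auto-detecting
    orientation; indels are left-aligned to a canonical placement."""
    read = read.upper()
    if len(read) < params.min_read_length:
        return AlignmentResult(float("-inf"), "+", [], {}, failed=True)
    aligner = _make_aligner(params)
    best = None
    for orientation, seq in (("+", read), ("-", reverse_complement(read))):
        score = aligner.score(ref.sequence, seq)
        if best is None or score > best[0]:
            best = (score, orientation, seq)
    score, orientation, seq = best
    if score / max(len(read), 1) < params.score_floor_per_base:
        return AlignmentResult(score, orientation, [], {}, failed=True)
    alignment = aligner.align(ref.sequence, seq)[0]
    indels, ref_to_read = _extract(alignment, ref.sequence, seq)
    return AlignmentResult(score, orientation, indels, ref_to_read)


def _intersects_window(indel: Indel, window: tuple[int, int]) -> bool:
    """Does any equivalent placement of the indel touch the window?"""
    a, b = window
    if indel.kind == "del":
        return indel.start < b and indel.amb_end > a
    # insertion: a point event between bases; boundary placements count
    return a <= indel.amb_end and indel.start <= b


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    call: str  # "intact" | "NHEJ" | "HDR" | "fail"
    indels: tuple[Indel, ...] = ()
    alignment_score: float = float("nan")
    orientation: str = "+"


def classify_read(
    read: str,
    ref: AmpliconRef,
    read_id: str = "",
    params: AlignParams = AlignParams(),
) -> ReadCall:
    """Classify one read as intact / NHEJ / HDR / fail (see module docs)."""
    aln = align_read(read, ref, params)
    if aln.failed:
        return ReadCall(read_id, "fail", alignment_score=aln.score)
    cut_hit = any(_intersects_window(i, ref.cut_window) for i in aln.indels)
    if ref.donor_signature and not cut_hit:
        if all(aln.ref_to_read_base.get(i) == b for i, b in ref.donor_signature):
            return ReadCall(read_id, "HDR", tuple(aln.indels), aln.score, aln.orientation)
    call = "NHEJ" if cut_hit else "intact"
    return ReadCall(read_id, call, tuple(aln.indels), aln.score, aln.orientation)


def classify_reads(
    reads: list[tuple[str, str]], ref: AmpliconRef, params: AlignParams = AlignParams()
) -> list[ReadCall]:
    """Classify (read_id, sequence) pairs; one call per read."""
    return [classify_read(seq, ref, rid, params) for rid, seq in reads]


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class DisruptionSummary:
    """Aggregated rates over non-failed reads with Wilson 95% CIs."""

    n_total: int
    n_disrupted: int
    n_hdr: int | None = None
    n_fail: int = 0

    @property
    def rate(self) -> float:
        return self.n_disrupted / self.n_total

    @property
    def rate_pct(self) -> float:
        """Disruption rate as a percentage, one decimal place."""
        return round(100 * self.rate, 1)

    @property
    def ci(self) -> tuple[float, float]:
        return _wilson(self.n_disrupted, self.n_total)

    @property
    def hdr_rate(self) -> float | None:
        return None if self.n_hdr is None else self.n_hdr / self.n_total

    @property
    def hdr_ci(self) -> tuple[float, float] | None:
        return None if self.n_hdr is None else _wilson(self.n_hdr, self.n_total)

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_disrupted": self.n_disrupted,
            "n_fail": self.n_fail,
            "disruption_rate": self.rate,
            "disruption_rate_pct": self.rate_pct,
            "disruption_ci95": list(self.ci),
        }
        if self.n_hdr is not None:
            d["n_hdr"] = self.n_hdr
            d["hdr_rate"] = self.hdr_rate
            d["hdr_rate_pct"] = round(100 * self.hdr_rate, 1)
            d["hdr_ci95"] = list(self.hdr_ci)
        return d


def summarize(calls: list[ReadCall], donor: bool = False) -> DisruptionSummary:
    """Aggregate read calls; disruption = NHEJ fraction of non-failed reads.

    The HDR rate is reported separately when a donor signature was in play
    (``donor=True``) or any HDR call is present.
    """
    ok = [c for c in calls if c.call != "fail"]
    n_fail = len(calls) - len(ok)
    if not ok:
        raise ValueError("all reads failed alignment; nothing to summarize")
    n_nhej = sum(c.call == "NHEJ" for c in ok)
    n_hdr = sum(c.call == "HDR" for c in ok)
    return DisruptionSummary(
        n_total=len(ok),
        n_disrupted=n_nhej,
        n_hdr=n_hdr if (donor or n_hdr > 0) else None,
        n_fail=n_fail,
    )


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two disruption rates; flagged (not raised) when the
    denominator rate is zero."""

    ratio: float
    undefined: bool = False


def fold_change(a: DisruptionSummary, b: DisruptionSummary) -> FoldChange:
    """a.rate / b.rate, e.g. on-target over off-target disruption."""
    if b.rate == 0:
        return FoldChange(float("inf"), undefined=True)
    return FoldChange(a.rate / b.rate)
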