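"""One-off cleavage specificity profiles and mismatch-tolerance prediction.

A "one-off" profile measures an enzyme's cleavage of every single-base
substituted variant of its target site (3L variants for a site of length L),
normalized so the on-target sequence scores exactly 1. With a tolerance
threshold theta (default 0.5, i.e. 50% of on-target cleavage):

* a position is *degenerate* if at least one alternative base there exceeds
  theta, otherwise *specific*;
* a single mismatch is *tolerated* if its relative cleavage r exceeds theta
  (strictly: r = theta is not tolerated);
* a multi-mismatch candidate site is predicted *tolerated* only when every
  constituent single mismatch is individually tolerated.

The last rule is the combination rule used to triage genomic near-match
sites found by :mod:`lhekit.offtarget`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .sites import (
    DNA_BASES,
    Mismatch,
    MismatchSet,
    TargetSite,
    apply_mismatches,
    index_to_label,
)

__all__ = [
    "ProfileStateError",
    "SpecificityProfile",
    "TolerancePrediction",
    "classify_positions",
    "combined_score",
    "enumerate_one_off",
    "normalize_profile",
    "predict_tolerance",
    "tolerated_single_mismatches",
]


class ProfileStateError(ValueError):
    """Operation requires a normalized profile."""


Cell = tuple[int, str]  # (signed position label, alternative base)


@dataclass(frozen=True)
class SpecificityProfile:
    """Per-position, per-alternative-base relative cleavage matrix.

    ``r[(label, base)]`` is the cleavage of the one-off variant with
    ``base`` at ``label``, as a fraction of on-target cleavage; the
    reference base at every position implicitly has r = 1 after
    normalization. ``se``/``n`` optionally carry per-cell standard errors
    and replicate counts; classification uses point estimates only.
    """

    enzyme: str
    site: TargetSite
    r: dict[Cell, float]
    theta: float = 0.5
    normalized: bool = True
    se: dict[Cell, float] = field(default_factory=dict)
    n: dict[Cell, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = {
            (label, b)
            for label in self.site.labels()
            for b in DNA_BASES
            if b != self.site.base_at(label)
        }
        if set(self.r) != expected:
            missing = expected - set(self.r)
            extra = set(self.r) - expected
            raise ValueError(
                f"profile must have exactly 3 alternative-base cells per position; "
                f"missing={sorted(missing)[:4]} extra={sorted(extra)[:4]}"
            )
        if any(v < 0 for v in self.r.values()):
            raise ValueError("relative cleavage values must be >= 0")
        if not 0 <= self.theta:
            raise ValueError("theta must be >= 0")

    def cells(self) -> list[Cell]:
        """All cells, position ascending then base A<C<G<T."""
        return sorted(self.r, key=lambda c: (self.site.labels().index(c[0]), c[1]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "position_label": f"{label:+d}",
                "alt_base": base,
                "r": self.r[(label, base)],
                "se": self.se.get((label, base), float("nan")),
                "n": self.n.get((label, base), 0),
            }
            for (label, base) in self.cells()
        ]
        return pd.DataFrame(rows)


def enumerate_one_off(site: TargetSite) -> list[tuple[MismatchSet, TargetSite]]:
    """All 3L single-base variants of a site, in deterministic order
    (position ascending, base A<C<G<T)."""
    out = []
    for idx in range(site.length):
        label = index_to_label(idx, site.length)
        for base in DNA_BASES:
            if base == site.sequence[idx]:
                continue
            m = MismatchSet(entries=(Mismatch(label, base),), relative_to=site.name)
            out.append((m, apply_mismatches(site, m)))
    return out


def normalize_profile(
    raw: dict[Cell, float],
    on_target: float,
    site: TargetSite,
    enzyme: str = "",
    theta: float = 0.5,
    se: dict[Cell, float] | None = None,
    n: dict[Cell, int] | None = None,
) -> SpecificityProfile:
    """Normalize raw per-variant cleavage fractions to the on-target value."""
    if on_target <= 0:
        raise ZeroDivisionError(
            "on-target cleavage must be > 0 to normalize a profile"
        )
    if any(v < 0 for v in raw.values()):
        raise ValueError("raw cleavage values must be >= 0")
    r = {cell: v / on_target for cell, v in raw.items()}
    se_scaled = {cell: v / on_target for cell, v in (se or {}).items()}
    return SpecificityProfile(
        enzyme=enzyme,
        site=site,
        r=r,
        theta=theta,
        normalized=True,
        se=se_scaled,
        n=dict(n or {}),
    )


def classify_positions(p: SpecificityProfile) -> dict[str, list[int]]:
    """Partition the site's positions into specific vs degenerate.

    A position is degenerate iff at least one of its three alternative
    bases has r strictly greater than theta.
    """
    if not p.normalized:
        raise ProfileStateError("profile must be normalized before classification")
    specific, degenerate = [], []
    for label in p.site.labels():
        worst = max(
            p.r[(label, b)] for b in DNA_BASES if b != p.site.base_at(label)
        )
        (degenerate if worst > p.theta else specific).append(label)
    return {"specific": specific, "degenerate": degenerate}


def tolerated_single_mismatches(p: SpecificityProfile) -> set[Cell]:
    """Cells with relative cleavage strictly above theta."""
    if not p.normalized:
        raise ProfileStateError("profile must be normalized")
    return {cell for cell, v in p.r.items() if v > p.theta}


@dataclass(frozen=True)
class TolerancePrediction:
    """Outcome of the tolerance-combination rule for one candidate site."""

    call: str  # "tolerated" | "not_tolerated"
    per_entry_r: tuple[float, ...]

    @property
    def tolerated(self) -> bool:
        return self.call == "tolerated"


def predict_tolerance(m: MismatchSet, p: SpecificityProfile) -> TolerancePrediction:
    """Predict whether a multi-mismatch site is cleavable.

    Tolerated iff every entry is individually tolerated in the one-off
    profile; the empty set (the on-target site) is always tolerated. Entries
    whose base is not a profile cell (e.g. an N from a genomic scan) are
    treated as not tolerated.
    """
    rs = []
    ok = True
    for e in m:
        if e.base == p.site.base_at(e.position):
            raise ValueError(
                f"entry {e} equals the reference base; not a valid mismatch"
            )
        r = p.r.get((e.position, e.base))
        if r is None:  # ambiguous genomic base: conservatively intolerant
            rs.append(0.0)
            ok = False
        else:
            rs.append(r)
            ok = ok and r > p.theta
    return TolerancePrediction(
        call="tolerated" if ok else "not_tolerated", per_entry_r=tuple(rs)
    )


def combined_score(m: MismatchSet, p: SpecificityProfile) -> float:
    """Optional quantitative multi-mismatch score: product of per-entry r
    under an independence assumption. Reported alongside, never used by,
    the binary combination rule."""
    return math.prod(p.r.get((e.position, e.base), 0.0) for e in m)
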