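"""Seeded synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: random genomes
with planted near-match sites, one-off specificity profiles with a chosen
tolerated-cell set, amplicon reads with cut-site indels and sequencing
error, saturation-binding titrations, and multi-population flow-event
tables. Each generator is a pure function of (parameters, seed) and
returns the artifact together with a :class:`GroundTruth` record, so
recovery tests can compare pipeline output against known truth.

Seed discipline: a single master seed is split into per-component child
seeds via ``numpy.random.SeedSequence([master, crc32(component_name)])``,
so components are decorrelated but individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .assays import BindingTitration, FlowEventSet, binding_model
from .offtarget import scan
from .readout import AmpliconRef
from .sites import DNA_BASES, MismatchSet, TargetSite, apply_mismatches, reverse_complement
from .specificity import Cell, SpecificityProfile

import pandas as pd

__all__ = [
    "GenerationError",
    "GroundTruth",
    "child_seed",
    "gen_flow_events",
    "gen_genome",
    "gen_profile",
    "gen_reads",
    "gen_titration",
]


class GenerationError(RuntimeError):
    """Rejection sampling failed within the attempt budget; retry with a
    different seed."""


def child_seed(master: int, component: str) -> int:
    """Derive a per-component child seed from the master seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(component.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class GroundTruth:
    """What a generator planted, serialized alongside every dataset."""

    kind: str
    seed: int
    params: dict
    truth: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# genomes with planted near-match sites


def gen_genome(
    length: int,
    target: TargetSite,
    plants: list[tuple[MismatchSet, str]],
    k_max: int = 2,
    gc: float = 0.5,
    seed: int = 0,
    chrom: str = "chr1",
    max_attempts: int = 50,
) -> tuple[dict[str, str], GroundTruth]:
    """Random genome with planted target variants at recorded loci.

    The iid background (given GC content) is rejection-sampled until it
    contains no window within ``k_max`` mismatches of the target other
    than the planted ones, so a subsequent scan at that ``k_max`` must
    recover exactly the planted loci. Plants are placed non-overlapping
    with at least one site length of separation.
    """
    L = target.length
    if length < max(1, len(plants)) * L * 10:
        raise ValueError("genome too short for the requested plants")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), attempt, zlib.crc32(b"genome")])
        )
        seq = rng.choice(bases, size=length, p=probs)
        # non-overlapping plant positions with >= L separation
        starts: list[int] = []
        guard = 0
        while len(starts) < len(plants) and guard < 10_000:
            cand = int(rng.integers(0, length - L + 1))
            if all(abs(cand - s) >= 2 * L for s in starts):
                starts.append(cand)
            guard += 1
        if len(starts) < len(plants):
            continue
        planted = []
        for (mset, strand), start in zip(plants, starts):
            variant = apply_mismatches(target, mset).sequence
            ins = variant if strand == "+" else reverse_complement(variant)
            seq[start : start + L] = list(ins)
            planted.append(
                {"chrom": chrom, "start": start, "strand": strand, "label": mset.label}
            )
        genome = {chrom: "".join(seq)}
        hits = scan(genome, target, k_max)
        expected = {
            (p["start"], p["strand"])
            for p, (mset, _) in zip(planted, plants)
            if len(mset) <= k_max
        }
        extra = {(h.start, h.strand) for h in hits} - expected
        if not extra:
            truth = GroundTruth(
                kind="genome",
                seed=seed,
                params={
                    "length": length, "gc": gc, "k_max": k_max,
                    "target": target.sequence, "chrom": chrom,
                },
                truth={"planted": sorted(planted, key=lambda p: p["start"])},
            )
            return genome, truth
    raise GenerationError(
        f"could not generate a clean background in {max_attempts} attempts; "
        "retry with a new seed"
    )


# ---------------------------------------------------------------------------
# specificity profiles with a designated tolerated-cell set


def gen_profile(
    site: TargetSite,
    tolerated_cells: set[Cell],
    theta: float = 0.5,
    seed: int = 0,
    enzyme: str = "synthetic",
    eps: float = 0.05,
) -> tuple[SpecificityProfile, GroundTruth]:
    """Profile whose tolerated set is exactly ``tolerated_cells``.

    Tolerated cells draw r ~ U(theta+eps, 1.2); all others draw
    r ~ U(0, theta-eps), so classification at theta is unambiguous.
    """
    rng = np.random.default_rng(child_seed(seed, "profile"))
    r: dict[Cell, float] = {}
    for label in site.labels():
        for base in DNA_BASES:
            if base == site.base_at(label):
                continue
            if (label, base) in tolerated_cells:
                r[(label, base)] = float(rng.uniform(theta + eps, 1.2))
            else:
                r[(label, base)] = float(rng.uniform(0, theta - eps))
    bad = tolerated_cells - set(r)
    if bad:
        raise ValueError(f"tolerated cells not valid for this site: {sorted(bad)}")
    profile = SpecificityProfile(enzyme=enzyme, site=site, r=r, theta=theta)
    truth = GroundTruth(
        kind="profile",
        seed=seed,
        params={"site": site.sequence, "theta": theta, "eps": eps},
        truth={
            "tolerated_cells": sorted(f"{p:+d}{b}" for p, b in tolerated_cells),
            "r": {f"{p:+d}{b}": v for (p, b), v in sorted(r.items())},
        },
    )
    return profile, truth


# ---------------------------------------------------------------------------
# amplicon reads


def _default_indel(rng: np.random.Generator, insertion_fraction: float = 0.1):
    """Default mutagenic-NHEJ event: deletions of 1-10 bp (uniform) centered
    at the cut site; 10% insertions of 1-3 bp."""
    if rng.uniform() < insertion_fraction:
        return ("ins", int(rng.integers(1, 4)))
    return ("del", int(rng.integers(1, 11)))


def gen_reads(
    ref: AmpliconRef,
    n: int,
    p_nhej: float,
    p_hdr: float = 0.0,
    err_rate: float = 0.0,
    seed: int = 0,
    binomial: bool = False,
    insertion_fraction: float = 0.1,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Amplicon reads with planted NHEJ/HDR events and substitution error.

    Counts are deterministic (round(n*p)) by default — observed clone
    counts are fixed numbers, not draws — with a ``binomial`` mode for
    CI-coverage studies. NHEJ reads carry an indel at the cut-window
    center; HDR reads carry the donor signature; every read then receives
    iid substitution errors at ``err_rate`` per base.
    """
    if p_nhej + p_hdr > 1:
        raise ValueError("p_nhej + p_hdr must be <= 1")
    if p_hdr > 0 and not ref.donor_signature:
        raise ValueError("HDR reads require a donor_signature on the reference")
    rng = np.random.default_rng(child_seed(seed, "reads"))
    if binomial:
        kinds = rng.choice(
            ["NHEJ", "HDR", "intact"], size=n, p=[p_nhej, p_hdr, 1 - p_nhej - p_hdr]
        ).tolist()
    else:
        n_nhej = int(round(n * p_nhej))
        n_hdr = int(round(n * p_hdr))
        kinds = ["NHEJ"] * n_nhej + ["HDR"] * n_hdr + ["intact"] * (n - n_nhej - n_hdr)
        rng.shuffle(kinds)
    c0, c1 = ref.cut_window
    center = (c0 + c1) // 2
    reads: list[tuple[str, str]] = []
    per_read = []
    bases = np.array(list(DNA_BASES))
    for i, kind in enumerate(kinds):
        seq = list(ref.sequence)
        event = None
        if kind == "NHEJ":
            op, size = _default_indel(rng, insertion_fraction)
            if op == "del":
                start = max(0, center - size // 2)
                event = {"type": "del", "start": start, "length": size}
                del seq[start : start + size]
            else:
                ins = "".join(rng.choice(bases, size=size))
                event = {"type": "ins", "start": center, "length": size, "seq": ins}
                seq[center:center] = list(ins)
        elif kind == "HDR":
            for idx, base in ref.donor_signature:
                seq[idx] = base
            event = {"type": "hdr"}
        arr = np.array(seq)
        if err_rate > 0:
            hit = np.flatnonzero(rng.uniform(size=len(arr)) < err_rate)
            for j in hit:
                alt = [b for b in DNA_BASES if b != arr[j]]
                arr[j] = alt[int(rng.integers(0, 3))]
        rid = f"read{i:05d}"
        reads.append((rid, "".join(arr)))
        per_read.append({"read_id": rid, "class": kind, "event": event})
    truth = GroundTruth(
        kind="reads",
        seed=seed,
        params={
            "n": n, "p_nhej": p_nhej, "p_hdr": p_hdr, "err_rate": err_rate,
            "binomial": binomial,
        },
        truth={
            "per_read": per_read,
            "n_nhej": sum(k == "NHEJ" for k in kinds),
            "n_hdr": sum(k == "HDR" for k in kinds),
        },
    )
    return reads, truth


# ---------------------------------------------------------------------------
# binding titrations


def gen_titration(
    kd: float,
    fmax: float,
    f0: float,
    concentrations: tuple[float, ...] | None = None,
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[BindingTitration, GroundTruth]:
    """Saturation titration from the 1:1 isotherm with Gaussian noise of
    standard deviation ``sigma * Fmax``. Default design: 8 log-spaced
    concentrations spanning 1-500 nM."""
    if kd <= 0 or fmax <= 0 or sigma < 0:
        raise ValueError("require kd > 0, fmax > 0, sigma >= 0")
    if concentrations is None:
        concentrations = tuple(np.geomspace(1.0, 500.0, 8))
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(child_seed(seed, "titration"))
    y = binding_model(c, kd, fmax, f0) + rng.normal(0, sigma * fmax, size=len(c))
    t = BindingTitration(tuple(c), tuple(np.maximum(y, 0.0)))
    truth = GroundTruth(
        kind="titration",
        seed=seed,
        params={"concentrations": list(map(float, c)), "sigma": sigma},
        truth={"kd": kd, "fmax": fmax, "f0": f0},
    )
    return t, truth


# ---------------------------------------------------------------------------
# flow events


def gen_flow_events(
    populations: list[tuple[float, dict[str, tuple[float, float]]]],
    n: int,
    seed: int = 0,
) -> tuple[FlowEventSet, GroundTruth]:
    """Mixture of lognormal populations: each entry is (fraction,
    {channel: (mean_log10, sd_log10)}). Per-population counts are
    deterministic (round(n*fraction)); events are shuffled."""
    fracs = [f for f, _ in populations]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("population fractions must sum to 1")
    channels = sorted({ch for _, params in populations for ch in params})
    rng = np.random.default_rng(child_seed(seed, "flow"))
    counts = [int(round(n * f)) for f in fracs]
    counts[-1] += n - sum(counts)
    frames = []
    for (_, params), k in zip(populations, counts):
        cols = {}
        for ch in channels:
            mu, sd = params.get(ch, (0.0, 0.1))
            cols[ch] = 10 ** rng.normal(mu, sd, size=k)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    truth = GroundTruth(
        kind="flow",
        seed=seed,
        params={"n": n, "channels": channels},
        truth={"fractions": fracs, "counts": counts},
    )
    return FlowEventSet(df), truth
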