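"""Quantification of flow-cytometry and gel readouts for nuclease assays.

Covers the non-sequencing readouts of a surface-display cleavage platform:

* **yeast-surface cleavage index** — fluorophore-labelled dsOligo substrate
  is tethered to displaying cells; in Mg2+ the enzyme cleaves and the 3'
  label is released, while Ca2+ supports binding but not catalysis and
  serves as the uncleaved control. Cleavage = 1 - median(Mg)/median(Ca) on
  expression-gated events.
* **traffic-light reporter (TLR) fractions** — mutagenic NHEJ makes cells
  mCherry+, HDR with a donor makes them GFP+, both scored within a
  nuclease-expression (BFP+) gate.
* **gel cleavage fraction** — cleaved band over total substrate.
* **saturation-binding Kd** — the 1:1 site-binding isotherm
  ``F(c) = F0 + Fmax * c / (Kd + c)`` fitted to median-fluorescence
  titrations by Levenberg-Marquardt least squares with multi-start
  initialization.

Flow summaries use medians throughout (robust to the heavy right tails of
fluorescence distributions); fractions carry Wilson 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "BindingFit",
    "BindingTitration",
    "FlowEventSet",
    "GateResult",
    "binding_model",
    "cleavage_index",
    "expression_band_gate",
    "fit_binding",
    "gate_from_negative_control",
    "gel_fraction",
    "tlr_fractions",
]


@dataclass
class FlowEventSet:
    """Per-event channel intensities (one row per event, one column per
    channel); all intensities must be non-negative."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("event set must contain at least one event")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def gate_from_negative_control(
    control: FlowEventSet, channel: str, quantile: float = 0.995
) -> float:
    """Positivity threshold: the given quantile of a negative control."""
    return float(control.data[channel].quantile(quantile))


def expression_band_gate(
    events: FlowEventSet, channel: str, fraction: float = 0.10
) -> tuple[float, float]:
    """Band around the median expression capturing ~``fraction`` of events,
    used to compare populations at matched surface-expression level."""
    lo_q, hi_q = 0.5 - fraction / 2, 0.5 + fraction / 2
    col = events.data[channel]
    return float(col.quantile(lo_q)), float(col.quantile(hi_q))


def cleavage_index(
    mg: FlowEventSet, ca: FlowEventSet, channel: str = "A647"
) -> float:
    """Surface-cleavage index = 1 - median(substrate, Mg)/median(substrate, Ca).

    Both event sets must already be gated on equal expression; the Ca2+
    condition is the binding-only (uncleaved) control. The index is clamped
    to [0, 1] — small negative values from noise and values above 1 carry
    no physical meaning.
    """
    med_ca = float(ca.data[channel].median())
    if med_ca == 0:
        raise ZeroDivisionError(
            "Ca2+ control median is zero: control failure, index undefined"
        )
    med_mg = float(mg.data[channel].median())
    return float(np.clip(1.0 - med_mg / med_ca, 0.0, 1.0))


@dataclass(frozen=True)
class GateResult:
    """Gated fractions with Wilson 95% CIs."""

    gate: dict
    n_events: int
    n_in_gate: int
    fractions: dict[str, float]
    ci: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "gate": self.gate,
            "n_events": self.n_events,
            "n_in_gate": self.n_in_gate,
            "fractions": self.fractions,
            "ci95": {k: list(v) for k, v in self.ci.items()},
        }


def tlr_fractions(
    events: FlowEventSet,
    thresholds: dict[str, float],
    expression_channel: str = "BFP",
    nhej_channel: str = "mCherry",
    hdr_channel: str = "GFP",
    mock: bool = False,
) -> GateResult:
    """Traffic-light reporter fractions.

    NHEJ fraction = mCherry+ / BFP+; HDR fraction = GFP+ / BFP+ when a GFP
    channel is present. In ``mock`` mode (untransfected control, no
    expression marker) fractions are computed within the total population.
    """
    df = events.data
    use_gate = not mock and expression_channel in df.columns
    if use_gate:
        gated = df[df[expression_channel] > thresholds[expression_channel]]
        if len(gated) == 0:
            raise ValueError("empty expression gate: no BFP+ events")
    else:
        gated = df
    n = len(gated)
    fractions: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    counts: dict[str, int] = {}
    for label, chan in (("NHEJ", nhej_channel), ("HDR", hdr_channel)):
        if chan in gated.columns and chan in thresholds:
            k = int((gated[chan] > thresholds[chan]).sum())
            counts[label] = k
            fractions[label] = k / n
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            ci[label] = (float(lo), float(hi))
    if "NHEJ" in fractions and "HDR" in fractions:
        both = int(
            (
                (gated[nhej_channel] > thresholds[nhej_channel])
                & (gated[hdr_channel] > thresholds[hdr_channel])
            ).sum()
        )
        fractions["unmodified"] = (n - counts["NHEJ"] - counts["HDR"] + both) / n
    return GateResult(
        gate={
            "expression_channel": expression_channel if use_gate else None,
            "thresholds": thresholds,
            "mock": mock,
        },
        n_events=len(df),
        n_in_gate=n,
        fractions=fractions,
        ci=ci,
    )


def gel_fraction(cleaved: float, uncut: float) -> float:
    """Fraction cleaved = cleaved / (cleaved + uncut) from band intensities."""
    if cleaved < 0 or uncut < 0:
        raise ValueError("band intensities must be >= 0")
    total = cleaved + uncut
    if total == 0:
        raise ZeroDivisionError("both band intensities are zero; fraction undefined")
    return cleaved / total


@dataclass(frozen=True)
class BindingTitration:
    """A saturation-binding titration: ligand concentrations (nM, ascending,
    positive) and median fluorescence responses (arbitrary units)."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if len(c) != len(r):
            raise ValueError("concentrations and responses must have equal length")
        if len(c) < 4:
            raise ValueError("need >= 4 titration points to fit")
        if (c <= 0).any():
            raise ValueError("concentrations must be > 0")
        if (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be strictly ascending")
        object.__setattr__(self, "concentrations", tuple(map(float, c)))
        object.__setattr__(self, "responses", tuple(map(float, r)))


def binding_model(c: np.ndarray, kd: float, fmax: float, f0: float) -> np.ndarray:
    """1:1 site-binding isotherm without ligand depletion."""
    c = np.asarray(c, dtype=float)
    return f0 + fmax * c / (kd + c)


@dataclass(frozen=True)
class BindingFit:
    """Result of fitting the saturation isotherm."""

    kd: float
    fmax: float
    f0: float
    rss: float
    converged: bool
    warnings: tuple[str, ...] = ()


def fit_binding(t: BindingTitration) -> BindingFit:
    """Least-squares fit of F(c) = F0 + Fmax*c/(Kd+c) (Levenberg-Marquardt,
    multi-start over Kd), with honest convergence and identifiability flags.

    Warnings are attached when the design cannot pin Kd down: a flat
    titration (Fmax ~ 0), a Kd estimate far outside the sampled
    concentration range, or concentrations spanning less than one order of
    magnitude.
    """
    c = np.asarray(t.concentrations)
    y = np.asarray(t.responses)
    scale = max(float(np.ptp(y)), 1e-12)
    f0_init = float(np.min(y))

    def residuals(params):
        kd, fmax, f0 = params
        return binding_model(c, kd, fmax, f0) - y

    best = None
    for kd0 in np.geomspace(c.min() / 10, c.max() * 10, 7):
        try:
            sol = least_squares(
                residuals,
                x0=[kd0, float(np.max(y) - np.min(y)) or scale, f0_init],
                method="lm",
                max_nfev=10_000,
            )
        except Exception:
            continue
        if sol.x[0] <= 0:  # LM is unconstrained; reject unphysical optima
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12 * scale**2:
            best = (rss, sol)
    if best is None:
        return BindingFit(
            kd=float("nan"), fmax=float("nan"), f0=float("nan"),
            rss=float("inf"), converged=False,
            warnings=("no positive-Kd optimum found from any start",),
        )
    rss, sol = best
    kd, fmax, f0 = map(float, sol.x)
    warns: list[str] = []
    if abs(fmax) < 1e-3 * scale or np.ptp(y) < 1e-9:
        warns.append("flat titration: Fmax ~ 0, Kd unidentifiable")
    if not (c.min() / 100 <= kd <= c.max() * 100):
        warns.append("Kd far outside sampled concentration range; poorly identified")
    if c.max() / c.min() < 10:
        warns.append("concentrations span < 1 order of magnitude")
    return BindingFit(
        kd=kd, fmax=fmax, f0=f0, rss=rss,
        converged=bool(sol.success), warnings=tuple(warns),
    )
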