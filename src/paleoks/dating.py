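"""Convert Ks peaks to event ages.

Two estimators are provided.  Anchored dating scales a calibrated age
interval for the shared core-eudicot triplication (ceWGT, taken as 115-130
million years ago) by the ratio of the event peak to the ceWGT peak; being
ratio-based it is invariant to any per-species scalar rate correction.
Fixed-rate dating divides the peak by twice a clock rate r (default
7.0e-9 synonymous substitutions per site per year; the factor 2 because
both duplicate lineages accumulate substitutions since the event).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from paleoks.peaks import PeakModel


class DatingError(ValueError):
    pass


@dataclass(frozen=True)
class DatingConfig:
    """Calibration anchor (Myr) and molecular clock rate (subst/site/year)."""

    anchor_low: float = 115.0
    anchor_high: float = 130.0
    rate_r: float = 7.0e-9

    def __post_init__(self) -> None:
        if not (0 < self.anchor_low <= self.anchor_high):
            raise DatingError(
                f"need 0 < anchor_low <= anchor_high, got "
                f"({self.anchor_low}, {self.anchor_high})"
            )
        if self.rate_r <= 0:
            raise DatingError(f"rate_r must be positive, got {self.rate_r}")


@dataclass(frozen=True)
class DatingResult:
    species: str
    event: str
    age_low: float
    age_high: float
    method: str  # "anchored" | "fixed_rate"


def date_with_anchor(
    peak_event: float,
    peak_cewgt: float,
    cfg: DatingConfig = DatingConfig(),
    species: str = "",
    event: str = "",
) -> DatingResult:
    """Age interval by proportionality to the ceWGT anchor.

    age = anchor * peak_event / peak_cewgt for both interval ends.  The
    ratio cancels any per-species correction scalar.
    """
    if peak_event <= 0 or peak_cewgt <= 0:
        raise DatingError(
            f"peaks must be positive, got {peak_event}, {peak_cewgt}"
        )
    if peak_event > peak_cewgt:
        warnings.warn(
            f"event peak {peak_event} exceeds ceWGT peak {peak_cewgt}; "
            "dated event would predate the anchor"
        )
    ratio = peak_event / peak_cewgt
    return DatingResult(
        species=species,
        event=event,
        age_low=cfg.anchor_low * ratio,
        age_high=cfg.anchor_high * ratio,
        method="anchored",
    )


def date_with_rate(
    peak: float,
    cfg: DatingConfig = DatingConfig(),
    species: str = "",
    event: str = "",
) -> DatingResult:
    """Point age (Myr) under a fixed clock: T = Ks / (2 r)."""
    if peak <= 0:
        raise DatingError(f"peak must be positive, got {peak}")
    age_myr = peak / (2.0 * cfg.rate_r) / 1e6
    return DatingResult(
        species=species,
        event=event,
        age_low=age_myr,
        age_high=age_myr,
        method="fixed_rate",
    )


def date_model(model: PeakModel, cfg: DatingConfig = DatingConfig()
               ) -> list[DatingResult]:
    """Anchored and fixed-rate dates for every labelled event of a model."""
    peak_cewgt = model.peak("ceWGT")
    results: list[DatingResult] = []
    for event in sorted(model.event_labels,
                        key=lambda e: -model.components[model.event_labels[e]].mu):
        p = model.peak(event)
        results.append(date_with_anchor(p, peak_cewgt, cfg,
                                        species=model.species, event=event))
        results.append(date_with_rate(p, cfg,
                                      species=model.species, event=event))
    return results


def dating_table(results: list[DatingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"species": r.species, "event": r.event, "method": r.method,
          "age_low": r.age_low, "age_high": r.age_high} for r in results],
        columns=["species", "event", "method", "age_low", "age_high"],
    )
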