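"""Reference-anchored linear Ks correction.

Species accumulate synonymous substitutions at different lineage rates, so
the shared polyploidy event (ceWGT) peaks at different Ks in different
genomes.  Taking one slowly evolving reference species (grapevine in the
motivating analysis, configurable here), every species q gets a scalar
correction coefficient

    C_q = P_ref / P_q

where P_q is the species' fitted ceWGT peak and P_ref the reference's.
Corrected values are Ks' = Ks * C_q, which by construction aligns every
corrected ceWGT peak exactly to the reference peak.  The correction is a
positive scalar per species, so within-species peak ratios are invariant
and the reference species is a fixed point (C_ref = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from paleoks.formats import SpeciesMeta
from paleoks.peaks import GaussianComponent, PeakModel


class CorrectionError(ValueError):
    """Raised on invalid peaks or missing reference/event labels."""


@dataclass(frozen=True)
class CorrectionFactor:
    """The per-species correction scalar and its provenance."""

    species: str
    c: float
    p_ref: float
    p_q: float


def correction_coefficient(
    p_ref: float, p_q: float, species: str = ""
) -> CorrectionFactor:
    """C_q = P_ref / P_q; both peaks must be positive."""
    if p_ref <= 0 or p_q <= 0:
        raise CorrectionError(
            f"peaks must be positive, got p_ref={p_ref}, p_q={p_q}"
        )
    return CorrectionFactor(species=species, c=p_ref / p_q, p_ref=p_ref, p_q=p_q)


def apply_correction(ks_values, factor: CorrectionFactor):
    """Multiply every Ks by the correction scalar, preserving order."""
    return [v * factor.c for v in ks_values]


def correct_model(model: PeakModel, factor: CorrectionFactor) -> PeakModel:
    """Scale a fitted peak model by the correction scalar.

    Exact by linearity of the Gaussian family under scaling: means and
    standard deviations multiply by c, weights are unchanged, so no refit
    is needed.
    """
    components = [
        GaussianComponent(c.mu * factor.c, c.sigma * factor.c, c.weight)
        for c in model.components
    ]
    return replace(model, components=components)


def correct_all(
    models: list[PeakModel],
    meta: list[SpeciesMeta],
) -> tuple[list[CorrectionFactor], list[PeakModel]]:
    """Correction factors and corrected peak models for a species set.

    The reference is the single metadata row flagged ``is_reference``;
    every model must carry a ``ceWGT`` event label.
    """
    refs = [m for m in meta if m.is_reference]
    if len(refs) != 1:
        raise CorrectionError(
            f"exactly one reference species required, found {len(refs)}"
        )
    ref_name = refs[0].species
    by_species = {m.species: m for m in models}
    if ref_name not in by_species:
        raise CorrectionError(f"no peak model for reference {ref_name!r}")
    for m in models:
        if "ceWGT" not in m.event_labels:
            raise CorrectionError(f"{m.species}: model lacks a ceWGT label")
    p_ref = by_species[ref_name].peak("ceWGT")
    factors = [
        correction_coefficient(p_ref, m.peak("ceWGT"), species=m.species)
        for m in models
    ]
    corrected = [correct_model(m, f) for m, f in zip(models, factors)]
    return factors, corrected


def correct_ks_table(ks: pd.DataFrame,
                     factors: list[CorrectionFactor]) -> pd.DataFrame:
    """Apply per-species correction scalars to a pair-level Ks table."""
    scale = {f.species: f.c for f in factors}
    unknown = set(ks["species"]) - set(scale)
    if unknown:
        raise CorrectionError(f"no correction factor for species {sorted(unknown)}")
    out = ks.copy()
    c = out["species"].map(scale)
    out["ks"] = out["ks"] * c
    out["ka"] = out["ka"] * c
    return out


def factors_table(factors: list[CorrectionFactor]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"species": f.species, "c": f.c, "p_ref": f.p_ref, "p_q": f.p_q}
         for f in factors],
        columns=["species", "c", "p_ref", "p_q"],
    )
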