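"""Synthetic datasets with known ground truth for every pipeline stage.

Two independent generator families are provided.  Table-level generators
produce multi-species collinearity/Ks datasets: each polyploidy event of a
species contributes one cloud of pair-level Ks values, normal around
``mu = 2 * base_rate * age_in_years * rate_multiplier`` and truncated at
zero, optionally contaminated with a uniform background to emulate the
long tails of real Ks distributions.  Sequence-level generators evolve
codon pairs from a random ancestor under independent Poisson processes of
synonymous and nonsynonymous single-nucleotide substitutions, calibrated
so the expected synonymous divergence per synonymous site equals the
requested target.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from paleoks.formats import (
    CollinearBlock,
    SpeciesMeta,
    write_annotation,
    write_collinearity,
    write_ks_table,
    write_species_meta,
)
from paleoks.ng86 import _CODE, SENSE_CODONS, translate_codon

DEFAULT_BASE_RATE = 7.0e-9  # synonymous substitutions / site / year
DEFAULT_CATEGORIES = (
    "metabolism",
    "genetic information processing",
    "environmental information processing",
    "cellular processes",
    "organismal systems",
    "carbohydrate metabolism",
    "lipid metabolism",
    "biosynthesis of other secondary metabolites",
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class EventSpec:
    """One polyploidy event of a species."""

    name: str
    true_age_myr: float
    n_blocks: int = 500
    pairs_per_block_mean: float = 8.0


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground-truth description of one simulated species.

    ``rate_multiplier`` scales the lineage's synonymous substitution rate
    relative to the clock; ``sigma_ks`` is the pair-level spread of each
    event's Ks cloud.
    """

    name: str
    rate_multiplier: float = 1.0
    events: tuple[EventSpec, ...] = ()
    sigma_ks: float = 0.2
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.rate_multiplier <= 0:
            raise SimulationError(f"{self.name}: rate_multiplier must be > 0")
        if self.sigma_ks <= 0:
            raise SimulationError(f"{self.name}: sigma_ks must be > 0")
        ages = [e.true_age_myr for e in self.events]
        if len(set(ages)) != len(ages):
            raise SimulationError(f"{self.name}: event ages must be distinct")
        for e in self.events:
            if e.n_blocks < 10:
                raise SimulationError(
                    f"{self.name}/{e.name}: need >= 10 blocks per event"
                )

    def true_mu(self, event: EventSpec, base_rate: float) -> float:
        return 2.0 * base_rate * event.true_age_myr * 1e6 * self.rate_multiplier


@dataclass(frozen=True)
class SimConfig:
    species: tuple[SpeciesSpec, ...]
    base_rate: float = DEFAULT_BASE_RATE
    seed: int = 0
    contamination: float = 0.05  # uniform-background fraction of pairs
    contamination_range: tuple[float, float] = (0.05, 4.0)
    enrichment_category: str = "carbohydrate metabolism"
    enrichment_odds: float = 3.0

    def __post_init__(self) -> None:
        if not self.species:
            raise SimulationError("need at least one species")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise SimulationError("duplicate species names")
        if sum(s.is_reference for s in self.species) != 1:
            raise SimulationError("exactly one species must be the reference")
        if not (0 <= self.contamination < 1):
            raise SimulationError("contamination must be in [0, 1)")
        if self.enrichment_odds < 1:
            raise SimulationError("enrichment odds must be >= 1")


@dataclass
class SimulatedDataset:
    """In-memory dataset plus the ground truth needed to score every stage."""

    blocks: dict[str, list[CollinearBlock]]
    ks: pd.DataFrame
    meta: list[SpeciesMeta]
    annotation: dict[str, list[str]]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for species, blocks in self.blocks.items():
            write_collinearity(blocks, outdir / f"{species}.collinearity.tsv")
        write_ks_table(self.ks, outdir / "ks.tsv")
        write_species_meta(self.meta, outdir / "species_meta.tsv")
        write_annotation(self.annotation, outdir / "annotation.tsv")
        import json

        with (outdir / "ground_truth.json").open(
            "w", encoding="utf-8", newline="\n"
        ) as fh:
            json.dump(self.truth, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# table-level generator


def simulate_ks_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate collinear blocks, pair Ks values, metadata and annotation.

    Block b of event e receives ``Poisson(pairs_per_block_mean) + 1``
    pairs; each pair's Ks is drawn from ``Normal(mu_e, sigma_ks)``
    truncated at zero, replaced with probability ``contamination`` by a
    uniform background draw.  The per-species annotation plants category
    enrichment in the empirically fastest 20% of pairs (see
    :func:`simulate_annotation`).
    """
    rng = np.random.default_rng(cfg.seed)
    blocks: dict[str, list[CollinearBlock]] = {}
    rows: list[dict] = []
    meta: list[SpeciesMeta] = []
    truth: dict = {"base_rate": cfg.base_rate, "seed": cfg.seed, "species": {}}
    lo, hi = cfg.contamination_range
    for spec in cfg.species:
        species_blocks: list[CollinearBlock] = []
        sp_truth = {
            "rate_multiplier": spec.rate_multiplier,
            "sigma_ks": spec.sigma_ks,
            "events": {},
        }
        gene_counter = 0
        for event in spec.events:
            mu = spec.true_mu(event, cfg.base_rate)
            sp_truth["events"][event.name] = {
                "true_age_myr": event.true_age_myr,
                "true_mu": mu,
                "n_blocks": event.n_blocks,
            }
            n_pairs_per_block = rng.poisson(
                event.pairs_per_block_mean - 1, size=event.n_blocks
            ) + 1
            total = int(n_pairs_per_block.sum())
            ks_values = rng.normal(mu, spec.sigma_ks, size=total)
            while (ks_values < 0).any():  # truncate the cloud at zero
                neg = ks_values < 0
                ks_values[neg] = rng.normal(mu, spec.sigma_ks, size=neg.sum())
            contam = rng.random(total) < cfg.contamination
            ks_values[contam] = rng.uniform(lo, hi, size=int(contam.sum()))
            idx = 0
            for b, n_pairs in enumerate(n_pairs_per_block):
                block_id = f"{event.name}_b{b:05d}"
                pairs: list[tuple[str, str]] = []
                for _ in range(int(n_pairs)):
                    gene_counter += 1
                    ga = f"{spec.name}.g{gene_counter:06d}a"
                    gb = f"{spec.name}.g{gene_counter:06d}b"
                    pairs.append((ga, gb))
                    rows.append(
                        {
                            "species": spec.name,
                            "block_id": block_id,
                            "gene_a": ga,
                            "gene_b": gb,
                            "ks": float(ks_values[idx]),
                            "ka": np.nan,
                        }
                    )
                    idx += 1
                species_blocks.append(
                    CollinearBlock(block_id=block_id, species=spec.name,
                                   pairs=pairs)
                )
        blocks[spec.name] = species_blocks
        meta.append(
            SpeciesMeta(
                species=spec.name,
                rounds=len(spec.events),
                is_reference=spec.is_reference,
            )
        )
        truth["species"][spec.name] = sp_truth
    ks = pd.DataFrame(rows, columns=["species", "block_id", "gene_a",
                                     "gene_b", "ks", "ka"])
    annotation = _dataset_annotation(ks, cfg, rng)
    return SimulatedDataset(blocks=blocks, ks=ks, meta=meta,
                            annotation=annotation, truth=truth)


def _dataset_annotation(ks: pd.DataFrame, cfg: SimConfig,
                        rng: np.random.Generator) -> dict[str, list[str]]:
    """Annotate all genes, planting enrichment in each species' fastest 20%."""
    fast: set[str] = set()
    for _, sub in ks.groupby("species"):
        cut = sub["ks"].quantile(0.8)
        hot = sub[sub["ks"] >= cut]
        fast |= set(hot["gene_a"]) | set(hot["gene_b"])
    genes = sorted(set(ks["gene_a"]) | set(ks["gene_b"]))
    return simulate_annotation(genes, cfg, fast, rng=rng)


def simulate_annotation(
    genes: Sequence[str],
    cfg: SimConfig,
    fast_genes: set[str],
    rng: np.random.Generator | None = None,
) -> dict[str, list[str]]:
    """One pathway category per gene, uniform over a fixed list, with the
    enrichment category's odds multiplied by ``cfg.enrichment_odds`` for
    genes in ``fast_genes``."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cats = list(DEFAULT_CATEGORIES)
    if cfg.enrichment_category not in cats:
        cats.append(cfg.enrichment_category)
    base = np.ones(len(cats)) / len(cats)
    boosted = base.copy()
    boosted[cats.index(cfg.enrichment_category)] *= cfg.enrichment_odds
    boosted /= boosted.sum()
    genes = list(genes)
    is_fast = np.array([g in fast_genes for g in genes], dtype=bool)
    draws = np.empty(len(genes), dtype=int)
    draws[~is_fast] = rng.choice(len(cats), size=int((~is_fast).sum()), p=base)
    draws[is_fast] = rng.choice(len(cats), size=int(is_fast.sum()), p=boosted)
    return {g: [cats[d]] for g, d in zip(genes, draws)}


# ---------------------------------------------------------------------------
# a realistic multi-species default


def default_multi_species_config(
    seed: int = 0,
    n_p1r: int = 12,
    n_p2r: int = 16,
    p2r_rate_boost: float = 1.05,
    rate_jitter_sd: float = 0.015,
    n_blocks: int = 500,
    cewgt_age_myr: float = 122.5,
    sigma_ks: float = 0.2,
) -> SimConfig:
    """A 28-species study design: ``n_p1r`` species with only the shared
    triplication and ``n_p2r`` with one additional, younger WGD.

    P2R lineages carry a planted mean rate elevation of
    ``p2r_rate_boost`` (default +5%); every non-reference lineage gets
    log-normal rate jitter of spread ``rate_jitter_sd`` around its group
    mean, representing residual lineage-specific rate variation.  The
    reference species is the first P1R lineage at multiplier exactly 1.
    """
    rng = np.random.default_rng(seed)
    species: list[SpeciesSpec] = []
    for i in range(n_p1r):
        mult = 1.0 if i == 0 else float(np.exp(rng.normal(0.0, rate_jitter_sd)))
        species.append(
            SpeciesSpec(
                name=f"p1r_{i:02d}",
                rate_multiplier=mult,
                events=(EventSpec("ceWGT", cewgt_age_myr, n_blocks),),
                sigma_ks=sigma_ks,
                is_reference=(i == 0),
            )
        )
    for i in range(n_p2r):
        mult = float(p2r_rate_boost * np.exp(rng.normal(0.0, rate_jitter_sd)))
        wgd_age = float(rng.uniform(30.0, 60.0))
        species.append(
            SpeciesSpec(
                name=f"p2r_{i:02d}",
                rate_multiplier=mult,
                events=(
                    EventSpec("ceWGT", cewgt_age_myr, n_blocks),
                    EventSpec("WGD", wgd_age, n_blocks),
                ),
                sigma_ks=sigma_ks,
            )
        )
    return SimConfig(species=tuple(species), seed=seed)


# ---------------------------------------------------------------------------
# sequence-level generator


def _jc_forward(d: float) -> float:
    """Expected proportion of differing sites after divergence ``d`` under
    the Jukes–Cantor model (the inverse of the NG86 correction)."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * d))


def _mutate_codon(codon: str, p_syn: float, p_non: float,
                  rng: np.random.Generator) -> str:
    """Plant at most one single-nucleotide substitution in the codon.

    Every synonymous alternative is chosen with probability ``p_syn / 3``
    and every nonsynonymous sense alternative with ``p_non / 3`` (stop
    codons are never substituted into), so the expected synonymous
    differences per synonymous site equal ``p_syn`` exactly.  Restricting
    to one change per codon keeps the NG86 difference decomposition exact
    (a single change is classified identically along every substitution
    ordering); multiple-hit saturation lives in the planted proportions,
    not in repeated hits.
    """
    aa = _CODE[codon]
    u = rng.random()
    acc = 0.0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            alt_aa = _CODE.get(alt)
            if alt_aa is None:
                continue
            acc += (p_syn if alt_aa == aa else p_non) / 3.0
            if u < acc:
                return alt
    if acc > 1.0:
        raise SimulationError(
            "divergence targets too large for the one-change-per-codon "
            "substitution scheme"
        )
    return codon


def simulate_codon_pair(
    n_codons: int,
    target_ds: float,
    target_dn: float = 0.02,
    seed: int = 0,
    n_gap_columns: int = 0,
) -> tuple[str, str, str, str]:
    """Generate a codon-sequence pair at target synonymous divergence.

    One sequence is a random sense-codon ancestor; the other carries
    independently planted single-nucleotide substitutions (at most one
    per codon) whose per-site probabilities are the targets pushed
    through the Jukes–Cantor map (``p = 3/4 (1 - exp(-4 d / 3))``), so
    the expected NG86 ks estimate equals the target — multiple-hit
    saturation is built into the planted proportions rather than
    simulated event by event.  The nonsynonymous target is approximate
    (stop codons are counted as nonsynonymous sites but never substituted
    into).  Returns
    ``(cds_a, cds_b, protein_aln_a, protein_aln_b)`` where the proteins
    are the true alignment; optional gap columns delete a codon from one
    sequence and gap its protein.
    """
    if n_codons < 1:
        raise SimulationError("n_codons must be >= 1")
    if target_ds < 0 or target_dn < 0:
        raise SimulationError("divergence targets must be >= 0")
    if target_ds >= 3:
        raise SimulationError(f"target_ds={target_ds} is beyond saturation")
    if n_gap_columns >= n_codons:
        raise SimulationError("cannot gap every column")
    rng = np.random.default_rng(seed)
    p_syn = _jc_forward(target_ds)
    p_non = _jc_forward(target_dn)
    ancestor = [SENSE_CODONS[int(i)]
                for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    codons_a = list(ancestor)
    codons_b = [_mutate_codon(c, p_syn, p_non, rng) for c in ancestor]
    prot_a = [translate_codon(c) for c in codons_a]
    prot_b = [translate_codon(c) for c in codons_b]
    if n_gap_columns:
        gap_cols = rng.choice(n_codons, size=n_gap_columns, replace=False)
        for col in sorted(gap_cols, reverse=True):
            if rng.random() < 0.5:
                del codons_a[col]
                prot_a[col] = "-"
            else:
                del codons_b[col]
                prot_b[col] = "-"
    return (
        "".join(codons_a),
        "".join(codons_b),
        "".join(prot_a),
        "".join(prot_b),
    )
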