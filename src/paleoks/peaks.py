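"""Per-species Ks peak models from collinear-block medians.

Raw pair-level Ks distributions carry long tails; the median Ks of each
collinear block is a statistically stable summary, and the per-species
distribution of block medians is fitted with a Gaussian mixture whose
component count equals the number of known polyploidy rounds.  Each
component mean is a peak location P_q; the highest-mean component is the
shared core-eudicot triplication (ceWGT) peak.

The mixture is fitted by expectation–maximisation with deterministic
quantile-spaced initialisation: means at the (i + 0.5)/K data quantiles, a
pooled-variance start, uniform weights.  Convergence is declared when the
total log-likelihood improves by less than 1e-6, capped at 500 iterations.
A degenerate component (sigma < 1e-4 or weight < 0.01) triggers one refit
from a seed-perturbed initialisation, then an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from paleoks.formats import CollinearBlock, SpeciesMeta

DEFAULT_WINDOW: tuple[float, float] = (0.05, 4.0)
DEFAULT_MIN_PAIRS: int = 5

_EM_TOL = 1e-6
_EM_MAX_ITER = 500
_MIN_SIGMA = 1e-4
_MIN_WEIGHT = 0.01


class PeakFitError(RuntimeError):
    """Raised when medians cannot be formed or the mixture fit degenerates."""


@dataclass(frozen=True)
class BlockMedianSet:
    """Block-median Ks values for one species, after pair filtering."""

    species: str
    medians: np.ndarray
    filter_window: tuple[float, float]
    min_pairs: int

    @property
    def n_blocks_used(self) -> int:
        return len(self.medians)


@dataclass(frozen=True)
class GaussianComponent:
    mu: float
    sigma: float
    weight: float


@dataclass
class PeakModel:
    """Fitted Gaussian mixture over block medians for one species.

    ``components`` are sorted by mean ascending; ``event_labels`` maps an
    event name (``"ceWGT"``, ``"WGD_1"``, ...) to a component index.
    """

    species: str
    components: list[GaussianComponent]
    log_likelihood: float
    seed: int
    event_labels: dict[str, int] = field(default_factory=dict)
    ll_trace: list[float] = field(default_factory=list, repr=False)

    def peak(self, event: str) -> float:
        return self.components[self.event_labels[event]].mu

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "components": [
                {"mu": c.mu, "sigma": c.sigma, "weight": c.weight}
                for c in self.components
            ],
            "event_labels": self.event_labels,
            "log_likelihood": self.log_likelihood,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PeakModel":
        return cls(
            species=d["species"],
            components=[
                GaussianComponent(c["mu"], c["sigma"], c["weight"])
                for c in d["components"]
            ],
            event_labels={k: int(v) for k, v in d["event_labels"].items()},
            log_likelihood=float(d["log_likelihood"]),
            seed=int(d["seed"]),
        )


def save_peak_models(models: list[PeakModel], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=2)
        fh.write("\n")


def load_peak_models(path: str | Path) -> list[PeakModel]:
    with Path(path).open(encoding="utf-8") as fh:
        return [PeakModel.from_dict(d) for d in json.load(fh)]


def peaks_table(models: list[PeakModel]) -> pd.DataFrame:
    """Flatten fitted models into a (species, event, mu, sigma, weight) table."""
    rows = []
    for m in models:
        for event, idx in sorted(m.event_labels.items(),
                                 key=lambda kv: -m.components[kv[1]].mu):
            c = m.components[idx]
            rows.append({"species": m.species, "event": event,
                         "mu": c.mu, "sigma": c.sigma, "weight": c.weight})
    return pd.DataFrame(rows, columns=["species", "event", "mu", "sigma", "weight"])


# ---------------------------------------------------------------------------
# block medians


def block_medians(
    blocks: list[CollinearBlock],
    ks: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> BlockMedianSet:
    """Median Ks per collinear block, after windowing pair-level values.

    Pair Ks values outside ``(ks_min, ks_max]`` are excluded (the lower
    bound removes allelic/tandem near-zero pairs, the upper saturated
    estimates); blocks retaining fewer than ``min_pairs`` values are
    dropped.  Pairs absent from the Ks table are skipped with a warning.
    """
    ks_min, ks_max = window
    if not blocks:
        raise PeakFitError("no blocks given")
    species = blocks[0].species
    lookup: dict[tuple[str, str], float] = {}
    sub = ks[ks["species"] == species]
    for row in sub.itertuples():
        lookup[(row.gene_a, row.gene_b)] = row.ks
        lookup[(row.gene_b, row.gene_a)] = row.ks
    medians: list[float] = []
    n_missing = 0
    for block in blocks:
        if block.species != species:
            raise PeakFitError(
                f"mixed species in block list: {block.species!r} vs {species!r}"
            )
        values = []
        for pair in block.pairs:
            ks_value = lookup.get(pair)
            if ks_value is None or np.isnan(ks_value):
                n_missing += 1
                continue
            if ks_min < ks_value <= ks_max:
                values.append(ks_value)
        if len(values) >= min_pairs:
            medians.append(float(np.median(values)))
    if n_missing:
        warnings.warn(
            f"{species}: {n_missing} block pairs had no Ks value; skipped"
        )
    if not medians:
        raise PeakFitError(
            f"{species}: no block retained >= {min_pairs} in-window Ks values"
        )
    return BlockMedianSet(
        species=species,
        medians=np.asarray(medians, dtype=float),
        filter_window=(ks_min, ks_max),
        min_pairs=min_pairs,
    )


# ---------------------------------------------------------------------------
# EM mixture fit


def _log_gauss(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    # x: (n,), mu/sigma: (K,) -> (n, K)
    z = (x[:, None] - mu[None, :]) / sigma[None, :]
    return -0.5 * z**2 - np.log(sigma[None, :]) - 0.5 * np.log(2.0 * np.pi)


def _em(
    x: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    weight: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(_EM_MAX_ITER):
        log_prob = _log_gauss(x, mu, sigma) + np.log(weight[None, :])
        log_norm = np.logaddexp.reduce(log_prob, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_prob - log_norm[:, None])
        nk = resp.sum(axis=0)
        weight = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, _MIN_SIGMA**2 / 4))
        if ll - prev_ll < _EM_TOL:
            break
        prev_ll = ll
    return mu, sigma, weight, trace


def _quantile_init(
    x: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    qs = (np.arange(n_components) + 0.5) / n_components
    mu = np.quantile(x, qs)
    pooled = float(np.std(x)) / max(n_components, 1)
    sigma = np.full(n_components, max(pooled, 10 * _MIN_SIGMA))
    weight = np.full(n_components, 1.0 / n_components)
    return mu, sigma, weight


def fit_peak_model(
    medians: BlockMedianSet,
    n_components: int,
    seed: int = 0,
) -> PeakModel:
    """Fit an ``n_components`` Gaussian mixture to the block medians by EM.

    Deterministic given ``seed`` (the seed only enters through the
    perturbed re-initialisation used when a first fit degenerates).
    Components are returned sorted by mean.
    """
    x = np.asarray(medians.medians, dtype=float)
    if n_components < 1:
        raise PeakFitError("n_components must be >= 1")
    if len(x) < 10 * n_components:
        raise PeakFitError(
            f"{medians.species}: {len(x)} medians is too few for "
            f"{n_components} components (need >= {10 * n_components})"
        )
    mu0, sigma0, w0 = _quantile_init(x, n_components)
    mu, sigma, weight, trace = _em(x, mu0, sigma0, w0)
    if _degenerate(sigma, weight):
        rng = np.random.default_rng(seed)
        jitter = rng.normal(0.0, float(np.std(x)) * 0.1, size=n_components)
        mu, sigma, weight, trace = _em(x, mu0 + jitter, sigma0, w0)
        if _degenerate(sigma, weight):
            raise PeakFitError(
                f"{medians.species}: degenerate mixture component after refit "
                f"(sigma={sigma}, weight={weight})"
            )
    order = np.argsort(mu)
    components = [
        GaussianComponent(float(mu[i]), float(sigma[i]), float(weight[i]))
        for i in order
    ]
    return PeakModel(
        species=medians.species,
        components=components,
        log_likelihood=trace[-1],
        seed=seed,
        ll_trace=trace,
    )


def _degenerate(sigma: np.ndarray, weight: np.ndarray) -> bool:
    return bool((sigma < _MIN_SIGMA).any() or (weight < _MIN_WEIGHT).any())


def assign_events(model: PeakModel, meta: SpeciesMeta) -> PeakModel:
    """Label mixture components with event names.

    The highest-mean component is the ceWGT (oldest shared event); younger
    components are ``WGD_1``, ``WGD_2``, ... in descending mean (older
    first).  Requires as many components as the species has polyploidy
    rounds.
    """
    if len(model.components) != meta.rounds:
        raise PeakFitError(
            f"{model.species}: {len(model.components)} components but "
            f"{meta.rounds} polyploidy rounds"
        )
    # components are sorted ascending by mu
    labels: dict[str, int] = {"ceWGT": len(model.components) - 1}
    for k, idx in enumerate(range(len(model.components) - 2, -1, -1), start=1):
        labels[f"WGD_{k}"] = idx
    return replace(model, event_labels=labels)
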