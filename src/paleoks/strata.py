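"""Fast/slow-evolving gene strata and pathway-proportion testing.

Paralog pairs are ranked by Ks; pairs in the top and bottom quantile
(default 20%) define the fast- and slowly evolving gene sets.  Gene-level
pathway annotations (e.g. KEGG categories) then give a 2 x K contingency
table of stratum x category incidences, tested with a Pearson chi-square
test (no continuity correction, df = K - 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from paleoks.peaks import PeakModel


class StrataError(ValueError):
    pass


@dataclass(frozen=True)
class StrataConfig:
    """Quantile cut and pair scope for stratification.

    ``scope`` restricts ranking to pairs attributable to the shared ceWGT
    event (those inside the fitted ceWGT component's +-2.5 sigma window)
    or uses all pairs.
    """

    quantile: float = 0.2
    scope: str = "ceWGT_pairs_only"  # or "all_pairs"

    def __post_init__(self) -> None:
        if not (0 < self.quantile < 0.5):
            raise StrataError(f"quantile must be in (0, 0.5), got {self.quantile}")
        if self.scope not in {"ceWGT_pairs_only", "all_pairs"}:
            raise StrataError(f"unknown scope {self.scope!r}")


@dataclass
class StrataResult:
    fast_genes: set[str]
    slow_genes: set[str]
    table: pd.DataFrame  # rows fast/slow, columns categories
    chi2: float
    p_value: float
    df: int
    low_expected_warning: bool
    n_dropped_overlap: int = 0
    config: StrataConfig = field(default_factory=StrataConfig)

    def to_dict(self) -> dict:
        return {
            "fast_genes": sorted(self.fast_genes),
            "slow_genes": sorted(self.slow_genes),
            "categories": list(self.table.columns),
            "table": self.table.values.tolist(),
            "chi2": self.chi2,
            "p_value": self.p_value,
            "df": self.df,
            "low_expected_warning": self.low_expected_warning,
            "n_dropped_overlap": self.n_dropped_overlap,
            "quantile": self.config.quantile,
            "scope": self.config.scope,
        }


def cewgt_window(model: PeakModel, n_sigma: float = 2.5) -> tuple[float, float]:
    """Ks window attributing pairs to the ceWGT component: mu +- n_sigma*sigma."""
    idx = model.event_labels["ceWGT"]
    c = model.components[idx]
    return (max(c.mu - n_sigma * c.sigma, 0.0), c.mu + n_sigma * c.sigma)


def stratify_by_ks(
    ks: pd.DataFrame,
    cfg: StrataConfig = StrataConfig(),
    window: tuple[float, float] | None = None,
) -> tuple[set[str], set[str]]:
    """Fast and slow gene sets from the top/bottom Ks quantiles.

    Both strata take ceil(q * n) pairs; both genes of a selected pair
    enter the stratum.  A gene landing in both strata (through different
    pairs) is dropped from both with a warning.  Ties at the quantile
    boundary are broken by gene-id lexicographic order, so the result is
    deterministic.

    ``window`` (from :func:`cewgt_window`) restricts the ranked pairs when
    the config scope is ``ceWGT_pairs_only``; it is ignored for
    ``all_pairs``.
    """
    fast, slow, _ = _stratify(ks, cfg, window)
    return fast, slow


def _stratify(
    ks: pd.DataFrame,
    cfg: StrataConfig,
    window: tuple[float, float] | None,
) -> tuple[set[str], set[str], int]:
    df = ks.dropna(subset=["ks"])
    if cfg.scope == "ceWGT_pairs_only":
        if window is None:
            raise StrataError(
                "scope ceWGT_pairs_only requires a ceWGT Ks window"
            )
        lo, hi = window
        df = df[(df["ks"] >= lo) & (df["ks"] <= hi)]
    n = len(df)
    if n < 5:
        raise StrataError(f"need >= 5 pairs to stratify, got {n}")
    k = math.ceil(cfg.quantile * n)
    ordered = df.sort_values(["ks", "gene_a", "gene_b"], kind="mergesort")
    slow_pairs = ordered.head(k)
    # fast stratum ranks from the high end; under ties the two strata take
    # opposite lexicographic ends so they stay disjoint and deterministic
    fast_pairs = ordered.iloc[::-1].head(k)
    fast = set(fast_pairs["gene_a"]) | set(fast_pairs["gene_b"])
    slow = set(slow_pairs["gene_a"]) | set(slow_pairs["gene_b"])
    overlap = fast & slow
    if overlap:
        warnings.warn(
            f"{len(overlap)} genes fell in both strata; dropped from both"
        )
    return fast - overlap, slow - overlap, len(overlap)


def pathway_table(
    fast: set[str],
    slow: set[str],
    annot: dict[str, list[str]],
) -> pd.DataFrame:
    """2 x K table of (stratum, pathway category) incidences.

    A multi-category gene counts once per category; categories absent from
    both strata are dropped.  Columns are sorted for determinism.
    """
    counts: dict[str, dict[str, int]] = {"fast": {}, "slow": {}}
    for stratum, genes in (("fast", fast), ("slow", slow)):
        for gene in genes:
            for cat in annot.get(gene, []):
                counts[stratum][cat] = counts[stratum].get(cat, 0) + 1
    categories = sorted(set(counts["fast"]) | set(counts["slow"]))
    if not categories:
        raise StrataError("no annotated genes in either stratum")
    table = pd.DataFrame(
        [[counts[s].get(c, 0) for c in categories] for s in ("fast", "slow")],
        index=["fast", "slow"],
        columns=categories,
        dtype=int,
    )
    return table


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    p_value: float
    df: int
    low_expected_warning: bool


def chisq_test(table: pd.DataFrame | np.ndarray) -> ChisqResult:
    """Pearson chi-square on a 2 x K table, df = K - 1, no continuity
    correction.  Flags tables with any expected count below 5."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise StrataError(f"need a 2 x K table with K >= 2, got {arr.shape}")
    if (arr.sum(axis=0) <= 0).any():
        raise StrataError("every category must have a positive column sum")
    if (arr.sum(axis=1) <= 0).any():
        raise StrataError("every stratum must have a positive row sum")
    chi2, p, df, expected = stats.chi2_contingency(arr, correction=False)
    return ChisqResult(
        chi2=float(chi2),
        p_value=float(p),
        df=int(df),
        low_expected_warning=bool((expected < 5).any()),
    )


def run_strata(
    ks: pd.DataFrame,
    annot: dict[str, list[str]],
    cfg: StrataConfig = StrataConfig(),
    model: PeakModel | None = None,
) -> StrataResult:
    """Stratify, tabulate and test in one step."""
    window = None
    if cfg.scope == "ceWGT_pairs_only":
        if model is None:
            raise StrataError("ceWGT scope requires a fitted peak model")
        window = cewgt_window(model)
    fast_all, slow_all, n_dropped = _stratify(ks, cfg, window)
    table = pathway_table(fast_all, slow_all, annot)
    test = chisq_test(table)
    return StrataResult(
        fast_genes=fast_all,
        slow_genes=slow_all,
        table=table,
        chi2=test.chi2,
        p_value=test.p_value,
        df=test.df,
        low_expected_warning=test.low_expected_warning,
        n_dropped_overlap=n_dropped,
        config=cfg,
    )
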