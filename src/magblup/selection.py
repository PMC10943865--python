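"""Candidate filtering and round-robin forward-AIC selection of alr-MG.

From the catalog of MG x ADG genomic correlations, candidates are MG
with a credibly non-zero rg (P0 >= 0.85) against at least one growth
trait and a numerator mean relative abundance >= 0.001%. Two candidate
pools are supported: unrestricted ("non-uniform") and the subset whose
four rg medians share one sign ("uniform"). The final 32-trait subset
(8 per ADG trait) is picked by forward stepwise regression on GEBV:
cycling ADG_1 -> ADG_2 -> ADG_3 -> ADG_4, each step regresses the
current trait's GEBV on the other three ADG GEBV plus all previously
selected MG GEBV plus one candidate, adding the candidate that minimises
AIC = n*ln(RSS/n) + 2k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def filter_candidates(
    catalog: pd.DataFrame,
    p0_min: float = 0.85,
    min_rel_abundance: float = 1e-5,
) -> list[str]:
    """MG ids passing the P0 and mean-relative-abundance filters.

    ``catalog`` is indexed by MG id with columns ``p0_ADG_k`` (k=1..4)
    and ``rel_abundance``; both bounds are inclusive.
    """
    p0_cols = [c for c in catalog.columns if c.startswith("p0_")]
    if not p0_cols:
        raise ValueError("catalog has no p0_* columns")
    keep = (catalog[p0_cols] >= p0_min).any(axis=1) & (
        catalog["rel_abundance"] >= min_rel_abundance
    )
    out = list(catalog.index[keep])
    if not out:
        raise ValueError("no candidate MG survive the filters")
    return out


def uniform_sign_subset(candidates: list[str], catalog: pd.DataFrame) -> list[str]:
    """Restrict to MG whose four rg medians share one sign.

    Exact-zero medians carry no sign and break uniformity.
    """
    rg_cols = [c for c in catalog.columns if c.startswith("rg_")]
    rg = catalog.loc[candidates, rg_cols]
    all_pos = (rg > 0).all(axis=1)
    all_neg = (rg < 0).all(axis=1)
    return list(rg.index[all_pos | all_neg])


@dataclass
class SelectionResult:
    selected: list[str]
    trait_of_step: list[str]
    aic_trace: list[float]
    adjusted_r2: dict[str, float]
    label: str = "non-uniform"
    warnings: list[str] = field(default_factory=list)

    def per_trait_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trait_of_step:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.selected) + 1),
                "trait": self.trait_of_step,
                "mg": self.selected,
                "aic": self.aic_trace,
            }
        )


def _aic(y: np.ndarray, Xcols: list[np.ndarray]) -> float:
    """AIC (constant terms dropped) of an OLS fit with intercept."""
    n = y.size
    X = np.column_stack([np.ones(n)] + Xcols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ coef) ** 2).sum())
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * X.shape[1]


def _adjusted_r2(y: np.ndarray, Xcols: list[np.ndarray]) -> float:
    n = y.size
    X = np.column_stack([np.ones(n)] + Xcols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ coef) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    p = X.shape[1] - 1
    return 1.0 - (rss / (n - p - 1)) / (tss / (n - 1))


def stepwise_select(
    gebv_adg: pd.DataFrame,
    gebv_mg: pd.DataFrame,
    quota_per_trait: int = 8,
    label: str = "non-uniform",
) -> SelectionResult:
    """Round-robin forward stepwise AIC selection of MG GEBV predictors.

    ``gebv_adg``: animals x 4 ADG GEBV; ``gebv_mg``: animals x candidate
    MG GEBV (aligned rows). Ties in AIC break on candidate id order.
    Stops at 4 * quota_per_trait selections or when the pool empties.
    """
    traits = list(gebv_adg.columns)
    if len(traits) != 4:
        raise ValueError("expected four ADG GEBV columns")
    pool = list(gebv_mg.columns)
    selected: list[str] = []
    trait_of_step: list[str] = []
    aic_trace: list[float] = []
    warnings: list[str] = []
    target_total = 4 * quota_per_trait

    adg_arrays = {t: gebv_adg[t].to_numpy(dtype=float) for t in traits}
    mg_arrays = {m: gebv_mg[m].to_numpy(dtype=float) for m in pool}

    step = 0
    while len(selected) < target_total:
        trait = traits[step % 4]
        if not pool:
            warnings.append(
                f"candidate pool exhausted after {len(selected)} selections"
            )
            break
        y = adg_arrays[trait]
        base = [adg_arrays[t] for t in traits if t != trait] + [
            mg_arrays[m] for m in selected
        ]
        best_mg, best_aic = None, np.inf
        for m in sorted(pool):
            aic = _aic(y, base + [mg_arrays[m]])
            if aic < best_aic:
                best_mg, best_aic = m, aic
        selected.append(best_mg)
        trait_of_step.append(trait)
        aic_trace.append(best_aic)
        pool.remove(best_mg)
        step += 1

    adj = {}
    for t in traits:
        y = adg_arrays[t]
        cols = [adg_arrays[s] for s in traits if s != t] + [
            mg_arrays[m] for m in selected
        ]
        adj[t] = _adjusted_r2(y, cols)
    return SelectionResult(
        selected=selected,
        trait_of_step=trait_of_step,
        aic_trace=aic_trace,
        adjusted_r2=adj,
        label=label,
        warnings=warnings,
    )
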