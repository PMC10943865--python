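"""Compositional treatment of microbial gene (KO) count tables.

The rumen KO counts are compositional: only relative information is
carried by a sequencing sample. The pipeline here is

1. core filtering — keep microbial genes (MG) detected in at least a
   fraction (default 70%) of samples;
2. geometric Bayesian-multiplicative (GBM) zero replacement — remaining
   zeros become small positive proportions under a Dirichlet prior whose
   expected proportions are the column geometric means, with the non-zero
   parts rescaled multiplicatively so each sample still sums to one;
3. additive log-ratio (alr) transform against a single reference gene,
   chosen as a trade-off between preserving the full log-ratio geometry
   (Procrustes correlation with the clr configuration) and having a low
   log-abundance variance so alr values read as the numerator gene.

The two tabular transformers follow the scikit-learn fit/transform
protocol and operate on pandas DataFrames (samples x MG).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin


def _check_counts(counts: pd.DataFrame) -> None:
    x = counts.to_numpy()
    if (x < 0).any():
        raise ValueError("counts must be non-negative")


class CoreFilter(BaseEstimator, TransformerMixin):
    """Keep MG present (non-zero) in at least ``presence_frac`` of samples.

    Fitted attributes
    -----------------
    kept_columns_ : Index of retained MG ids
    presence_cutoff_ : minimum number of samples an MG must appear in
    retained_count_fraction_ : fraction of total counts the kept MG carry
    """

    def __init__(self, presence_frac: float = 0.70):
        self.presence_frac = presence_frac

    def fit(self, X: pd.DataFrame, y=None):
        if not 0.0 < self.presence_frac <= 1.0:
            raise ValueError("presence_frac must lie in (0, 1]")
        _check_counts(X)
        n = X.shape[0]
        self.presence_cutoff_ = math.ceil(self.presence_frac * n)
        presence = (X > 0).sum(axis=0)
        self.kept_columns_ = X.columns[presence >= self.presence_cutoff_]
        if len(self.kept_columns_) == 0:
            raise ValueError("core filter removed every MG")
        total = X.to_numpy().sum()
        kept = X[self.kept_columns_].to_numpy().sum()
        self.retained_count_fraction_ = float(kept / total) if total else 0.0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_columns_]


class GbmZeroImputer(BaseEstimator, TransformerMixin):
    """Geometric Bayesian-multiplicative replacement of count zeros.

    A zero of MG j in a sample of depth N is replaced by the posterior
    expected proportion ``t_j * s / (N + s)`` where ``t_j`` are prior
    proportions proportional to the column geometric means (over samples
    where the MG is observed) and ``s`` is the prior strength, by default
    the square root of the mean sequencing depth. Non-zero proportions of
    the sample are multiplied by one minus the total imputed mass, which
    preserves their ratios and restores closure.
    """

    def __init__(self, strength: float | None = None):
        self.strength = strength

    def fit(self, X: pd.DataFrame, y=None):
        _check_counts(X)
        x = X.to_numpy(dtype=float)
        if (x.sum(axis=1) == 0).any():
            raise ValueError("sample with all-zero counts")
        if (x == 0).all(axis=0).any():
            raise ValueError("all-zero MG column; apply CoreFilter first")
        depth = x.sum(axis=1, keepdims=True)
        prop = x / depth
        # geometric mean of observed (non-zero) proportions per column
        logp = np.where(prop > 0, np.log(np.where(prop > 0, prop, 1.0)), np.nan)
        gm = np.exp(np.nanmean(logp, axis=0))
        self.prior_proportions_ = gm / gm.sum()
        self.strength_ = (
            float(self.strength)
            if self.strength is not None
            else float(np.sqrt(depth.mean()))
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        _check_counts(X)
        x = X.to_numpy(dtype=float)
        if (x.sum(axis=1) == 0).any():
            raise ValueError("sample with all-zero counts")
        depth = x.sum(axis=1, keepdims=True)
        prop = x / depth
        s = self.strength_
        t = self.prior_proportions_
        repl = np.broadcast_to(t, prop.shape) * (s / (depth + s))
        is_zero = prop == 0
        imputed_mass = np.where(is_zero, repl, 0.0).sum(axis=1, keepdims=True)
        out = np.where(is_zero, repl, prop * (1.0 - imputed_mass))
        return pd.DataFrame(out, index=X.index, columns=X.columns)


class AlrTransform(BaseEstimator, TransformerMixin):
    """Additive log-ratio transform against a fixed reference MG."""

    def __init__(self, reference: str):
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None):
        if self.reference not in X.columns:
            raise ValueError(f"reference {self.reference!r} not in table")
        self.feature_columns_ = X.columns.drop(self.reference)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        x = X.to_numpy(dtype=float)
        if (x <= 0).any():
            raise ValueError("alr requires strictly positive compositions")
        ref = np.log(X[self.reference].to_numpy(dtype=float))
        out = np.log(X[self.feature_columns_].to_numpy(dtype=float)) - ref[:, None]
        return pd.DataFrame(out, index=X.index, columns=self.feature_columns_)


def alr_inverse(alr: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Composition from alr values: softmax with a zero slot for the reference."""
    cols = list(alr.columns) + [reference]
    z = np.column_stack([alr.to_numpy(dtype=float), np.zeros(alr.shape[0])])
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    comp = ez / ez.sum(axis=1, keepdims=True)
    return pd.DataFrame(comp, index=alr.index, columns=cols)


def clr_matrix(comp: np.ndarray) -> np.ndarray:
    """Centred log-ratio values: log proportion minus sample log geometric mean."""
    lx = np.log(comp)
    return lx - lx.mean(axis=1, keepdims=True)


def procrustes_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes correlation between two sample configurations.

    Both matrices are column-centred; the statistic is the sum of singular
    values of A'B over the geometric mean of the two total sums of squares
    — 1 when the configurations match after rotation/scaling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    ssa = (a * a).sum()
    ssb = (b * b).sum()
    if ssa == 0.0 or ssb == 0.0:
        raise ValueError("zero-variance configuration")
    sv = linalg.svd(a.T @ b, compute_uv=False)
    return float(sv.sum() / np.sqrt(ssa * ssb))


@dataclass
class ReferenceDiagnostics:
    candidate_mg: str
    procrustes_corr: float
    logratio_variance: float
    cv_percent: float


def select_alr_reference(
    comp: pd.DataFrame, top_quantile: float = 0.10
) -> tuple[str, pd.DataFrame]:
    """Choose the alr reference MG and report per-candidate diagnostics.

    Every MG is scored by (i) the Procrustes correlation between the clr
    configuration of the full composition and the alr configuration it
    generates, and (ii) the variance of its log relative abundance across
    samples. Among candidates in the top ``top_quantile`` of Procrustes
    correlation, the one with minimum log-abundance variance wins, so alr
    values can be read as the numerator gene while sample geometry is
    preserved.
    """
    if comp.shape[1] < 3:
        raise ValueError("need at least 3 parts to choose a reference")
    x = comp.to_numpy(dtype=float)
    if (x <= 0).any():
        raise ValueError("composition must be strictly positive")
    lx = np.log(x)
    clr = lx - lx.mean(axis=1, keepdims=True)
    rows = []
    for j, mg in enumerate(comp.columns):
        alr = np.delete(lx, j, axis=1) - lx[:, [j]]
        corr = procrustes_correlation(clr, alr)
        lj = lx[:, j]
        var = float(lj.var(ddof=1))
        mean = float(lj.mean())
        cv = float(100.0 * np.sqrt(var) / abs(mean)) if mean != 0 else np.inf
        rows.append(ReferenceDiagnostics(str(mg), corr, var, cv))
    diag = pd.DataFrame([r.__dict__ for r in rows]).set_index("candidate_mg")
    cut = diag["procrustes_corr"].quantile(1.0 - top_quantile)
    top = diag[diag["procrustes_corr"] >= cut]
    ref = top["logratio_variance"].idxmin()
    return str(ref), diag
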