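"""Assemble multi-trait (co)variance matrices from pairwise bivariate fits.

Estimating a 36 x 36 genomic covariance directly is infeasible at herd
scale, so each coefficient comes from a bivariate model. Off-diagonals
are the pairwise covariance estimates; each diagonal is the arithmetic
mean of that trait's variance estimates across the bivariate models that
include it. The assembled matrix is generally not positive definite and
is bent by eigenvalue flooring (tolerance 1e-3); validation checks that
bending moved no entry by more than its posterior SE and shifted no
trait's heritability by more than 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BendingReport:
    min_eig_before: float
    min_eig_after: float
    max_abs_change: float
    n_floored: int


def assemble_covariances(
    pairs: dict, trait_names: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build symmetric G and R from per-pair 2x2 estimates.

    Parameters
    ----------
    pairs
        Mapping (trait_i, trait_j) -> {"G": 2x2 array, "R": 2x2 array}
        with the 2x2 blocks ordered (i, j). Every unordered pair must
        appear exactly once.
    trait_names
        Full trait ordering of the assembled matrices.

    Returns
    -------
    (G, R, source) DataFrames; ``source`` records, per off-diagonal cell,
    the model (pair key) the covariance came from.
    """
    t = len(trait_names)
    idx = {name: i for i, name in enumerate(trait_names)}
    G = np.full((t, t), np.nan)
    R = np.full((t, t), np.nan)
    diag_g: dict[int, list[float]] = {i: [] for i in range(t)}
    diag_r: dict[int, list[float]] = {i: [] for i in range(t)}
    source = np.full((t, t), "", dtype=object)

    seen = set()
    for (a, b), est in pairs.items():
        if a not in idx or b not in idx:
            raise ValueError(f"unknown trait in pair ({a}, {b})")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"pair ({a}, {b}) provided more than once")
        seen.add(key)
        i, j = idx[a], idx[b]
        g = np.asarray(est["G"], dtype=float)
        r = np.asarray(est["R"], dtype=float)
        G[i, j] = G[j, i] = g[0, 1]
        R[i, j] = R[j, i] = r[0, 1]
        source[i, j] = source[j, i] = f"{a}~{b}"
        diag_g[i].append(g[0, 0])
        diag_g[j].append(g[1, 1])
        diag_r[i].append(r[0, 0])
        diag_r[j].append(r[1, 1])

    for i in range(t):
        for j in range(i + 1, t):
            if np.isnan(G[i, j]):
                raise ValueError(
                    f"missing pairwise estimate for ({trait_names[i]}, {trait_names[j]})"
                )
    for i in range(t):
        if not diag_g[i]:
            raise ValueError(f"no variance estimate for trait {trait_names[i]}")
        G[i, i] = float(np.mean(diag_g[i]))
        R[i, i] = float(np.mean(diag_r[i]))

    as_df = lambda m: pd.DataFrame(m, index=trait_names, columns=trait_names)
    return as_df(G), as_df(R), as_df(source)


def bend_matrix(
    m: pd.DataFrame | np.ndarray, min_eig: float = 1e-3
) -> tuple[pd.DataFrame | np.ndarray, BendingReport]:
    """Floor the eigenvalues of a symmetric matrix at ``min_eig``.

    Eigenvectors are untouched, so bending is idempotent and a no-op for
    matrices already above the tolerance.
    """
    is_df = isinstance(m, pd.DataFrame)
    a = m.to_numpy(dtype=float) if is_df else np.asarray(m, dtype=float)
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    w, q = np.linalg.eigh(a)
    floored = w < min_eig
    w_new = np.maximum(w, min_eig)
    bent = (q * w_new) @ q.T
    bent = (bent + bent.T) / 2.0
    if not floored.any():
        bent = a.copy()
    report = BendingReport(
        min_eig_before=float(w.min()),
        min_eig_after=float(np.linalg.eigvalsh(bent).min()),
        max_abs_change=float(np.abs(bent - a).max()),
        n_floored=int(floored.sum()),
    )
    out = pd.DataFrame(bent, index=m.index, columns=m.columns) if is_df else bent
    return out, report


def validate_bending(
    original: np.ndarray,
    bent: np.ndarray,
    posterior_se: np.ndarray,
    R_original: np.ndarray | None = None,
    R_bent: np.ndarray | None = None,
    h2_tolerance: float = 0.05,
) -> dict:
    """Check the bent matrix against its estimation uncertainty.

    Passes when every |bent - original| entry is <= its posterior SE
    (inclusive) and, if residual matrices are supplied, when each trait's
    relative h2 shift is <= ``h2_tolerance`` (inclusive).
    """
    orig = np.asarray(original, dtype=float)
    new = np.asarray(bent, dtype=float)
    se = np.asarray(posterior_se, dtype=float)
    diff = np.abs(new - orig)
    entry_ok = diff <= se
    out = {
        "entries_ok": entry_ok,
        "all_entries_ok": bool(entry_ok.all()),
        "max_abs_change": float(diff.max()),
    }
    if R_original is not None:
        ro = np.asarray(R_original, dtype=float)
        rb = np.asarray(R_bent if R_bent is not None else R_original, dtype=float)
        h2_orig = np.diag(orig) / (np.diag(orig) + np.diag(ro))
        h2_bent = np.diag(new) / (np.diag(new) + np.diag(rb))
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = np.abs(h2_bent - h2_orig) / np.abs(h2_orig)
        shift = np.where(h2_orig == 0, np.abs(h2_bent - h2_orig), shift)
        # inclusive boundary, robust to roundoff at exactly the tolerance
        h2_ok = shift <= h2_tolerance + 1e-12
        out.update(
            {
                "h2_shift": shift,
                "h2_ok": h2_ok,
                "all_h2_ok": bool(h2_ok.all()),
            }
        )
    return out
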