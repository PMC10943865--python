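"""Genetic-parameter estimation campaign over growth and microbial traits.

Thin orchestration over the :class:`~magblup.gblup.GBLUP` sampler:

* per-MG univariate heritability scan;
* per-MG x per-ADG bivariate genomic-correlation scan (the rg catalog);
* the 4-trait growth analysis from six pairwise bivariate models, with
  each trait's h2 posterior pooled from the three bivariates that
  contain it;
* permutation null distribution of h2;
* prior-sensitivity reruns over a grid of prior degrees of freedom.

Each model derives its own seed deterministically from the master seed
and the trait id(s), so scans are order-independent and resumable.
"""

from __future__ import annotations

import itertools
import zlib

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from magblup.gblup import (
    GBLUP,
    McmcSettings,
    PriorSpec,
    summarize_posterior,
)


def seed_for(master_seed: int, *ids: str) -> int:
    """Deterministic 31-bit per-model seed from the master seed and ids."""
    tag = "|".join(str(i) for i in ids)
    return (int(master_seed) * 2654435761 + zlib.crc32(tag.encode())) % (2**31)


def _summary_row(summary, prefix: str = "") -> dict:
    d = summary.as_dict()
    return {f"{prefix}{k}": v for k, v in d.items()}


def _fit_univariate(y, K, X, prior: PriorSpec, mcmc: McmcSettings, seed: int):
    model = GBLUP(
        n_iter=mcmc.n_iter,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        seed=seed,
        df0_genomic=prior.df0_genomic,
        df0_residual=prior.df0_residual,
        r2=prior.r2,
        s0_genomic=prior.s0_genomic,
        s0_residual=prior.s0_residual,
        store_u=False,
    )
    model.fit(y, K, X)
    return model


def scan_mg_heritability(
    alr: pd.DataFrame,
    grm: pd.DataFrame,
    fixed_design: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Univariate h2 scan over every alr-MG column.

    Results are independent of execution order (per-MG seeds). Chains
    with |Geweke Z| > 3 or failing the MCSE check are flagged, not
    dropped.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    K = grm.to_numpy(dtype=float)

    def one(mg: str) -> dict:
        model = _fit_univariate(
            alr[mg].to_numpy(dtype=float),
            K,
            fixed_design,
            prior,
            mcmc,
            seed_for(master_seed, mg),
        )
        pars = model.genetic_parameters()
        s = pars["h2"][0]["summary"]
        flagged = (
            not np.isfinite(s.geweke_z) or abs(s.geweke_z) > 3 or not s.mcse_ok
        )
        return {"mg": mg, **_summary_row(s, "h2_"), "convergence_flag": flagged}

    rows = Parallel(n_jobs=n_jobs)(delayed(one)(mg) for mg in alr.columns)
    return pd.DataFrame(rows).set_index("mg")


def scan_mg_adg_correlations(
    alr: pd.DataFrame,
    adg: pd.DataFrame,
    grm: pd.DataFrame,
    fixed_design: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    rel_abundance: pd.Series | None = None,
    p0_threshold: float = 0.85,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Bivariate rg catalog: each alr-MG against each of the 4 ADG traits.

    Returns one row per MG with, per ADG trait: rg median, HPD95% bounds
    and P0, plus a ``nonzero_*`` flag at ``p0_threshold``, the MG h2
    (pooled over the four bivariates) and the numerator mean relative
    abundance when supplied.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    K = grm.to_numpy(dtype=float)
    adg = adg.reindex(alr.index)

    def one(mg: str) -> dict:
        row: dict = {"mg": mg}
        h2_chains = []
        for trait in adg.columns:
            y = np.column_stack(
                [adg[trait].to_numpy(dtype=float), alr[mg].to_numpy(dtype=float)]
            )
            model = _fit_univariate(
                y, K, fixed_design, prior, mcmc, seed_for(master_seed, mg, trait)
            )
            pars = model.genetic_parameters()
            s = pars["rg"][(0, 1)]["summary"]
            row[f"rg_{trait}"] = s.median
            row[f"rg_low_{trait}"] = s.hpd95_low
            row[f"rg_high_{trait}"] = s.hpd95_high
            row[f"p0_{trait}"] = s.p0
            row[f"nonzero_{trait}"] = s.p0 >= p0_threshold
            h2_chains.append(pars["h2"][1]["chain"])
        row["h2_mg"] = float(np.median(np.concatenate(h2_chains)))
        if rel_abundance is not None:
            row["rel_abundance"] = float(rel_abundance[mg])
        return row

    rows = Parallel(n_jobs=n_jobs)(delayed(one)(mg) for mg in alr.columns)
    catalog = pd.DataFrame(rows).set_index("mg")
    return catalog


def nonzero_counts(catalog: pd.DataFrame) -> pd.Series:
    """Number of credibly non-zero rg per ADG trait, plus the union count."""
    cols = [c for c in catalog.columns if c.startswith("nonzero_")]
    counts = catalog[cols].sum(axis=0).astype(int)
    counts["any"] = int(catalog[cols].any(axis=1).sum())
    return counts


def estimate_adg_parameters(
    adg: pd.DataFrame,
    grm: pd.DataFrame,
    fixed_design: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    master_seed: int = 0,
) -> dict:
    """Growth-trait h2 and rg from the six pairwise bivariate models.

    Each trait's h2 posterior pools (concatenates) the three thinned h2
    chains from the bivariates involving it. Also returns the per-pair
    2x2 G/R posterior medians and SEs needed for covariance assembly.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    K = grm.to_numpy(dtype=float)
    traits = list(adg.columns)
    h2_chains: dict[str, list[np.ndarray]] = {t: [] for t in traits}
    rg_summaries: dict[tuple, object] = {}
    pairwise: dict[tuple, dict] = {}

    for a, b in itertools.combinations(traits, 2):
        y = np.column_stack(
            [adg[a].to_numpy(dtype=float), adg[b].to_numpy(dtype=float)]
        )
        model = _fit_univariate(
            y, K, fixed_design, prior, mcmc, seed_for(master_seed, a, b)
        )
        pars = model.genetic_parameters()
        h2_chains[a].append(pars["h2"][0]["chain"])
        h2_chains[b].append(pars["h2"][1]["chain"])
        rg_summaries[(a, b)] = pars["rg"][(0, 1)]["summary"]
        pairwise[(a, b)] = {
            "G": np.median(model.G_chain_, axis=0),
            "R": np.median(model.R_chain_, axis=0),
            "G_se": model.G_chain_.std(axis=0, ddof=1),
            "R_se": model.R_chain_.std(axis=0, ddof=1),
        }

    h2_summaries = {
        t: summarize_posterior(np.concatenate(chains))
        for t, chains in h2_chains.items()
    }
    return {
        "h2": h2_summaries,
        "h2_chains": {t: np.concatenate(c) for t, c in h2_chains.items()},
        "rg": rg_summaries,
        "pairwise": pairwise,
    }


def permutation_null(
    y: np.ndarray,
    grm: pd.DataFrame,
    fixed_design: np.ndarray,
    n_perm: int = 1000,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Null h2 distribution from re-fits after permuting phenotype rows.

    Only the phenotype vector is shuffled; the GRM and fixed-effect
    design stay in place, severing the genotype-phenotype link.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    y = np.asarray(y, dtype=float).ravel()
    K = grm.to_numpy(dtype=float)

    def one(r: int) -> dict:
        rng = np.random.default_rng(seed_for(seed, "perm", str(r)))
        perm = rng.permutation(y.size)
        model = _fit_univariate(
            y[perm], K, fixed_design, prior, mcmc, seed_for(seed, "fit", str(r))
        )
        s = model.genetic_parameters()["h2"][0]["summary"]
        return {"replicate": r, "h2_median": s.median}

    rows = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(n_perm))
    return pd.DataFrame(rows).set_index("replicate")


def prior_sensitivity(
    y: np.ndarray,
    grm: pd.DataFrame,
    fixed_design: np.ndarray,
    df0_list: tuple[float, ...] = (1, 5, 10, 20),
    mcmc: McmcSettings | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Re-estimate h2 (or rg for 2-column y) across prior df0 settings.

    S0 is recomputed for each df0 from the phenotypic variance, so only
    the prior informativeness changes across rows.
    """
    mcmc = mcmc or McmcSettings()
    y = np.asarray(y, dtype=float)
    K = grm.to_numpy(dtype=float)
    bivariate = y.ndim == 2 and y.shape[1] == 2
    rows = []
    for df0 in df0_list:
        prior = PriorSpec(df0_genomic=float(df0))
        model = _fit_univariate(
            y, K, fixed_design, prior, mcmc, seed_for(master_seed, "df0", str(df0))
        )
        pars = model.genetic_parameters()
        row = {"df0": df0, "h2_median": pars["h2"][0]["summary"].median}
        if bivariate:
            row["rg_median"] = pars["rg"][(0, 1)]["summary"].median
        row["s0_genomic"] = float(model.S0_genomic_[0, 0])
        rows.append(row)
    return pd.DataFrame(rows).set_index("df0")
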