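"""Reference desk-scale evaluation scenarios.

These fix the synthetic study conditions used by the package's own
validation runs: a 400-head half-sib, multi-breed herd genotyped at
2000 SNPs, four growth traits at the study-scale heritabilities and
genomic correlations, and ten microbial traits each genomically
correlated (|rg| = 0.3) with one growth trait. Scenario parameters are
part of the package contract and are not tuning knobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from magblup.gblup import design_matrix
from magblup.growth import ADG_NAMES, adg_table
from magblup.simulate import SimulationConfig, SyntheticDataset, simulate_dataset

#: every MG links to one ADG trait, round-robin, alternating sign
RECOVERY_LINKS = {
    i: {i % 4: 0.3 if i % 2 == 0 else -0.3} for i in range(10)
}

#: weight-slope measurement noise variance implied by 2 kg weighing error
#: over a 5-point window: sigma^2 / sum (x - xbar)^2 = 4 / 490
SLOPE_NOISE_VAR = 4.0 / 490.0


def recovery_config(seed: int) -> SimulationConfig:
    """The 4-trait + 10-MG parameter-recovery scenario."""
    return SimulationConfig(
        n_animals=400,
        n_sires_extra=30,
        n_snps=2000,
        n_mg=10,
        mg_adg_rg=RECOVERY_LINKS,
        seed=seed,
    )


def prepared_recovery_data(seed: int) -> dict:
    """Simulate the recovery scenario and assemble model-ready tables.

    Returns the phenotyped-animal ADG table, latent alr-MG phenotypes,
    GRM, fixed-effect design, the dataset bundle and the realized truth
    (variance of the drawn breeding values against the residual variance,
    with the weighing-noise slope variance folded into the residual).
    """
    cfg = recovery_config(seed)
    data = simulate_dataset(cfg)
    adg = adg_table(data.weights)
    pheno = adg.index
    grm = data.grm.loc[pheno, pheno]
    X = design_matrix(data.truth.fixed_level.reindex(pheno))
    alr = data.truth.latent_log_abundance

    ut = data.truth.true_u.loc[pheno, ADG_NAMES].to_numpy()
    se2 = data.truth.true_sigma_e2[ADG_NAMES].to_numpy() + SLOPE_NOISE_VAR
    su2 = ut.var(axis=0, ddof=1)
    h2_real = su2 / (su2 + se2)
    rg13_real = float(
        np.corrcoef(
            data.truth.true_u.loc[pheno, "ADG_1"],
            data.truth.true_u.loc[pheno, "ADG_3"],
        )[0, 1]
    )
    mg_rg_real = {}
    for mg, links in RECOVERY_LINKS.items():
        mg_id = data.truth.latent_log_abundance.columns[mg]
        (adg_idx, _), = links.items()
        trait = ADG_NAMES[adg_idx]
        mg_rg_real[mg_id] = (
            trait,
            float(
                np.corrcoef(
                    data.truth.true_u.loc[pheno, trait],
                    data.truth.true_u.loc[pheno, mg_id],
                )[0, 1]
            ),
        )
    return {
        "config": cfg,
        "data": data,
        "adg": adg,
        "alr": alr,
        "grm": grm,
        "X": X,
        "h2_real": dict(zip(ADG_NAMES, h2_real)),
        "rg13_real": rg13_real,
        "mg_rg_real": mg_rg_real,
    }


def strategy_tables(data: SyntheticDataset) -> dict:
    """Full-herd tables (sires carried with missing phenotypes) plus the
    true (G, R) used as the fixed covariances of the strategy runs."""
    cfg = data.config
    grm = data.grm
    animals = list(grm.index)
    pheno = data.truth.latent_log_abundance.index
    adg = adg_table(data.weights).reindex(animals)
    mg_cols = list(data.truth.latent_log_abundance.columns)
    alr = pd.DataFrame(np.nan, index=animals, columns=mg_cols)
    alr.loc[pheno] = data.truth.latent_log_abundance.to_numpy()
    X = design_matrix(data.truth.fixed_level.reindex(animals).fillna("sire"))
    names = ADG_NAMES + mg_cols
    su = np.sqrt(data.truth.true_sigma_u2[names].to_numpy())
    idx = [cfg.trait_names.index(t) for t in names]
    corr = data.truth.genetic_corr[np.ix_(idx, idx)]
    G = pd.DataFrame(corr * np.outer(su, su), index=names, columns=names)
    se2 = data.truth.true_sigma_e2[names].to_numpy().copy()
    se2[:4] += SLOPE_NOISE_VAR
    R = pd.DataFrame(np.diag(se2), index=names, columns=names)
    return {"adg": adg, "alr": alr, "grm": grm, "X": X, "G": G, "R": R}
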