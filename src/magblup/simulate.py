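"""Synthetic herd generator with the statistical structure the pipeline assumes.

Emulated study conditions: ~359 phenotyped beef cattle plus a handful of
genotyped-only sires; biallelic SNPs in Hardy-Weinberg proportions;
17 weekly body weights per animal over four consecutive 4-week intervals
with interval ADG means near 1.57/1.50/1.48/1.41 kg/day; a 17-level
diet x breed x year fixed-effect factor; heritabilities around 0.3 for
growth and 0.19-0.44 for microbial traits; and multinomial KO sequencing
counts whose log-scale latent abundances carry genomic, fixed and
residual components, so structural zeros arise naturally at low depth.

Breeding values are drawn with covariance (genetic scale) (x) GRM via
Cholesky factors of both matrices, so the full pipeline can be checked by
parameter recovery against the stored ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from magblup.grm import compute_grm
from magblup.growth import ADG_NAMES

WEEK = 7
N_WEIGHTS = 17
N_ADG = 4

#: interval mean gains (kg/day) matching the finishing-period study design
DEFAULT_ADG_MEANS = (1.57, 1.50, 1.48, 1.41)
#: growth heritabilities for the four intervals
DEFAULT_H2_ADG = (0.31, 0.27, 0.29, 0.27)
#: genomic correlations among the four interval gains
DEFAULT_ADG_CORR = np.array(
    [
        [1.00, 0.30, 0.39, 0.07],
        [0.30, 1.00, 0.25, 0.15],
        [0.39, 0.25, 1.00, -0.13],
        [0.07, 0.15, -0.13, 1.00],
    ]
)


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the study herd (scaled SNP count).

    ``genetic_corr`` may be given explicitly ((4 + n_mg) square correlation
    matrix); when None a block structure is built: the ADG block above,
    independent MG, and ``mg_adg_rg`` injected for the first MG against
    the chosen ADG trait(s).
    """

    n_animals: int = 359
    n_sires_extra: int = 30
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_mg: int = 100
    h2_adg: tuple[float, ...] = DEFAULT_H2_ADG
    h2_mg: tuple[float, float] = (0.19, 0.44)
    genetic_corr: np.ndarray | None = None
    mg_adg_rg: dict[int, dict[int, float]] = field(default_factory=dict)
    adg_means: tuple[float, ...] = DEFAULT_ADG_MEANS
    adg_phen_sd: float = 0.42
    mg_phen_sd: float = 0.55
    n_fixed_levels: int = 17
    fixed_sd_adg: float = 0.10
    fixed_sd_mg: float = 0.30
    start_weight_mean: float = 450.0
    start_weight_sd: float = 40.0
    weight_noise_sd: float = 2.0
    depth_range: tuple[int, int] = (50_000, 200_000)
    missing_geno_rate: float = 0.0
    use_grm_for_effects: bool = True
    family_structure: bool = True
    n_breeds: int = 3
    fst: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if len(self.h2_adg) != N_ADG or len(self.adg_means) != N_ADG:
            raise ValueError("h2_adg and adg_means must have 4 entries")
        for h in self.h2_adg:
            if not 0.0 <= h <= 1.0:
                raise ValueError("heritabilities must lie in [0, 1]")
        if self.n_animals < 2 or self.n_snps < 1:
            raise ValueError("need n_animals >= 2 and n_snps >= 1")

    @property
    def n_traits(self) -> int:
        return N_ADG + self.n_mg

    @property
    def trait_names(self) -> list[str]:
        return ADG_NAMES + mg_ids(self.n_mg)


def mg_ids(n_mg: int) -> list[str]:
    """KO-style identifiers K00001.. for the simulated microbial genes."""
    return [f"K{i + 1:05d}" for i in range(n_mg)]


@dataclass
class TrueParameters:
    """Ground truth for recovery tests."""

    true_u: pd.DataFrame  # animals x traits breeding values
    true_b: pd.DataFrame  # fixed-effect solutions, levels x traits
    fixed_level: pd.Series  # level assignment per phenotyped animal
    true_sigma_u2: pd.Series  # per-trait genomic variances
    true_sigma_e2: pd.Series  # per-trait residual variances
    latent_log_abundance: pd.DataFrame  # samples x MG
    genetic_corr: np.ndarray


def build_genetic_corr(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Block correlation matrix over (4 ADG + n_mg) traits.

    ADG block from the study-scale defaults; MG mutually independent;
    MG-ADG entries zero unless injected through ``cfg.mg_adg_rg``
    (mapping mg index -> {adg index -> rg}).
    """
    t = cfg.n_traits
    corr = np.eye(t)
    corr[:N_ADG, :N_ADG] = DEFAULT_ADG_CORR
    for mg_idx, links in cfg.mg_adg_rg.items():
        for adg_idx, rg in links.items():
            corr[N_ADG + mg_idx, adg_idx] = rg
            corr[adg_idx, N_ADG + mg_idx] = rg
    return corr


def _validate_corr(corr: np.ndarray, t: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (t, t):
        raise ValueError(f"genetic_corr must be {t} x {t}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("genetic_corr must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError("genetic_corr must have a unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("genetic_corr is not positive semidefinite")
    return corr


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Dosage matrix for phenotyped animals plus genotyped-only sires.

    Each SNP draws its allele frequency uniformly on ``maf_range``. With
    ``family_structure`` (and sires present) the phenotyped animals form
    half-sib families: each inherits one allele by Mendelian transmission
    from a randomly assigned sire and one from the base population, which
    reproduces the relatedness a sire-structured herd carries while
    keeping Hardy-Weinberg margins. Otherwise (or for the sires
    themselves) dosages are two independent Bernoulli(p) allele draws.
    The herd is multi-breed: with ``n_breeds > 1``, breed-specific allele
    frequencies follow the Balding-Nichols model around the base
    frequency with differentiation ``fst``, as in a crossbred/purebred
    beef herd. SNPs are unlinked.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_animals + cfg.n_sires_extra
    p = rng.uniform(*cfg.maf_range, size=cfg.n_snps)

    if cfg.n_breeds > 1 and cfg.fst > 0:
        shape = (1.0 - cfg.fst) / cfg.fst
        p_breed = rng.beta(p * shape, (1.0 - p) * shape, size=(cfg.n_breeds, cfg.n_snps))
        p_breed = np.clip(p_breed, 1e-4, 1 - 1e-4)
    else:
        p_breed = np.tile(p, (max(cfg.n_breeds, 1), 1))

    breed_of_animal = rng.integers(0, max(cfg.n_breeds, 1), size=cfg.n_animals)
    breed_of_sire = rng.integers(0, max(cfg.n_breeds, 1), size=cfg.n_sires_extra)

    if cfg.family_structure and cfg.n_sires_extra > 0:
        ps = p_breed[breed_of_sire]
        sires = (rng.binomial(1, ps) + rng.binomial(1, ps)).astype(float)
        # sires serve their own breed where possible
        sire_of = np.empty(cfg.n_animals, dtype=int)
        for i, b in enumerate(breed_of_animal):
            own = np.where(breed_of_sire == b)[0]
            pool = own if own.size else np.arange(cfg.n_sires_extra)
            sire_of[i] = pool[rng.integers(0, pool.size)]
        paternal = rng.binomial(1, sires[sire_of] / 2.0)
        maternal = rng.binomial(1, p_breed[breed_of_animal])
        dosages = np.vstack([(paternal + maternal).astype(float), sires])
    else:
        pa = p_breed[breed_of_animal]
        offspring = (rng.binomial(1, pa) + rng.binomial(1, pa)).astype(float)
        if cfg.n_sires_extra > 0:
            ps = p_breed[breed_of_sire]
            sires = (rng.binomial(1, ps) + rng.binomial(1, ps)).astype(float)
            dosages = np.vstack([offspring, sires])
        else:
            dosages = offspring
    if cfg.missing_geno_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_geno_rate
        dosages[mask] = np.nan
    ids = [f"A{i + 1:04d}" for i in range(cfg.n_animals)] + [
        f"S{i + 1:04d}" for i in range(cfg.n_sires_extra)
    ]
    snps = [f"snp{j + 1:05d}" for j in range(cfg.n_snps)]
    return pd.DataFrame(dosages, index=ids, columns=snps)


def simulate_true_effects(
    cfg: SimulationConfig,
    grm: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> TrueParameters:
    """Breeding values, fixed effects and latent MG abundances.

    u is drawn with covariance S ⊗ GRM, S the genetic scale matrix built
    from per-trait genomic variances (h2 targets against the configured
    phenotypic variances) and the genetic correlation matrix.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    t = cfg.n_traits
    corr = (
        build_genetic_corr(cfg, rng)
        if cfg.genetic_corr is None
        else cfg.genetic_corr
    )
    corr = _validate_corr(corr, t)

    h2_mg = (
        rng.uniform(*cfg.h2_mg, size=cfg.n_mg)
        if len(cfg.h2_mg) == 2
        else np.asarray(cfg.h2_mg, dtype=float)
    )
    h2 = np.concatenate([np.asarray(cfg.h2_adg, dtype=float), h2_mg])
    phen_var = np.concatenate(
        [
            np.full(N_ADG, cfg.adg_phen_sd**2),
            np.full(cfg.n_mg, cfg.mg_phen_sd**2),
        ]
    )
    sigma_u2 = h2 * phen_var
    sigma_e2 = (1.0 - h2) * phen_var

    su = np.sqrt(sigma_u2)
    scale = corr * np.outer(su, su)
    # Cholesky of the trait scale; zero-variance traits stay exactly zero
    w, q = np.linalg.eigh(scale)
    l_scale = q @ np.diag(np.sqrt(np.maximum(w, 0.0)))

    k = grm.to_numpy(dtype=float)
    if not np.allclose(k, k.T, atol=1e-8):
        raise ValueError("grm must be symmetric")
    wk, qk = np.linalg.eigh(k)
    if wk.min() < -1e-6:
        raise ValueError("grm must be positive semidefinite")
    l_grm = qk @ np.diag(np.sqrt(np.maximum(wk, 0.0)))

    n = k.shape[0]
    u = l_grm @ rng.standard_normal((n, t)) @ l_scale.T
    u[:, sigma_u2 == 0.0] = 0.0
    true_u = pd.DataFrame(u, index=grm.index, columns=cfg.trait_names)

    b = rng.normal(
        0.0,
        np.concatenate(
            [np.full(N_ADG, cfg.fixed_sd_adg), np.full(cfg.n_mg, cfg.fixed_sd_mg)]
        ),
        size=(cfg.n_fixed_levels, t),
    )
    true_b = pd.DataFrame(
        b, index=[f"L{i + 1:02d}" for i in range(cfg.n_fixed_levels)],
        columns=cfg.trait_names,
    )
    pheno_ids = [i for i in grm.index if str(i).startswith("A")][: cfg.n_animals]
    levels = pd.Series(
        rng.integers(0, cfg.n_fixed_levels, size=len(pheno_ids)),
        index=pheno_ids,
        name="level",
    ).map(lambda i: true_b.index[i])

    # latent log abundance: MG baseline + fixed + genomic + residual
    base = rng.normal(0.0, 2.0, size=cfg.n_mg)
    mg_cols = cfg.trait_names[N_ADG:]
    e = rng.normal(
        0.0, np.sqrt(sigma_e2[N_ADG:]), size=(len(pheno_ids), cfg.n_mg)
    )
    latent = (
        base
        + true_b.loc[levels.to_numpy(), mg_cols].to_numpy()
        + true_u.loc[pheno_ids, mg_cols].to_numpy()
        + e
    )
    latent_df = pd.DataFrame(latent, index=pheno_ids, columns=mg_cols)

    names = cfg.trait_names
    return TrueParameters(
        true_u=true_u,
        true_b=true_b,
        fixed_level=levels,
        true_sigma_u2=pd.Series(sigma_u2, index=names),
        true_sigma_e2=pd.Series(sigma_e2, index=names),
        latent_log_abundance=latent_df,
        genetic_corr=corr,
    )


def simulate_weight_series(
    true: TrueParameters,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long table of 17 weekly weights per phenotyped animal.

    The latent trajectory is piecewise linear and continuous: within
    interval k the slope is adg_means[k] + b_k + u_k + e_k; i.i.d.
    measurement noise of sd ``weight_noise_sd`` is added on top.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    animals = true.latent_log_abundance.index
    n = len(animals)
    slopes = np.tile(np.asarray(cfg.adg_means), (n, 1))
    slopes += true.true_b.loc[true.fixed_level.to_numpy(), ADG_NAMES].to_numpy()
    slopes += true.true_u.loc[animals, ADG_NAMES].to_numpy()
    slopes += rng.normal(
        0.0, np.sqrt(true.true_sigma_e2[ADG_NAMES].to_numpy()), size=(n, N_ADG)
    )

    start = rng.normal(cfg.start_weight_mean, cfg.start_weight_sd, size=n)
    days = np.arange(N_WEIGHTS) * WEEK
    # interval index of each 7-day step (4 steps per interval)
    step_interval = np.repeat(np.arange(N_ADG), 4)
    increments = slopes[:, step_interval] * WEEK
    traj = np.column_stack([start, start[:, None] + np.cumsum(increments, axis=1)])
    traj = traj + rng.normal(0.0, cfg.weight_noise_sd, size=traj.shape)

    return pd.DataFrame(
        {
            "animal": np.repeat(animals, N_WEIGHTS),
            "day": np.tile(days, n),
            "weight_kg": traj.ravel(),
        }
    )


def simulate_mg_counts(
    true: TrueParameters,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Multinomial KO counts per sample from the latent log abundances.

    Depth is drawn uniformly on ``depth_range``; category probabilities
    are the softmax of the sample's latent log-abundance row.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    if cfg.depth_range[0] < cfg.n_mg:
        import warnings

        warnings.warn(
            "minimum depth below the number of MG; expect extreme zero inflation",
            stacklevel=2,
        )
    latent = true.latent_log_abundance.to_numpy()
    z = latent - latent.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    depths = rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1, size=latent.shape[0])
    counts = np.vstack(
        [rng.multinomial(depth, p) for depth, p in zip(depths, probs)]
    )
    return pd.DataFrame(
        counts,
        index=true.latent_log_abundance.index,
        columns=true.latent_log_abundance.columns,
    )


@dataclass
class SyntheticDataset:
    """Bundle of generated inputs plus ground truth."""

    config: SimulationConfig
    genotypes: pd.DataFrame
    grm: pd.DataFrame
    weights: pd.DataFrame
    counts: pd.DataFrame
    fixed_effects: pd.DataFrame
    truth: TrueParameters

    def to_dir(self, path: str | Path) -> None:
        """Write the pipeline's TSV inputs plus a JSON ground-truth file."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_csv(path / "genotypes.tsv", sep="\t", index_label="animal")
        self.weights.to_csv(path / "weights.tsv", sep="\t", index=False)
        self.counts.to_csv(path / "ko_counts.tsv", sep="\t", index_label="sample")
        self.fixed_effects.to_csv(path / "fixed_effects.tsv", sep="\t", index=False)
        truth = {
            "sigma_u2": self.truth.true_sigma_u2.to_dict(),
            "sigma_e2": self.truth.true_sigma_e2.to_dict(),
            "h2": (
                self.truth.true_sigma_u2
                / (self.truth.true_sigma_u2 + self.truth.true_sigma_e2)
            ).to_dict(),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
                if not isinstance(v, (np.ndarray, dict))
            },
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=2))
        self.truth.true_u.to_csv(path / "true_breeding_values.tsv", sep="\t")


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full input bundle under one master seed."""
    rng = np.random.default_rng(cfg.seed)
    genotypes = simulate_genotypes(cfg, rng)
    complete = genotypes.fillna(genotypes.mean(axis=0)) if cfg.missing_geno_rate else genotypes
    if cfg.use_grm_for_effects:
        p_obs = complete.mean(axis=0) / 2.0
        poly = complete.loc[:, (p_obs > 0) & (p_obs < 1)]
        grm = compute_grm(poly)
    else:
        grm = pd.DataFrame(
            np.eye(len(genotypes)), index=genotypes.index, columns=genotypes.index
        )
    truth = simulate_true_effects(cfg, grm, rng)
    weights = simulate_weight_series(truth, cfg, rng)
    counts = simulate_mg_counts(truth, cfg, rng)
    fixed = pd.DataFrame(
        {"animal": truth.fixed_level.index, "level": truth.fixed_level.to_numpy()}
    )
    return SyntheticDataset(
        config=cfg,
        genotypes=genotypes,
        grm=grm,
        weights=weights,
        counts=counts,
        fixed_effects=fixed,
        truth=truth,
    )
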