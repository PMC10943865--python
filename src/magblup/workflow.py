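"""End-to-end pipeline orchestration with checkpointed stages.

A run is driven by a :class:`RunConfig` (typically parsed from YAML).
Stages execute in the analysis order — simulate (optional), adg, grm,
compose, scan-h2, scan-rg, adg-params, assemble, select, evaluate —
and every stage writes its artifacts plus a sidecar JSON carrying the
stage name, a config hash and the master seed. A stage whose sidecar
matches the current config hash is skipped on resume.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from magblup import (
    AlrTransform,
    CoreFilter,
    GbmZeroImputer,
    McmcSettings,
    QcThresholds,
    SimulationConfig,
    adg_table,
    assemble_covariances,
    bend_matrix,
    compute_grm,
    filter_candidates,
    predicted_response,
    qc_filter,
    run_strategy,
    select_alr_reference,
    simulate_dataset,
    stepwise_select,
    uniform_sign_subset,
)
from magblup.gblup import GBLUP, design_matrix
from magblup.growth import ADG_NAMES
from magblup.params import (
    estimate_adg_parameters,
    scan_mg_adg_correlations,
    scan_mg_heritability,
    seed_for,
)

ALL_STAGES = [
    "simulate",
    "adg",
    "grm",
    "compose",
    "scan-h2",
    "scan-rg",
    "adg-params",
    "select",
    "assemble",
    "evaluate",
]


@dataclass
class RunConfig:
    """Run settings; paths may be None when the simulate stage provides them."""

    outdir: str = "magblup_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    genotypes_tsv: str | None = None
    weights_tsv: str | None = None
    ko_counts_tsv: str | None = None
    fixed_effects_tsv: str | None = None
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    presence_frac: float = 0.70
    alr_top_quantile: float = 0.10
    p0_threshold: float = 0.85
    min_rel_abundance: float = 1e-5
    quota_per_trait: int = 8
    selection_proportion: float = 0.10
    bend_min_eig: float = 1e-3
    mcmc: dict = field(default_factory=dict)
    max_id_drop_fraction: float = 0.5
    uniform_subset: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def config_hash(self) -> str:
        # stage selection and input paths (mutated by the simulate stage)
        # do not alter what a stage computes from given file contents
        skip = {"stages", "genotypes_tsv", "weights_tsv", "ko_counts_tsv",
                "fixed_effects_tsv"}
        payload = {k: v for k, v in asdict(self).items() if k not in skip}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def mcmc_settings(self, seed: int | None = None) -> McmcSettings:
        kwargs = dict(self.mcmc)
        kwargs.setdefault("seed", self.seed if seed is None else seed)
        return McmcSettings(**kwargs)


def _read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def load_inputs(cfg: RunConfig) -> dict:
    """Read and reconcile the four input tables on shared animal ids.

    Animals present in the genotype table but absent from the weight or
    microbiome tables are kept with missing phenotypes (that is how
    genotyped-only sires enter); the reconciliation report counts ids
    kept and dropped per source. A drop fraction above
    ``max_id_drop_fraction`` in any phenotype source is an error.
    """
    genotypes = _read_tsv(cfg.genotypes_tsv, index_col=0)
    weights = _read_tsv(cfg.weights_tsv)
    bad = pd.to_numeric(weights["weight_kg"], errors="coerce").isna()
    if bad.any():
        line = int(np.where(bad)[0][0]) + 2  # header + 1-based
        raise ValueError(f"non-numeric weight_kg at line {line} of weights table")
    counts = _read_tsv(cfg.ko_counts_tsv, index_col=0)
    fixed = _read_tsv(cfg.fixed_effects_tsv)

    geno_ids = set(genotypes.index)
    report = {"n_genotyped": len(geno_ids)}
    for name, ids in (
        ("weights", set(weights["animal"])),
        ("ko_counts", set(counts.index)),
        ("fixed_effects", set(fixed["animal"])),
    ):
        kept = ids & geno_ids
        report[name] = {"kept": len(kept), "dropped": len(ids - geno_ids)}
        if ids and len(ids - geno_ids) / len(ids) > cfg.max_id_drop_fraction:
            raise ValueError(
                f"{name}: {len(ids - geno_ids)}/{len(ids)} ids not genotyped; "
                "check id reconciliation"
            )
    weights = weights[weights["animal"].isin(geno_ids)]
    counts = counts.loc[[i for i in counts.index if i in geno_ids]]
    fixed = fixed[fixed["animal"].isin(geno_ids)]
    return {
        "genotypes": genotypes,
        "weights": weights,
        "counts": counts,
        "fixed": fixed,
        "report": report,
    }


class PipelineRun:
    """Stateful executor writing checkpointed artifacts under ``outdir``."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.ctx: dict = {}

    # -- checkpoint helpers -------------------------------------------------

    def _sidecar(self, stage: str) -> Path:
        return self.outdir / f"{stage}.stage.json"

    def _is_done(self, stage: str) -> bool:
        sc = self._sidecar(stage)
        if not sc.exists():
            return False
        meta = json.loads(sc.read_text())
        return meta.get("config_hash") == self.cfg.config_hash()

    def _mark_done(self, stage: str, elapsed: float, **extra) -> None:
        meta = {
            "stage": stage,
            "config_hash": self.cfg.config_hash(),
            "seed": self.cfg.seed,
            "elapsed_s": round(elapsed, 3),
            **extra,
        }
        self._sidecar(stage).write_text(json.dumps(meta, indent=2, default=str))

    def _write(self, name: str, df: pd.DataFrame, **kwargs) -> None:
        df.to_csv(self.outdir / name, sep="\t", **kwargs)

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> None:
        sim_cfg = SimulationConfig(**{"seed": self.cfg.seed, **self.cfg.simulate})
        data = simulate_dataset(sim_cfg)
        data.to_dir(self.outdir / "inputs")
        for key in ("genotypes", "weights", "ko_counts", "fixed_effects"):
            fname = {"genotypes": "genotypes.tsv", "weights": "weights.tsv",
                     "ko_counts": "ko_counts.tsv", "fixed_effects": "fixed_effects.tsv"}[key]
            setattr(self.cfg, f"{key}_tsv", str(self.outdir / "inputs" / fname))
        self.ctx["truth"] = data.truth

    def stage_adg(self) -> None:
        inputs = self.ctx["inputs"]
        adg = adg_table(inputs["weights"])
        self.ctx["adg"] = adg
        self._write("adg.tsv", adg)

    def stage_grm(self) -> None:
        inputs = self.ctx["inputs"]
        filtered, report = qc_filter(
            inputs["genotypes"], QcThresholds(**self.cfg.qc)
        )
        grm = compute_grm(filtered)
        self.ctx["grm"] = grm
        self._write("grm.tsv", grm)
        (self.outdir / "qc_report.json").write_text(
            json.dumps(report, indent=2)
        )

    def stage_compose(self) -> None:
        inputs = self.ctx["inputs"]
        counts = inputs["counts"]
        core = CoreFilter(self.cfg.presence_frac).fit(counts)
        kept = core.transform(counts)
        comp = GbmZeroImputer().fit(kept).transform(kept)
        ref, diag = select_alr_reference(comp, self.cfg.alr_top_quantile)
        alr = AlrTransform(ref).fit(comp).transform(comp)
        self.ctx["alr"] = alr
        self.ctx["rel_abundance"] = comp.mean(axis=0)
        self.ctx["alr_reference"] = ref
        self._write("alr.tsv", alr)
        self._write("composition.tsv", comp)
        self._write("alr_reference_diagnostics.tsv", diag)

    def _aligned(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, np.ndarray]:
        """alr/adg/grm restricted to animals with microbiome data, plus X."""
        alr = self.ctx["alr"]
        adg = self.ctx["adg"]
        grm = self.ctx["grm"]
        animals = [a for a in alr.index if a in grm.index and a in adg.index]
        fixed = self.ctx["inputs"]["fixed"].set_index("animal")["level"]
        X = design_matrix(fixed.reindex(animals).fillna("L00"))
        return (
            alr.loc[animals],
            adg.loc[animals],
            grm.loc[animals, animals],
            X,
        )

    def stage_scan_h2(self) -> None:
        alr, _, grm, X = self._aligned()
        table = scan_mg_heritability(
            alr, grm, X, mcmc=self.cfg.mcmc_settings(), master_seed=self.cfg.seed
        )
        self.ctx["mg_h2"] = table
        self._write("mg_h2.tsv", table)

    def stage_scan_rg(self) -> None:
        alr, adg, grm, X = self._aligned()
        catalog = scan_mg_adg_correlations(
            alr,
            adg,
            grm,
            X,
            mcmc=self.cfg.mcmc_settings(),
            rel_abundance=self.ctx["rel_abundance"],
            p0_threshold=self.cfg.p0_threshold,
            master_seed=self.cfg.seed,
        )
        self.ctx["catalog"] = catalog
        self._write("rg_catalog.tsv", catalog)

    def stage_adg_params(self) -> None:
        _, adg, grm, X = self._aligned()
        res = estimate_adg_parameters(
            adg, grm, X, mcmc=self.cfg.mcmc_settings(), master_seed=self.cfg.seed
        )
        self.ctx["adg_params"] = res
        rows = [
            {"trait": t, **s.as_dict()} for t, s in res["h2"].items()
        ]
        self._write("adg_h2.tsv", pd.DataFrame(rows).set_index("trait"))
        rows = [
            {"pair": f"{a}~{b}", **s.as_dict()}
            for (a, b), s in res["rg"].items()
        ]
        self._write("adg_rg.tsv", pd.DataFrame(rows).set_index("pair"))

    def stage_select(self) -> None:
        alr, adg, grm, X = self._aligned()
        catalog = self.ctx["catalog"]
        candidates = filter_candidates(
            catalog, self.cfg.p0_threshold, self.cfg.min_rel_abundance
        )
        if self.cfg.uniform_subset:
            candidates = uniform_sign_subset(candidates, catalog)
        mcmc = self.cfg.mcmc_settings()
        gebv_adg = {}
        for t in adg.columns:
            m = GBLUP(
                n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
                seed=seed_for(self.cfg.seed, "gebv", t), store_u=True,
            ).fit(adg[t].to_numpy(dtype=float), grm.to_numpy(), X)
            gebv_adg[t] = m.u_mean_[:, 0]
        gebv_mg = {}
        for mg in candidates:
            m = GBLUP(
                n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
                seed=seed_for(self.cfg.seed, "gebv", mg), store_u=True,
            ).fit(alr[mg].to_numpy(dtype=float), grm.to_numpy(), X)
            gebv_mg[mg] = m.u_mean_[:, 0]
        quota = self.cfg.quota_per_trait
        n_needed = 4 * quota
        if len(candidates) < n_needed:
            quota = max(len(candidates) // 4, 1)
        result = stepwise_select(
            pd.DataFrame(gebv_adg, index=adg.index),
            pd.DataFrame(gebv_mg, index=adg.index),
            quota_per_trait=quota,
            label="uniform" if self.cfg.uniform_subset else "non-uniform",
        )
        self.ctx["selection"] = result
        self._write("selection.tsv", result.to_frame(), index=False)

    def stage_assemble(self) -> None:
        alr, adg, grm, X = self._aligned()
        selected = self.ctx["selection"].selected
        traits = list(adg.columns) + selected
        data = pd.concat([adg, alr[selected]], axis=1)
        mcmc = self.cfg.mcmc_settings()
        pairs: dict = {}
        import itertools

        for a, b in itertools.combinations(traits, 2):
            y = np.column_stack(
                [data[a].to_numpy(dtype=float), data[b].to_numpy(dtype=float)]
            )
            m = GBLUP(
                n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
                seed=seed_for(self.cfg.seed, "pair", a, b), store_u=False,
            ).fit(y, grm.to_numpy(), X)
            pairs[(a, b)] = {
                "G": np.median(m.G_chain_, axis=0),
                "R": np.median(m.R_chain_, axis=0),
            }
        G, R, _ = assemble_covariances(pairs, traits)
        G_bent, g_rep = bend_matrix(G, self.cfg.bend_min_eig)
        R_bent, r_rep = bend_matrix(R, self.cfg.bend_min_eig)
        self.ctx["G"], self.ctx["R"] = G_bent, R_bent
        self._write("G_bent.tsv", G_bent)
        self._write("R_bent.tsv", R_bent)
        (self.outdir / "bending_report.json").write_text(
            json.dumps(
                {"G": g_rep.__dict__, "R": r_rep.__dict__}, indent=2
            )
        )

    def stage_evaluate(self) -> None:
        alr, adg, grm, X = self._aligned()
        selected = self.ctx["selection"].selected
        G, R = self.ctx["G"], self.ctx["R"]
        adg_names = list(adg.columns)
        results = {}
        for mode in ("direct", "microbiome", "combined"):
            if mode == "direct":
                Gm = bend_matrix(
                    G.loc[adg_names, adg_names], self.cfg.bend_min_eig
                )[0]
                Rm = bend_matrix(
                    R.loc[adg_names, adg_names], self.cfg.bend_min_eig
                )[0]
                subset = None
            else:
                Gm, Rm = G, R
                subset = alr[selected]
            gset = run_strategy(
                mode, adg, subset, grm, X, Gm, Rm,
                mcmc=self.cfg.mcmc_settings(seed_for(self.cfg.seed, "strategy", mode)),
            )
            resp = predicted_response(gset, self.cfg.selection_proportion)
            results[mode] = {
                "mean_accuracy": gset.mean_accuracy().to_dict(),
                "response": resp["response_median"].to_dict(),
            }
            out = gset.gebv.copy()
            for c in ADG_NAMES:
                out[f"sd_{c}"] = gset.sd[c]
                out[f"acc_{c}"] = gset.accuracy[c]
            self._write(f"gebv_{mode}.tsv", out)
        (self.outdir / "strategy_comparison.json").write_text(
            json.dumps(results, indent=2)
        )
        self.ctx["strategy_results"] = results

    # -- resume -------------------------------------------------------------

    def _try_resume(self, stage: str) -> bool:
        """Reload a completed stage's artifacts; True when skipped."""
        if not self._is_done(stage):
            return False
        out = self.outdir
        try:
            if stage == "simulate":
                d = out / "inputs"
                for key in ("genotypes", "weights", "ko_counts", "fixed_effects"):
                    setattr(self.cfg, f"{key}_tsv", str(d / f"{key}.tsv"))
            elif stage == "adg":
                self.ctx["adg"] = _read_tsv(out / "adg.tsv", index_col=0)
            elif stage == "grm":
                self.ctx["grm"] = _read_tsv(out / "grm.tsv", index_col=0)
            elif stage == "compose":
                self.ctx["alr"] = _read_tsv(out / "alr.tsv", index_col=0)
                comp = _read_tsv(out / "composition.tsv", index_col=0)
                self.ctx["rel_abundance"] = comp.mean(axis=0)
                diag = _read_tsv(out / "alr_reference_diagnostics.tsv", index_col=0)
                self.ctx["alr_reference"] = str(
                    set(comp.columns).difference(self.ctx["alr"].columns).pop()
                ) if comp.shape[1] == self.ctx["alr"].shape[1] + 1 else str(diag.index[0])
            elif stage == "scan-h2":
                self.ctx["mg_h2"] = _read_tsv(out / "mg_h2.tsv", index_col=0)
            elif stage == "scan-rg":
                self.ctx["catalog"] = _read_tsv(out / "rg_catalog.tsv", index_col=0)
            elif stage == "select":
                tbl = _read_tsv(out / "selection.tsv")
                from magblup.selection import SelectionResult

                self.ctx["selection"] = SelectionResult(
                    selected=list(tbl["mg"]),
                    trait_of_step=list(tbl["trait"]),
                    aic_trace=list(tbl["aic"]),
                    adjusted_r2={},
                )
            elif stage == "assemble":
                self.ctx["G"] = _read_tsv(out / "G_bent.tsv", index_col=0)
                self.ctx["R"] = _read_tsv(out / "R_bent.tsv", index_col=0)
            elif stage in ("adg-params", "evaluate"):
                pass
            return True
        except FileNotFoundError:
            return False

    # -- driver -------------------------------------------------------------

    def run(self) -> dict:
        stage_fns = {
            "simulate": self.stage_simulate,
            "adg": self.stage_adg,
            "grm": self.stage_grm,
            "compose": self.stage_compose,
            "scan-h2": self.stage_scan_h2,
            "scan-rg": self.stage_scan_rg,
            "adg-params": self.stage_adg_params,
            "select": self.stage_select,
            "assemble": self.stage_assemble,
            "evaluate": self.stage_evaluate,
        }
        summary = {"config_hash": self.cfg.config_hash(), "seed": self.cfg.seed,
                   "stages": {}}
        # single-stage invocations: pull earlier artifacts into context
        for stage in ALL_STAGES:
            if stage not in self.cfg.stages:
                self._try_resume(stage)
        for stage in self.cfg.stages:
            if stage not in stage_fns:
                raise ValueError(f"unknown stage {stage!r}")
            if self._try_resume(stage):
                if stage == "simulate":
                    self.ctx["inputs"] = load_inputs(self.cfg)
                summary["stages"][stage] = "skipped"
                continue
            if stage == "simulate":
                t0 = time.time()
                stage_fns[stage]()
                self.ctx["inputs"] = load_inputs(self.cfg)
                self._mark_done(stage, time.time() - t0)
                summary["stages"][stage] = "ran"
                continue
            if "inputs" not in self.ctx:
                self.ctx["inputs"] = load_inputs(self.cfg)
            t0 = time.time()
            try:
                stage_fns[stage]()
            except Exception as err:
                raise RuntimeError(f"stage {stage!r} failed: {err}") from err
            self._mark_done(stage, time.time() - t0)
            summary["stages"][stage] = "ran"
        (self.outdir / "summary.json").write_text(
            json.dumps(summary, indent=2)
        )
        return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run summary."""
    return PipelineRun(cfg).run()
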