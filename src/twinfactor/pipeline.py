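"""End-to-end orchestration: data in (CSV or synthetic) -> bifactor
measurement -> factor scores -> external regressions -> univariate
biometrics -> multivariate Cholesky ladders -> report bundle.

The stage order follows the analysis it re-implements: measurement first,
then phenotypic validation, then univariate variance components as a
prelude to the multivariate decompositions.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bifactor import BifactorSpec, default_odd_spec, factor_scores, fit_bifactor, FACTOR_NAMES
from .biometric import BiometricParams, compare_biometric_models, fit_biometric
from .cholesky import compare_cholesky_models
from .data import TwinSample, TwinStudy, read_twin_csv, write_twin_csv
from .regression import fit_external_regression, test_sex_invariance
from .simulate import GenerativeConfig, default_generative_config, simulate_study, simulate_univariate_twin_sample

__all__ = ["AnalysisConfig", "run_pipeline", "recovery_experiment"]


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "twinfactor_out"
    input_csv: str | None = None                 # None -> synthetic mode
    generative: GenerativeConfig | None = None
    odd_items: list[str] = field(default_factory=lambda: list(default_odd_spec().items))
    externals: list[str] = field(default_factory=list)
    univariate_models: list[str] = field(default_factory=lambda: ["ACE", "ADE", "AE", "CE", "AE+s"])
    cholesky_contrast: dict[str, bool] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        gen = raw.pop("generative", None)
        cfg = cls(**raw)
        if gen is not None:
            biom = {k: BiometricParams(**v) for k, v in gen.pop("biometric", {}).items()}
            reg = {k: np.asarray(v, dtype=float) for k, v in gen.pop("regression", {}).items()}
            cfg.generative = GenerativeConfig(biometric=biom, regression=reg, **gen)
        return cfg


def _validate_columns(study: TwinStudy, config: AnalysisConfig) -> None:
    missing = [v for v in config.odd_items + config.externals if v not in study.variables]
    if missing:
        raise ValueError(f"missing variables in input data: {missing}")
    if len(config.odd_items) != 8:
        raise ValueError("exactly 8 ODD items are required")


def _score_study(study: TwinStudy, config: AnalysisConfig):
    """Fit the bifactor model on pooled children and attach per-twin scores."""
    items = config.odd_items
    pooled = study.children_frame()
    fit = fit_bifactor(pooled[items], spec=None if items == list(default_odd_spec().items)
                       else BifactorSpec(tuple(items), default_odd_spec().pattern))
    scores = factor_scores(fit, pooled[items])
    # reshape pooled (per-child) scores back to (n_pairs, 2, 3) per group
    groups = {}
    offset = 0
    for g in study.groups:
        n = g.n_pairs
        block = np.empty((n, 2, 3))
        # children_frame stacks twin 1 then twin 2 within each group
        block[:, 0, :] = scores.iloc[offset:offset + n].to_numpy()
        block[:, 1, :] = scores.iloc[offset + n:offset + 2 * n].to_numpy()
        offset += 2 * n
        ext_idx = [g.variables.index(v) for v in config.externals]
        phen = np.concatenate([block, g.phenotypes[:, :, ext_idx]], axis=2)
        groups[g.zygosity] = TwinSample(
            g.zygosity, phen, FACTOR_NAMES + config.externals, g.sex, g.age
        )
    return fit, scores, TwinStudy(mz=groups["MZ"], dz=groups["DZ"])


def run_pipeline(config: AnalysisConfig) -> dict[str, str]:
    """Run every stage and write the report bundle; returns output paths.

    Any stage failure raises with a stage-tagged message; outputs written up
    to that point are preserved in the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    # --- stage: input
    if config.input_csv is not None:
        study = read_twin_csv(config.input_csv)
    else:
        gen = config.generative or default_generative_config(seed=config.seed)
        if not config.externals:
            config.externals = list(gen.regression)
        study = simulate_study(gen)
        p = out / "synthetic_input.csv"
        write_twin_csv(study, p)
        paths["input"] = str(p)
    _validate_columns(study, config)

    stage = "bifactor"
    try:
        fit, scores, scored = _score_study(study, config)
        p = out / "bifactor_loadings.csv"
        fit.loadings_frame().to_csv(p)
        paths["loadings"] = str(p)
        p = out / "factor_scores.csv"
        kids = study.children_frame()[["pair_id", "zygosity", "twin"]]
        pd.concat([kids.reset_index(drop=True), scores], axis=1).to_csv(p, index=False)
        paths["scores"] = str(p)
        summary = {"converged": fit.converged, **fit.fitstats.to_dict()}
        p = out / "bifactor_summary.json"
        p.write_text(json.dumps(summary, indent=2, default=float))
        paths["bifactor_summary"] = str(p)

        stage = "regression"
        kids_all = scored.children_frame()
        rows = []
        for ext in config.externals:
            res = fit_external_regression(kids_all[FACTOR_NAMES], kids_all[ext])
            inv = None
            if "sex" in kids_all and kids_all["sex"].notna().all():
                inv = test_sex_invariance(kids_all[FACTOR_NAMES], kids_all[ext], kids_all["sex"].to_numpy())
            row = {"outcome": ext,
                   **{f"beta_{f}": res.beta[f] for f in FACTOR_NAMES},
                   "r2_odd": res.r2_odd}
            for f in FACTOR_NAMES:
                row[f"beta_{f}_lo"] = res.beta_ci.loc[f, "lo"]
                row[f"beta_{f}_hi"] = res.beta_ci.loc[f, "hi"]
            if inv is not None:
                row.update({"chi2_sex": inv.chi2, "df_sex": inv.df, "p_sex": inv.pvalue,
                            "bic_equated": inv.bic_equated, "bic_by_sex": inv.bic_by_sex})
            rows.append(row)
        p = out / "external_regressions.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["regressions"] = str(p)

        stage = "univariate_biometric"
        tables = []
        for var in FACTOR_NAMES + config.externals:
            tbl = compare_biometric_models(scored, var, config.univariate_models, seed=config.seed)
            tbl.insert(0, "variable", var)
            tables.append(tbl.reset_index())
        p = out / "univariate_biometric.csv"
        pd.concat(tables, ignore_index=True).to_csv(p, index=False)
        paths["univariate"] = str(p)

        stage = "cholesky"
        for ext in config.externals:
            variables = ("general", "defiant", "irritability", ext)
            tbl = compare_cholesky_models(
                scored, variables,
                contrast=config.cholesky_contrast.get(ext, False),
                free_means=True, seed=config.seed,
            )
            p = out / f"cholesky_{ext}.csv"
            tbl.to_csv(p)
            paths[f"cholesky_{ext}"] = str(p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "package": "twinfactor",
        "version": __version__,
        "seed": config.seed,
        "mode": "csv" if config.input_csv else "synthetic",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": paths,
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(mp)
    return paths


def recovery_experiment(
    truth: BiometricParams,
    model: str,
    n_mz: int,
    n_dz: int,
    n_reps: int,
    seed: int,
    tolerance: float | None = None,
) -> dict:
    """Simulate-and-refit distribution of variance-component estimates.

    Returns the per-replicate estimates plus bias and Monte Carlo standard
    error of each reported component, and a pass flag when a tolerance on
    the absolute bias is supplied.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        s = int(rng.integers(0, 2**31 - 1))
        study = simulate_univariate_twin_sample(truth, n_mz, n_dz, seed=s)
        fit = fit_biometric(study, model=model, seed=s % 1000)
        rows.append({**fit.components, "converged": fit.converged})
    est = pd.DataFrame(rows)
    contrast = model.endswith("+s")
    tot = truth.total_variance
    true_vals = {}
    for path, comp in (("a", "h2"), ("c", "c2"), ("d", "d2"), ("e", "e2")):
        if comp in est.columns:
            raw = getattr(truth, path) ** 2
            true_vals[comp] = raw if contrast else raw / tot
    if contrast:
        true_vals["s"] = truth.s
    summary = {}
    for comp, tv in true_vals.items():
        vals = est[comp].to_numpy()
        bias = float(vals.mean() - tv)
        mcse = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        summary[comp] = {"truth": tv, "mean": float(vals.mean()), "bias": bias, "mcse": mcse}
        if tolerance is not None:
            summary[comp]["pass"] = abs(bias) <= tolerance
    return {"estimates": est, "summary": summary}
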