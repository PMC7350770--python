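"""End-to-end pipeline: quantify -> model fits -> rjMCMC -> ANOVA.

Driven by a flat YAML config; every stage reads only prior-stage outputs and
the whole bundle is deterministic given the configured seeds. A run manifest
(JSON) records the config snapshot, stage wall times, warnings, and a
checksummed inventory of every output file — written even on partial failure.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import bh_adjust, phylo_anova
from .continuous import ContinuousFit, ContinuousModelSpec, fit_model, rank_models
from .io import (
    read_landmark_table,
    read_metadata,
    read_scheme,
    validate_dataset,
)
from .metrics import drop_region, quantify, radii_frame
from .rjmcmc import (
    PriorConfig,
    diagnostics,
    run_rjmcmc,
    summarize_jumps,
    summarize_shifts,
)
from .trees import paint_regimes, prune_to_taxa, read_tree, resolve_polytomies


class PipelineError(ValueError):
    pass


DEFAULT_SCENARIOS = ("ancestral", "regime", "regime-split", "echo", "echo-freq")

#: metadata column backing each scenario's tip states
SCENARIO_COLUMNS = {
    "ancestral": "group",
    "regime": "regime",
    "regime-split": "regime_split",
    "echo": "echo_presence",
    "echo-freq": "echo_frequency",
    "age": "geologic_age",
    "suborder": "group",
}

MODEL_CLASSES_PER_SCENARIO = ("BMM", "BMMtr", "BMMsm", "OUM")
SINGLE_REGIME_CLASSES = ("BM", "BMtr", "OU")


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)  # name -> {seconds, status}
    warnings: list[str] = field(default_factory=list)
    files: dict = field(default_factory=dict)  # path -> sha256
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "stages": self.stages,
                "warnings": self.warnings,
                "files": self.files,
                "failed_stage": self.failed_stage,
            },
            indent=2,
            default=str,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a mapping")
    return cfg


REQUIRED_INPUTS = ("landmarks", "scheme", "metadata", "tree")


def _check_inputs(config: dict) -> None:
    for key in REQUIRED_INPUTS:
        if key not in config:
            raise PipelineError(f"config missing required input {key!r}")
        if not Path(config[key]).exists():
            raise PipelineError(f"input {key!r} not found: {config[key]}")


def _species_trait(sums: dict[str, float], metadata) -> dict[str, float]:
    """Specimen scores -> species-level trait (mean over conspecifics)."""
    per_species: dict[str, list[float]] = {}
    for m in metadata:
        if m.specimen_id in sums:
            per_species.setdefault(m.species or m.specimen_id, []).append(
                sums[m.specimen_id]
            )
    return {sp: float(np.mean(v)) for sp, v in per_species.items()}


def _tip_states(metadata, column: str, trait: dict[str, float]) -> dict[str, str]:
    states = {}
    for m in metadata:
        sp = m.species or m.specimen_id
        if sp in trait:
            val = getattr(m, column, "")
            states[sp] = val if val else "unknown"
    return states


class Pipeline:
    """Stage runner. Use :func:`run` for the one-shot entry point."""

    def __init__(self, config: dict, outdir: str | Path):
        self.config = dict(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config=dict(config))
        self.state: dict = {}

    # -- helpers -----------------------------------------------------------

    def _write_csv(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        self.manifest.files[name] = _sha256(path)
        return path

    def _write_json(self, obj, name: str) -> Path:
        path = self.outdir / name
        path.write_text(json.dumps(obj, indent=2, default=str))
        self.manifest.files[name] = _sha256(path)
        return path

    def _stage(self, name: str, fn) -> None:
        start = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn()
            for w in caught:
                self.manifest.warnings.append(f"{name}: {w.message}")
            self.manifest.stages[name] = {
                "seconds": round(time.perf_counter() - start, 3),
                "status": "ok",
            }
        except Exception as e:
            self.manifest.stages[name] = {
                "seconds": round(time.perf_counter() - start, 3),
                "status": f"failed: {e}",
            }
            self.manifest.failed_stage = name
            raise
        finally:
            (self.outdir / "manifest.json").write_text(self.manifest.to_json())

    # -- stages ------------------------------------------------------------

    def stage_quantify(self) -> None:
        cfg = self.config
        scheme = read_scheme(cfg["scheme"])
        dataset = read_landmark_table(cfg["landmarks"], scheme)
        dataset.metadata = read_metadata(cfg["metadata"])
        # re-validate id coverage now that metadata is attached
        dataset.__post_init__()

        if cfg.get("drop_rostrum"):
            dataset = drop_region(dataset, "rostrum")
        if cfg.get("drop_fossils"):
            fossil_ids = {m.specimen_id for m in dataset.metadata if m.is_fossil}
            dataset.configurations = [
                c for c in dataset.configurations if c.specimen_id not in fossil_ids
            ]
            dataset.metadata = [
                m for m in dataset.metadata if not m.is_fossil
            ]

        report = validate_dataset(dataset)
        result = quantify(
            dataset, include_estimated=not cfg.get("exclude_estimated", False)
        )
        self.state["dataset"] = dataset
        self.state["result"] = result

        self._write_csv(radii_frame(result["records"]), "radii.csv")
        sums = result["sums"]
        meta_by_id = {m.specimen_id: m for m in dataset.metadata}
        summary = pd.DataFrame(
            [
                {
                    "specimen_id": sid,
                    "sum_rho": total,
                    "species": meta_by_id[sid].species,
                    "group": meta_by_id[sid].group,
                }
                for sid, total in sorted(sums.items())
            ]
        )
        self._write_csv(summary, "asymmetry_summary.csv")
        if result["pca"] is not None:
            pc = result["pca"]
            df = pd.DataFrame(
                pc.scores[:, : min(10, pc.scores.shape[1])],
                columns=[f"PC{i + 1}" for i in range(min(10, pc.scores.shape[1]))],
            )
            df.insert(0, "specimen_id", pc.specimen_ids)
            self._write_csv(df, "pca_scores.csv")
        self._write_json(
            {
                "n_specimens": report.n_specimens,
                "fraction_with_missing": report.fraction_with_missing,
                "flagged": report.flagged,
                "excluded": result["excluded"],
            },
            "quantify_report.json",
        )

    def _load_tree(self):
        tree = read_tree(self.config["tree"])
        tree = resolve_polytomies(tree)
        trait = _species_trait(
            self.state["result"]["sums"], self.state["dataset"].metadata
        )
        if self.config.get("matrix_tree_taxa"):
            keep = [t for t in tree.tip_labels if t in set(self.config["matrix_tree_taxa"])]
            tree = prune_to_taxa(tree, keep)
        tips = set(tree.tip_labels)
        trait = {k: v for k, v in trait.items() if k in tips}
        if set(trait) != tips:
            tree = prune_to_taxa(tree, sorted(trait))
        self.state["tree"] = tree
        self.state["trait"] = trait

    def stage_fit(self) -> None:
        self._load_tree()
        tree, trait = self.state["tree"], self.state["trait"]
        metadata = self.state["dataset"].metadata
        scenarios = self.config.get("scenarios", list(DEFAULT_SCENARIOS))
        seed = int(self.config.get("seed", 0))

        fits: list[ContinuousFit] = []
        for cls in SINGLE_REGIME_CLASSES:
            fits.append(fit_model(ContinuousModelSpec(cls), tree, trait, seed=seed))
        for scenario in scenarios:
            column = SCENARIO_COLUMNS.get(scenario)
            if column is None:
                raise PipelineError(f"unknown scenario {scenario!r}")
            states = _tip_states(metadata, column, trait)
            if len(set(states.values())) < 2:
                self.manifest.warnings.append(
                    f"fit: scenario {scenario!r} has <2 states; skipped"
                )
                continue
            painting = paint_regimes(tree, tip_states=states)
            for cls in MODEL_CLASSES_PER_SCENARIO:
                fits.append(
                    fit_model(
                        ContinuousModelSpec(cls, scenario),
                        tree,
                        trait,
                        painting=painting,
                        seed=seed,
                    )
                )
        ranking = rank_models(fits)
        self.state["ranking"] = ranking
        self._write_csv(ranking.reset_index(), "model_ranking.csv")

    def stage_mcmc(self) -> None:
        if "tree" not in self.state:
            self._load_tree()
        tree, trait = self.state["tree"], self.state["trait"]
        cfg = self.config
        seed = int(cfg.get("seed", 0))
        n_gen = int(cfg.get("mcmc_generations", 200_000))
        thin = int(cfg.get("mcmc_thin", 200))
        n_chains = int(cfg.get("mcmc_chains", 2))
        model = cfg.get("mcmc_model", "jump-rbm")
        prior = PriorConfig()

        traces = [
            run_rjmcmc(
                tree,
                trait,
                prior=prior,
                n_generations=n_gen,
                thin=thin,
                model=model,
                seed=seed + i,
            )
            for i in range(n_chains)
        ]
        shifts = summarize_shifts(traces[0])
        self._write_csv(shifts.table, "shifts.csv")
        jumps = summarize_jumps(traces[0])
        self._write_csv(jumps.table, "jumps.csv")
        diag = diagnostics(traces)
        self._write_json(
            {
                "ess": diag.ess,
                "psrf": diag.psrf,
                "n_samples": diag.n_samples,
                "flags": diag.flags,
                "acceptance": traces[0].acceptance,
                "seed": seed,
            },
            "mcmc_diagnostics.json",
        )

    def stage_anova(self) -> None:
        if "tree" not in self.state:
            self._load_tree()
        tree, trait = self.state["tree"], self.state["trait"]
        metadata = self.state["dataset"].metadata
        scenarios = self.config.get(
            "anova_scenarios",
            ["regime", "regime-split", "echo-freq", "age", "suborder", "echo"],
        )
        rows = []
        for scenario in scenarios:
            column = SCENARIO_COLUMNS.get(scenario)
            if column is None:
                raise PipelineError(f"unknown scenario {scenario!r}")
            states = _tip_states(metadata, column, trait)
            if len(set(states.values())) < 2:
                self.manifest.warnings.append(
                    f"anova: scenario {scenario!r} has <2 levels; skipped"
                )
                continue
            res = phylo_anova(trait, states, tree, scenario=scenario)
            rows.append(
                {
                    "scenario": scenario,
                    "F": res.f_statistic,
                    "df1": res.df_num,
                    "df2": res.df_den,
                    "p": res.p_value,
                    "lambda": res.lam,
                }
            )
        table = pd.DataFrame(rows)
        if not table.empty:
            adj = bh_adjust(table["p"].tolist(), table["scenario"].tolist())
            table["p_bh"] = adj["p_bh"].to_numpy()
        self._write_csv(table, "anova.csv")


def run(config: dict, outdir: str | Path, stages: tuple[str, ...] = ("quantify", "fit", "mcmc", "anova")) -> RunManifest:
    """Execute the pipeline stages in order; returns the manifest."""
    _check_inputs(config)
    pipe = Pipeline(config, outdir)
    stage_fns = {
        "quantify": pipe.stage_quantify,
        "fit": pipe.stage_fit,
        "mcmc": pipe.stage_mcmc,
        "anova": pipe.stage_anova,
    }
    for name in stages:
        if name not in stage_fns:
            raise PipelineError(f"unknown stage {name!r}")
        if name != "quantify" and "result" not in pipe.state:
            pipe._stage("quantify", pipe.stage_quantify)
        pipe._stage(name, stage_fns[name])
    (pipe.outdir / "manifest.json").write_text(pipe.manifest.to_json())
    return pipe.manifest


SENSITIVITY_MODES = ("no-fossils", "no-rostrum", "matrix-tree")


def sensitivity(
    config: dict, outdir: str | Path, mode: str, matrix_taxa: list[str] | None = None
) -> dict:
    """Re-run quantify+fit under a modification; compare AIC orderings.

    Returns {"base": ranking, "modified": ranking, "ordering_preserved": bool}.
    """
    if mode not in SENSITIVITY_MODES:
        raise PipelineError(f"unknown sensitivity mode {mode!r}")
    outdir = Path(outdir)
    base_manifest = run(config, outdir / "base", stages=("quantify", "fit"))
    mod_config = dict(config)
    if mode == "no-rostrum":
        mod_config["drop_rostrum"] = True
    elif mode == "no-fossils":
        mod_config["drop_fossils"] = True
    else:
        mod_config["matrix_tree_taxa"] = matrix_taxa or []
    run(mod_config, outdir / mode, stages=("quantify", "fit"))

    base = pd.read_csv(outdir / "base" / "model_ranking.csv")
    mod = pd.read_csv(outdir / mode / "model_ranking.csv")
    shared = [m for m in base["model"] if m in set(mod["model"])]
    base_order = [m for m in base["model"] if m in shared]
    mod_order = [m for m in mod["model"] if m in shared]
    preserved = base_order == mod_order
    comparison = pd.DataFrame(
        {"rank": np.arange(1, len(base_order) + 1), "base": base_order, mode: mod_order}
    )
    comparison.to_csv(outdir / f"sensitivity_{mode}.csv", index=False)
    return {"base": base, "modified": mod, "ordering_preserved": preserved}
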