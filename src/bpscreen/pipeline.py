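"""End-to-end orchestration: simulate -> preprocess -> normogram ->
impute -> prediction models -> validation -> sequential screening.

One master seed deterministically derives every stage seed, the run
configuration is serialized next to the outputs, and a manifest records
each artifact with a content hash so stage provenance can be verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import GeneratorConfig, alspac_like_config, apply_missingness, \
    generate_cohort, sws_like_config
from .evaluation import evaluate_registry, recalibrate_model
from .impute import complete_data_set, impute_chained, passive_normative
from .io import write_cohort
from .normogram import add_normative_columns, fit_normograms, save_normograms
from .prediction import build_all_models, save_registry
from .preprocess import derive_table
from .screening import average_threshold, render_flowchart, sequential_screen

log = logging.getLogger("bpscreen")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    master_seed: int = 0
    n_development: int = 13000
    n_validation: int = 3005
    m_imputations: int = 20
    n_cycles: int = 10
    selection_threshold: float = 0.2
    gestations: tuple = (20, 25, 28, 31, 34, 36)
    bootstrap_b: int = 500
    sensitivity_targets: tuple = (0.95, 0.99)
    normogram_subsample: int = 3000
    normogram_min_women: int = 200
    outcomes: tuple = ("pe", "preterm", "sga")
    apply_missingness: bool = True
    recalibrate: bool = True
    development: GeneratorConfig = None
    validation: GeneratorConfig = None

    def __post_init__(self):
        # stage seeds derived deterministically from the master seed
        ss = np.random.SeedSequence(self.master_seed)
        seeds = [int(s) % (2 ** 31) for s in ss.generate_state(6)]
        self.stage_seeds = dict(zip(
            ("dev", "val", "missing", "impute", "normogram", "bootstrap"), seeds))
        if self.development is None:
            self.development = alspac_like_config(self.n_development,
                                                  seed=self.stage_seeds["dev"])
        if self.validation is None:
            self.validation = sws_like_config(self.n_validation,
                                              seed=self.stage_seeds["val"])

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k in ("development", "validation"):
            for kk, v in d[k].items():
                if isinstance(v, np.ndarray):
                    d[k][kk] = v.tolist()
            for sub in ("trajectory", "pe_mechanism", "missingness"):
                if isinstance(d[k].get(sub), dict):
                    for kk, v in d[k][sub].items():
                        if isinstance(v, np.ndarray):
                            d[k][sub][kk] = v.tolist()
        return yaml.safe_dump(d, sort_keys=False, default_flow_style=None)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute every stage in order and return the run directory.

    Identical config and master seed give identical CSV/JSON outputs.
    A failing stage aborts with the stage name; artifacts written so far
    stay in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stages": [], "artifacts": {}}
    (out / "run.yaml").write_text(config.to_yaml())

    def record(stage, paths, t0):
        manifest["stages"].append({"stage": stage,
                                   "seconds": round(time.time() - t0, 2)})
        for p in paths:
            manifest["artifacts"][p.name] = _sha(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    stage = "simulate"
    try:
        t0 = time.time()
        dev_truth = generate_cohort(config.development)
        dev = apply_missingness(dev_truth, config.development,
                                seed=config.stage_seeds["missing"]) \
            if config.apply_missingness else dev_truth
        write_cohort(dev, out / "development")
        val_truth = []
        if config.n_validation > 0:
            val_truth = generate_cohort(config.validation)
            val = apply_missingness(val_truth, config.validation,
                                    seed=config.stage_seeds["missing"] + 1) \
                if config.apply_missingness else val_truth
            write_cohort(val, out / "validation")
        record(stage, [out / "development" / "visits.csv",
                       out / "development" / "pregnancies.csv"], t0)

        stage = "preprocess"
        t0 = time.time()
        derived_dev = derive_table(dev)
        derived_dev.to_csv(out / "derived_dev.csv", index=False)
        derived_val = None
        if config.n_validation > 0:
            derived_val = derive_table(val)
            derived_val.to_csv(out / "derived_val.csv", index=False)
        record(stage, [out / "derived_dev.csv"], t0)

        stage = "normogram"
        t0 = time.time()
        fits = fit_normograms(dev, derived_dev,
                              subsample=config.normogram_subsample,
                              seed=config.stage_seeds["normogram"],
                              min_women=config.normogram_min_women)
        save_normograms(fits, out / "normogram.json")
        record(stage, [out / "normogram.json"], t0)

        stage = "impute"
        t0 = time.time()
        if config.apply_missingness:
            imp_dev = impute_chained(derived_dev, m=config.m_imputations,
                                     n_cycles=config.n_cycles,
                                     seed=config.stage_seeds["impute"])
        else:
            imp_dev = complete_data_set(derived_dev)
        imp_dev = passive_normative(imp_dev, fits, config.gestations)
        imp_dir = out / "imputed"
        imp_dir.mkdir(exist_ok=True)
        for i, t in enumerate(imp_dev.completed_tables, start=1):
            t.to_csv(imp_dir / f"imp_{i:02d}.csv", index=False)
        (imp_dir / "imputation_log.json").write_text(
            json.dumps(imp_dev.log, indent=1, default=str))
        record(stage, sorted(imp_dir.glob("imp_*.csv")), t0)

        stage = "fit-models"
        t0 = time.time()
        registry = build_all_models(imp_dev, outcomes=config.outcomes,
                                    gestations=config.gestations,
                                    threshold=config.selection_threshold)
        save_registry(registry, out / "models.json")
        record(stage, [out / "models.json"], t0)

        stage = "validate"
        t0 = time.time()
        ev = evaluate_registry(registry, imp_dev, "development")
        results = {"development": ev.to_dict(orient="records")}
        imp_val = None
        if derived_val is not None:
            if config.apply_missingness:
                imp_val = impute_chained(derived_val, m=config.m_imputations,
                                         n_cycles=config.n_cycles,
                                         seed=config.stage_seeds["impute"] + 1)
            else:
                imp_val = complete_data_set(derived_val)
            imp_val = passive_normative(imp_val, fits, config.gestations)
            ev_val = evaluate_registry(registry, imp_val, "validation")
            results["validation"] = ev_val.to_dict(orient="records")
            if config.recalibrate:
                # recalibrated copies are reported/saved; screening uses the
                # original development-cohort models with the development
                # threshold, as in the published flowchart construction
                import copy as _copy
                recal_registry = {k: _copy.deepcopy(m)
                                  for k, m in registry.items()}
                val0 = imp_val.completed_tables[0]
                for model in recal_registry.values():
                    if model.outcome == "pe":
                        recalibrate_model(model, val0)
                save_registry(recal_registry, out / "models.json")
        (out / "evaluation.json").write_text(json.dumps(results, indent=1))
        ev_all = ev if imp_val is None else pd.concat([ev, ev_val],
                                                      ignore_index=True)
        ev_all.to_csv(out / "evaluation.csv", index=False)
        record(stage, [out / "evaluation.json", out / "evaluation.csv"], t0)

        stage = "screen"
        t0 = time.time()
        dev0 = imp_dev.completed_tables[0]
        screen_table = imp_val.completed_tables[0] if imp_val is not None else dev0
        flows = {}
        for target in config.sensitivity_targets:
            thr = average_threshold(dev0, registry, target)
            flow = sequential_screen(screen_table, registry, thr)
            flows[f"sensitivity_{target:g}"] = flow.to_dict()
            (out / f"flow_{target:g}.txt").write_text(render_flowchart(flow))
        (out / "flow.json").write_text(json.dumps(flows, indent=1))
        record(stage, [out / "flow.json"], t0)
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e
    return out
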