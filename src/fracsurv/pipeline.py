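"""End-to-end pipeline: cohort -> BED columns -> forest/SHAP stage ->
cut-points -> causal stage -> refutations, driven by a single config.

Every artifact directory gets a ``run_info.json`` stamped with the config
hash and global seed so outputs are attributable and reruns with the same
seed are byte-identical.  Stages run in order and a failure in a later
stage leaves earlier stage outputs on disk.
"""

from __future__ import annotations

import argparse
import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bed as bed_mod
from .bed import FractionationRegimen, bed_table
from .causal import CausalTask, NuisanceConfig, blp, estimate_effects, km_logrank, per_patient_effects
from .cohort import CohortSpec, read_cohort, sample_cohort, write_cohort
from .cutpoints import DEFAULT_CUTPOINTS, CutpointSpec, binarize, suggest_cutpoint, transfer_cutpoint_by_percentile
from .forest import ForestConfig, SplitPlan, evaluate_concordance, normalize_shap, shap_feature_correlations, shap_values
from .refute import battery_frame, run_battery

logger = logging.getLogger(__name__)

BED_VARIANTS = ("bed_dd", "bed_di", "bed_simp")


@dataclass
class PipelineConfig:
    """Single configuration object for the whole two-step pipeline."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    cohort_csv: str | None = None  # if None, generate synthetically
    n_patients: int = 2000
    alpha_beta: tuple[float, ...] = (7.0, 10.0, 13.0)
    train_fraction: float = 0.70
    cv_folds: int = 10
    forest: ForestConfig | None = None
    treatment_variants: tuple[str, ...] = ("bed_dd",)
    cutpoint_mode: str = "manual"  # manual | shap_changepoint
    horizons: tuple[float, ...] = tuple(float(h) for h in range(1, 13))
    causal_folds: int = 10
    outcome_trees: int = 52
    run_refutations: bool = False
    shap_patients: int = 150
    shap_permutations: int = 10
    shap_background: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        forest = raw.pop("forest", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if forest:
            cfg.forest = ForestConfig(**forest)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(out: Path, cfg: PipelineConfig, stage: str) -> None:
    info = {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    (out / "run_info.json").write_text(json.dumps(info, indent=2) + "\n")


def run(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of the main artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # stage 1: cohort ------------------------------------------------------
    if cfg.cohort_csv:
        cohort = read_cohort(cfg.cohort_csv)
    else:
        cohort = sample_cohort(CohortSpec(n_patients=cfg.n_patients, seed=cfg.seed))
    cohort = cohort.copy()
    write_cohort(cohort, out / "cohort.csv")
    artifacts["cohort"] = cohort
    _stamp(out, cfg, "cohort")
    logger.info("cohort: %d patients, %.1f%% events", len(cohort), 100 * cohort.Status.mean())

    # stage 2: BED comparison table ---------------------------------------
    regs = sorted(
        {
            (int(r.fractions), float(r.dose_per_fraction), int(r.fractions_per_day))
            for r in cohort.itertuples()
        }
    )
    table = bed_table(
        [FractionationRegimen(m, d, fpd) for m, d, fpd in regs], cfg.alpha_beta
    )
    table.to_csv(out / "bed_table.csv", index=False)
    artifacts["bed_table"] = table

    # stage 3: forest + SHAP ----------------------------------------------
    plan = SplitPlan(cfg.train_fraction, cfg.cv_folds, cfg.seed)
    fcfg = cfg.forest or ForestConfig(seed=cfg.seed)
    report, model, train, test = evaluate_concordance(cohort, fcfg, plan)
    (out / "metrics.json").write_text(json.dumps(report.summary(), indent=2) + "\n")
    rng = np.random.default_rng(cfg.seed)
    explain = test.iloc[
        rng.choice(len(test), size=min(cfg.shap_patients, len(test)), replace=False)
    ]
    shap_frame, base = shap_values(
        model,
        explain,
        n_background=cfg.shap_background,
        n_permutations=cfg.shap_permutations,
        seed=cfg.seed,
    )
    shap_frame.to_csv(out / "shap.csv", index=False)
    curves = {
        v: normalize_shap(shap_frame, explain, v) for v in BED_VARIANTS
    }
    pd.concat([c.assign(variant=v) for v, c in curves.items()]).to_csv(
        out / "shap_curves.csv", index=False
    )
    shap_feature_correlations(shap_frame, explain).to_csv(out / "shap_correlations.csv")
    artifacts.update(concordance=report, model=model, shap=shap_frame, shap_base=base)
    _stamp(out, cfg, "forest")

    # stage 4: cut-points ---------------------------------------------------
    cutpoints: dict[str, CutpointSpec] = {}
    for v in BED_VARIANTS:
        if cfg.cutpoint_mode == "manual":
            cutpoints[v] = CutpointSpec(v, DEFAULT_CUTPOINTS[v], "manual")
        else:
            curve = curves[v]
            if v == "bed_simp":
                cut = transfer_cutpoint_by_percentile(
                    cutpoints["bed_dd"].cutpoint, cohort["bed_dd"], cohort["bed_simp"]
                )
                cutpoints[v] = CutpointSpec(v, cut, "percentile")
            else:
                cut = suggest_cutpoint(
                    curve["value"], curve["smoothed"], dose_values=cohort[v]
                )
                cutpoints[v] = CutpointSpec(v, cut, "shap_changepoint")
    (out / "cutpoints.json").write_text(
        json.dumps({v: s.cutpoint for v, s in cutpoints.items()}, indent=2) + "\n"
    )
    artifacts["cutpoints"] = cutpoints

    # stage 5: causal -------------------------------------------------------
    nuis = NuisanceConfig(outcome_trees=cfg.outcome_trees)
    for v in cfg.treatment_variants:
        cdir = out / f"causal_{v}"
        cdir.mkdir(exist_ok=True)
        data = cohort.copy()
        data["treatment"] = binarize(data[v], cutpoints[v])
        # the two competing BED variants never enter the adjustment set
        data = data.drop(columns=[b for b in BED_VARIANTS if b != v])
        task = CausalTask(horizons=cfg.horizons)
        rep = estimate_effects(data, task, folds=cfg.causal_folds, seed=cfg.seed, nuisance=nuis)
        ate = rep.ate.copy()
        ate.loc[ate.estimand == "sp", ["estimate", "se"]] *= 100.0  # percent
        ate.to_csv(cdir / "ate.csv", index=False)
        rep.fold_effects.to_csv(cdir / "fold_effects.csv", index=False)
        ppe = per_patient_effects(rep, seed=cfg.seed)
        pd.DataFrame({"cate": ppe.cate, "se": ppe.cate_se}).to_csv(cdir / "cate.csv", index=False)
        blp_tab = blp(rep)
        blp_tab.to_csv(cdir / "blp.csv", index=False)
        curves_km, chi2, p = km_logrank(data, data["treatment"].to_numpy())
        (cdir / "logrank.json").write_text(
            json.dumps({"chi2": chi2, "p_value": p}, indent=2) + "\n"
        )
        artifacts[f"causal_{v}"] = rep
        _stamp(cdir, cfg, f"causal_{v}")

        if cfg.run_refutations:
            battery = run_battery(
                data, task, nuisance=nuis, folds=cfg.causal_folds, seed=cfg.seed, reference=rep
            )
            battery_frame(battery).to_csv(cdir / "refutations.csv", index=False)
            artifacts[f"refutations_{v}"] = battery
    return artifacts


# ---------------------------------------------------------------------------
# command-line interface


def _cmd_run(args) -> int:
    cfg = (
        PipelineConfig.from_yaml(args.config)
        if args.config
        else PipelineConfig(out_dir=args.out, seed=args.seed, n_patients=args.n_patients)
    )
    if args.out:
        cfg.out_dir = args.out
    if args.seed is not None:
        cfg.seed = args.seed
    try:
        run(cfg)
    except Exception as exc:  # surface the failing stage on stderr
        logger.error("pipeline failed: %s", exc)
        return 1
    return 0


def _cmd_bed_table(args) -> int:
    regs = pd.read_csv(args.regimens)
    regimens = [
        FractionationRegimen(
            int(r.fractions),
            float(r.dose_per_fraction),
            int(getattr(r, "fractions_per_day", 1)),
            float(r.duration_weeks) if "duration_weeks" in regs.columns and not pd.isna(r.duration_weeks) else None,
        )
        for r in regs.itertuples()
    ]
    r_values = tuple(float(x) for x in args.alpha_beta.split(","))
    tab = bed_table(regimens, r_values, convention=args.convention)
    tab.to_csv(args.out, index=False)
    return 0


def main(argv: list[str] | None = None) -> int:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    ap = argparse.ArgumentParser(prog="fracsurv", description=__doc__)
    sub = ap.add_subparsers(dest="command", required=True)

    p_run = sub.add_parser("run", help="run the full pipeline")
    p_run.add_argument("--config", default=None, help="YAML pipeline config")
    p_run.add_argument("--out", default="results/pipeline")
    p_run.add_argument("--seed", type=int, default=0)
    p_run.add_argument("--n-patients", type=int, default=2000)
    p_run.set_defaults(func=_cmd_run)

    p_bed = sub.add_parser("bed-table", help="tabulate BED variants for regimens")
    p_bed.add_argument("--regimens", required=True, help="CSV with fractions, dose_per_fraction[, fractions_per_day, duration_weeks]")
    p_bed.add_argument("--alpha-beta", default="7,10,13")
    p_bed.add_argument("--convention", default=bed_mod.DEFAULT_CONVENTION)
    p_bed.add_argument("--out", default="bed_table.csv")
    p_bed.set_defaults(func=_cmd_bed_table)

    args = ap.parse_args(argv)
    return args.func(args)


if __name__ == "__main__":
    raise SystemExit(main())
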