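"""End-to-end pipeline driver and cohort file I/O.

``run_pipeline`` executes the full analysis chain from one YAML config:
simulate or load a cohort, screen for sex differences on stratified fits,
add moderation parameters, fit, prune non-significant paths, refit the final
model, and write publication-style coefficient, descriptive and effect-type
tables plus machine-readable JSON for every stage.  All randomness flows
from a single master seed that spawns per-stage seeds, so identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import classify_effects, effect_table
from .estimate import McmcConfig, PriorSpec, sample_posterior, summarize
from .model import PathModel, build_initial_model, read_model
from .selection import add_moderation, compare_models, fit_by_sex, prune_nonsignificant
from .simulate import (
    COHORT_COLUMNS,
    GeneratorConfig,
    descriptive_table,
    generate_cohort,
    reference_config,
)

__all__ = ["read_cohort", "write_cohort", "run_pipeline", "CohortSchemaError"]

logger = logging.getLogger(__name__)

_BINARY_COLUMNS = ("sex", "MS", "T2DM")

_COLUMN_UNITS = {
    "age": "years",
    "sex": "0=female,1=male",
    "MS": "0/1",
    "T2DM": "0/1",
    "PTH": "pmol/l",
    "vitD": "nmol/l",
    "magnesium": "mmol/l",
    "calcium": "mmol/l",
    "phosphate": "mmol/l",
}


class CohortSchemaError(ValueError):
    """Raised when a cohort file violates the canonical schema."""


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; keep complete cases only.

    Requires the canonical header (age, sex, MS, T2DM, PTH, vitD, magnesium,
    calcium, phosphate; '#' lines are comments), numeric cells, and binary
    columns in {0,1}.  Rows with any missing value are dropped with a logged
    count, the complete-case contract of the analysis.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing columns: {', '.join(missing)}")
    df = df[COHORT_COLUMNS]
    for col in COHORT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise CohortSchemaError(
                f"non-numeric values in column {col!r} (first at row {int(bad.idxmax())})"
            )
        df[col] = coerced

    n_total = len(df)
    df = df.dropna().reset_index(drop=True)
    dropped = n_total - len(df)
    if dropped:
        logger.info(
            "complete-case filter: kept %d of %d rows (%.1f%%), dropped %d incomplete",
            len(df), n_total, 100 * len(df) / n_total, dropped,
        )
    for col in _BINARY_COLUMNS:
        vals = set(np.unique(df[col]))
        if not vals <= {0.0, 1.0}:
            raise CohortSchemaError(
                f"column {col!r} must be coded 0/1, found {sorted(vals - {0.0, 1.0})}"
            )
        df[col] = df[col].astype(np.int64)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise CohortSchemaError("non-finite values in cohort")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV with unit annotations in header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for col in COHORT_COLUMNS:
            fh.write(f"# {col}: {_COLUMN_UNITS[col]}\n")
        cohort[COHORT_COLUMNS].to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _resolve_model(section) -> PathModel:
    if section in (None, "initial"):
        return build_initial_model()
    if section == "final":
        from .model import build_final_model

        return build_final_model()
    if isinstance(section, (str, Path)):
        return read_model(section)
    return PathModel.from_dict(section)


def _resolve_cohort(section, master: np.random.SeedSequence) -> pd.DataFrame:
    if isinstance(section, (str, Path)):
        return read_cohort(section)
    if isinstance(section, dict) and "path" in section:
        return read_cohort(section["path"])
    sim = dict(section.get("simulate", {})) if isinstance(section, dict) else {}
    seed = int(master.generate_state(1, np.uint32)[0] % 2**31)
    gen = reference_config(n=int(sim.get("n", 971)), seed=seed)
    # by default simulate from the sex-moderated pruned truth, whatever model
    # is being fitted downstream
    gen_model = _resolve_model(sim.get("model", "final"))
    return generate_cohort(gen_model, gen)


def _mcmc_config(section: dict | None, seed: int) -> McmcConfig:
    section = section or {}
    return McmcConfig(
        chains=int(section.get("chains", 3)),
        iterations=int(section.get("iterations", 10_000)),
        burnin=int(section.get("burnin", 5_000)),
        thinning=int(section.get("thinning", 1)),
        seed=seed,
    )


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> Path:
    """Run the full analysis chain; returns the populated run directory.

    Config sections (all optional): ``seed``; ``model`` (path or 'initial');
    ``data`` (cohort path, or ``simulate: {n: ...}``); ``mcmc`` (chains,
    iterations, burnin, thinning); ``selection`` (``keep`` /
    ``keep_moderation`` edge lists like 'age->MS', ``skip: true`` to fit the
    declared model directly); ``report`` (``level``).
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pthpath")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        master_seed = int(cfg.get("seed", 0))
        logger.info("pthpath %s pipeline start, master seed %d", __version__, master_seed)
        ss = np.random.SeedSequence(master_seed)
        stage_seeds = [
            int(s.generate_state(1, np.uint32)[0] % 2**31) for s in ss.spawn(6)
        ]
        logger.info("stage seeds: %s", stage_seeds)

        model = _resolve_model(cfg.get("model"))
        cohort = _resolve_cohort(cfg.get("data", {}), np.random.SeedSequence(stage_seeds[0]))
        write_cohort(cohort, out / "cohort.csv")
        desc = descriptive_table(cohort)
        desc.to_csv(out / "table1_descriptives.csv")

        priors = PriorSpec()
        level = float(cfg.get("report", {}).get("level", 0.95) if cfg.get("report") else 0.95)
        sel_cfg = cfg.get("selection") or {}

        fits_for_ranking = []

        if sel_cfg.get("skip"):
            final_model = model
            selection_record: dict = {"skipped": True}
        else:
            screen_mcmc = _mcmc_config(cfg.get("mcmc"), stage_seeds[1])
            screen = fit_by_sex(model, cohort, priors, screen_mcmc)
            screen.comparison.to_csv(out / "sex_screen.csv")
            logger.info("screen flagged edges: %s", screen.flagged_edges)

            base_fit = sample_posterior(
                model, cohort, priors, _mcmc_config(cfg.get("mcmc"), stage_seeds[2])
            )
            fits_for_ranking.append(base_fit)
            _write_json(base_fit.to_jsonable(), out / "fit_base.json")

            moderated = add_moderation(model, screen.flagged_edges)
            mod_fit = sample_posterior(
                moderated, cohort, priors, _mcmc_config(cfg.get("mcmc"), stage_seeds[3])
            )
            fits_for_ranking.append(mod_fit)
            _write_json(mod_fit.to_jsonable(), out / "fit_moderated.json")

            keep = {_parse_edge(s) for s in sel_cfg.get("keep", [])}
            keep_mod = {_parse_edge(s) for s in sel_cfg.get("keep_moderation", [])}
            final_model = prune_nonsignificant(moderated, mod_fit, keep, keep_mod, level)
            selection_record = {
                "skipped": False,
                "flagged_edges": [list(p) for p in screen.flagged_edges],
                "pruned_model_edges": [
                    {"source": e.source, "target": e.target, "sex_moderated": e.sex_moderated}
                    for e in final_model.edges
                ],
            }

        final_fit = sample_posterior(
            final_model, cohort, priors, _mcmc_config(cfg.get("mcmc"), stage_seeds[4])
        )
        fits_for_ranking.append(final_fit)
        _write_json(final_fit.to_jsonable(), out / "fit_final.json")
        logger.info(
            "final fit: DIC=%.1f, max EPSR=%.4f, converged=%s",
            final_fit.dic["dic"], max(final_fit.epsr.values()), final_fit.converged,
        )
        if not final_fit.converged:
            logger.warning("FINAL FIT DID NOT CONVERGE (EPSR above threshold)")

        ranking = compare_models(fits_for_ranking)
        ranking.to_csv(out / "model_ranking.csv", index=False)
        selection_record["dic_ranking"] = ranking.to_dict(orient="records")
        _write_json(selection_record, out / "selection.json")

        summarize(final_fit, level).to_csv(out / "coefficients.csv")
        effect_table(final_fit, level).round(4).to_csv(out / "table2_effects.csv", index=False)
        classify_effects(final_model, final_fit).to_csv(out / "table3_effect_types.csv")

        logger.info("pipeline complete: %s", out)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()


def _parse_edge(text: str) -> tuple[str, str]:
    src, _, tgt = text.partition("->")
    if not src or not tgt:
        raise ValueError(f"cannot parse edge {text!r}; expected 'source->target'")
    return (src.strip(), tgt.strip())
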