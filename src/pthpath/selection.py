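"""Three-step model selection: sex-stratified screen, moderation, DIC pruning.

The selection procedure mirrors a common epidemiological workflow for
moderated path models: (1) fit the un-moderated model separately to men and
women and flag paths whose coefficients look sex-dependent; (2) add male
offset parameters on the flagged paths of the pooled model; (3) remove
non-significant direct paths (credible interval covering zero), with a user
keep-list for paths retained on DIC grounds despite a null-covering
interval; competing models are ranked by DIC on the identical cohort.

The stratified screening rule — flag an edge when either sex's credible
interval excludes the other sex's posterior mean — is an explicit,
configurable stand-in for what is usually an informal judgment call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .estimate import FitResult, McmcConfig, PriorSpec, sample_posterior, summarize
from .model import PathEdge, PathModel

__all__ = [
    "SexStratifiedScreen",
    "fit_by_sex",
    "add_moderation",
    "prune_nonsignificant",
    "compare_models",
]

logger = logging.getLogger(__name__)

MIN_SUBJECTS_PER_PARAMETER = 10


@dataclass
class SexStratifiedScreen:
    """Result of the sex-stratified preliminary analysis."""

    female_fit: FitResult
    male_fit: FitResult
    comparison: pd.DataFrame  # per-edge posterior means, CrIs and flag
    flagged_edges: list[tuple[str, str]]


def _strip_moderation(model: PathModel) -> PathModel:
    edges = [PathEdge(e.source, e.target, sex_moderated=False) for e in model.edges]
    return PathModel(variables=dict(model.variables), edges=edges, name=model.name)


def fit_by_sex(
    model: PathModel,
    cohort: pd.DataFrame,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    level: float = 0.95,
) -> SexStratifiedScreen:
    """Fit the un-moderated model separately per sex and screen for differences.

    An edge is flagged as a candidate sex moderation when the female credible
    interval excludes the male posterior mean, or vice versa.  Raises on a
    single-sex cohort; warns when a sex subgroup is small relative to the
    largest equation (fewer than 10 subjects per parameter).
    """
    config = config or McmcConfig()
    sexes = set(cohort["sex"].unique())
    if sexes != {0, 1}:
        raise ValueError("sex-stratified analysis needs both sexes present")

    base = _strip_moderation(model)
    max_params = max(len(p) + 1 for p in base.equations().values())
    fits = {}
    for sexval, label in ((0, "female"), (1, "male")):
        sub = cohort[cohort["sex"] == sexval].reset_index(drop=True)
        if len(sub) < MIN_SUBJECTS_PER_PARAMETER * max_params:
            warnings.warn(
                f"{label} subgroup has only {len(sub)} subjects for up to "
                f"{max_params} parameters per equation",
                stacklevel=2,
            )
        seed_offset = 1 + sexval
        cfg = McmcConfig(
            chains=config.chains,
            iterations=config.iterations,
            burnin=config.burnin,
            seed=config.seed + seed_offset,
            thinning=config.thinning,
        )
        fits[label] = sample_posterior(base, sub, priors, cfg)

    rows = []
    flagged = []
    for e in base.edges:
        name = f"{e.target}.{e.source}"
        fem, mal = fits["female"], fits["male"]
        fmean, mmean = fem.posterior_mean(name), mal.posterior_mean(name)
        flo, fhi = fem.credible_interval(name, level)
        mlo, mhi = mal.credible_interval(name, level)
        flag = not (flo <= mmean <= fhi) or not (mlo <= fmean <= mhi)
        rows.append(
            {
                "edge": f"{e.source}->{e.target}",
                "source": e.source,
                "target": e.target,
                "female_mean": fmean,
                "female_lo": flo,
                "female_hi": fhi,
                "male_mean": mmean,
                "male_lo": mlo,
                "male_hi": mhi,
                "difference": mmean - fmean,
                "flagged": flag,
            }
        )
        if flag:
            flagged.append(e.pair)
            logger.info("sex-difference screen flagged %s", rows[-1]["edge"])

    return SexStratifiedScreen(
        female_fit=fits["female"],
        male_fit=fits["male"],
        comparison=pd.DataFrame(rows).set_index("edge"),
        flagged_edges=flagged,
    )


def add_moderation(
    model: PathModel, flagged_edges: list[tuple[str, str]]
) -> PathModel:
    """Return the model with sex-moderation enabled on the flagged edges."""
    pairs = {e.pair for e in model.edges}
    for pair in flagged_edges:
        if pair not in pairs:
            raise KeyError(f"cannot moderate nonexistent edge {pair[0]}->{pair[1]}")
    flagged = set(flagged_edges)
    edges = [
        PathEdge(e.source, e.target, sex_moderated=e.sex_moderated or e.pair in flagged)
        for e in model.edges
    ]
    return PathModel(
        variables=dict(model.variables), edges=edges, name=f"{model.name}+moderation"
    )


def prune_nonsignificant(
    model: PathModel,
    fit: FitResult,
    keep: set[tuple[str, str]] | None = None,
    keep_moderation: set[tuple[str, str]] | None = None,
    level: float = 0.95,
) -> PathModel:
    """Remove direct edges whose coefficient credible interval covers zero.

    ``keep`` lists (source, target) pairs retained regardless of their
    interval (e.g. on DIC grounds); ``keep_moderation`` does the same for
    male-offset parameters, which are otherwise dropped from moderated edges
    when non-significant.  An edge whose removal would leave an endogenous
    variable without predictors is retained with a warning.
    """
    keep = keep or set()
    keep_moderation = keep_moderation or set()
    summ = summarize(fit, level)

    def significant(name: str) -> bool:
        return bool(summ.loc[name, "significant"])

    new_edges: list[PathEdge] = []
    removed: list[str] = []
    for e in model.edges:
        name = f"{e.target}.{e.source}"
        if significant(name) or e.pair in keep:
            moderated = e.sex_moderated
            if moderated:
                off = f"{name}.male_offset"
                if not significant(off) and e.pair not in keep_moderation:
                    moderated = False
                    logger.info("dropping non-significant moderation on %s", name)
            new_edges.append(PathEdge(e.source, e.target, moderated))
        else:
            removed.append(name)

    # never orphan an endogenous equation
    for outcome in model.endogenous:
        if not any(e.target == outcome for e in new_edges):
            candidates = [e for e in model.edges if e.target == outcome]
            best = max(
                candidates, key=lambda e: abs(fit.posterior_mean(f"{e.target}.{e.source}"))
            )
            warnings.warn(
                f"all predictors of {outcome!r} were non-significant; retaining "
                f"{best.source}->{best.target} to keep the equation defined",
                stacklevel=2,
            )
            new_edges.append(PathEdge(best.source, best.target, False))
            removed.remove(f"{best.target}.{best.source}")

    if removed:
        logger.info("pruned edges: %s", ", ".join(removed))
    ordered = [e for e in model.edges if any(n.pair == e.pair for n in new_edges)]
    final = [next(n for n in new_edges if n.pair == e.pair) for e in ordered]
    return PathModel(
        variables=dict(model.variables), edges=final, name=f"{model.name}-pruned"
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits of competing models on the same cohort by ascending DIC."""
    if not fits:
        raise ValueError("no fits to compare")
    checksums = {f.cohort_checksum for f in fits}
    if len(checksums) > 1:
        raise ValueError("fits were computed on different cohorts (checksum mismatch)")
    rows = [
        {
            "model": f.model.name,
            "dbar": f.dic["dbar"],
            "pd": f.dic["pd"],
            "dic": f.dic["dic"],
            "converged": f.converged,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    out["delta_dic"] = out["dic"] - out["dic"].iloc[0]
    return out
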