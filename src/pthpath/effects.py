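"""Direct, indirect and total effects along pathways of a fitted path model.

Mediation here follows the product-of-coefficients convention: the indirect
effect along a pathway of continuous mediators is the product of the edge
coefficients, and the total effect of one variable on another is the direct
coefficient plus the sum of the quantifiable indirect products.  When a
binary variable sits strictly inside a pathway (e.g. type 2 diabetes between
magnesium and MS), linear and logistic coefficients cannot be multiplied
meaningfully; the pathway is reported as non-quantifiable and enters only
the significance classification.  A binary *terminal* outcome is fine — the
product is then a log-odds effect.

Sex moderation: moderated edges carry a female-reference coefficient plus a
male offset; the male coefficient is their sum, applied per posterior draw
when credible intervals are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .estimate import FitResult
from .model import PathModel, Pathway, enumerate_pathways

__all__ = [
    "EffectEstimate",
    "male_effect",
    "edge_coefficient",
    "pathway_effect",
    "total_effect",
    "unstandardize_linear",
    "unstandardize_logistic",
    "classify_effect_types",
    "classify_effects",
    "effect_table",
]

SEXES = ("female", "male", "pooled")


@dataclass
class EffectEstimate:
    """A direct, indirect or total effect for an ordered variable pair."""

    source: str
    target: str
    kind: str  # direct | indirect | total
    sex: str
    scale: str  # standardized | log-odds | natural-units | odds-ratio
    value: float | None
    cri: tuple[float, float] | None = None
    pathways: tuple[Pathway, ...] = ()
    excluded_pathways: tuple[Pathway, ...] = ()
    quantifiable: bool = True


def male_effect(female_coefficient: float, male_offset: float) -> float:
    """Coefficient for males: female-reference coefficient plus male offset."""
    return female_coefficient + male_offset


def edge_coefficient(
    coefficients: Mapping[tuple[str, str], float],
    male_offsets: Mapping[tuple[str, str], float],
    edge,
    sex: str,
) -> float:
    """Resolve one edge's coefficient for the requested sex."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    coef = coefficients[edge.pair]
    if sex == "male" and edge.sex_moderated:
        coef = male_effect(coef, male_offsets[edge.pair])
    return coef


def pathway_effect(
    pathway: Pathway,
    coefficients: Mapping[tuple[str, str], float],
    male_offsets: Mapping[tuple[str, str], float] | None = None,
    sex: str = "female",
) -> float | None:
    """Product of edge coefficients along a pathway; None if non-quantifiable."""
    if not pathway.quantifiable:
        return None
    male_offsets = male_offsets or {}
    prod = 1.0
    for e in pathway.edges:
        if e.pair not in coefficients:
            raise KeyError(f"missing coefficient for edge {e}")
        prod *= edge_coefficient(coefficients, male_offsets, e, sex)
    return prod


def _terminal_scale(model: PathModel, target: str) -> str:
    return "log-odds" if model.is_binary(target) else "standardized"


def total_effect(
    model: PathModel,
    coefficients: Mapping[tuple[str, str], float] | FitResult,
    source: str,
    target: str,
    sex: str = "female",
    male_offsets: Mapping[tuple[str, str], float] | None = None,
    level: float = 0.95,
) -> EffectEstimate:
    """Total effect of ``source`` on ``target``: direct + sum of products.

    Two modes.  With a plain coefficient mapping (optionally a male-offset
    mapping) the arithmetic runs on point estimates.  With a
    :class:`FitResult` the sums and products are applied per posterior draw,
    giving a credible interval whose point estimate (posterior mean) equals
    the point-mode arithmetic applied to posterior means of the draws.

    Non-quantifiable pathways (binary mediators) are excluded from the sum
    and reported in ``excluded_pathways``.
    """
    pathways = enumerate_pathways(model, source, target)
    if not pathways:
        raise ValueError(f"no pathway from {source!r} to {target!r}")
    quant = tuple(p for p in pathways if p.quantifiable)
    excluded = tuple(p for p in pathways if not p.quantifiable)

    if isinstance(coefficients, FitResult):
        fit = coefficients
        pooled = _draw_coefficients(fit)
        ndraws = next(iter(pooled.values())).size if pooled else 0
        total = np.zeros(ndraws)
        for p in quant:
            prod = np.ones(ndraws)
            for e in p.edges:
                prod = prod * _draw_edge(pooled, fit, e, sex)
            total = total + prod
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(total, [a, 100 - a])
        return EffectEstimate(
            source=source,
            target=target,
            kind="total",
            sex=sex,
            scale=_terminal_scale(model, target),
            value=float(total.mean()),
            cri=(float(lo), float(hi)),
            pathways=quant,
            excluded_pathways=excluded,
            quantifiable=not excluded,
        )

    value = 0.0
    for p in quant:
        value += pathway_effect(p, coefficients, male_offsets, sex)
    return EffectEstimate(
        source=source,
        target=target,
        kind="total",
        sex=sex,
        scale=_terminal_scale(model, target),
        value=value,
        pathways=quant,
        excluded_pathways=excluded,
        quantifiable=not excluded,
    )


def _draw_coefficients(fit: FitResult) -> dict[str, np.ndarray]:
    return {name: fit.pooled(name) for name in fit.parameter_names}


def _draw_edge(pooled: dict[str, np.ndarray], fit: FitResult, e, sex: str) -> np.ndarray:
    base = pooled[f"{e.target}.{e.source}"]
    if sex == "male" and e.sex_moderated:
        return base + pooled[f"{e.target}.{e.source}.male_offset"]
    return base


# ---------------------------------------------------------------------------
# Standardized <-> natural-unit conversion
# ---------------------------------------------------------------------------

def unstandardize_linear(
    std_coefficient: float, sd_predictor: float, sd_outcome: float
) -> float:
    """Natural-unit slope from a standardized one: b * SD_outcome / SD_predictor."""
    if not (sd_predictor > 0 and sd_outcome > 0):
        raise ValueError("standard deviations must be > 0")
    return std_coefficient * sd_outcome / sd_predictor


def unstandardize_logistic(std_coefficient: float, sd_predictor: float) -> float:
    """Odds ratio per natural unit of the predictor: exp(b / SD_predictor)."""
    if not sd_predictor > 0:
        raise ValueError("standard deviation must be > 0")
    return float(np.exp(std_coefficient / sd_predictor))


# ---------------------------------------------------------------------------
# Effect-type classification (the mediation summary table)
# ---------------------------------------------------------------------------

def _edge_significance_from_fit(fit: FitResult, level: float = 0.95):
    """Per-edge significance for each sex, from credible intervals.

    Female: the female-reference coefficient's CrI excludes 0.  Male: for
    moderated edges the per-draw sum (coefficient + offset) CrI excludes 0;
    unmoderated edges share the female coefficient.
    """
    def significant(draws: np.ndarray) -> bool:
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(draws, [a, 100 - a])
        return bool(lo > 0 or hi < 0)

    sig: dict[tuple[str, str], dict[str, bool]] = {}
    for e in fit.model.edges:
        base = fit.pooled(f"{e.target}.{e.source}")
        fem = significant(base)
        if e.sex_moderated:
            male = significant(base + fit.pooled(f"{e.target}.{e.source}.male_offset"))
        else:
            male = fem
        sig[e.pair] = {"female": fem, "male": male}
    return sig


def classify_effect_types(
    model: PathModel,
    edge_significance: Mapping[tuple[str, str], Mapping[str, bool]],
    target: str = "MS",
) -> pd.DataFrame:
    """Effect-type table: per explanatory variable and sex, how it reaches the target.

    A variable has a *direct* effect when its direct edge to the target is
    significant for that sex, and a significant *indirect* route along a
    pathway iff every edge on the pathway is significant for that sex
    (joint-significance rule).  The label lists the mediators of the
    significant indirect routes, e.g. 'indirect through PTH and T2DM'.
    """
    rows = []
    for name in model.variables:
        if name == target:
            continue
        pathways = enumerate_pathways(model, name, target)
        if not pathways:
            continue
        row: dict[str, str] = {"variable": name}
        for sex in ("female", "male"):
            direct = any(
                len(p) == 1 and edge_significance[p.edges[0].pair][sex]
                for p in pathways
            )
            mediators: list[str] = []
            for p in pathways:
                if len(p) == 1:
                    continue
                if all(edge_significance[e.pair][sex] for e in p.edges):
                    for m in p.mediators:
                        if m not in mediators:
                            mediators.append(m)
            if direct and mediators:
                label = "direct and indirect through " + " and ".join(mediators)
            elif direct:
                label = "direct"
            elif mediators:
                label = "indirect through " + " and ".join(mediators)
            else:
                label = "none"
            row[sex] = label
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def classify_effects(model: PathModel, fit: FitResult, target: str = "MS") -> pd.DataFrame:
    """Effect-type table computed from a fit's credible intervals."""
    return classify_effect_types(model, _edge_significance_from_fit(fit), target)


# ---------------------------------------------------------------------------
# Publication-style coefficient table
# ---------------------------------------------------------------------------

def effect_table(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Per-edge report: female-reference, male offset, male effect, natural units.

    Standardized direct effects with CrIs for the female reference, the male
    offset where the path is moderated, the corresponding male effect
    (per-draw sum), and the natural-unit conversion: SD-rescaled slope for
    linear equations, odds ratio per natural unit for logistic equations.
    """
    std = fit.standardization
    a = 100 * (1 - level) / 2

    def ci(draws: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(draws, [a, 100 - a])
        return float(lo), float(hi)

    rows = []
    for e in fit.model.edges:
        outcome, pred = e.target, e.source
        base = fit.pooled(f"{outcome}.{pred}")
        row: dict = {
            "outcome": outcome,
            "predictor": pred,
            "direct": float(base.mean()),
            "direct_lo": ci(base)[0],
            "direct_hi": ci(base)[1],
        }
        if e.sex_moderated:
            off = fit.pooled(f"{outcome}.{pred}.male_offset")
            male = base + off
            row.update(
                gender_diff=float(off.mean()),
                gender_diff_lo=ci(off)[0],
                gender_diff_hi=ci(off)[1],
                male=float(male.mean()),
                male_lo=ci(male)[0],
                male_hi=ci(male)[1],
            )
        binary_outcome = fit.model.is_binary(outcome)
        binary_pred = fit.model.is_binary(pred)
        if binary_outcome and not binary_pred:
            sd_x = std.sd(pred)
            nat = np.exp(base / sd_x)
            row["natural"] = float(nat.mean())
            row["natural_lo"], row["natural_hi"] = ci(nat)
            row["natural_scale"] = "odds-ratio per unit"
        elif binary_outcome and binary_pred:
            nat = np.exp(base)
            row["natural"] = float(nat.mean())
            row["natural_lo"], row["natural_hi"] = ci(nat)
            row["natural_scale"] = "odds-ratio"
        elif not binary_outcome and not binary_pred:
            nat = base * std.sd(outcome) / std.sd(pred)
            row["natural"] = float(nat.mean())
            row["natural_lo"], row["natural_hi"] = ci(nat)
            row["natural_scale"] = "unit per unit"
        rows.append(row)
    return pd.DataFrame(rows)
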