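"""Synthetic clinical cohorts simulated from a path model with known truth.

The generator draws subject-level records from the structural equations of a
:class:`~pthpath.model.PathModel` with declared standardized coefficients,
calibrated so the simulated marginals (means, SDs, prevalences) match a
declared target population.  The default calibration,
:func:`reference_config`, describes a bariatric-clinic population of
morbidly obese adults (n=971 complete cases, 67.5% women, 68.1% metabolic
syndrome, 25% type 2 diabetes) together with published standardized path
coefficients, so estimation and mediation code can be exercised against a
cohort with known ground truth.

Simulation runs on the standardized (z) scale in topological order:
exogenous variables come from truncated Gaussians renormalized to their
declared mean/SD; each continuous endogenous variable is a linear
combination of standardized parents plus sex offsets and a Gaussian
residual, then de-standardized to natural units; each binary endogenous
variable is Bernoulli with a logistic link whose intercept is calibrated by
Monte Carlo root-finding so the marginal prevalence hits its target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .model import PathModel, build_final_model

__all__ = [
    "GeneratorConfig",
    "CalibrationError",
    "COHORT_COLUMNS",
    "reference_coefficients",
    "reference_male_offsets",
    "reference_config",
    "calibrate_intercept",
    "generate_cohort",
    "descriptive_table",
]

logger = logging.getLogger(__name__)

#: Canonical cohort column order (sex coded 0=female, 1=male).
COHORT_COLUMNS = [
    "age",
    "sex",
    "MS",
    "T2DM",
    "PTH",
    "vitD",
    "magnesium",
    "calcium",
    "phosphate",
]

# Minimum residual SD on the z scale: guards against configs whose structural
# part already explains (numerically) all of the marginal variance.
_MIN_RESID_SD = 1e-3


class CalibrationError(RuntimeError):
    """Raised when an intercept target cannot be achieved."""


@dataclass
class MarginalSpec:
    """Mean/SD (and optional physiologic range) of a continuous variable."""

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"marginal SD must be > 0, got {self.sd}")


@dataclass
class GeneratorConfig:
    """Ground truth for cohort simulation.

    ``coefficients`` maps (source, target) to the standardized coefficient of
    that edge; ``male_offsets`` maps sex-moderated edges to the additive male
    offset (female reference).  ``exogenous_marginals`` may carry a single
    :class:`MarginalSpec` per variable or a ``{"female": ..., "male": ...}``
    pair.  ``endogenous_scaling`` gives the natural-unit mean/SD used to
    de-standardize continuous endogenous variables.  ``residual_sds`` entries
    of ``None`` are solved so the marginal z-variance is 1 (total variance =
    explained + residual).  ``target_prevalences`` are the marginal
    probabilities the calibrated logistic intercepts must reproduce.
    """

    n: int
    seed: int
    male_fraction: float
    exogenous_marginals: dict[str, MarginalSpec | dict[str, MarginalSpec]]
    endogenous_scaling: dict[str, MarginalSpec]
    coefficients: dict[tuple[str, str], float]
    male_offsets: dict[tuple[str, str], float] = field(default_factory=dict)
    residual_sds: dict[str, float | None] = field(default_factory=dict)
    target_prevalences: dict[str, float] = field(default_factory=dict)
    calibration_draws: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must lie in (0,1)")
        for name, p in self.target_prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"target prevalence for {name} must lie in (0,1)")
        for name, sd in self.residual_sds.items():
            if sd is not None and not sd > 0:
                raise ValueError(f"residual SD for {name} must be > 0")

    def validate_against(self, model: PathModel) -> None:
        """Raise if the config does not fully cover the model's structure."""
        for e in model.edges:
            if e.pair not in self.coefficients:
                raise ValueError(f"no coefficient declared for edge {e}")
            if e.sex_moderated and e.pair not in self.male_offsets:
                raise ValueError(f"no male offset declared for moderated edge {e}")
        for name in model.exogenous:
            if name not in self.exogenous_marginals:
                raise ValueError(f"no marginal declared for exogenous {name!r}")
        for name in model.endogenous:
            if model.is_binary(name):
                if name not in self.target_prevalences:
                    raise ValueError(f"no target prevalence for binary {name!r}")
            else:
                if name not in self.endogenous_scaling:
                    raise ValueError(f"no natural-unit scaling for {name!r}")


def reference_coefficients() -> dict[tuple[str, str], float]:
    """Standardized path coefficients of the default (female-reference) truth."""
    return {
        ("T2DM", "MS"): 3.47,
        ("age", "MS"): 0.31,
        ("PTH", "MS"): 0.36,
        ("phosphate", "MS"): 0.28,
        ("age", "PTH"): 0.20,
        ("magnesium", "PTH"): 0.12,
        ("vitD", "PTH"): -0.27,
        ("phosphate", "PTH"): -0.26,
        ("calcium", "PTH"): -0.09,
        ("phosphate", "calcium"): 0.27,
        ("magnesium", "T2DM"): -0.76,
        ("age", "T2DM"): 0.88,
    }


def reference_male_offsets() -> dict[tuple[str, str], float]:
    """Male offsets on the four sex-moderated paths (female reference)."""
    return {
        ("age", "MS"): -0.29,
        ("PTH", "MS"): -0.43,
        ("phosphate", "MS"): -0.42,
        ("age", "PTH"): -0.18,
    }


def reference_config(
    n: int = 971,
    seed: int = 0,
    sex_specific_exogenous: bool = False,
) -> GeneratorConfig:
    """Default study conditions for the morbidly obese reference population.

    Marginals: age 42 (12) years, 25-OH vitamin D 52 (22) nmol/l, magnesium
    0.84 (0.07) mmol/l, phosphate 1.09 (0.17) mmol/l, calcium 2.35 (0.07)
    mmol/l, PTH 5.8 (2.3) pmol/l; MS prevalence 68.1%, T2DM 25%; 32.5% men.
    With ``sex_specific_exogenous`` the exogenous marginals differ by sex
    (e.g. phosphate 1.10 in women vs 1.06 mmol/l in men).
    """
    if sex_specific_exogenous:
        exo: dict = {
            "age": {
                "female": MarginalSpec(41, 12, 18, 75),
                "male": MarginalSpec(44, 12, 18, 75),
            },
            "vitD": {
                "female": MarginalSpec(54, 22, 2, None),
                "male": MarginalSpec(50, 21, 2, None),
            },
            "magnesium": {
                "female": MarginalSpec(0.84, 0.07, 0.4, None),
                "male": MarginalSpec(0.85, 0.07, 0.4, None),
            },
            "phosphate": {
                "female": MarginalSpec(1.10, 0.16, 0.3, None),
                "male": MarginalSpec(1.06, 0.17, 0.3, None),
            },
        }
    else:
        exo = {
            "age": MarginalSpec(42, 12, 18, 75),
            "vitD": MarginalSpec(52, 22, 2, None),
            "magnesium": MarginalSpec(0.84, 0.07, 0.4, None),
            "phosphate": MarginalSpec(1.09, 0.17, 0.3, None),
        }
    return GeneratorConfig(
        n=n,
        seed=seed,
        male_fraction=0.325,
        exogenous_marginals=exo,
        endogenous_scaling={
            "calcium": MarginalSpec(2.35, 0.07),
            "PTH": MarginalSpec(5.8, 2.3),
        },
        coefficients=reference_coefficients(),
        male_offsets=reference_male_offsets(),
        residual_sds={"calcium": None, "PTH": None},
        target_prevalences={"MS": 0.681, "T2DM": 0.25},
    )


def calibrate_intercept(
    linear_predictor_samples: np.ndarray, target_prevalence: float
) -> float:
    """Intercept c with mean(logistic(c + samples)) = target, to 1e-6.

    Monotone Brent root-finding on the Monte Carlo prevalence curve; the
    mean of logistic(c + s) over finite samples is strictly increasing in c
    and spans (0,1), so any target in (0,1) is attainable.
    """
    s = np.asarray(linear_predictor_samples, dtype=float)
    if s.size == 0:
        raise CalibrationError("empty linear-predictor sample")
    if not np.all(np.isfinite(s)):
        raise CalibrationError("non-finite linear-predictor samples")
    if not 0 < target_prevalence < 1:
        raise CalibrationError("target prevalence must lie in (0,1)")

    def gap(c: float) -> float:
        return float(expit(c + s).mean() - target_prevalence)

    lo, hi = -10.0, 10.0
    while gap(lo) > 0:
        lo *= 2
        if lo < -1e6:  # pragma: no cover - defensive
            raise CalibrationError("target unattainable from below")
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:  # pragma: no cover - defensive
            raise CalibrationError("target unattainable from above")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-9))


def _truncated_standard_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float,
    lower: float | None, upper: float | None,
) -> np.ndarray:
    """z-scores with exact unit mean-0/SD-1 marginals under soft truncation.

    Draws from the Gaussian truncated to the physiologic range, then
    renormalizes by the truncated distribution's own mean/SD so the declared
    marginal moments are matched exactly in expectation.
    """
    a = -np.inf if lower is None else (lower - mean) / sd
    b = np.inf if upper is None else (upper - mean) / sd
    dist = stats.truncnorm(a, b)
    z = dist.rvs(size=n, random_state=rng)
    m, s = dist.mean(), dist.std()
    return (z - m) / s


def _simulate_z(
    model: PathModel,
    config: GeneratorConfig,
    rng: np.random.Generator,
    n: int,
    constants: dict | None,
) -> tuple[dict[str, np.ndarray], np.ndarray, dict]:
    """One simulation pass on the z scale.

    When ``constants`` is None this is the calibration pass: residual SDs,
    centering intercepts and logistic intercepts are solved from the sample
    itself and returned for reuse.  Binary variables are stored as 0/1; all
    continuous variables as z-scores.
    """
    calibrating = constants is None
    consts: dict = {"residual_sd": {}, "center": {}, "logit_intercept": {}}
    if not calibrating:
        consts = constants  # type: ignore[assignment]

    male = (rng.random(n) < config.male_fraction).astype(np.int64)
    z: dict[str, np.ndarray] = {}

    for name in model.exogenous:
        spec = config.exogenous_marginals[name]
        if isinstance(spec, Mapping):
            vals = np.empty(n)
            for sexval, key in ((0, "female"), (1, "male")):
                mask = male == sexval
                ms = spec[key]
                vals[mask] = _truncated_standard_normal(
                    rng, int(mask.sum()), ms.mean, ms.sd, ms.lower, ms.upper
                )
            z[name] = vals
        else:
            z[name] = _truncated_standard_normal(
                rng, n, spec.mean, spec.sd, spec.lower, spec.upper
            )

    for name in model.topological_order():
        if model.variable(name).role != "endogenous":
            continue
        lp = np.zeros(n)
        for e in model.edges:
            if e.target != name:
                continue
            coef = config.coefficients[e.pair]
            if e.sex_moderated:
                coef = coef + config.male_offsets[e.pair] * male
            lp = lp + coef * z[e.source]
        if model.is_binary(name):
            if calibrating:
                consts["logit_intercept"][name] = calibrate_intercept(
                    lp, config.target_prevalences[name]
                )
            c = consts["logit_intercept"][name]
            z[name] = (rng.random(n) < expit(c + lp)).astype(np.int64)
        else:
            if calibrating:
                declared = config.residual_sds.get(name)
                if declared is None:
                    explained = float(np.var(lp))
                    declared = float(np.sqrt(max(1.0 - explained, _MIN_RESID_SD**2)))
                consts["residual_sd"][name] = declared
                consts["center"][name] = float(lp.mean())
            sd = consts["residual_sd"][name]
            zval = lp - consts["center"][name] + rng.normal(0.0, sd, size=n)
            z[name] = zval

    return z, male, consts


def generate_cohort(model: PathModel, config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a complete-case cohort from a path model with known truth.

    Two passes share one seeded RNG stream: a large calibration pass
    (``config.calibration_draws`` subjects) solves residual SDs, centering
    terms and logistic intercepts; the production pass then draws the
    ``config.n`` subjects actually returned.  Fixed seed implies bit-identical
    output.  Returns a DataFrame with the canonical columns in natural units.
    """
    from .model import validate_model

    validate_model(model).raise_if_invalid()
    config.validate_against(model)

    ss = np.random.SeedSequence(config.seed)
    cal_rng, main_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    _, _, consts = _simulate_z(model, config, cal_rng, config.calibration_draws, None)
    z, male, _ = _simulate_z(model, config, main_rng, config.n, consts)

    data: dict[str, np.ndarray] = {"sex": male}
    for name in model.variables:
        spec = model.variable(name)
        if spec.scale == "binary":
            data[name] = z[name]
            continue
        if spec.role == "exogenous":
            mspec = config.exogenous_marginals[name]
            if isinstance(mspec, Mapping):
                vals = np.empty(config.n)
                for sexval, key in ((0, "female"), (1, "male")):
                    mask = male == sexval
                    vals[mask] = mspec[key].mean + mspec[key].sd * z[name][mask]
                data[name] = vals
            else:
                data[name] = mspec.mean + mspec.sd * z[name]
        else:
            scale = config.endogenous_scaling[name]
            data[name] = scale.mean + scale.sd * z[name]

    cohort = pd.DataFrame(data)
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    return cohort[cols]


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-sex descriptive summary with univariate comparison p-values.

    Continuous variables: mean (SD) and two-sided independent-samples t-test;
    binary variables: count (%) and chi-square test.  If only one sex is
    present the comparison columns are omitted with a warning.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    sexes = sorted(cohort["sex"].unique())
    both = set(sexes) == {0, 1}
    if not both:
        warnings.warn("single-sex cohort: comparison columns omitted", stacklevel=2)

    female = cohort[cohort["sex"] == 0]
    male = cohort[cohort["sex"] == 1]
    rows = []

    def fmt_cont(s: pd.Series) -> str:
        return f"{s.mean():.2f} ({s.std(ddof=1):.2f})"

    def fmt_bin(s: pd.Series) -> str:
        return f"{int(s.sum())} ({100 * s.mean():.1f}%)"

    rows.append(
        {
            "variable": "n",
            "total": str(len(cohort)),
            "female": str(len(female)) if both else None,
            "male": str(len(male)) if both else None,
            "p_value": np.nan,
        }
    )
    for col in cohort.columns:
        if col == "sex":
            continue
        binary = set(np.unique(cohort[col])) <= {0, 1}
        row = {"variable": col, "p_value": np.nan}
        if binary:
            row["total"] = fmt_bin(cohort[col])
            if both:
                row["female"] = fmt_bin(female[col])
                row["male"] = fmt_bin(male[col])
                table = pd.crosstab(cohort["sex"], cohort[col])
                if table.shape == (2, 2) and (table.values > 0).all():
                    row["p_value"] = stats.chi2_contingency(table)[1]
                else:
                    warnings.warn(
                        f"degenerate contingency table for {col}; p-value omitted",
                        stacklevel=2,
                    )
        else:
            row["total"] = fmt_cont(cohort[col])
            if both:
                row["female"] = fmt_cont(female[col])
                row["male"] = fmt_cont(male[col])
                if len(female) > 1 and len(male) > 1 and (
                    female[col].std(ddof=1) > 0 or male[col].std(ddof=1) > 0
                ):
                    row["p_value"] = stats.ttest_ind(female[col], male[col])[1]
                else:
                    warnings.warn(
                        f"degenerate variance for {col}; p-value omitted",
                        stacklevel=2,
                    )
        rows.append(row)

    out = pd.DataFrame(rows).set_index("variable")
    if not both:
        out = out.drop(columns=["female", "male"], errors="ignore")
    return out
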