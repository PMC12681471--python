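"""Synthetic survey generator with known reporting-heterogeneity truth.

Emulates the statistical structure of a large general-population health
survey: sparse, positively correlated long-term-condition indicators at
realistic prevalences, a short-term limitation item, ethnic-group shares
dominated by one majority group, one-hot demographic families, heterogeneous
lognormal survey weights, and five ordinal outcomes generated by running
the two-equation ordered-probit model forward. Because the generating
parameters are known, estimation bias, interval coverage, and contrast
recovery are all directly measurable.

Comorbidity is induced by a single-factor Gaussian copula: each condition
indicator thresholds rho*u + sqrt(1-rho^2)*e against the quantile of its
target prevalence, with u shared within a respondent. One factor is enough
to produce 2- and 3-way condition overlaps at the frequencies that make an
interaction prevalence screen meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .contrasts import bootstrap_contrasts, build_profiles, delta_tau
from .designs import (
    LatentDesign,
    RespondentTable,
    TableSchema,
    ThresholdDesign,
    build_latent_design,
    build_threshold_design,
)
from .model import N_CUTS, HopitParams, fit

__all__ = ["SyntheticConfig", "SyntheticTable", "generate", "recovery_experiment"]

DIMENSIONS = (
    "Mobility",
    "Self-care",
    "Usual Activities",
    "Pain/Discomfort",
    "Anxiety/Depression",
)

_OUTCOME_COLS = {
    "Mobility": "mobility",
    "Self-care": "self_care",
    "Usual Activities": "usual_activities",
    "Pain/Discomfort": "pain_discomfort",
    "Anxiety/Depression": "anxiety_depression",
}

#: marginal prevalences at the scale seen in English general-practice
#: survey data: hypertension and arthritis common, dementia rare
DEFAULT_PREVALENCE = {
    "alzheimers": 0.0014,
    "angina": 0.036,
    "arthritis": 0.106,
    "asthma": 0.104,
    "blindness": 0.005,
    "cancer": 0.028,
    "deafness": 0.023,
    "diabetes": 0.065,
    "epilepsy": 0.011,
    "high_blood_pressure": 0.17,
    "kidney_liver": 0.015,
    "back_problem": 0.095,
    "mental_health": 0.053,
    "neurological": 0.02,
    "other_condition": 0.132,
}

DEFAULT_GROUP_SHARES = {
    "group_white": 0.88,
    "group_asian": 0.06,
    "group_black": 0.027,
    "group_mixed": 0.008,
    "group_other": 0.023,
}

_AGE_BANDS = ("25_34", "35_44", "45_54", "55_64", "65_74")
_AGE_SHARES = (0.21, 0.21, 0.23, 0.19, 0.16)
_SEXES = ("m", "f")

#: latent-health slopes on the standard-normal scale; limitation dummies
#: carry the largest decrements (an acute limitation dominates today's
#: functioning)
DEFAULT_BETA = {
    "alzheimers": 0.45,
    "angina": 0.35,
    "arthritis": 0.5,
    "asthma": 0.2,
    "blindness": 0.4,
    "cancer": 0.3,
    "deafness": 0.2,
    "diabetes": 0.25,
    "epilepsy": 0.3,
    "high_blood_pressure": 0.2,
    "kidney_liver": 0.3,
    "back_problem": 0.45,
    "mental_health": 0.4,
    "neurological": 0.5,
    "other_condition": 0.35,
    "limitation_a_lot": 0.8,
    "limitation_a_little": 0.4,
}

#: cut-point intercepts: tau = (1.0, 1.6, 2.1, 2.6) at z = 0, putting the
#: bulk of respondents in the least severe level as in the real instrument
DEFAULT_LAMBDA = (1.0, np.log(0.6), np.log(0.5), np.log(0.5))

#: group-specific cut-point shifts (on the eta scale, one entry per cut);
#: the first entry moves tau_1 directly, later entries scale increments
DEFAULT_GROUP_SHIFTS = {
    "group_asian": (0.2, 0.1, 0.0, 0.0),
    "group_black": (0.3, 0.0, -0.05, 0.0),
    "group_mixed": (0.0, 0.0, 0.0, 0.0),
    "group_other": (0.15, 0.0, -0.1, -0.05),
}

#: mild non-group reporting effects so profiles are not degenerate
DEFAULT_COVARIATE_EFFECTS = {
    "dep_tercile2": (0.05, 0.0, 0.0, 0.0),
    "dep_tercile3": (0.1, 0.02, 0.0, 0.0),
    "agesex_65_74_f": (-0.05, 0.0, 0.0, 0.0),
    "gp_use": (-0.05, 0.0, 0.0, 0.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs, including the ground truth."""

    n: int = 20_000
    seed: int = 0
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    factor_loading: float = 0.5
    group_shares: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SHARES)
    )
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    true_lambda: tuple = DEFAULT_LAMBDA
    group_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SHIFTS)
    )
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    weight_sigma: float = 0.5
    n_waves: int = 3
    dimensions: tuple = DIMENSIONS
    threshold_families: tuple | None = None  # None = all families

    def __post_init__(self) -> None:
        for name, p in self.prevalence.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {name!r} outside (0,1)")
        total = sum(self.group_shares.values())
        if abs(total - 1.0) > 0.01:
            raise ValueError("group shares must sum to 1")
        if not (0.0 <= self.factor_loading < 1.0):
            raise ValueError("factor loading must lie in [0, 1)")

    def compact(self, n: int | None = None, seed: int | None = None) -> "SyntheticConfig":
        """A reduced specification (5 conditions, group family plus
        deprivation only) for simulation studies where many replicates
        must be fitted."""
        keep = ("arthritis", "asthma", "diabetes", "high_blood_pressure",
                "back_problem")
        return replace(
            self,
            n=self.n if n is None else n,
            seed=self.seed if seed is None else seed,
            prevalence={k: self.prevalence[k] for k in keep},
            true_beta={
                k: v
                for k, v in self.true_beta.items()
                if k in keep or k.startswith("limitation")
            },
            covariate_effects={
                k: v
                for k, v in self.covariate_effects.items()
                if k.startswith("dep_")
            },
            n_waves=1,
            threshold_families=("group", "deprivation"),
        )


def _schema(config: SyntheticConfig) -> TableSchema:
    families: dict[str, tuple[str, ...]] = {
        "group": tuple(config.group_shares),
        "agesex": tuple(
            f"agesex_{a}_{s}" for a in _AGE_BANDS for s in _SEXES
        ),
        "deprivation": ("dep_tercile1", "dep_tercile2", "dep_tercile3"),
    }
    baselines = {
        "group": "group_white",
        "agesex": "agesex_25_34_m",
        "deprivation": "dep_tercile1",
    }
    if config.n_waves > 1:
        families["wave"] = tuple(f"wave_{k}" for k in range(1, config.n_waves + 1))
        baselines["wave"] = "wave_1"
    for extra in ("gp_use", "nurse_use", "easy_appointment"):
        if extra in config.covariate_effects or extra == "gp_use":
            families[extra] = (extra,)
    return TableSchema(
        outcomes=dict(_OUTCOME_COLS) if config.dimensions == DIMENSIONS else {
            d: _OUTCOME_COLS[d] for d in config.dimensions
        },
        conditions=tuple(config.prevalence),
        limitation="limitation",
        families=families,
        baselines=baselines,
        weight="weight",
    )


@dataclass
class SyntheticTable:
    """Generated respondents plus the hidden ground truth.

    ``hidden`` carries, per dimension, the true latent index and the true
    category implied by the latent draw and the true per-row thresholds —
    enough to verify generator self-consistency exactly.
    """

    table: RespondentTable
    config: SyntheticConfig
    hidden: pd.DataFrame
    latent: LatentDesign
    threshold: ThresholdDesign
    true_params: HopitParams

    def truth_delta_tau(self, weighted: bool = True) -> dict[str, np.ndarray]:
        """True contrast values at the generated sample's profiles."""
        profiles = build_profiles(
            self.threshold, self.table.weights, weighted=weighted
        )
        return {p.group: delta_tau(self.true_params, p) for p in profiles}


def _gamma_matrix(config: SyntheticConfig, threshold: ThresholdDesign) -> np.ndarray:
    gamma = np.zeros((N_CUTS, threshold.n_columns))
    effects = {**config.covariate_effects, **config.group_shifts}
    for name, vec in effects.items():
        if name not in threshold.column_names:
            continue
        j = threshold.column_names.index(name)
        gamma[:, j] = np.asarray(vec, dtype=float)
    return gamma


def generate(config: SyntheticConfig) -> SyntheticTable:
    """Draw one respondent table from the configured truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    schema = _schema(config)

    # correlated condition indicators via a one-factor Gaussian copula
    u = rng.standard_normal(n)
    rho = config.factor_loading
    cols: dict[str, np.ndarray] = {}
    for name, prev in config.prevalence.items():
        v = rho * u + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
        cols[name] = (v < ndtri(prev)).astype(int)

    # short-term limitation, mildly loaded on the same factor
    wlat = 0.6 * u + 0.8 * rng.standard_normal(n)
    lim = np.full(n, "no", dtype=object)
    lim[wlat > ndtri(0.84)] = "a_little"
    lim[wlat > ndtri(0.96)] = "a_lot"
    cols["limitation"] = lim

    # demographic families
    group_names = list(config.group_shares)
    shares = np.array(list(config.group_shares.values()), dtype=float)
    shares = shares / shares.sum()
    gidx = rng.choice(len(group_names), size=n, p=shares)
    for k, name in enumerate(group_names):
        cols[name] = (gidx == k).astype(int)

    cell_names = [f"agesex_{a}_{s}" for a in _AGE_BANDS for s in _SEXES]
    cell_p = np.repeat(np.asarray(_AGE_SHARES) / 2.0, 2)
    cell_p = cell_p / cell_p.sum()
    cidx = rng.choice(len(cell_names), size=n, p=cell_p)
    for k, name in enumerate(cell_names):
        cols[name] = (cidx == k).astype(int)

    didx = rng.choice(3, size=n)
    for k in range(3):
        cols[f"dep_tercile{k + 1}"] = (didx == k).astype(int)

    if config.n_waves > 1:
        widx = rng.choice(config.n_waves, size=n)
        for k in range(config.n_waves):
            cols[f"wave_{k + 1}"] = (widx == k).astype(int)

    for extra, p_extra in (("gp_use", 0.7), ("nurse_use", 0.4),
                           ("easy_appointment", 0.7)):
        if extra in schema.families:
            cols[extra] = (rng.random(n) < p_extra).astype(int)

    # survey weights: lognormal, unit mean, independent of everything else
    sig = config.weight_sigma
    cols["weight"] = rng.lognormal(mean=-0.5 * sig * sig, sigma=sig, size=n)

    frame = pd.DataFrame(cols)

    # forward model for each requested dimension
    interim = RespondentTable(data=frame.assign(
        **{c: 1 for c in schema.outcomes.values()}
    ), schema=schema)
    latent = build_latent_design(interim, interactions=[])
    beta = np.array(
        [config.true_beta.get(c, 0.0) for c in latent.column_names]
    )
    threshold = build_threshold_design(
        interim,
        families=None if config.threshold_families is None
        else list(config.threshold_families),
        contrast_family="group",
        latent=latent,
    )
    gamma = _gamma_matrix(config, threshold)
    params = HopitParams(
        beta=beta, lam=np.asarray(config.true_lambda, dtype=float), gamma=gamma
    )

    from .model import latent_index, thresholds as _thresholds

    xb = latent_index(params, latent)
    tau = _thresholds(params, threshold)
    hidden = {}
    for dim in config.dimensions:
        hstar = xb + rng.standard_normal(n)
        category = 1 + np.sum(hstar[:, None] >= tau, axis=1)
        frame[_OUTCOME_COLS[dim]] = category
        hidden[f"latent_{_OUTCOME_COLS[dim]}"] = hstar
        hidden[f"category_{_OUTCOME_COLS[dim]}"] = category
    for j in range(N_CUTS):
        hidden[f"tau_{j + 1}"] = tau[:, j]

    table = RespondentTable.from_frame(frame, schema)
    return SyntheticTable(
        table=table,
        config=config,
        hidden=pd.DataFrame(hidden),
        latent=latent,
        threshold=threshold,
        true_params=params,
    )


def recovery_experiment(
    config: SyntheticConfig,
    n_replicates: int,
    seed: int = 0,
    dimension: str | None = None,
    n_draws: int = 500,
) -> pd.DataFrame:
    """Generate-fit-contrast repeatedly and summarize estimation quality.

    Returns one row per tracked quantity (every model parameter and every
    group's four cut-point contrasts) with the truth, mean bias, RMSE, and
    the share of 95% intervals covering the truth. Replicates that fail to
    converge are counted in the ``n_failed`` attribute of the frame.
    """
    dimension = dimension or config.dimensions[0]
    rng = np.random.default_rng(seed)
    est_rows: list[np.ndarray] = []
    cover_rows: list[np.ndarray] = []
    dt_rows: list[np.ndarray] = []
    dt_cover: list[np.ndarray] = []
    n_failed = 0
    truth_theta = None
    names = None
    dt_names = None
    truth_dt = None
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        synth = generate(replace(config, seed=rep_seed))
        outcome = synth.table.outcome(dimension)
        w = synth.table.weights
        fitted = fit(
            synth.latent, synth.threshold, outcome, w, dimension=dimension,
            fit_null=False,
        )
        if not fitted.converged:
            n_failed += 1
            continue
        if truth_theta is None:
            truth_theta = synth.true_params.pack()
            names = fitted.parameter_names
            truth_dt_map = synth.truth_delta_tau()
            dt_names = [
                f"delta_tau{j + 1}:{g}"
                for g in truth_dt_map
                for j in range(N_CUTS)
            ]
            truth_dt = np.concatenate(list(truth_dt_map.values()))
        theta = fitted.params.pack()
        se = np.sqrt(np.clip(np.diag(fitted.vcov), 0, None))
        est_rows.append(theta)
        cover_rows.append(
            (np.abs(theta - truth_theta) <= 1.959964 * se).astype(float)
        )
        profiles = build_profiles(synth.threshold, w)
        contrasts = bootstrap_contrasts(
            fitted, profiles, n_draws=n_draws, seed=rep_seed
        )
        dt = np.concatenate([c.delta for c in contrasts])
        lo = np.concatenate([c.ci_se[:, 0] for c in contrasts])
        hi = np.concatenate([c.ci_se[:, 1] for c in contrasts])
        dt_rows.append(dt)
        dt_cover.append(((lo <= truth_dt) & (truth_dt <= hi)).astype(float))
    if not est_rows:
        raise RuntimeError("no replicate converged")
    est = np.array(est_rows)
    dt = np.array(dt_rows)
    summary = pd.DataFrame(
        {
            "quantity": list(names) + list(dt_names),
            "truth": np.concatenate([truth_theta, truth_dt]),
            "bias": np.concatenate(
                [est.mean(0) - truth_theta, dt.mean(0) - truth_dt]
            ),
            "rmse": np.concatenate(
                [
                    np.sqrt(np.mean((est - truth_theta) ** 2, axis=0)),
                    np.sqrt(np.mean((dt - truth_dt) ** 2, axis=0)),
                ]
            ),
            "coverage": np.concatenate(
                [np.array(cover_rows).mean(0), np.array(dt_cover).mean(0)]
            ),
        }
    )
    summary.attrs["n_failed"] = n_failed
    summary.attrs["n_replicates"] = n_replicates
    return summary
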