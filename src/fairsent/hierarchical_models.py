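"""Hierarchical Bayesian models for sentence-evaluation data.

Two likelihoods share one crossed random-intercept design:

* **Gaussian reaction times** — standardized RT for positive responses,
  ``RT_z = beta0 + b_participant + b_item + beta_gender * gender
  [+ beta_condition * condition + beta_gxc * gender * condition] + eps``,
  ``eps ~ N(0, sigma)``.
* **Lapse-rate logistic accuracy** — yes/no correctness with chance level
  0.5, ``P(correct) = 0.5 + (0.5 - p_miss) * logistic(eta)`` where ``eta``
  follows the same linear structure.  ``p_miss`` (the lapse rate, shared by
  all participants) sets the upper asymptote at ``1 - p_miss``.

Codings: gender feminine=0 / masculine=1; condition unmarked=0 /
contracted=1.  Experiment 1 has no condition terms; experiment 2 adds the
condition main effect and its interaction with gender.

Priors: N(0, 1) on all fixed effects (data are standardized),
Gamma(2, 0.1) on every dispersion parameter, Beta(5, 10) on the lapse rate.

Fitting uses the package's Hamiltonian Monte Carlo engine
(:mod:`fairsent._engine`) with non-centred random intercepts; convergence is
monitored with split R-hat, bulk effective sample size, and divergence
counts (via :mod:`arviz`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import _engine
from .trial_data import CONDITION_CODE, GENDER_CODE

logger = logging.getLogger(__name__)

FIXED_EFFECT_ORDER = ["beta0", "beta_gender", "beta_condition", "beta_gender_condition"]

#: Convergence thresholds for the Diagnostics pass flag.
RHAT_MAX = 1.01
ESS_MIN = 400.0

#: HMC trajectory settings: total integration time (in units of the adapted
#: mass-standardized scale) and the leapfrog-step cap.
INTEGRATION_TIME = 3.0
MAX_LEAPFROG = 128


class PriorConfig(BaseModel):
    """Prior hyperparameters (all weakly informative)."""

    fixed_effect_scale: float = Field(default=1.0, gt=0)
    sigma_shape: float = Field(default=2.0, gt=0)
    sigma_rate: float = Field(default=0.1, gt=0)
    pmiss_alpha: float = Field(default=5.0, gt=0)
    pmiss_beta: float = Field(default=10.0, gt=0)


class MCMCConfig(BaseModel):
    """Sampler settings.  Defaults mirror the reference analysis (7 chains
    of 7,000 iterations, 3,000 burn-in, estimates on 4,000 per chain); use
    :meth:`fast` for a light profile suited to simulation harnesses."""

    n_chains: int = Field(default=7, ge=1)
    n_iter_per_chain: int = Field(default=7000, ge=2)
    n_burnin: int = Field(default=3000, ge=1)
    n_retained: int = Field(default=4000, ge=1)
    seed: int = 0
    target_acceptance: float = Field(default=0.9, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "MCMCConfig":
        if self.n_burnin + self.n_retained != self.n_iter_per_chain:
            raise ValueError("n_burnin + n_retained must equal n_iter_per_chain")
        return self

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        """4 chains x 2,000 iterations — for recovery/calibration loops."""
        return cls(n_chains=4, n_iter_per_chain=2000, n_burnin=1000, n_retained=1000, seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0) -> "MCMCConfig":
        """2 chains x 1,200 iterations — for rank-calibration replicates."""
        return cls(n_chains=2, n_iter_per_chain=1200, n_burnin=600, n_retained=600, seed=seed)


class ModelSpec(BaseModel):
    """Declarative description of one likelihood + priors + coding."""

    likelihood: Literal["gaussian_rt", "lapse_logistic_acc"]
    fixed_effects: list[str]
    random_intercepts: tuple[str, str] = ("participant", "item")
    experiment: int = Field(default=1, ge=1, le=2)
    prior: PriorConfig = Field(default_factory=PriorConfig)
    #: Per-effect multipliers on ``prior.fixed_effect_scale`` (sensitivity sweeps).
    fixed_effect_scale_multipliers: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ModelSpec":
        if any(e not in FIXED_EFFECT_ORDER for e in self.fixed_effects):
            raise ValueError(f"fixed effects must be among {FIXED_EFFECT_ORDER}")
        if self.fixed_effects != [e for e in FIXED_EFFECT_ORDER if e in self.fixed_effects]:
            raise ValueError("fixed effects must follow the canonical order")
        has_cond = "beta_condition" in self.fixed_effects
        if self.experiment == 1 and has_cond:
            raise ValueError("experiment-1 models have no condition terms")
        return self

    def fixed_scales(self) -> np.ndarray:
        base = self.prior.fixed_effect_scale
        return np.array(
            [base * self.fixed_effect_scale_multipliers.get(e, 1.0) for e in self.fixed_effects]
        )


@dataclass
class PosteriorSamples:
    """Labelled MCMC draws, one ``(chain, draw)`` array per parameter."""

    draws: dict[str, np.ndarray]
    n_divergent: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def parameters(self) -> list[str]:
        return list(self.draws)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-to-wide export: chain/draw index columns + one column per
        parameter."""
        n_c, n_d = self.n_chains, self.n_draws_per_chain
        out = {
            "chain": np.repeat(np.arange(n_c), n_d),
            "draw": np.tile(np.arange(n_d), n_c),
        }
        for name, arr in self.draws.items():
            out[name] = arr.reshape(-1)
        return pd.DataFrame(out)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_divergent: int = 0, meta: dict | None = None):
        """Inverse of :meth:`to_dataframe` (chain/draw columns required)."""
        n_c = int(df["chain"].max()) + 1
        n_d = int(df["draw"].max()) + 1
        draws = {
            name: df[name].to_numpy().reshape(n_c, n_d)
            for name in df.columns
            if name not in ("chain", "draw")
        }
        return cls(draws=draws, n_divergent=n_divergent, meta=meta or {})


@dataclass
class Diagnostics:
    """Split R-hat / ESS per parameter plus the divergence count."""

    rhat: dict[str, float]
    effective_sample_size: dict[str, float]
    n_divergent: int
    passed: bool

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "effective_sample_size": self.effective_sample_size,
            "n_divergent": self.n_divergent,
            "pass": self.passed,
        }

    @property
    def max_rhat(self) -> float:
        return float(np.nanmax(list(self.rhat.values())))

    @property
    def min_ess(self) -> float:
        return float(np.nanmin(list(self.effective_sample_size.values())))


# ---------------------------------------------------------------------------
# deterministic model arithmetic


def _require(fixed: Mapping[str, float], name: str) -> float:
    if name not in fixed:
        raise KeyError(f"missing coefficient {name!r}")
    return float(fixed[name])


def rt_location(
    fixed: Mapping[str, float],
    alpha_dev_participant: float,
    alpha_dev_item: float,
    gender: int,
    condition: int | None = None,
) -> float:
    """Location of the Gaussian RT likelihood for one trial.

    ``fixed`` must contain ``beta0`` and ``beta_gender`` (plus
    ``beta_condition`` and ``beta_gender_condition`` when ``condition`` is
    given).  ``gender``/``condition`` use the 0/1 codings.
    """
    mu = (
        _require(fixed, "beta0")
        + alpha_dev_participant
        + alpha_dev_item
        + _require(fixed, "beta_gender") * gender
    )
    if condition is not None:
        mu += _require(fixed, "beta_condition") * condition
        mu += _require(fixed, "beta_gender_condition") * gender * condition
    return mu


def accuracy_prob(
    fixed: Mapping[str, float],
    alpha_dev_participant: float,
    alpha_dev_item: float,
    gender: int,
    condition: int | None = None,
    p_miss: float = 0.0,
) -> float:
    """Lapse-rate psychometric probability of a correct response.

    ``P = 0.5 + (0.5 - p_miss) * logistic(eta)`` with ``eta`` the same
    linear predictor as :func:`rt_location`.  Requires ``0 <= p_miss < 0.5``
    so that the function stays above chance and increases with ``eta``.
    """
    if not 0.0 <= p_miss < 0.5:
        raise ValueError("p_miss must lie in [0, 0.5)")
    eta = rt_location(fixed, alpha_dev_participant, alpha_dev_item, gender, condition)
    p = 1.0 / (1.0 + np.exp(-eta))
    return 0.5 + (0.5 - p_miss) * p


# ---------------------------------------------------------------------------
# model builders


def _effects_for(experiment: int) -> list[str]:
    if experiment == 1:
        return ["beta0", "beta_gender"]
    return list(FIXED_EFFECT_ORDER)


def build_rt_model(
    trials: pd.DataFrame, experiment: int, prior: PriorConfig | None = None
) -> ModelSpec:
    """Gaussian RT model spec for a filtered, standardized trial table."""
    if "rt_z" not in trials.columns or trials["rt_z"].isna().any():
        raise ValueError("rt_z column absent or incomplete; run standardize_rt first")
    if len(trials) and not (
        (trials["trial_role"] == "experimental").all() and (trials["response"] == "yes").all()
    ):
        raise ValueError("RT model requires positive experimental responses only")
    return ModelSpec(
        likelihood="gaussian_rt",
        fixed_effects=_effects_for(experiment),
        experiment=experiment,
        prior=prior or PriorConfig(),
    )


def build_accuracy_model(
    trials: pd.DataFrame, experiment: int, prior: PriorConfig | None = None
) -> ModelSpec:
    """Lapse-rate logistic accuracy model spec (yes and no responses)."""
    if len(trials) and not (trials["trial_role"] == "experimental").all():
        raise ValueError("accuracy model requires experimental trials only")
    return ModelSpec(
        likelihood="lapse_logistic_acc",
        fixed_effects=_effects_for(experiment),
        experiment=experiment,
        prior=prior or PriorConfig(),
    )


# ---------------------------------------------------------------------------
# fitting


def _model_arrays(spec: ModelSpec, trials: pd.DataFrame):
    if spec.likelihood == "gaussian_rt":
        data = trials
        y = data["rt_z"].to_numpy(dtype=np.float64)
    else:
        data = trials[trials["response"] != "none"]
        dropped = len(trials) - len(data)
        if dropped:
            logger.info("accuracy model: dropped %d non-responses", dropped)
        y = data["correct"].to_numpy(dtype=np.float64)
    g = data["pronoun_gender"].map(GENDER_CODE).to_numpy(dtype=np.float64)
    c = data["condition"].map(CONDITION_CODE).to_numpy(dtype=np.float64)
    participants = sorted(data["participant_id"].unique())
    items = sorted(data["item_id"].unique())
    pidx = data["participant_id"].map({p: j for j, p in enumerate(participants)}).to_numpy(
        dtype=np.int64
    )
    iidx = data["item_id"].map({w: j for j, w in enumerate(items)}).to_numpy(dtype=np.int64)
    return y, g, c, pidx, iidx, participants, items


def fit_model(
    spec: ModelSpec, trials: pd.DataFrame, mcmc: MCMCConfig | None = None
) -> tuple[PosteriorSamples, Diagnostics]:
    """Sample the posterior of ``spec`` on ``trials`` with HMC.

    Returns labelled draws (fixed effects, dispersions, lapse rate, and
    every participant/item intercept deviation on the natural scale) and
    convergence diagnostics.  A fixed (seed, data, spec, mcmc) combination
    reproduces the draws exactly.  Non-convergence is flagged through
    ``Diagnostics.passed`` and a warning, never silently accepted.
    """
    mcmc = mcmc or MCMCConfig()
    y, g, c, pidx, iidx, participants, items = _model_arrays(spec, trials)
    n_p, n_i = len(participants), len(items)
    if 0 < n_p < 2 or 0 < n_i < 2:
        warnings.warn(
            "single participant or item: the corresponding sigma is weakly identified",
            stacklevel=2,
        )
    if spec.likelihood == "gaussian_rt" and len(y) and np.isnan(y).any():
        raise ValueError("rt_z contains missing values")

    k = len(spec.fixed_effects)
    kind = _engine.GAUSSIAN_RT if spec.likelihood == "gaussian_rt" else _engine.LAPSE_LOGISTIC
    prior = np.array(
        [spec.prior.sigma_shape, spec.prior.sigma_rate, spec.prior.pmiss_alpha, spec.prior.pmiss_beta]
    )
    scales = spec.fixed_scales()
    d = k + 3 + n_p + n_i

    all_draws = np.empty((mcmc.n_chains, mcmc.n_retained, d))
    n_div = 0
    for chain in range(mcmc.n_chains):
        chain_seed = int((mcmc.seed * 1000003 + 77779 * chain + 1) % (2**31 - 1))
        init_rng = np.random.default_rng(chain_seed)
        x0 = init_rng.uniform(-2.0, 2.0, d)
        draws, div = _engine.glmm_chain(
            kind,
            y,
            g,
            c,
            pidx,
            iidx,
            n_p,
            n_i,
            k,
            scales,
            prior,
            x0,
            mcmc.n_burnin,
            mcmc.n_retained,
            mcmc.target_acceptance,
            chain_seed,
            INTEGRATION_TIME,
            MAX_LEAPFROG,
        )
        all_draws[chain] = draws
        n_div += int(div)

    named: dict[str, np.ndarray] = {}
    for j, eff in enumerate(spec.fixed_effects):
        named[eff] = all_draws[:, :, j]
    sigma_p = np.exp(all_draws[:, :, k])
    sigma_i = np.exp(all_draws[:, :, k + 1])
    named["sigma_participant"] = sigma_p
    named["sigma_item"] = sigma_i
    if kind == _engine.GAUSSIAN_RT:
        named["sigma_resid"] = np.exp(all_draws[:, :, k + 2])
    else:
        named["p_miss"] = 1.0 / (1.0 + np.exp(-all_draws[:, :, k + 2]))
    for j, pid in enumerate(participants):
        named[f"alpha_participant[{pid}]"] = sigma_p * all_draws[:, :, k + 3 + j]
    for j, wid in enumerate(items):
        named[f"alpha_item[{wid}]"] = sigma_i * all_draws[:, :, k + 3 + n_p + j]

    samples = PosteriorSamples(
        draws=named,
        n_divergent=n_div,
        meta={
            "likelihood": spec.likelihood,
            "experiment": spec.experiment,
            "seed": mcmc.seed,
            "n_chains": mcmc.n_chains,
            "n_retained": mcmc.n_retained,
            "n_observations": int(len(y)),
            "participants": list(participants),
            "items": list(items),
            "engine": "fairsent-hmc",
        },
    )
    diag = check_convergence(samples) if mcmc.n_chains >= 2 else None
    if diag is not None and not diag.passed:
        warnings.warn(
            f"convergence not reached (max rhat {diag.max_rhat:.3f}, "
            f"min ESS {diag.min_ess:.0f}, {diag.n_divergent} divergent)",
            stacklevel=2,
        )
    return samples, diag


def check_convergence(samples: PosteriorSamples) -> Diagnostics:
    """Split R-hat and bulk ESS per parameter (arviz), plus the pass flag
    (max R-hat <= 1.01, no divergences, min ESS >= 400)."""
    import arviz as az

    if samples.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=samples.draws)
        r = az.rhat(idata)
        e = az.ess(idata)
    for name in samples.draws:
        rhat[name] = float(r[name].values)
        ess[name] = float(e[name].values)
    passed = (
        np.nanmax(list(rhat.values())) <= RHAT_MAX
        and samples.n_divergent == 0
        and np.nanmin(list(ess.values())) >= ESS_MIN
    )
    return Diagnostics(
        rhat=rhat,
        effective_sample_size=ess,
        n_divergent=samples.n_divergent,
        passed=bool(passed),
    )
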