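"""Synthetic sentence-evaluation data with the models' exact generative structure.

The generator inverts the two analysis models: standardized reaction times
follow a Gaussian with crossed participant/item random intercepts and a
fixed effect of continuation-pronoun gender (plus condition terms in the
between-subjects experiment), and yes/no responses follow a lapse-rate
logistic psychometric function

    P(correct) = 0.5 + (0.5 - p_miss) * logistic(eta),

with its own crossed random intercepts.  Reaction times are generated on
the z scale and affinely mapped to milliseconds so that the full pipeline
(filtering, re-standardization) is exercised downstream.

Default :class:`TrueParams` encode the study conditions this package is
designed around: a masculine processing advantage of -0.22 z units after a
gender-unmarked antecedent that is cancelled (interaction +0.26) by a
contracted double form, an accuracy advantage of 1.49 logits, a 6% lapse
rate, and a negative correlation (-0.43) between an item's RT and accuracy
intercepts.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .trial_data import COLUMNS, GENDER_CODE, CONDITION_CODE

logger = logging.getLogger(__name__)

#: Reaction times below this floor (ms) are clamped after the z -> ms map.
RT_FLOOR_MS = 50.0


class TrueParams(BaseModel):
    """Complete generative specification (RT channel in z units, accuracy
    channel in logit units)."""

    beta0_rt: float = 0.11
    beta_gender_rt: float = -0.22
    beta_condition_rt: float = -0.17
    beta_interaction_rt: float = 0.26
    sigma_participant_rt: float = Field(default=0.40, ge=0)
    sigma_item_rt: float = Field(default=0.30, ge=0)
    sigma_resid_rt: float = Field(default=0.85, ge=0)

    beta0_acc: float = 1.22
    beta_gender_acc: float = 1.49
    beta_condition_acc: float = 0.20
    beta_interaction_acc: float = -0.39
    sigma_participant_acc: float = Field(default=0.80, ge=0)
    sigma_item_acc: float = Field(default=0.60, ge=0)

    p_miss: float = Field(default=0.06, ge=0)
    #: Correlation between an item's RT and accuracy intercepts.
    intercept_correlation: float = Field(default=-0.43, ge=-1, le=1)

    rt_backtransform_mean_ms: float = Field(default=1500.0, gt=0)
    rt_backtransform_sd_ms: float = Field(default=400.0, gt=0)

    @model_validator(mode="after")
    def _check_pmiss(self) -> "TrueParams":
        if not self.p_miss < 0.5:
            raise ValueError("p_miss must lie in [0, 0.5)")
        return self


class SimConfig(BaseModel):
    """Design + generative parameters for one simulated experiment.

    ``n_participants`` is the total for experiment 1; for experiment 2 it is
    either a per-condition count or an explicit ``(unmarked, contracted)``
    pair (the study ran 34/36).
    """

    experiment: int = Field(default=1, ge=1, le=2)
    n_participants: int | tuple[int, int] = 47
    n_items: int = 22
    n_lists: int = 2
    seed: int = 0
    true_params: TrueParams = Field(default_factory=TrueParams)
    include_fillers: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_items % 2 != 0 or self.n_items < 2:
            raise ValueError("n_items must be even (half il / half elle per list)")
        if self.n_lists != 2:
            raise ValueError("the counterbalancing scheme uses exactly 2 lists")
        n = self.n_participants
        if isinstance(n, int):
            if n < 1:
                raise ValueError("n_participants must be >= 1")
        else:
            if self.experiment != 2:
                raise ValueError("per-condition participant counts require experiment 2")
            if len(n) != 2 or min(n) < 1:
                raise ValueError("participant pair must be two positive counts")
        return self

    def participants_per_condition(self) -> list[tuple[str, int]]:
        """(condition, count) groups; experiment 1 is all-unmarked."""
        if self.experiment == 1:
            assert isinstance(self.n_participants, int)
            return [("unmarked", self.n_participants)]
        n = self.n_participants
        pair = (n, n) if isinstance(n, int) else tuple(n)
        return [("unmarked", pair[0]), ("contracted", pair[1])]


def make_design(config: SimConfig) -> pd.DataFrame:
    """Build the counterbalanced trial skeleton (no responses).

    Each participant is assigned to one of two lists (alternating).  Within
    a list, half of the items take a feminine continuation pronoun and half
    a masculine one; the two lists swap the assignment so that, pooled, each
    item appears once with each pronoun gender.  Experiment 2 splits
    participants between the two conditions (between-subjects).
    """
    items = [f"W{j + 1:03d}" for j in range(config.n_items)]
    half = config.n_items // 2
    # list A: first half masculine, second half feminine; list B swaps.
    gender_by_list = {
        "A": ["masculine"] * half + ["feminine"] * half,
        "B": ["feminine"] * half + ["masculine"] * half,
    }
    rows = []
    p_counter = 0
    for condition, n_part in config.participants_per_condition():
        for p in range(n_part):
            p_counter += 1
            pid = f"P{p_counter:03d}"
            list_id = "A" if p % 2 == 0 else "B"
            for item, gender in zip(items, gender_by_list[list_id]):
                rows.append(
                    {
                        "participant_id": pid,
                        "item_id": item,
                        "experiment": config.experiment,
                        "condition": condition,
                        "pronoun_gender": gender,
                        "list_id": list_id,
                        "trial_role": "experimental",
                        "response": "none",
                        "correct": pd.NA,
                        "rt_ms": np.nan,
                    }
                )
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["correct"] = df["correct"].astype("boolean")
    return df


def _linear_predictor(df: pd.DataFrame, b0, bg, bc, bgc) -> np.ndarray:
    g = df["pronoun_gender"].map(GENDER_CODE).to_numpy(float)
    c = df["condition"].map(CONDITION_CODE).to_numpy(float)
    return b0 + bg * g + bc * c + bgc * g * c


def simulate_trials(config: SimConfig) -> pd.DataFrame:
    """Simulate a full trial table; identical seed gives a bit-identical table.

    Random intercepts are drawn per participant and per item, independently
    for the RT and accuracy channels except for the item-level correlation
    ``intercept_correlation``.  RT is generated on the z scale, mapped to ms
    via the back-transform, floored at 50 ms (clamp count in
    ``df.attrs["n_rt_clamped"]``), and rounded to 3 decimals (the CSV
    dialect's precision).
    """
    tp = config.true_params
    design = make_design(config)
    rng = np.random.default_rng(config.seed)

    participants = design["participant_id"].unique()
    items = design["item_id"].unique()
    n_p, n_i = len(participants), len(items)

    a_p_rt = rng.normal(0.0, tp.sigma_participant_rt, n_p)
    a_p_acc = rng.normal(0.0, tp.sigma_participant_acc, n_p)
    rho = tp.intercept_correlation
    z1 = rng.standard_normal(n_i)
    z2 = rng.standard_normal(n_i)
    a_i_rt = tp.sigma_item_rt * z1
    a_i_acc = tp.sigma_item_acc * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    p_pos = pd.Series(np.arange(n_p), index=participants)
    i_pos = pd.Series(np.arange(n_i), index=items)
    pi = design["participant_id"].map(p_pos).to_numpy()
    ii = design["item_id"].map(i_pos).to_numpy()

    use_condition = config.experiment == 2
    bc_rt = tp.beta_condition_rt if use_condition else 0.0
    bgc_rt = tp.beta_interaction_rt if use_condition else 0.0
    bc_acc = tp.beta_condition_acc if use_condition else 0.0
    bgc_acc = tp.beta_interaction_acc if use_condition else 0.0

    eta_rt = (
        _linear_predictor(design, tp.beta0_rt, tp.beta_gender_rt, bc_rt, bgc_rt)
        + a_p_rt[pi]
        + a_i_rt[ii]
    )
    rt_z = eta_rt + rng.normal(0.0, tp.sigma_resid_rt, len(design))
    rt_ms = tp.rt_backtransform_mean_ms + tp.rt_backtransform_sd_ms * rt_z
    n_clamped = int((rt_ms < RT_FLOOR_MS).sum())
    if n_clamped:
        logger.info("clamped %d reaction times to the %.0f ms floor", n_clamped, RT_FLOOR_MS)
    rt_ms = np.round(np.maximum(rt_ms, RT_FLOOR_MS), 3)

    eta_acc = (
        _linear_predictor(design, tp.beta0_acc, tp.beta_gender_acc, bc_acc, bgc_acc)
        + a_p_acc[pi]
        + a_i_acc[ii]
    )
    p_correct = 0.5 + (0.5 - tp.p_miss) / (1.0 + np.exp(-eta_acc))
    yes = rng.random(len(design)) < p_correct

    out = design.copy()
    out["response"] = np.where(yes, "yes", "no")
    out["correct"] = pd.array(yes, dtype="boolean")
    out["rt_ms"] = rt_ms

    if config.include_fillers:
        out = pd.concat([out, _make_fillers(config, rng)], ignore_index=True)

    out.attrs["n_rt_clamped"] = n_clamped
    out.attrs["seed"] = config.seed
    return out


def _make_fillers(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Inert filler rows (good and bad continuations), never modelled.

    Responses are deterministically correct; reaction times are drawn from
    the back-transform distribution with unit z variance.
    """
    tp = config.true_params
    rows = []
    p_counter = 0
    genders = ["feminine", "masculine"]
    for condition, n_part in config.participants_per_condition():
        for p in range(n_part):
            p_counter += 1
            pid = f"P{p_counter:03d}"
            list_id = "A" if p % 2 == 0 else "B"
            for role, resp in (("filler_good", "yes"), ("filler_bad", "no")):
                for j in range(config.n_items):
                    rows.append(
                        {
                            "participant_id": pid,
                            "item_id": f"{'FG' if role == 'filler_good' else 'FB'}{j + 1:03d}",
                            "experiment": config.experiment,
                            "condition": condition,
                            "pronoun_gender": genders[j % 2],
                            "list_id": list_id,
                            "trial_role": role,
                            "response": resp,
                            "correct": True,
                            "rt_ms": np.nan,
                        }
                    )
    df = pd.DataFrame(rows, columns=COLUMNS)
    z = rng.standard_normal(len(df))
    df["rt_ms"] = np.round(
        np.maximum(tp.rt_backtransform_mean_ms + tp.rt_backtransform_sd_ms * z, RT_FLOOR_MS),
        3,
    )
    df["correct"] = df["correct"].astype("boolean")
    return df


def simulate_pretest_ratings(
    n_raters: int,
    word_profiles: Sequence[tuple[str, float, float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-rater norming data for :mod:`fairsent.stimulus_pretest`.

    ``word_profiles`` holds ``(word, true_mean_masc_pct, true_sd, miss_prob)``
    tuples.  Masculine-percentage ratings are drawn from a Gaussian
    truncated to [0, 100]; the emitted table is on the feminine orientation
    (``feminine_pct = 100 - masculine``), matching the ingestion dialect.
    Missingness is Bernoulli per rater x word.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for word, mean, sd, miss in word_profiles:
        if sd < 0:
            raise ValueError(f"true_sd must be >= 0 (word {word!r})")
        if not 0 <= miss <= 1:
            raise ValueError(f"miss_prob must lie in [0, 1] (word {word!r})")
        if sd == 0:
            masc = np.full(n_raters, float(mean))
        else:
            a, b = (0 - mean) / sd, (100 - mean) / sd
            masc = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n_raters, random_state=rng)
        missing = rng.random(n_raters) < miss
        fem = 100.0 - masc
        for r in range(n_raters):
            rows.append(
                {
                    "rater_id": f"R{r + 1:03d}",
                    "word": word,
                    "feminine_pct": np.nan if missing[r] else fem[r],
                }
            )
    return pd.DataFrame(rows, columns=["rater_id", "word", "feminine_pct"])
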