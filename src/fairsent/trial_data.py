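"""Trial-level data model for sentence-evaluation experiments.

A *trial table* is a tidy :class:`pandas.DataFrame` with one row per
(participant, item) presentation of a context sentence followed by a
pronoun-initial continuation sentence.  Columns:

``participant_id``
    Opaque participant label.
``item_id``
    Opaque item (word) label.
``experiment``
    ``1`` (within-subjects, gender-unmarked forms only) or ``2``
    (between-subjects comparison of gender-unmarked vs. contracted double
    forms).
``condition``
    ``"unmarked"`` or ``"contracted"``.  Experiment 1 is always
    ``"unmarked"``.
``pronoun_gender``
    Grammatical gender of the continuation pronoun: ``"feminine"`` (il/elle
    coding 0) or ``"masculine"`` (coding 1).
``list_id``
    Counterbalancing list, ``"A"`` or ``"B"``.
``trial_role``
    ``"experimental"`` (good continuation, analysed), ``"filler_good"`` or
    ``"filler_bad"`` (never analysed).
``response``
    ``"yes"``, ``"no"`` or ``"none"`` (no response recorded).
``correct``
    Boolean; missing when ``response == "none"``.  For experimental trials
    (good continuations) correctness is equivalent to ``response == "yes"``.
``rt_ms``
    Reaction time from continuation onset, milliseconds (> 0 whenever a
    response was given).
``rt_z``
    Standardized reaction time, filled by :func:`standardize_rt`.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the on-disk CSV dialect (``rt_z`` is appended when present).
COLUMNS = [
    "participant_id",
    "item_id",
    "experiment",
    "condition",
    "pronoun_gender",
    "list_id",
    "trial_role",
    "response",
    "correct",
    "rt_ms",
]

CONDITIONS = ("unmarked", "contracted")
GENDERS = ("feminine", "masculine")
ROLES = ("experimental", "filler_good", "filler_bad")
RESPONSES = ("yes", "no", "none")

#: 0/1 codings used throughout the models.
GENDER_CODE = {"feminine": 0, "masculine": 1}
CONDITION_CODE = {"unmarked": 0, "contracted": 1}

SCHEMA_VERSION = "trials-v1"


class SchemaError(ValueError):
    """Header or dtype of a trials file does not match the dialect."""


class TrialValidationError(ValueError):
    """One or more rows violate a trial-table invariant."""


def _fail_rows(mask: pd.Series, message: str) -> None:
    if mask.any():
        rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:50]]
        raise TrialValidationError(f"{message}; offending rows (0-based): {rows}")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table in place and return it.

    Raises :class:`SchemaError` on missing columns and
    :class:`TrialValidationError` (with row numbers) on invariant
    violations.
    """
    missing = [c for c in COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    if len(trials) == 0:
        logger.warning("trial table is empty")
        return trials

    _fail_rows(~trials["experiment"].isin([1, 2]), "experiment must be 1 or 2")
    _fail_rows(~trials["condition"].isin(CONDITIONS), "unknown condition label")
    _fail_rows(~trials["pronoun_gender"].isin(GENDERS), "unknown pronoun_gender label")
    _fail_rows(~trials["trial_role"].isin(ROLES), "unknown trial_role label")
    _fail_rows(~trials["response"].isin(RESPONSES), "unknown response label")

    responded = trials["response"] != "none"
    rt = pd.to_numeric(trials["rt_ms"], errors="coerce")
    _fail_rows(responded & ~(rt > 0), "rt_ms must be > 0 on responded trials")

    # Good continuations: correct iff the participant answered yes.
    exp_rows = (trials["trial_role"] == "experimental") & responded
    corr = trials.loc[exp_rows, "correct"].astype("boolean")
    yes = trials.loc[exp_rows, "response"] == "yes"
    bad = (corr != yes).fillna(True)
    _fail_rows(
        bad.reindex(trials.index, fill_value=False),
        "experimental trials must satisfy correct == (response == 'yes')",
    )

    exp1 = trials["experiment"] == 1
    _fail_rows(
        exp1 & (trials["condition"] != "unmarked"),
        "experiment 1 has only the unmarked condition",
    )
    return trials


def load_trials(path, schema_version: str = SCHEMA_VERSION) -> pd.DataFrame:
    """Read and validate a trials CSV (see module docstring for the dialect)."""
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}")
    df = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "item_id": str,
            "condition": str,
            "pronoun_gender": str,
            "list_id": str,
            "trial_role": str,
            "response": str,
        },
        keep_default_na=True,
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df["experiment"] = pd.to_numeric(df["experiment"], errors="coerce").astype("Int64")
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["correct"] = df["correct"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    df["correct"] = df["correct"].astype("boolean")
    if "rt_z" in df.columns:
        df["rt_z"] = pd.to_numeric(df["rt_z"], errors="coerce")
    if len(df):
        df["experiment"] = df["experiment"].astype(int)
    else:
        df["experiment"] = df["experiment"].astype("Int64")
    return validate_trials(df)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical CSV dialect (UTF-8, empty string
    for missing values, booleans as ``true``/``false``)."""
    cols = COLUMNS + (["rt_z"] if "rt_z" in trials.columns else [])
    out = trials[cols].copy()
    out["correct"] = out["correct"].map({True: "true", False: "false"})
    out.to_csv(path, index=False, encoding="utf-8")


def filter_positive_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep only experimental trials answered *yes* (the reaction-time
    analysis set).  Fillers are dropped regardless of their response."""
    keep = (trials["trial_role"] == "experimental") & (trials["response"] == "yes")
    removed = int((~keep).sum())
    logger.info("filter_positive_responses: removed %d of %d rows", removed, len(trials))
    return trials.loc[keep].reset_index(drop=True)


def standardize_rt(trials: pd.DataFrame, scope: str = "pooled_per_experiment") -> pd.DataFrame:
    """Fill the ``rt_z`` column with z-scored reaction times.

    ``scope="pooled_per_experiment"`` (default) pools all retained trials
    within each experiment; ``scope="per_participant"`` standardizes within
    participant (exploratory).  The input must already be filtered to
    positive responses on experimental trials.  Idempotent: ``rt_z`` is
    always recomputed from ``rt_ms``.
    """
    if scope not in ("pooled_per_experiment", "per_participant"):
        raise ValueError(f"unknown scope {scope!r}")
    if len(trials) and not (
        (trials["trial_role"] == "experimental").all()
        and (trials["response"] == "yes").all()
    ):
        raise ValueError(
            "standardize_rt expects a table filtered to positive experimental responses"
        )
    out = trials.copy()
    keys = ["experiment"] if scope == "pooled_per_experiment" else ["experiment", "participant_id"]

    def _z(group: pd.Series) -> pd.Series:
        if len(group) < 2:
            raise ValueError("standardize_rt requires at least 2 trials per scope group")
        mu = group.mean()
        sd = group.std(ddof=1)
        if not sd > 0:
            raise ValueError("standardize_rt: zero variance within scope group")
        return (group - mu) / sd

    out["rt_z"] = out.groupby(keys, group_keys=False)["rt_ms"].apply(_z)
    return out


def summarize_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics per (experiment, condition, pronoun_gender) cell.

    Reaction-time statistics use positive responses only; percent correct
    uses all experimental trials with a recorded response.  Empty cells are
    omitted with a warning.
    """
    exp = trials[trials["trial_role"] == "experimental"]
    rows = []
    for key, cell in exp.groupby(["experiment", "condition", "pronoun_gender"], observed=True):
        if len(cell) == 0:  # pragma: no cover - groupby never yields empty groups
            logger.warning("empty cell %s omitted", key)
            continue
        yes = cell[cell["response"] == "yes"]
        answered = cell[cell["response"] != "none"]
        pct = 100.0 * answered["correct"].astype(float).mean() if len(answered) else np.nan
        rows.append(
            {
                "experiment": key[0],
                "condition": key[1],
                "pronoun_gender": key[2],
                "mean_rt_ms": yes["rt_ms"].mean() if len(yes) else np.nan,
                "sd_rt_ms": yes["rt_ms"].std(ddof=1) if len(yes) > 1 else np.nan,
                "pct_correct": pct,
                "n_trials": len(cell),
                "n_participants": cell["participant_id"].nunique(),
            }
        )
    if not rows:
        logger.warning("summarize_cells: no experimental trials")
    return pd.DataFrame(
        rows,
        columns=[
            "experiment",
            "condition",
            "pronoun_gender",
            "mean_rt_ms",
            "sd_rt_ms",
            "pct_correct",
            "n_trials",
            "n_participants",
        ],
    )
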