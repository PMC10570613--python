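"""Stimulus norming: aggregate stereotypicality ratings and select items.

Raters judge, for each role noun, whether it is more readily represented by
men or women, on a continuous 0-100% scale.  Ratings are ingested on the
*feminine* orientation (``feminine_pct``; a 60% feminine rating means 40%
masculine) and aggregated into per-word norms on the masculine orientation.
Items for the sentence-evaluation experiment are then chosen to be as
gender-unstereotyped as possible: the ``k_closest`` words nearest 50%
masculine, excluding words whose ratings disperse too much across raters or
that too many raters declined to rate (a proxy for not knowing the word).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

logger = logging.getLogger(__name__)

RATING_COLUMNS = ["rater_id", "word", "feminine_pct"]
NORM_COLUMNS = ["word", "mean_masc_pct", "sd_masc_pct", "n_ratings", "missing_rate"]

#: Exclusion rules recorded in the selection log.
RULE_NOT_CLOSEST = "not_among_k_closest"
RULE_HIGH_SD = "sd_above_max"
RULE_HIGH_MISSING = "missing_above_max"


class SelectionParams(BaseModel):
    """Item-selection thresholds.

    ``sd_max`` has no single canonical value; the default 19.0 separates the
    dispersion range observed for retained items (up to ~17.9) from clearly
    unstable ones (~19.8 and above).  ``missing_max`` operationalizes
    "more than 10% of raters did not know the word".
    """

    k_closest: int = Field(default=25, ge=1)
    sd_max: float = Field(default=19.0, gt=0)
    missing_max: float = Field(default=0.10, gt=0)
    target_pct: float = 50.0


def aggregate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-rater feminine-percentage ratings into word norms.

    Returns a frame with ``word, mean_masc_pct, sd_masc_pct, n_ratings,
    missing_rate``.  A missing ``feminine_pct`` counts toward
    ``missing_rate`` for that word; words with zero usable ratings are
    dropped with a warning.  Single-rating words get ``sd_masc_pct = 0``.
    """
    missing_cols = [c for c in RATING_COLUMNS if c not in ratings.columns]
    if missing_cols:
        raise ValueError(f"ratings table missing columns: {missing_cols}")
    fem = pd.to_numeric(ratings["feminine_pct"], errors="coerce")
    present = fem.notna()
    if ((fem < 0) | (fem > 100)).any():
        raise ValueError("feminine_pct outside [0, 100]")

    masc = 100.0 - fem
    rows = []
    for word, idx in ratings.groupby("word").groups.items():
        vals = masc.loc[idx].dropna()
        total = len(idx)
        if len(vals) == 0:
            logger.warning("word %r has no usable ratings; excluded from norms", word)
            continue
        rows.append(
            {
                "word": word,
                "mean_masc_pct": float(vals.mean()),
                "sd_masc_pct": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "n_ratings": int(len(vals)),
                "missing_rate": float((total - len(vals)) / total),
            }
        )
    return pd.DataFrame(rows, columns=NORM_COLUMNS)


def select_items(
    norms: pd.DataFrame, params: SelectionParams | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three-step item-selection filter.

    1. rank words by ``|mean_masc_pct - target_pct|`` ascending (ties broken
       by smaller ``sd_masc_pct``, then lexicographically) and keep the
       ``k_closest``;
    2. drop kept words with ``sd_masc_pct > sd_max``;
    3. drop kept words with ``missing_rate > missing_max``.

    Returns ``(selected_words, exclusion_log)`` where the word list keeps
    the closeness order and the log has one row per excluded word with the
    single rule that removed it.  Deterministic in the *set* of input norms:
    permuting rows never changes the result.
    """
    params = params or SelectionParams()
    if len(norms) == 0:
        raise ValueError("no norms supplied")

    ranked = norms.copy()
    ranked["_dist"] = (ranked["mean_masc_pct"] - params.target_pct).abs()
    ranked = ranked.sort_values(
        ["_dist", "sd_masc_pct", "word"], kind="mergesort"
    ).reset_index(drop=True)

    k = params.k_closest
    if k > len(ranked):
        logger.warning(
            "k_closest=%d exceeds %d available norms; keeping all", k, len(ranked)
        )
        k = len(ranked)

    exclusions: list[dict] = []
    for _, row in ranked.iloc[k:].iterrows():
        exclusions.append({"word": row["word"], "rule": RULE_NOT_CLOSEST})

    selected: list[str] = []
    for _, row in ranked.iloc[:k].iterrows():
        if row["sd_masc_pct"] > params.sd_max:
            exclusions.append({"word": row["word"], "rule": RULE_HIGH_SD})
        elif row["missing_rate"] > params.missing_max:
            exclusions.append({"word": row["word"], "rule": RULE_HIGH_MISSING})
        else:
            selected.append(row["word"])

    log = pd.DataFrame(exclusions, columns=["word", "rule"])
    for _, row in log.iterrows():
        logger.info("excluded %r (%s)", row["word"], row["rule"])
    return selected, log
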