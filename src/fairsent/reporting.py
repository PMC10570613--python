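"""Publication-style figures and report bundles.

Figures mirror the standard presentation of sentence-evaluation results:
participant-level boxplots of mean reaction time and percent correct by
pronoun gender (and condition), and posterior densities for the fixed
effects with the 95% credible region shaded and the 99% interval marked.
All figures are written as SVG with deterministic ids so that re-running a
report from the same artifacts is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .hierarchical_models import PosteriorSamples
from .posterior_analysis import summarize_posterior

plt.rcParams["svg.hashsalt"] = "fairsent"

_SVG_META = {"Date": None}


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping (provenance key)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def participant_boxplots(trials: pd.DataFrame, path: Path) -> None:
    """Boxplots of per-participant mean RT (positive responses) and percent
    correct, split by pronoun gender within each condition."""
    exp = trials[trials["trial_role"] == "experimental"]
    yes = exp[exp["response"] == "yes"]
    rt = (
        yes.groupby(["condition", "pronoun_gender", "participant_id"], observed=True)["rt_ms"]
        .mean()
        .reset_index()
    )
    answered = exp[exp["response"] != "none"].copy()
    answered["correct_f"] = answered["correct"].astype(float)
    acc = (
        answered.groupby(["condition", "pronoun_gender", "participant_id"], observed=True)[
            "correct_f"
        ]
        .mean()
        .mul(100)
        .reset_index()
    )

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, data, col, label in (
        (axes[0], rt, "rt_ms", "mean reaction time (ms)"),
        (axes[1], acc, "correct_f", "percent correct"),
    ):
        groups, labels = [], []
        for (cond, gender), block in data.groupby(["condition", "pronoun_gender"], observed=True):
            groups.append(block[col].to_numpy())
            labels.append(f"{cond}\n{gender}")
        ax.boxplot(groups, tick_labels=labels)
        ax.set_ylabel(label)
        ax.tick_params(axis="x", labelsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata=_SVG_META)
    plt.close(fig)


def posterior_density_figure(
    samples: PosteriorSamples, parameters: list[str], path: Path
) -> None:
    """Histogram-based posterior densities with the 95% credible region
    shaded and the 99% interval delimited by contour lines."""
    params = [p for p in parameters if p in samples.draws]
    fig, axes = plt.subplots(1, len(params), figsize=(3.2 * len(params), 3), squeeze=False)
    for ax, name in zip(axes[0], params):
        x = samples.flat(name)
        lo95, hi95 = np.quantile(x, [0.025, 0.975])
        lo99, hi99 = np.quantile(x, [0.005, 0.995])
        counts, edges = np.histogram(x, bins=60, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.plot(centers, counts, color="k", lw=1)
        inside = (centers >= lo95) & (centers <= hi95)
        ax.fill_between(centers[inside], counts[inside], color="#6699cc", alpha=0.6)
        for b in (lo99, hi99):
            ax.axvline(b, color="k", lw=0.8)
        ax.set_title(name, fontsize=9)
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata=_SVG_META)
    plt.close(fig)


def write_report_bundle(
    out_dir: Path,
    trials: pd.DataFrame,
    cell_summary: pd.DataFrame,
    fits: dict[str, tuple[PosteriorSamples, object]],
    provenance: dict,
) -> dict:
    """Assemble tables, figures and a provenance block into ``out_dir``.

    ``fits`` maps a model label (e.g. ``"rt"``) to ``(samples,
    diagnostics)``.  Returns a manifest of written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    cell_path = out_dir / "cell_summary.csv"
    cell_summary.to_csv(cell_path, index=False)
    manifest["cell_summary"] = cell_path.name

    box_path = out_dir / "participant_boxplots.svg"
    participant_boxplots(trials, box_path)
    manifest["boxplots"] = box_path.name

    for label, (samples, diag) in fits.items():
        summ = summarize_posterior(samples)
        sp = out_dir / f"summary_{label}.csv"
        summ.to_csv(sp, index=False)
        manifest[f"summary_{label}"] = sp.name
        fixed = [
            p
            for p in ("beta0", "beta_gender", "beta_condition", "beta_gender_condition", "p_miss")
            if p in samples.draws
        ]
        fp = out_dir / f"posterior_{label}.svg"
        posterior_density_figure(samples, fixed, fp)
        manifest[f"posterior_{label}"] = fp.name
        if diag is not None:
            dp = out_dir / f"diagnostics_{label}.json"
            dp.write_text(json.dumps(diag.to_dict(), indent=2, sort_keys=True))
            manifest[f"diagnostics_{label}"] = dp.name

    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True, default=str))
    manifest["provenance"] = prov_path.name

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
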