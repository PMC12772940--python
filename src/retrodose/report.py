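"""Machine-readable reports, CSV tables, and posterior-curve figures."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .model import PopPKModelSpec, spec_hash
from .posterior import AdherenceAssessment, AnalysisResult

__all__ = ["curves_frame", "analysis_report", "write_report", "plot_curves"]


def curves_frame(result: AnalysisResult) -> pd.DataFrame:
    """Posterior curves as a tidy table: one row per grid concentration."""
    data = {"concentration_mg_L": result.curves.grid}
    for i, bits in enumerate(result.curves.bits):
        data[f"posterior_w{bits}"] = result.curves.posteriors[i]
    data["marginal_density"] = result.curves.marginal
    return pd.DataFrame(data)


def analysis_report(
    spec: PopPKModelSpec,
    result: AnalysisResult,
    assessment: AdherenceAssessment | None = None,
    extra: dict | None = None,
) -> dict:
    """JSON-serializable report echoing inputs and all derived outputs."""
    report = {
        "version": __version__,
        "spec_hash": spec_hash(spec),
        "drug": spec.drug_name,
        "seed": result.settings.seed,
        "settings": asdict(result.settings),
        "n": result.sset.n,
        "priors": dict(zip(result.sset.bits, result.sset.priors())),
        "thresholds": [
            {"between": list(pair), "concentration_mg_L": c}
            for pair, c in result.thresholds.crossings
        ],
        "partition": [
            {"scenario": b, "from_mg_L": lo, "to_mg_L": hi}
            for b, lo, hi in result.thresholds.partition
        ],
        "retrodiction": {
            "label": result.retrodiction.label,
            "cutoff": result.retrodiction.cutoff,
            "max_posterior": result.retrodiction.max_posterior,
        },
    }
    if assessment is not None:
        report["assessment"] = {
            "observed_mg_L": assessment.observed_c,
            "posterior": assessment.posterior,
            "most_likely": assessment.most_likely,
            "ties": assessment.ties,
            "undefined": assessment.undefined,
            "settings_hash": assessment.settings_hash,
        }
    if extra:
        report.update(extra)
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def plot_curves(result: AnalysisResult, path: str | Path, title: str = "") -> None:
    """One posterior curve per scenario with threshold verticals."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for i, bits in enumerate(result.curves.bits):
        ax.plot(result.curves.grid, result.curves.posteriors[i], label=f"$\\omega_{{{bits}}}$")
    for _, c in result.thresholds.crossings:
        ax.axvline(c, color="grey", linestyle=":", linewidth=0.8)
    ax.axhline(result.retrodiction.cutoff, color="black", linestyle="--", linewidth=0.6)
    ax.set_xlabel("concentration (mg/L)")
    ax.set_ylabel("posterior probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8, ncol=2)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
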