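"""End-to-end screen execution and reporting."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import validate_inputs, write_manifest, write_plate_features
from .screen import PARAMS, ScreenResult, score_screen
from .synth import LibrarySpec, PlateFeatureSet, simulate_screen_features

log = logging.getLogger("neuromat")

__all__ = ["run_screen", "report"]


def run_screen(cfg: PipelineConfig,
               features: Optional[pd.DataFrame] = None,
               out_dir: Optional[str | Path] = None,
               lib: Optional[LibrarySpec] = None):
    """Run pair → b-score → z-score → filter → PCA → hits and write results.

    With no ``features`` table, a synthetic screen is simulated from
    ``cfg.seed``.  Writes the z-matrix, PCA scores, hit lists and a manifest
    to ``out_dir`` (defaults to ``cfg.out_dir``) and returns the
    :class:`~neuromat.screen.ScreenResult`.
    """
    truth = None
    if features is None:
        lib = lib or LibrarySpec(seed=cfg.seed)
        plates = simulate_screen_features(lib)
        features, truth = plates.features, plates.truth
    violations = validate_inputs(plate_features=features)
    if violations:
        raise ValueError("input validation failed:\n  " +
                         "\n  ".join(violations))
    log.info("scoring screen: %d wells", len(features))
    result = score_screen(features, cfg.screen)

    out_dir = Path(out_dir if out_dir is not None else cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    files.append(write_plate_features(features, out_dir / "well_features.csv"))

    zm = result.zmatrix.copy()
    zm.insert(0, "compound_id", zm.index)
    path = out_dir / "zscores.csv"
    zm.to_csv(path, index=False)
    files.append(path)

    pcs = result.pc_scores.copy()
    pcs.insert(0, "compound_id", pcs.index)
    pcs["cluster"] = result.cluster_labels
    path = out_dir / "pca_scores.csv"
    pcs.to_csv(path, index=False)
    files.append(path)

    summary = {
        "hits_pca": list(result.hits_pca),
        "hits_single_param": list(result.hits_single_param),
        "excluded_toxic": list(result.excluded_toxic),
        "loadings": {c: result.loadings[c].round(10).tolist()
                     for c in result.loadings.columns},
        "parameters": list(PARAMS),
        "explained_variance": np.round(result.explained_variance, 10).tolist(),
        "thresholds": {"viability_z": cfg.screen.viability_z,
                       "pc1": cfg.screen.pc1_threshold,
                       "top_k": cfg.screen.top_k},
    }
    path = out_dir / "screen_result.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    files.append(path)

    plot_pca(result, out_dir / "pca_scatter.png")

    manifest = write_manifest(cfg, out_dir, files)
    log.info("screen complete: %d PCA hits, %d single-parameter hits, "
             "%d toxic excluded", len(result.hits_pca),
             len(result.hits_single_param), len(result.excluded_toxic))
    return result, truth, manifest


def plot_pca(result: ScreenResult, path: str | Path) -> None:
    """PC1/PC2 scatter colored by cluster, with the hit threshold marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"maturation-enhancing": "tab:orange",
              "maturation-inhibiting": "tab:blue",
              "non-neuronal-proliferation": "tab:gray",
              "other": "lightgray"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, color in colors.items():
        sel = result.cluster_labels == label
        if sel.any():
            ax.scatter(result.pc_scores.loc[sel, "PC1"],
                       result.pc_scores.loc[sel, "PC2"],
                       s=6, c=color, label=label, linewidths=0)
    ax.axvline(4.0, ls="--", lw=0.8, c="k")
    ax.set_xlabel(f"PC1 ({result.explained_variance[0]:.0%} var)")
    ax.set_ylabel(f"PC2 ({result.explained_variance[1]:.0%} var)")
    ax.legend(fontsize=6, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def report(result: ScreenResult) -> str:
    """Human-readable summary of a screen result."""
    lines = ["Screen summary", "=" * 14]
    n = len(result.zmatrix)
    lines.append(f"compounds analyzed (post-viability): {n}")
    lines.append(f"toxic compounds excluded (z < -2):   "
                 f"{len(result.excluded_toxic)}")
    lines.append(f"PCA hits (PC1 > threshold):          "
                 f"{len(result.hits_pca)}")
    lines.append(f"single-parameter hits added:         "
                 f"{len(result.hits_single_param)}")
    if n:
        lines.append("")
        lines.append("six-parameter z-score medians:")
        for p in PARAMS:
            lines.append(f"  {p:<20s} {result.zmatrix[p].median():8.3f}")
        lines.append("")
        ev = ", ".join(f"{v:.3f}" for v in result.explained_variance)
        lines.append(f"explained variance fractions: {ev}")
        counts = result.cluster_labels.value_counts()
        lines.append("clusters: " + ", ".join(
            f"{k}={v}" for k, v in counts.items()))
    return "\n".join(lines)
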