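"""Minimal diagnostic plots: genome-scan Manhattan panels and pairwise
ortholog score scatters with extreme-tail quantile guides."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diversity import quantile_threshold


def manhattan(
    values: pd.DataFrame,
    value_col: str,
    out_path: str | Path,
    quantile: float | None = 0.999,
    title: str = "",
) -> None:
    """Position-vs-statistic scatter, chromosomes laid end to end."""
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    pos_col = "pos0" if "pos0" in values.columns else "start"
    for i, (chrom, grp) in enumerate(values.groupby("chrom", sort=True)):
        x = grp[pos_col].to_numpy(float) + offset
        ax.scatter(x, grp[value_col], s=2, color="C0" if i % 2 == 0 else "C1")
        offset = x.max() + 1 if len(x) else offset
    finite = values[value_col].to_numpy(float)
    finite = finite[np.isfinite(finite)]
    if quantile is not None and finite.size:
        ax.axhline(quantile_threshold(finite, quantile), color="red", ls="--", lw=1)
    ax.set_xlabel("genome position (bp, concatenated)")
    ax.set_ylabel(value_col)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def pairwise_scores(
    pair_table: pd.DataFrame,
    out_path: str | Path,
    upper_q: float = 0.95,
    lower_q: float = 0.05,
    label_a: str = "species A",
    label_b: str = "species B",
) -> None:
    """Ortholog-matched score scatter with shared-extreme quantile guides."""
    a = pair_table["score_a"].to_numpy(float)
    b = pair_table["score_b"].to_numpy(float)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(a, b, s=5, alpha=0.4, color="grey")
    for q in (upper_q, lower_q):
        ax.axvline(quantile_threshold(a, q), color="red", ls="--", lw=1)
        ax.axhline(quantile_threshold(b, q), color="red", ls="--", lw=1)
    ax.set_xlabel(label_a)
    ax.set_ylabel(label_b)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
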