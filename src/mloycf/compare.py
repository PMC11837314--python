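"""Method-agreement analyses between the LRR-route and BAF-route CF estimates.

Two per-sample cell-fraction estimates exist for a male with mLOY: one from
the median LRR over the male-specific Y region (``cf_mlrry``) and one from
the BAF deviation of PAR1 heterozygotes (``cf_baf``).  This module pairs
them, measures their squared Pearson correlation, and summarizes the pairs
in equal-size bins of sorted mLRR_Y.  Binning medians averages out the
independent per-sample noise of the two routes, so the binned-median R²
exceeds the pairwise R² whenever both axes carry noise — the reason cohort
studies report both.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd

from .calling import SampleCall

EXCLUDE_NO_MLRRY = "no_mlrry"
EXCLUDE_POSITIVE_MLRRY = "positive_mlrry"
EXCLUDE_NO_BAF = "no_baf_call"

PAIR_COLUMNS = ("sample_id", "mlrr_y", "cf_mlrry", "cf_baf")


def pair_samples(calls: Iterable[SampleCall]) -> tuple[pd.DataFrame, Counter]:
    """Retain samples with both CF estimates and strictly negative mLRR_Y.

    Returns ``(pairs, exclusions)``: a DataFrame with columns
    ``sample_id, mlrr_y, cf_mlrry, cf_baf`` and a Counter of exclusion
    reasons (``no_mlrry``, ``positive_mlrry`` for mLRR_Y >= 0,
    ``no_baf_call``), so nothing disappears unaccounted.
    """
    rows, exclusions = [], Counter()
    for call in calls:
        if call.mlrr_y is None:
            exclusions[EXCLUDE_NO_MLRRY] += 1
        elif call.mlrr_y >= 0:
            exclusions[EXCLUDE_POSITIVE_MLRRY] += 1
        elif call.cf_baf is None:
            exclusions[EXCLUDE_NO_BAF] += 1
        else:
            rows.append((call.sample_id, call.mlrr_y, call.cf_mlrry, call.cf_baf))
    pairs = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    return pairs, exclusions


def r_squared(x, y=None) -> float:
    """Squared Pearson correlation of the two CF estimates.

    Accepts either a pairs DataFrame (uses cf_mlrry vs cf_baf) or two
    equal-length vectors.  Requires >= 3 pairs and nonzero variance on both
    axes.
    """
    if y is None:
        x, y = x["cf_mlrry"].to_numpy(float), x["cf_baf"].to_numpy(float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one axis; R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _sorted_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    # stable sort; ties on mlrr_y broken deterministically by sample_id
    return pairs.sort_values(["mlrr_y", "sample_id"], kind="mergesort").reset_index(drop=True)


def bin_summaries(pairs: pd.DataFrame, n_bins: int) -> tuple[pd.DataFrame, float]:
    """Split sorted mLRR_Y pairs into equal-size bins and summarize each.

    Bin sizes differ by at most 1; the remainder is distributed one sample
    per bin starting from the first (lowest-mLRR_Y) bin.  Returns the
    per-bin table (min/max/median/mean of each CF estimate) and the R² of
    (median cf_mlrry, median cf_baf) across bins.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > len(pairs):
        raise ValueError(f"n_bins={n_bins} exceeds number of pairs ({len(pairs)})")
    ordered = _sorted_pairs(pairs)
    chunks = np.array_split(np.arange(len(ordered)), n_bins)
    rows = []
    for b, idx in enumerate(chunks):
        sub = ordered.iloc[idx]
        row = {"bin_index": b, "n": len(sub)}
        for col in ("cf_mlrry", "cf_baf"):
            v = sub[col].to_numpy(float)
            row.update(
                {
                    f"{col}_min": v.min(),
                    f"{col}_max": v.max(),
                    f"{col}_median": float(np.median(v)),
                    f"{col}_mean": v.mean(),
                }
            )
        rows.append(row)
    bins = pd.DataFrame(rows)
    if n_bins >= 3:
        r2 = r_squared(bins["cf_mlrry_median"].to_numpy(), bins["cf_baf_median"].to_numpy())
    else:
        r2 = float("nan")  # two points always correlate perfectly; not meaningful
    return bins, r2


def write_pairs(pairs: pd.DataFrame, path) -> None:
    out = pairs.copy()
    for col in ("mlrr_y", "cf_mlrry", "cf_baf"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def write_bin_summaries(bins: pd.DataFrame, path) -> None:
    out = bins.copy()
    for col in out.columns:
        if col not in ("bin_index", "n"):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def plot_pairs(pairs: pd.DataFrame, path, bins: pd.DataFrame | None = None) -> None:
    """Scatter of cf_mlrry vs cf_baf (optionally overlaying bin medians)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs["cf_mlrry"], pairs["cf_baf"], s=8, alpha=0.4, label="samples")
    if bins is not None:
        ax.scatter(
            bins["cf_mlrry_median"], bins["cf_baf_median"], s=20, color="crimson",
            label="bin medians",
        )
    ax.plot([0, 1], [0, 1], lw=0.8, color="grey")
    ax.set_xlabel(r"CF$_{\mathrm{mLRR\_Y}}$")
    ax.set_ylabel(r"CF$_{\mathrm{BAF}}$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
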