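"""Closed-form conversions among LRR, copy number, cell fraction and BAF deviation.

The intensity model: a genotyping-array probe's Log2 R ratio (LRR) measures
observed copy number relative to the expected diploid/haploid state,

    CN_observed = CN_expected * 2**(LRR / scale),

where ``scale`` is the empirical magnitude of the LRR shift produced by a
one-copy deletion from the diploid state (about 0.45 on Illumina arrays;
a theoretical value of 1 is never observed in real data).

For a male sample the Y chromosome is expected at one copy, so the median
LRR over the male-specific Y region (mLRR_Y) converts directly to the
fraction of cells that lost the Y:

    CF = 1 - 2**(mLRR_Y / scale).

The complementary estimator uses the B-allele-frequency deviation (Bdev) of
heterozygous sites in the pseudoautosomal region PAR1, where Y loss unbalances
the two alleles:

    CF = 4*Bdev / (1 + 2*Bdev),   Bdev = CF / (4 - 2*CF).

All functions accept scalars or numpy arrays and return the matching shape;
internal math is full precision, display rounding is banker's (half-even).
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd

ArrayLike = Union[float, np.ndarray]

#: Empirical |LRR| of a one-copy deletion from the diploid state.
DEFAULT_SCALE: float = 0.45


def _as_array(x: ArrayLike, name: str, require_finite: bool = True) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if require_finite and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return arr


def _scalar_or_array(arr: np.ndarray) -> ArrayLike:
    return float(arr) if arr.ndim == 0 else arr


def _check_scale(scale: float) -> float:
    scale = float(scale)
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"scale factor must be a positive finite real, got {scale!r}")
    return scale


def cn_from_lrr(lrr: ArrayLike, expected_cn: int = 1, scale: float = DEFAULT_SCALE) -> ArrayLike:
    """Observed copy number implied by an LRR value.

    Parameters
    ----------
    lrr
        Log2 R ratio (finite real, scalar or array).
    expected_cn
        Copy number of the normal state: 1 for the male-specific Y region,
        2 for autosomes and PAR1.
    scale
        One-copy-deletion LRR magnitude used to rescale (default 0.45).
    """
    scale = _check_scale(scale)
    if expected_cn not in (1, 2):
        raise ValueError(f"expected_cn must be 1 or 2, got {expected_cn!r}")
    arr = _as_array(lrr, "lrr")
    return _scalar_or_array(expected_cn * np.exp2(arr / scale))


def cf_from_mlrry(mlrr_y: ArrayLike, scale: float = DEFAULT_SCALE) -> ArrayLike:
    """Cell fraction with Y loss implied by a median LRR over the MSY.

    Returns the raw value ``1 - 2**(mLRR_Y/scale)``, which is negative when
    mLRR_Y > 0; callers that need a proportion should use
    :func:`cf_from_mlrry_clamped`.  The sign is preserved deliberately so the
    calling layer can identify (and exclude) samples whose Y intensity sits
    above the normal one-copy level.
    """
    scale = _check_scale(scale)
    arr = _as_array(mlrr_y, "mlrr_y")
    return _scalar_or_array(1.0 - np.exp2(arr / scale))


def cf_from_mlrry_clamped(mlrr_y: ArrayLike, scale: float = DEFAULT_SCALE) -> ArrayLike:
    """Cell fraction from mLRR_Y truncated to the proportion range [0, 1]."""
    raw = np.asarray(cf_from_mlrry(mlrr_y, scale))
    return _scalar_or_array(np.clip(raw, 0.0, 1.0))


def mlrry_from_cf(cf: ArrayLike, scale: float = DEFAULT_SCALE) -> ArrayLike:
    """mLRR_Y expected for a given cell fraction: ``scale * log2(1 - CF)``.

    The algebraic inverse of :func:`cf_from_mlrry`; CF = 1 maps to -inf and
    is rejected.
    """
    scale = _check_scale(scale)
    arr = _as_array(cf, "cf")
    if np.any(arr < 0) or np.any(arr >= 1):
        raise ValueError(f"cf must lie in [0, 1), got {cf!r}")
    return _scalar_or_array(scale * np.log2(1.0 - arr))


def cf_from_bdev(bdev: ArrayLike) -> ArrayLike:
    """Cell fraction from the BAF deviation of PAR1 heterozygotes.

    ``CF = 4*Bdev / (1 + 2*Bdev)``; Bdev must lie in [0, 0.5]
    (0.5 = complete loss, heterozygote bands at 0 and 1).
    """
    arr = _as_array(bdev, "bdev")
    if np.any(arr < 0) or np.any(arr > 0.5):
        raise ValueError(f"bdev must lie in [0, 0.5], got {bdev!r}")
    return _scalar_or_array(4.0 * arr / (1.0 + 2.0 * arr))


def bdev_from_cf(cf: ArrayLike) -> ArrayLike:
    """BAF deviation implied by a cell fraction: ``Bdev = CF / (4 - 2*CF)``."""
    arr = _as_array(cf, "cf")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"cf must lie in [0, 1], got {cf!r}")
    return _scalar_or_array(arr / (4.0 - 2.0 * arr))


def reference_table(
    mlrry_min: float = -4.5,
    mlrry_max: float = 0.0,
    step: float = 0.01,
    scale: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Lookup table of cell fraction by mLRR_Y on a regular grid.

    Rows run from ``mlrry_max`` down to ``mlrry_min`` (CF increasing), so the
    table reads naturally from "no loss" to "complete loss".
    """
    scale = _check_scale(scale)
    if not (mlrry_min < mlrry_max <= 0):
        raise ValueError("require mlrry_min < mlrry_max <= 0")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(np.floor((mlrry_max - mlrry_min) / step + 1e-9)) + 1
    if n < 1:
        raise ValueError("empty mLRR_Y grid")
    # round to kill accumulated float drift so grids contain e.g. -0.15 exactly
    grid = np.round(mlrry_max - step * np.arange(n), 10)
    return pd.DataFrame({"mLRR_Y": grid, "CF": cf_from_mlrry(grid, scale)})


def write_reference_table(table: pd.DataFrame, path) -> None:
    """Write a reference table as TSV with header ``mLRR_Y<TAB>CF``."""
    out = table.copy()
    out["mLRR_Y"] = out["mLRR_Y"].map(lambda v: f"{v:.6f}")
    out["CF"] = out["CF"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def round_display(x: float, ndigits: int = 3) -> float:
    """Half-even rounding used everywhere values are printed."""
    return round(float(x), ndigits)
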