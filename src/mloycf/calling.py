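"""Per-sample mLOY calling: mLRR_Y, Bdev, QC metrics, and cell-fraction estimates.

For each sample the caller computes

* ``mlrr_y`` — the median LRR over probes in the male-specific Y region
  (MSY).  The median over >= ``min_msy_probes`` probes (default 30) is a
  stable location estimate even though single-probe LRR is noisy.
* the mLOY decision — ``mlrr_y <= threshold`` (default -0.15, inclusive at
  the boundary).  At the default scale this threshold corresponds to a
  detection floor of ~20.6% cell fraction.
* ``cf_mlrry`` — the LRR-route cell fraction, clamped to [0, 1].  Samples
  with mLRR_Y above zero have no meaningful LRR-route CF (it would be
  negative) and are flagged ``positive_mlrry`` instead.
* ``bdev`` / ``cf_baf`` — the BAF-route estimate: median |BAF - 0.5| over
  PAR1 probes genotyped AB.  This is a phase-free surrogate for the
  haplotype-phased Bdev used by dedicated mosaic-alteration callers; it reads
  the same band split off the raw BAF track and needs >= ``min_par1_het``
  heterozygotes (default 30) to be reported.
* QC metrics mirroring the standard mosaic-calling sample filters:
  call rate >= 0.97, BAF autocorrelation <= 0.03, PAR1 relative copy number
  < 2.5.  Failures flag the sample; measurements are never erased, so
  borderline samples stay auditable.

No-call and negative are distinct throughout: an absent statistic carries an
explicit reason flag rather than a sentinel value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import formulas
from .regions import AUTOSOME, MSY, PAR1, RegionMap, chrom_sort_key, default_region_map

# absence / QC flag vocabulary (enumerated, stable strings)
FLAG_NO_MSY = "no_msy_coverage"
FLAG_FEW_MSY = "too_few_msy_probes"
FLAG_NO_HET = "no_par1_het"
FLAG_FEW_HET = "too_few_par1_het"
FLAG_POSITIVE_MLRRY = "positive_mlrry"
FLAG_QC_CALL_RATE = "qc_call_rate"
FLAG_QC_BAF_AUTO = "qc_baf_auto"
FLAG_QC_REL_COV = "qc_rel_cov"


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds and minimum counts for per-sample calling."""

    mloy_threshold: float = -0.15  # mLRR_Y at/below which mLOY is called
    min_msy_probes: int = 30
    min_par1_het: int = 30
    call_rate_min: float = 0.97
    baf_auto_max: float = 0.03
    rel_cov_par1_max: float = 2.5
    scale: float = formulas.DEFAULT_SCALE

    def __post_init__(self):
        if not self.mloy_threshold < 0:
            raise ValueError(f"mloy_threshold must be negative, got {self.mloy_threshold}")
        if self.min_msy_probes < 1 or self.min_par1_het < 1:
            raise ValueError("minimum probe counts must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CallingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ValueError(f"{path}: config YAML must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class QCMetrics:
    """Sample-level quality metrics used as mLOY filters."""

    call_rate: Optional[float]
    baf_auto: Optional[float]
    rel_cov_par1: Optional[float]


@dataclass(frozen=True)
class SampleCall:
    """All per-sample outputs of the caller; None = not determinable."""

    sample_id: str
    n_msy_probes: int
    mlrr_y: Optional[float]
    cf_mlrry: Optional[float]
    n_par1_het: int
    bdev: Optional[float]
    cf_baf: Optional[float]
    qc: QCMetrics
    mloy_lrr: Optional[bool]
    threshold_used: Optional[float]
    flags: tuple[str, ...] = ()

    @property
    def qc_pass(self) -> bool:
        return not any(f.startswith("qc_") for f in self.flags)


def compute_mlrry(
    sample: pd.DataFrame, region_map: RegionMap, min_probes: int = 30
) -> tuple[Optional[float], int, Optional[str]]:
    """Median LRR over MSY probes: ``(mlrr_y, n_probes, absence_reason)``.

    Probes with missing LRR do not enter the median and do not count toward
    ``min_probes``.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    region = region_map.classify_array(sample["chrom"].to_numpy(), sample["position"].to_numpy())
    lrr = sample["lrr"].to_numpy(dtype=float)[region == MSY]
    lrr = lrr[np.isfinite(lrr)]
    n = int(lrr.size)
    if n == 0:
        return None, 0, FLAG_NO_MSY
    if n < min_probes:
        return None, n, FLAG_FEW_MSY
    return float(np.median(lrr)), n, None


def call_mloy_lrr(mlrr_y: Optional[float], threshold: float = -0.15) -> Optional[bool]:
    """mLOY yes/no from mLRR_Y; inclusive at the threshold. None stays None."""
    if not threshold < 0:
        raise ValueError(f"threshold must be negative, got {threshold}")
    if mlrr_y is None:
        return None
    return bool(mlrr_y <= threshold)


def estimate_bdev(
    sample: pd.DataFrame, region_map: RegionMap, min_het: int = 30
) -> tuple[Optional[float], int, Optional[str]]:
    """Median |BAF - 0.5| over PAR1 heterozygotes: ``(bdev, n_het, reason)``.

    Heterozygosity is taken from the genotype column (AB), not inferred from
    BAF — genotype miscalling at high cell fraction is precisely the failure
    mode this lets downstream analyses observe.
    """
    if min_het < 1:
        raise ValueError("min_het must be >= 1")
    region = region_map.classify_array(sample["chrom"].to_numpy(), sample["position"].to_numpy())
    mask = (region == PAR1) & (sample["genotype"].to_numpy() == "AB")
    baf = sample["baf"].to_numpy(dtype=float)[mask]
    baf = baf[np.isfinite(baf)]
    n = int(baf.size)
    if n == 0:
        return None, 0, FLAG_NO_HET
    if n < min_het:
        return None, n, FLAG_FEW_HET
    return float(np.median(np.abs(baf - 0.5))), n, None


def _lag1_autocorr(x: np.ndarray) -> Optional[float]:
    if x.size < 3:
        return None
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def compute_qc(
    sample: pd.DataFrame, region_map: RegionMap, scale: float = formulas.DEFAULT_SCALE
) -> QCMetrics:
    """Call rate, autosomal-BAF lag-1 autocorrelation, PAR1 relative copy number.

    ``baf_auto`` is the lag-1 autocorrelation of (BAF - 0.5) over autosomal
    probes in genomic order: spatially correlated BAF shifts (dye bias,
    contamination, widespread mosaicism) inflate it, white noise does not.
    ``rel_cov_par1`` = 2 * 2**(median PAR1 LRR / scale), the observed PAR1
    copy number on the diploid scale.
    """
    region = region_map.classify_array(sample["chrom"].to_numpy(), sample["position"].to_numpy())
    genotype = sample["genotype"].to_numpy()
    call_rate = float(np.mean(genotype != "NC")) if len(sample) else None

    auto = sample[region == AUTOSOME]
    # autocorrelation is defined along genomic order, whatever the input order
    auto = auto.sort_values(
        ["position"], kind="mergesort"
    ).sort_values("chrom", key=lambda c: c.map(lambda t: chrom_sort_key(t)[0]), kind="mergesort")
    auto_baf = auto["baf"].to_numpy(dtype=float)
    auto_baf = auto_baf[np.isfinite(auto_baf)]
    baf_auto = _lag1_autocorr(auto_baf - 0.5)

    par1_lrr = sample["lrr"].to_numpy(dtype=float)[region == PAR1]
    par1_lrr = par1_lrr[np.isfinite(par1_lrr)]
    rel_cov = float(formulas.cn_from_lrr(np.median(par1_lrr), 2, scale)) if par1_lrr.size else None
    return QCMetrics(call_rate=call_rate, baf_auto=baf_auto, rel_cov_par1=rel_cov)


def _assemble_call(
    sample_id: str,
    mlrr_y: Optional[float],
    n_msy: int,
    msy_reason: Optional[str],
    bdev: Optional[float],
    n_het: int,
    het_reason: Optional[str],
    qc: QCMetrics,
    config: CallingConfig,
) -> SampleCall:
    flags: list[str] = []
    if msy_reason:
        flags.append(msy_reason)
    if het_reason:
        flags.append(het_reason)

    cf_mlrry = None
    if mlrr_y is not None:
        if mlrr_y > 0:
            # above-normal Y intensity: the LRR route has no valid CF
            flags.append(FLAG_POSITIVE_MLRRY)
        else:
            cf_mlrry = float(np.clip(formulas.cf_from_mlrry(mlrr_y, config.scale), 0.0, 1.0))

    cf_baf = float(formulas.cf_from_bdev(min(bdev, 0.5))) if bdev is not None else None

    if qc.call_rate is not None and qc.call_rate < config.call_rate_min:
        flags.append(FLAG_QC_CALL_RATE)
    if qc.baf_auto is not None and qc.baf_auto > config.baf_auto_max:
        flags.append(FLAG_QC_BAF_AUTO)
    if qc.rel_cov_par1 is not None and qc.rel_cov_par1 >= config.rel_cov_par1_max:
        flags.append(FLAG_QC_REL_COV)

    return SampleCall(
        sample_id=sample_id,
        n_msy_probes=n_msy,
        mlrr_y=mlrr_y,
        cf_mlrry=cf_mlrry,
        n_par1_het=n_het,
        bdev=bdev,
        cf_baf=cf_baf,
        qc=qc,
        mloy_lrr=call_mloy_lrr(mlrr_y, config.mloy_threshold),
        threshold_used=config.mloy_threshold,
        flags=tuple(flags),
    )


def call_sample(
    sample_id: str,
    sample: pd.DataFrame,
    region_map: RegionMap | None = None,
    config: CallingConfig | None = None,
) -> SampleCall:
    """Run the full per-sample pipeline on one probe table."""
    region_map = region_map or default_region_map()
    config = config or CallingConfig()
    mlrr_y, n_msy, msy_reason = compute_mlrry(sample, region_map, config.min_msy_probes)
    bdev, n_het, het_reason = estimate_bdev(sample, region_map, config.min_par1_het)
    qc = compute_qc(sample, region_map, config.scale)
    return _assemble_call(sample_id, mlrr_y, n_msy, msy_reason, bdev, n_het, het_reason, qc, config)


def call_cohort(
    cohort: pd.DataFrame,
    region_map: RegionMap | None = None,
    config: CallingConfig | None = None,
) -> list[SampleCall]:
    """Vectorized calling over a cohort probe table (``sample_id`` column).

    Produces the same calls as :func:`call_sample` applied per sample, but
    computes the groupwise aggregates in bulk so tens of thousands of samples
    stay tractable.
    """
    region_map = region_map or default_region_map()
    config = config or CallingConfig()

    region = region_map.classify_array(cohort["chrom"].to_numpy(), cohort["position"].to_numpy())
    df = cohort[["sample_id", "chrom", "position", "lrr", "baf", "genotype"]].copy()
    df["region"] = region

    sample_ids = df["sample_id"].unique()

    msy = df[(df["region"] == MSY) & df["lrr"].notna()]
    msy_med = msy.groupby("sample_id")["lrr"].median()
    msy_n = msy.groupby("sample_id")["lrr"].size()

    het = df[(df["region"] == PAR1) & (df["genotype"] == "AB") & df["baf"].notna()].copy()
    het["dev"] = (het["baf"] - 0.5).abs()
    het_med = het.groupby("sample_id")["dev"].median()
    het_n = het.groupby("sample_id")["dev"].size()

    call_rate = df.assign(called=df["genotype"].to_numpy() != "NC").groupby("sample_id")["called"].mean()

    par1 = df[(df["region"] == PAR1) & df["lrr"].notna()]
    par1_med = par1.groupby("sample_id")["lrr"].median()

    auto = df[(df["region"] == AUTOSOME) & df["baf"].notna()]
    auto = auto.sort_values(
        ["position"], kind="mergesort"
    ).sort_values("chrom", key=lambda c: c.map(lambda t: chrom_sort_key(t)[0]), kind="mergesort")
    baf_auto = auto.groupby("sample_id")["baf"].agg(
        lambda s: np.nan if (v := _lag1_autocorr(s.to_numpy() - 0.5)) is None else v
    )

    calls = []
    for sid in sample_ids:
        n_msy = int(msy_n.get(sid, 0))
        if n_msy == 0:
            mlrr_y, msy_reason = None, FLAG_NO_MSY
        elif n_msy < config.min_msy_probes:
            mlrr_y, msy_reason = None, FLAG_FEW_MSY
        else:
            mlrr_y, msy_reason = float(msy_med[sid]), None

        n_het = int(het_n.get(sid, 0))
        if n_het == 0:
            bdev, het_reason = None, FLAG_NO_HET
        elif n_het < config.min_par1_het:
            bdev, het_reason = None, FLAG_FEW_HET
        else:
            bdev, het_reason = float(het_med[sid]), None

        ba = baf_auto.get(sid, np.nan)
        pm = par1_med.get(sid, np.nan)
        qc = QCMetrics(
            call_rate=float(call_rate[sid]),
            baf_auto=None if pd.isna(ba) else float(ba),
            rel_cov_par1=None if pd.isna(pm) else float(formulas.cn_from_lrr(pm, 2, config.scale)),
        )
        calls.append(
            _assemble_call(str(sid), mlrr_y, n_msy, msy_reason, bdev, n_het, het_reason, qc, config)
        )
    return calls
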