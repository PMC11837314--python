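"""Synthetic SNP-array cohort generator with known mLOY ground truth.

The generator inverts the caller's signal model to produce probe-level
intensity tables spanning every regime the method has to handle:

* a normal male (cell fraction CF = 0): MSY LRR centred at 0;
* graded mLOY: MSY LRR ~ Normal(scale * log2(max(1 - CF, cn_floor)),
  sigma_lrr); PAR1 heterozygote BAF split into bands at
  0.5 +/- Bdev(CF) with Gaussian noise; PAR1 LRR reflects the partial loss
  of one PAR copy (CN = 2 - CF);
* the high-CF failure mode of genotype calling: a probe is genotyped AB iff
  its *observed* BAF falls inside the het-call band (default [0.15, 0.85]),
  so widely split heterozygote bands are miscalled homozygous exactly as on
  real arrays;
* females: zero Y copies observed at an intensity floor ``cn_floor``
  (residual background signal; the default 0.005 puts female mLRR_Y near
  -3.4), no Y genotype calls, balanced PAR1 (two X copies, Bdev = 0).

MSY probes carry no BAF (the region is haploid; arrays report nothing
usable there and the method never reads it).  LRR noise is Gaussian and
probe-independent — real arrays add GC waves, but the downstream statistic
is a median over hundreds of probes, which is robust to symmetric noise.

Everything is reproducible from ``seed``: one generator, fixed draw order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import formulas

MALE = "male"
FEMALE = "female"

# default probe counts follow a widely used array layout: 397 MSY probes
# (OncoArray-like) and 434 PAR1 SNPs (GSA-like)
DEFAULT_N_MSY = 397
DEFAULT_N_PAR1 = 434

# MSY span on chrY between the PARs (GRCh38)
_MSY_LO, _MSY_HI = 2_781_480, 56_887_902
_PAR1_LO, _PAR1_HI = 10_001, 2_781_479


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort design: per-sample truth plus probe counts and noise levels.

    ``cf`` gives each sample's true mLOY cell fraction (ignored for
    females, whose Y copy number is pinned at ``cn_floor``).  ``sex`` is
    either one label broadcast to all samples or one label per sample.
    """

    cf: tuple
    seed: int
    sex: str | tuple = MALE
    n_msy_probes: int = DEFAULT_N_MSY
    n_par1_probes: int = DEFAULT_N_PAR1
    n_autosomal_probes: int = 5000
    sigma_lrr: float = 0.15
    sigma_baf: float = 0.03
    het_fraction: float = 0.30
    het_call_band: tuple = (0.15, 0.85)
    cn_floor: float = 0.005
    scale: float = formulas.DEFAULT_SCALE

    def __post_init__(self):
        cf = np.asarray(self.cf, dtype=float)
        if cf.ndim != 1 or cf.size == 0:
            raise ValueError("cf must be a non-empty 1-D sequence of per-sample cell fractions")
        if np.any(cf < 0) or np.any(cf > 1):
            raise ValueError("cell fractions must lie in [0, 1]")
        object.__setattr__(self, "cf", tuple(float(v) for v in cf))
        sex = self.sex
        if isinstance(sex, str):
            sex = (sex,) * len(self.cf)
        sex = tuple(str(s) for s in sex)
        if len(sex) != len(self.cf):
            raise ValueError("sex must be one label or one per sample")
        if any(s not in (MALE, FEMALE) for s in sex):
            raise ValueError(f"sex labels must be {MALE!r} or {FEMALE!r}")
        object.__setattr__(self, "sex", sex)
        if min(self.n_msy_probes, self.n_par1_probes, self.n_autosomal_probes) < 0:
            raise ValueError("probe counts must be >= 0")
        if self.sigma_lrr < 0 or self.sigma_baf < 0:
            raise ValueError("noise s.d. must be >= 0")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must lie in [0, 1]")
        lo, hi = self.het_call_band
        if not 0 < lo < hi < 1:
            raise ValueError("het_call_band must satisfy 0 < lo < hi < 1")
        object.__setattr__(self, "het_call_band", (float(lo), float(hi)))
        if not self.cn_floor > 0:
            raise ValueError("cn_floor must be > 0")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        int(self.seed)  # must be integral

    @property
    def n_samples(self) -> int:
        return len(self.cf)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: simulation config must be a mapping")
        if "seed" not in raw:
            raise ValueError(f"{path}: simulation config must set an explicit seed")
        if "het_call_band" in raw:
            raw["het_call_band"] = tuple(raw["het_call_band"])
        if "cf" in raw and np.isscalar(raw["cf"]):
            n = int(raw.pop("n_samples", 1))
            raw["cf"] = (float(raw["cf"]),) * n
        else:
            raw.pop("n_samples", None)
        if isinstance(raw.get("sex"), list):
            raw["sex"] = tuple(raw["sex"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["cf"] = list(self.cf)
        d["sex"] = list(self.sex)
        d["het_call_band"] = list(self.het_call_band)
        return d


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic ground truth per sample.

    ``expected_mlrry = scale * log2(max(1 - CF, cn_floor))`` and
    ``expected_bdev = CF / (4 - 2 CF)`` for males.  Females observe the Y
    intensity floor (``true_cf`` = 1) but have *no* PAR1 imbalance — both
    their PAR copies sit on X chromosomes — so their expected Bdev is 0.
    """
    ids = [f"S{i + 1:05d}" for i in range(config.n_samples)]
    sex = np.asarray(config.sex, dtype=object)
    cf = np.asarray(config.cf, dtype=float)
    female = sex == FEMALE
    true_cf = np.where(female, 1.0, cf)
    observed_cn = np.maximum(1.0 - true_cf, config.cn_floor)
    expected_mlrry = config.scale * np.log2(observed_cn)
    expected_bdev = np.where(female, 0.0, np.asarray(formulas.bdev_from_cf(cf)))
    return pd.DataFrame(
        {
            "sample_id": ids,
            "sex": sex,
            "true_cf": true_cf,
            "expected_mlrry": expected_mlrry,
            "expected_bdev": expected_bdev,
        }
    )


def _probe_positions(n: int, lo: int, hi: int) -> np.ndarray:
    return np.linspace(lo, hi, num=n, dtype=np.int64) if n else np.empty(0, dtype=np.int64)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(cohort, truth)``.

    ``cohort`` is one probe table for all samples (columns ``sample_id,
    probe_id, chrom, position, lrr, baf, genotype``, genomically sorted
    within each sample); ``truth`` is :func:`truth_table` for the same
    config.
    """
    rng = np.random.default_rng(int(config.seed))
    truth = truth_table(config)
    n = config.n_samples

    msy_pos = _probe_positions(config.n_msy_probes, _MSY_LO, _MSY_HI)
    par1_pos = _probe_positions(config.n_par1_probes, _PAR1_LO, _PAR1_HI)
    auto_pos = _probe_positions(config.n_autosomal_probes, 1_000_000, 200_000_000)
    msy_ids = np.array([f"msy{i + 1:05d}" for i in range(len(msy_pos))], dtype=object)
    par1_ids = np.array([f"par1_{i + 1:05d}" for i in range(len(par1_pos))], dtype=object)
    auto_ids = np.array([f"auto{i + 1:06d}" for i in range(len(auto_pos))], dtype=object)

    lo, hi = config.het_call_band
    frames = []
    for s in range(n):
        sid = truth["sample_id"].iloc[s]
        is_female = truth["sex"].iloc[s] == FEMALE
        true_cf = float(truth["true_cf"].iloc[s])
        mu_msy = float(truth["expected_mlrry"].iloc[s])
        bdev = float(truth["expected_bdev"].iloc[s])

        blocks = []
        if len(msy_pos):
            lrr = mu_msy + config.sigma_lrr * rng.standard_normal(len(msy_pos))
            if is_female:
                geno = np.full(len(msy_pos), "NC", dtype=object)
            else:
                geno = np.where(rng.random(len(msy_pos)) < 0.5, "AA", "BB").astype(object)
            blocks.append(
                pd.DataFrame(
                    {
                        "probe_id": msy_ids,
                        "chrom": "chrY",
                        "position": msy_pos,
                        "lrr": lrr,
                        "baf": np.nan,  # haploid region: no usable BAF
                        "genotype": geno,
                    }
                )
            )

        if len(par1_pos):
            m = len(par1_pos)
            # PAR1 stays diploid in females; males lose the Y copy in CF of cells
            par_cn = 2.0 if is_female else 2.0 - true_cf
            mu_par1 = config.scale * np.log2(par_cn / 2.0)
            lrr = mu_par1 + config.sigma_lrr * rng.standard_normal(m)
            is_het = rng.random(m) < config.het_fraction
            sign = np.where(rng.random(m) < 0.5, 1.0, -1.0)
            het_centre = 0.5 + sign * (0.0 if is_female else bdev)
            hom_centre = np.where(rng.random(m) < 0.5, 0.0, 1.0)
            centre = np.where(is_het, het_centre, hom_centre)
            baf = np.clip(centre + config.sigma_baf * rng.standard_normal(m), 0.0, 1.0)
            geno = np.where(
                (baf >= lo) & (baf <= hi), "AB", np.where(baf < 0.5, "AA", "BB")
            ).astype(object)
            blocks.append(
                pd.DataFrame(
                    {
                        "probe_id": par1_ids,
                        "chrom": "chrX",
                        "position": par1_pos,
                        "lrr": lrr,
                        "baf": baf,
                        "genotype": geno,
                    }
                )
            )

        if len(auto_pos):
            m = len(auto_pos)
            lrr = config.sigma_lrr * rng.standard_normal(m)
            is_het = rng.random(m) < config.het_fraction
            centre = np.where(is_het, 0.5, np.where(rng.random(m) < 0.5, 0.0, 1.0))
            baf = np.clip(centre + config.sigma_baf * rng.standard_normal(m), 0.0, 1.0)
            geno = np.where(
                (baf >= lo) & (baf <= hi), "AB", np.where(baf < 0.5, "AA", "BB")
            ).astype(object)
            blocks.append(
                pd.DataFrame(
                    {
                        "probe_id": auto_ids,
                        "chrom": "chr1",
                        "position": auto_pos,
                        "lrr": lrr,
                        "baf": baf,
                        "genotype": geno,
                    }
                )
            )

        table = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(
            columns=["probe_id", "chrom", "position", "lrr", "baf", "genotype"]
        )
        # genomic order within sample: chr1, chrX, chrY blocks as constructed
        order = {"chr1": 1, "chrX": 23, "chrY": 24}
        table = table.sort_values(
            ["position"], kind="mergesort"
        ).sort_values(["chrom"], key=lambda c: c.map(order), kind="mergesort")
        table.insert(0, "sample_id", sid)
        frames.append(table)

    cohort = pd.concat(frames, ignore_index=True)
    return cohort, truth


def miscall_rate(
    expected_bdev: float,
    sigma_baf: float,
    het_call_band: tuple[float, float] = (0.15, 0.85),
) -> float:
    """Analytic probability a true heterozygote is genotyped homozygous.

    Under the simulator's model the observed BAF of a true het is
    ``0.5 +/- Bdev + Normal(0, sigma_baf)`` with equiprobable sign, and the
    genotype is AB only inside the band — so the miscall probability is plain
    Gaussian tail mass, averaged over the two bands.  Clipping to [0, 1]
    never moves a value across a band edge (the band is interior), so it
    does not change the rate.
    """
    if not 0 <= expected_bdev <= 0.5:
        raise ValueError("expected_bdev must lie in [0, 0.5]")
    if sigma_baf < 0:
        raise ValueError("sigma_baf must be >= 0")
    lo, hi = het_call_band
    if not 0 < lo < hi < 1:
        raise ValueError("het_call_band must satisfy 0 < lo < hi < 1")

    def p_outside(mu: float) -> float:
        if sigma_baf == 0:
            return float(not lo <= mu <= hi)
        return float(norm.cdf((lo - mu) / sigma_baf) + norm.sf((hi - mu) / sigma_baf))

    return 0.5 * (p_outside(0.5 + expected_bdev) + p_outside(0.5 - expected_bdev))


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table as TSV with 6-decimal numerics."""
    out = truth.copy()
    for col in ("true_cf", "expected_mlrry", "expected_bdev"):
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)
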