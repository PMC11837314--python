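"""Read and write per-probe intensity tables and per-sample call tables.

The canonical input dialect mirrors an Illumina GenomeStudio "Final Report"
text export (one row per sample x probe):

    Sample ID  SNP Name  Chr  Position  Log R Ratio  B Allele Freq  GType

Other header layouts are handled through a *dialect*: a mapping from the
canonical keys (``sample``, ``probe``, ``chrom``, ``position``, ``lrr``,
``baf``, ``genotype``) to the header names actually present, loadable from a
small YAML file.

Parsing rules, chosen so that a noisy export degrades loudly instead of
silently: missing LRR/BAF ("NaN", "NA", empty, ".") are kept as missing — the
probe still contributes to genotype-based statistics; rows whose numeric
fields are garbage are skipped and counted; BAF outside [0, 1] is set to
missing and counted.  No sample is ever dropped silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .regions import chrom_sort_key, normalize_chrom

CANONICAL_KEYS = ("sample", "probe", "chrom", "position", "lrr", "baf", "genotype")

#: GenomeStudio Final Report header names, the ubiquitous Illumina text export.
GENOMESTUDIO_DIALECT: dict[str, str] = {
    "sample": "Sample ID",
    "probe": "SNP Name",
    "chrom": "Chr",
    "position": "Position",
    "lrr": "Log R Ratio",
    "baf": "B Allele Freq",
    "genotype": "GType",
}

_NA_TOKENS = {"", "NA", "NaN", "nan", "NAN", "na", "null", "NULL", "."}
_GENOTYPES = {"AA", "AB", "BB"}

#: Column order of the per-sample calls TSV.
CALL_COLUMNS = (
    "sample_id",
    "n_msy_probes",
    "mlrr_y",
    "cf_mlrry",
    "n_par1_het",
    "bdev",
    "cf_baf",
    "call_rate",
    "baf_auto",
    "rel_cov_par1",
    "qc_pass",
    "mloy_lrr",
    "threshold_used",
    "flags",
)


def load_dialect(path) -> dict[str, str]:
    """Load a header-remapping dialect from YAML ({canonical key: header})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: dialect YAML must be a mapping")
    unknown = set(raw) - set(CANONICAL_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown dialect keys {sorted(unknown)}; allowed: {CANONICAL_KEYS}")
    dialect = dict(GENOMESTUDIO_DIALECT)
    dialect.update({k: str(v) for k, v in raw.items()})
    return dialect


@dataclass
class ReadReport:
    """Per-file parse accounting; nothing is discarded without a count here."""

    n_rows: int = 0
    n_skipped: int = 0
    n_baf_out_of_range: int = 0
    n_probes_per_sample: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_skipped": self.n_skipped,
            "n_baf_out_of_range": self.n_baf_out_of_range,
            "n_probes_per_sample": dict(self.n_probes_per_sample),
        }


def _parse_float_column(raw: pd.Series, report: ReadReport) -> tuple[pd.Series, pd.Series]:
    """Return (values, bad_mask): NA tokens -> NaN, anything else unparseable flagged."""
    stripped = raw.astype(str).str.strip()
    is_na = stripped.isin(_NA_TOKENS)
    values = pd.to_numeric(stripped, errors="coerce")
    bad = values.isna() & ~is_na
    return values, bad


def read_intensity_table(path, dialect: Mapping[str, str] | None = None):
    """Parse an intensity table into per-sample probe tables.

    Returns ``(samples, report)`` where ``samples`` maps sample_id to a
    DataFrame with columns ``probe_id, chrom, position, lrr, baf, genotype``
    sorted by genomic position, and ``report`` is a :class:`ReadReport`.
    """
    dialect = dict(dialect) if dialect else dict(GENOMESTUDIO_DIALECT)
    missing_keys = set(CANONICAL_KEYS) - set(dialect)
    if missing_keys:
        raise ValueError(f"dialect lacks keys {sorted(missing_keys)}")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment=None)
    found = list(df.columns)
    missing_cols = [dialect[k] for k in CANONICAL_KEYS if dialect[k] not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing_cols}; found headers: {found}"
        )
    df = df.rename(columns={v: k for k, v in dialect.items()})[list(CANONICAL_KEYS)]

    report = ReadReport(n_rows=len(df))

    position = pd.to_numeric(df["position"].str.strip(), errors="coerce")
    lrr, bad_lrr = _parse_float_column(df["lrr"], report)
    baf, bad_baf = _parse_float_column(df["baf"], report)
    bad = position.isna() | (position < 1) | bad_lrr | bad_baf
    report.n_skipped = int(bad.sum())

    out = pd.DataFrame(
        {
            "sample_id": df["sample"].str.strip(),
            "probe_id": df["probe"].str.strip(),
            "chrom": [normalize_chrom(c) or str(c).strip() for c in df["chrom"]],
            "position": position,
            "lrr": lrr,
            "baf": baf,
            "genotype": df["genotype"].str.strip().str.upper(),
        }
    )[~bad.values].copy()
    out["position"] = out["position"].astype(np.int64)
    out["genotype"] = out["genotype"].where(out["genotype"].isin(_GENOTYPES), "NC")

    oob = out["baf"].notna() & ((out["baf"] < 0) | (out["baf"] > 1))
    report.n_baf_out_of_range = int(oob.sum())
    out.loc[oob, "baf"] = np.nan

    out["_ckey"] = [chrom_sort_key(c)[0] for c in out["chrom"]]
    out = out.sort_values(["sample_id", "_ckey", "position", "probe_id"], kind="mergesort")
    out = out.drop(columns="_ckey").reset_index(drop=True)

    samples = {
        sid: grp.drop(columns="sample_id").reset_index(drop=True)
        for sid, grp in out.groupby("sample_id", sort=True)
    }
    report.n_probes_per_sample = {sid: len(tbl) for sid, tbl in samples.items()}
    return samples, report


def concat_samples(samples: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample tables into one cohort table with a sample_id column."""
    frames = []
    for sid, tbl in samples.items():
        frame = tbl.copy()
        frame.insert(0, "sample_id", sid)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_intensity_table(cohort: pd.DataFrame, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a cohort probe table in the canonical (GenomeStudio-like) dialect."""
    dialect = dict(dialect) if dialect else dict(GENOMESTUDIO_DIALECT)
    canonical_cols = ["sample_id", "probe_id", "chrom", "position", "lrr", "baf", "genotype"]
    out = cohort[canonical_cols].copy()
    out["lrr"] = out["lrr"].map(lambda v: "NaN" if pd.isna(v) else f"{v:.6f}")
    out["baf"] = out["baf"].map(lambda v: "NaN" if pd.isna(v) else f"{v:.6f}")
    out.columns = [dialect[k] for k in CANONICAL_KEYS]
    out.to_csv(path, sep="\t", index=False)


def _fmt(value, ndigits: int = 6) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    return f"{value:.{ndigits}f}"


def _fmt_bool(value) -> str:
    if value is None:
        return "NA"
    return "yes" if value else "no"


def write_calls(calls, path) -> None:
    """Write per-sample calls as TSV (one row per sample, 6-decimal numerics).

    The format round-trips: write -> :func:`read_calls` -> write is
    byte-identical.
    """
    rows = []
    for call in calls:
        rows.append(
            {
                "sample_id": call.sample_id,
                "n_msy_probes": str(call.n_msy_probes),
                "mlrr_y": _fmt(call.mlrr_y),
                "cf_mlrry": _fmt(call.cf_mlrry),
                "n_par1_het": str(call.n_par1_het),
                "bdev": _fmt(call.bdev),
                "cf_baf": _fmt(call.cf_baf),
                "call_rate": _fmt(call.qc.call_rate),
                "baf_auto": _fmt(call.qc.baf_auto),
                "rel_cov_par1": _fmt(call.qc.rel_cov_par1),
                "qc_pass": _fmt_bool(call.qc_pass),
                "mloy_lrr": _fmt_bool(call.mloy_lrr),
                "threshold_used": _fmt(call.threshold_used),
                "flags": ";".join(call.flags) if call.flags else "-",
            }
        )
    pd.DataFrame(rows, columns=list(CALL_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_calls(path):
    """Read a calls TSV back into :class:`~mloycf.calling.SampleCall` objects."""
    from .calling import QCMetrics, SampleCall

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: calls file lacks columns {sorted(missing)}")

    def fnum(s):
        return None if s == "NA" else float(s)

    def fbool(s):
        return None if s == "NA" else (s == "yes")

    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            SampleCall(
                sample_id=row.sample_id,
                n_msy_probes=int(row.n_msy_probes),
                mlrr_y=fnum(row.mlrr_y),
                cf_mlrry=fnum(row.cf_mlrry),
                n_par1_het=int(row.n_par1_het),
                bdev=fnum(row.bdev),
                cf_baf=fnum(row.cf_baf),
                qc=QCMetrics(
                    call_rate=fnum(row.call_rate),
                    baf_auto=fnum(row.baf_auto),
                    rel_cov_par1=fnum(row.rel_cov_par1),
                ),
                mloy_lrr=fbool(row.mloy_lrr),
                threshold_used=fnum(row.threshold_used),
                flags=tuple() if row.flags == "-" else tuple(row.flags.split(";")),
            )
        )
    return calls


def write_run_summary(path, **payload) -> None:
    """Machine-readable JSON run summary (config echo, counts, versions)."""
    from . import __version__

    payload = {"mloycf_version": __version__, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
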