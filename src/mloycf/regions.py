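"""Genomic region definitions for the sex chromosomes and probe classification.

The method needs three named regions on GRCh38:

* ``PAR1`` — the large pseudoautosomal region shared by chrX and chrY
  (10,001-2,781,479 on each), diploid in males; its heterozygous SNPs carry
  the BAF-deviation signal.
* ``PAR2`` — the short distal pseudoautosomal region; the default map places
  the printed interval 56,887,903-57,217,415 on chrY, where those GRCh38
  coordinates belong (chrX PAR2 lies near 155.7 Mb and is not probed by the
  arrays this package targets).  Override via a region file if needed.
* ``MSY`` — the male-specific region of chrY: every chrY position outside the
  PARs.  Haploid in normal male cells; its probes carry the LRR signal.

Coordinates are 1-based inclusive internally; BED files use the standard
0-based half-open convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GRCH38 = "GRCh38"

# region labels
PAR1 = "PAR1"
PAR2 = "PAR2"
MSY = "MSY"
AUTOSOME = "AUTOSOME"
X_NONPAR = "X_NONPAR"
OTHER = "OTHER"

REGION_NAMES = (PAR1, PAR2, MSY)

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)}


def normalize_chrom(token) -> str | None:
    """Canonical chromosome name for the tokens array exports actually emit.

    ``"Y"``, ``"chrY"``, ``"24"`` -> ``"chrY"``; ``"X"``, ``"23"`` -> ``"chrX"``;
    ``"XY"`` (Illumina's code for PAR probes, reported at chrX positions) ->
    ``"chrX"``; ``"7"`` -> ``"chr7"``.  Unrecognized tokens return None.
    """
    if token is None:
        return None
    tok = str(token).strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    tok = tok.upper()
    if tok in ("Y", "24"):
        return "chrY"
    if tok in ("X", "23", "XY", "25"):
        return "chrX"
    if re.fullmatch(r"[0-9]+", tok) and 1 <= int(tok) <= 22:
        return f"chr{int(tok)}"
    return None


def chrom_sort_key(chrom) -> tuple[int, str]:
    """Genomic ordering: chr1..chr22, chrX, chrY, then unknowns by name."""
    canon = normalize_chrom(chrom)
    if canon is None:
        return (99, str(chrom))
    if canon == "chrX":
        return (23, canon)
    if canon == "chrY":
        return (24, canon)
    return (int(canon[3:]), canon)


@dataclass(frozen=True)
class GenomicInterval:
    """A named interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    name: str
    build: str = GRCH38

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end} ({self.name})")
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")

    def contains(self, position: int) -> bool:
        return self.start <= int(position) <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class RegionMap:
    """Named PAR1/PAR2/MSY intervals on one genome build.

    MSY may be implicit (any chrY position outside the PARs) or given
    explicitly; explicit MSY intervals must not overlap a PAR, so every chrY
    position maps to exactly one of PAR1, PAR2, MSY.
    """

    intervals: tuple[GenomicInterval, ...]
    build: str = GRCH38

    def __post_init__(self):
        for iv in self.intervals:
            if iv.name not in REGION_NAMES:
                raise ValueError(f"unknown region name {iv.name!r}; expected one of {REGION_NAMES}")
            if iv.build != self.build:
                raise ValueError(f"interval {iv.name} on build {iv.build!r} != map build {self.build!r}")
        y_pars = [iv for iv in self.intervals if iv.chrom == "chrY" and iv.name in (PAR1, PAR2)]
        for msy in (iv for iv in self.intervals if iv.name == MSY):
            for par in y_pars:
                if msy.overlaps(par):
                    raise ValueError(f"MSY interval {msy} overlaps {par.name} {par}")

    def named(self, name: str, chrom: str | None = None) -> GenomicInterval:
        for iv in self.intervals:
            if iv.name == name and (chrom is None or iv.chrom == chrom):
                return iv
        raise KeyError(f"no {name} interval" + (f" on {chrom}" if chrom else ""))

    @property
    def par1(self) -> GenomicInterval:
        return self.named(PAR1, "chrX")

    @property
    def par2(self) -> GenomicInterval:
        return self.named(PAR2)

    def classify(self, chrom, position) -> str:
        """Region label for one probe; PARs take precedence over MSY on chrY."""
        position = int(position)
        if position < 1:
            raise ValueError(f"position must be >= 1, got {position}")
        canon = normalize_chrom(chrom)
        if canon is None:
            return OTHER
        if canon in _AUTOSOMES:
            return AUTOSOME
        for name in (PAR1, PAR2):
            for iv in self.intervals:
                if iv.name == name and iv.chrom == canon and iv.contains(position):
                    return name
        if canon == "chrY":
            return MSY
        return X_NONPAR

    def classify_array(self, chroms: Sequence, positions: Sequence) -> np.ndarray:
        """Vectorized :meth:`classify` for cohort-scale tables."""
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        canon = np.array([normalize_chrom(c) for c in chroms], dtype=object)
        out = np.full(len(canon), OTHER, dtype=object)
        is_auto = np.array([c in _AUTOSOMES for c in canon])
        out[is_auto] = AUTOSOME
        for sex_chrom, fallback in (("chrX", X_NONPAR), ("chrY", MSY)):
            mask = canon == sex_chrom
            if not mask.any():
                continue
            lab = np.full(mask.sum(), fallback, dtype=object)
            pos = positions[mask]
            for name in (PAR2, PAR1):  # PAR1 last so it wins any (invalid) overlap
                for iv in self.intervals:
                    if iv.name == name and iv.chrom == sex_chrom:
                        lab[(pos >= iv.start) & (pos <= iv.end)] = name
            out[mask] = lab
        return out


def default_region_map() -> RegionMap:
    """Built-in GRCh38 map: PAR1 on chrX and chrY, PAR2 on chrY, MSY implicit."""
    return RegionMap(
        intervals=(
            GenomicInterval("chrX", 10_001, 2_781_479, PAR1),
            GenomicInterval("chrY", 10_001, 2_781_479, PAR1),
            GenomicInterval("chrY", 56_887_903, 57_217_415, PAR2),
        ),
        build=GRCH38,
    )


def load_region_map(path, build: str = GRCH38) -> RegionMap:
    """Read a region map from 4-column BED (chrom, start, end, name).

    BED coordinates are 0-based half-open and converted to the internal
    1-based inclusive representation.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 tab-separated columns, got {len(fields)}")
            chrom_tok, start_s, end_s, name = fields[:4]
            canon = normalize_chrom(chrom_tok)
            if canon is None:
                raise ValueError(f"{path}: line {lineno}: unrecognized chromosome {chrom_tok!r}")
            try:
                bed_start, bed_end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if bed_end <= bed_start:
                raise ValueError(f"{path}: line {lineno}: empty or inverted interval")
            if name not in REGION_NAMES:
                raise ValueError(f"{path}: line {lineno}: unknown region name {name!r}")
            intervals.append(GenomicInterval(canon, bed_start + 1, bed_end, name, build))
    if not intervals:
        raise ValueError(f"{path}: no intervals found")
    return RegionMap(tuple(intervals), build=build)


def write_region_map(region_map: RegionMap, path) -> None:
    """Write a region map as 4-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in region_map.intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n")
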