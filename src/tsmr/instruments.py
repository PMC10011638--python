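"""Genetic-instrument selection.

Three stages turn an exposure summary-statistics set into instruments:

1. genome-wide significance filtering (default p < 5e-8),
2. greedy LD clumping against an explicit r-squared matrix
   (default r² < 0.001 within a ±10,000 kb window), and
3. instrument-strength screening by the per-variant F statistic
   F = beta² / se² (report-only by default: F ranges are always logged,
   nothing is excluded unless ``f_min`` > 0).

The LD dependency is explicit: an :class:`LDMatrix` is supplied by the user
or a simulation.  Candidate pairs absent from the matrix are a hard error
unless the permissive flag is set, in which case they are treated as r² = 0
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import SummaryStatSet, VariantAssociation

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "filter_significant",
    "clump",
    "f_statistic",
    "screen_weak",
]

GENOME_WIDE_P = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_KB = 10_000.0


@dataclass
class LDMatrix:
    """Symmetric matrix of squared allelic correlations (r²) between variants."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r2.shape} does not match {k} rsids")
        if k and not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be 1")
        if k and not np.allclose(self.r2, self.r2.T):
            raise ValueError("LD matrix must be symmetric")
        if k and (self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12):
            raise ValueError("r² values must lie in [0, 1]")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    @classmethod
    def identity(cls, rsids) -> "LDMatrix":
        rsids = list(rsids)
        return cls(rsids=rsids, r2=np.eye(len(rsids)))

    @classmethod
    def read(cls, path) -> "LDMatrix":
        """Read a delimited r² matrix: header row of rsids, first column rsid."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(rsids=[str(c) for c in df.columns], r2=df.to_numpy(dtype=float))

    def write(self, path) -> str:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(path, sep="\t")
        return str(path)

    def lookup(self, rsid_a: str, rsid_b: str, permissive: bool = False) -> float:
        ia = self._index.get(rsid_a)
        ib = self._index.get(rsid_b)
        if ia is None or ib is None:
            missing = rsid_a if ia is None else rsid_b
            if not permissive:
                raise KeyError(f"variant {missing} absent from LD matrix")
            warnings.warn(f"variant {missing} absent from LD matrix; assuming r² = 0")
            return 0.0
        return float(self.r2[ia, ib])

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index


@dataclass
class InstrumentSet:
    """Selected exposure instruments with per-variant strength and provenance.

    ``provenance`` logs every candidate's fate: ``kept``,
    ``dropped:p-threshold``, ``dropped:clumped-with:<rsid>`` or
    ``dropped:weak-instrument``.
    """

    records: list[VariantAssociation]
    trait_name: str = ""
    trait_type: str = "continuous"
    provenance: list[tuple[str, str]] = field(default_factory=list)

    @property
    def f_stats(self) -> np.ndarray:
        return np.array([f_statistic(r) for r in self.records])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def f_range(self) -> tuple[float, float]:
        f = self.f_stats
        return (float(f.min()), float(f.max())) if len(f) else (np.nan, np.nan)

    def to_sumstats(self) -> SummaryStatSet:
        return SummaryStatSet(self.trait_name, self.trait_type, list(self.records))


def f_statistic(record: VariantAssociation) -> float:
    """Per-instrument strength, F = beta² / se²."""
    return record.beta**2 / record.se**2


def filter_significant(exposure: SummaryStatSet, p_threshold: float = GENOME_WIDE_P) -> SummaryStatSet:
    """Keep exactly the records with pval < p_threshold, order preserved."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    kept = [r for r in exposure.records if r.pval < p_threshold]
    return SummaryStatSet(exposure.trait_name, exposure.trait_type, kept)


def clump(
    candidates: SummaryStatSet,
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
    permissive: bool = False,
) -> InstrumentSet:
    """Greedy LD clumping.

    Repeatedly take the remaining candidate with the smallest p-value as an
    index SNP (ties break by smaller position, then rsid) and drop all
    remaining same-chromosome candidates within ``window_kb`` of it whose r²
    with it is at or above ``r2_threshold``.  The result is independent of
    input row order; kept records are returned in selection (p-value) order.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be > 0")
    if not permissive:
        for rec in candidates:
            if rec.rsid not in ld:
                raise KeyError(f"variant {rec.rsid} absent from LD matrix (use permissive=True to assume r²=0)")

    remaining = sorted(candidates.records, key=lambda r: (r.pval, r.pos, r.rsid))
    kept: list[VariantAssociation] = []
    provenance: list[tuple[str, str]] = []
    window_bp = window_kb * 1000.0
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        provenance.append((index.rsid, "kept"))
        survivors = []
        for rec in remaining:
            if (
                rec.chrom == index.chrom
                and abs(rec.pos - index.pos) <= window_bp
                and ld.lookup(index.rsid, rec.rsid, permissive=permissive) >= r2_threshold
            ):
                provenance.append((rec.rsid, f"dropped:clumped-with:{index.rsid}"))
            else:
                survivors.append(rec)
        remaining = survivors
    return InstrumentSet(
        records=kept,
        trait_name=candidates.trait_name,
        trait_type=candidates.trait_type,
        provenance=provenance,
    )


def screen_weak(instruments: InstrumentSet, f_min: float = 0.0) -> InstrumentSet:
    """Drop instruments with F below ``f_min`` (identity when f_min = 0).

    The default is report-only: following the convention of screening by
    inspection, F ranges are surfaced via :meth:`InstrumentSet.f_range`
    rather than silently excluding variants.
    """
    if f_min < 0:
        raise ValueError("f_min must be >= 0")
    kept, prov = [], list(instruments.provenance)
    for rec in instruments.records:
        if f_statistic(rec) >= f_min:
            kept.append(rec)
        else:
            prov.append((rec.rsid, "dropped:weak-instrument"))
    if not kept and instruments.records:
        warnings.warn(f"all {len(instruments.records)} instruments fall below F = {f_min}")
    return InstrumentSet(
        records=kept,
        trait_name=instruments.trait_name,
        trait_type=instruments.trait_type,
        provenance=prov,
    )
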