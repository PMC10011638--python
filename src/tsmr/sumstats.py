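"""Reading, validating and writing GWAS summary-statistics tables.

The canonical on-disk dialect is a delimited text table (TSV by default,
CSV accepted) with one variant per row and the header columns

    SNP  CHR  POS  EA  OA  EAF  BETA  SE  P  N

``SNP`` is the variant identifier, ``EA``/``OA`` the effect and other
allele, ``EAF`` the effect-allele frequency, ``BETA``/``SE`` the per-allele
association estimate and its standard error (log-odds for binary traits),
``P`` the association p-value and ``N`` the sample size.  Source files in
other dialects are adapted through an explicit ``column_map``.  ``EAF``,
``N``, ``CHR`` and ``POS`` may be missing; everything else is mandatory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryStatSet",
    "CANONICAL_COLUMNS",
    "MANDATORY_COLUMNS",
    "read_sumstats",
    "write_sumstats",
]

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]

_VALID_ALLELES = frozenset("ACGT")
_NA = "NA"


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary statistics for one trait.

    ``beta`` is the per-effect-allele change in the trait (log-odds for a
    binary trait, SD or trait units for a continuous one).  ``eaf`` and
    ``n`` may be ``None`` (missing); ``chrom``/``pos`` default to unknown,
    which only matters for distance-based LD clumping.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = _NA
    pos: int = 0
    eaf: float | None = None
    n: float | None = None

    def validate(self) -> None:
        if not self.rsid:
            raise ValueError("empty rsid")
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.rsid}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: identical alleles")
        if not (math.isfinite(self.beta)):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.rsid}: se must be finite and > 0")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.rsid}: pval outside (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf outside [0, 1]")
        if self.n is not None and not self.n > 0:
            raise ValueError(f"{self.rsid}: n must be > 0")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is ambiguous."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryStatSet:
    """An ordered, validated collection of variant associations for one trait.

    ``trait_type`` ('continuous' or 'binary') decides the downstream
    reporting scale: beta for continuous outcomes, odds ratio for binary.
    rsids are unique within a set.  ``n_dropped`` counts input rows removed
    during validation, broken down in ``drop_reasons``.
    """

    trait_name: str
    trait_type: str
    records: list[VariantAssociation] = field(default_factory=list)
    n_dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous or binary, got {self.trait_type!r}")
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.rsid in seen:
                raise ValueError(f"duplicate rsid {rec.rsid}")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_rsid(self) -> dict[str, VariantAssociation]:
        return {rec.rsid: rec for rec in self.records}

    def subset(self, rsids) -> "SummaryStatSet":
        keep = set(rsids)
        return SummaryStatSet(
            trait_name=self.trait_name,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.rsid in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "SNP": r.rsid,
                    "CHR": r.chrom,
                    "POS": r.pos,
                    "EA": r.effect_allele,
                    "OA": r.other_allele,
                    "EAF": np.nan if r.eaf is None else r.eaf,
                    "BETA": r.beta,
                    "SE": r.se,
                    "P": r.pval,
                    "N": np.nan if r.n is None else r.n,
                }
            )
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def _to_float(value) -> float | None:
    if value is None:
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(f) else f


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_name: str = "",
    trait_type: str = "continuous",
) -> SummaryStatSet:
    """Read a summary-statistics table, validating and dropping bad rows.

    Parameters
    ----------
    path
        Delimited text file; tab or comma, auto-detected from the header.
    column_map
        Mapping from file headers to canonical fields (``{"rs_id": "SNP"}``).
        Unmapped canonical headers already present in the file are used as-is.
    trait_name, trait_type
        Trait labelling; ``trait_type`` is 'continuous' or 'binary'.

    Rows failing validation (non-positive SE, malformed alleles, p outside
    (0,1], ...) are dropped and counted per reason.  Duplicate rsids keep the
    record with the smallest SE.  p-values of exactly 0 are clamped to the
    smallest positive normal float with a warning.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {', '.join(missing)}")

    records: list[VariantAssociation] = []
    drops: dict[str, int] = {}
    best_se: dict[str, float] = {}
    n_zero_p = 0

    def drop(reason: str) -> None:
        drops[reason] = drops.get(reason, 0) + 1

    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        rsid = str(row.get("SNP", "")).strip()
        ea = str(row.get("EA", "")).strip().upper()
        oa = str(row.get("OA", "")).strip().upper()
        beta = _to_float(row.get("BETA"))
        se = _to_float(row.get("SE"))
        pval = _to_float(row.get("P"))
        if pval is not None and pval == 0.0:
            pval = float(np.finfo(float).tiny)
            n_zero_p += 1
        eaf = _to_float(row.get("EAF"))
        n = _to_float(row.get("N"))
        chrom = str(row.get("CHR", _NA)).strip() or _NA
        pos_f = _to_float(row.get("POS"))
        pos = int(pos_f) if pos_f is not None else 0
        if beta is None or se is None or pval is None:
            drop("unparseable_numeric")
            continue
        rec = VariantAssociation(
            rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
            pval=pval, chrom=chrom, pos=pos, eaf=eaf, n=n,
        )
        try:
            rec.validate()
        except ValueError as exc:
            drop(f"invalid:{str(exc).split(': ')[-1].split(' ')[0]}")
            continue
        if rsid in best_se:
            # duplicate rsid: keep the more precise record
            drop("duplicate_rsid")
            if se < best_se[rsid]:
                records = [r for r in records if r.rsid != rsid]
            else:
                continue
        best_se[rsid] = min(se, best_se.get(rsid, se))
        records.append(rec)

    if n_zero_p:
        warnings.warn(f"{path}: clamped {n_zero_p} zero p-value(s) to the smallest positive float")
    return SummaryStatSet(
        trait_name=trait_name,
        trait_type=trait_type,
        records=records,
        n_dropped=sum(drops.values()),
        drop_reasons=drops,
    )


def write_sumstats(dataset: SummaryStatSet, path) -> str:
    """Write a summary-statistics set as TSV; read_sumstats round-trips it."""
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)
    return str(path)


def orient_record(rec: VariantAssociation) -> VariantAssociation:
    """Return the record re-expressed with the opposite effect allele."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )
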