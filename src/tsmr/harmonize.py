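"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR requires each instrument's exposure and outcome effects to be
expressed for the same effect allele.  Outcome records may report the
alleles swapped (fixed by negating the outcome beta and complementing its
frequency), on the opposite strand (fixed by complementing the alleles), or
both.  Palindromic variants (A/T or C/G) cannot be strand-resolved from the
alleles alone; they are oriented from the effect-allele frequencies when
both are available and informative (outside a band around 0.5), and dropped
otherwise.  Failures never raise: they become dropped records with reasons,
so one bad SNP cannot abort an analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .instruments import InstrumentSet
from .sumstats import SummaryStatSet, VariantAssociation

__all__ = [
    "HarmonizedRecord",
    "HarmonizedSet",
    "harmonize",
    "orient_positive",
    "DEFAULT_PALINDROME_BAND",
]

DEFAULT_PALINDROME_BAND = 0.08

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class HarmonizedRecord:
    """One instrument's aligned exposure/outcome effects.

    ``action`` is one of kept, sign_flipped, strand_flipped, dropped;
    dropped records carry a non-empty ``drop_reason``.
    """

    rsid: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf_x: float | None = None
    eaf_y: float | None = None
    action: str = "kept"
    drop_reason: str = ""

    def __post_init__(self) -> None:
        if self.action not in ("kept", "sign_flipped", "strand_flipped", "dropped"):
            raise ValueError(f"invalid action {self.action!r}")
        if self.action == "dropped" and not self.drop_reason:
            raise ValueError(f"{self.rsid}: dropped record needs a reason")
        if self.action != "dropped" and (self.se_x <= 0 or self.se_y <= 0):
            raise ValueError(f"{self.rsid}: SEs must be positive")


@dataclass
class HarmonizedSet:
    """Ordered harmonized records; estimators consume only the kept ones."""

    records: list[HarmonizedRecord] = field(default_factory=list)

    @property
    def kept(self) -> list[HarmonizedRecord]:
        return [r for r in self.records if r.action != "dropped"]

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.records) - self.n_kept

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, rsids) -> "HarmonizedSet":
        keep = set(rsids)
        return HarmonizedSet([r for r in self.kept if r.rsid in keep])

    def drop_rsids(self, rsids, reason: str) -> "HarmonizedSet":
        """Mark the named kept records as dropped (e.g. flagged outliers)."""
        target = set(rsids)
        out = []
        for r in self.records:
            if r.rsid in target and r.action != "dropped":
                out.append(replace(r, action="dropped", drop_reason=reason))
            else:
                out.append(r)
        return HarmonizedSet(out)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rsid, r.action, r.drop_reason) for r in self.records],
            columns=["SNP", "action", "drop_reason"],
        )

    def write_audit(self, path) -> str:
        self.audit_frame().to_csv(path, sep="\t", index=False)
        return str(path)


def _eaf_informative(eaf: float | None, band: float) -> bool:
    return eaf is not None and abs(eaf - 0.5) > band


def _drop(exp: VariantAssociation, out_rec, reason: str) -> HarmonizedRecord:
    return HarmonizedRecord(
        rsid=exp.rsid,
        beta_x=exp.beta,
        se_x=exp.se,
        beta_y=out_rec.beta if out_rec is not None else 0.0,
        se_y=out_rec.se if out_rec is not None else 0.0,
        eaf_x=exp.eaf,
        eaf_y=out_rec.eaf if out_rec is not None else None,
        action="dropped",
        drop_reason=reason,
    )


def harmonize(
    exposure: InstrumentSet | SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_eaf_band: float = DEFAULT_PALINDROME_BAND,
) -> HarmonizedSet:
    """Align outcome effects to each exposure instrument's effect allele.

    Per exposure SNP found in the outcome: a direct allele match is kept;
    swapped outcome alleles negate the outcome beta and complement its
    frequency (sign_flipped); alleles matching only after strand complement
    are complemented and re-evaluated (strand_flipped).  Palindromic SNPs
    are oriented by frequency and kept only when both eafs lie outside
    ``0.5 ± palindrome_eaf_band``; otherwise dropped as ambiguous.  Exposure
    SNPs absent from the outcome are dropped with reason
    ``missing_in_outcome``; irreconcilable alleles with
    ``incompatible_alleles``.  Harmonizing an already-consistent pair is the
    identity on the kept records.
    """
    outcome_by_rsid = outcome.by_rsid()
    records: list[HarmonizedRecord] = []
    for exp in exposure:
        out = outcome_by_rsid.get(exp.rsid)
        if out is None:
            records.append(_drop(exp, None, "missing_in_outcome"))
            continue

        ea, oa = exp.effect_allele, exp.other_allele
        o_ea, o_oa = out.effect_allele, out.other_allele
        beta_y, eaf_y = out.beta, out.eaf
        pair = {ea, oa}

        if exp.is_palindromic:
            if {o_ea, o_oa} != pair:
                records.append(_drop(exp, out, "incompatible_alleles"))
                continue
            if not (
                _eaf_informative(exp.eaf, palindrome_eaf_band)
                and _eaf_informative(eaf_y, palindrome_eaf_band)
            ):
                records.append(_drop(exp, out, "palindromic_ambiguous"))
                continue
            action = "kept"
            if o_ea != ea:  # letters swapped: nominal flip first
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                action = "sign_flipped"
            # strand orientation from frequency agreement
            if (exp.eaf < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                action = "strand_flipped"
            records.append(
                HarmonizedRecord(exp.rsid, exp.beta, exp.se, beta_y, out.se,
                                 exp.eaf, eaf_y, action=action)
            )
            continue

        if (o_ea, o_oa) == (ea, oa):
            action = "kept"
        elif (o_ea, o_oa) == (oa, ea):
            beta_y = -beta_y
            eaf_y = None if eaf_y is None else 1.0 - eaf_y
            action = "sign_flipped"
        else:
            c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
            if (c_ea, c_oa) == (ea, oa):
                action = "strand_flipped"
            elif (c_ea, c_oa) == (oa, ea):
                beta_y = -beta_y
                eaf_y = None if eaf_y is None else 1.0 - eaf_y
                action = "sign_flipped"
            else:
                records.append(_drop(exp, out, "incompatible_alleles"))
                continue
        records.append(
            HarmonizedRecord(exp.rsid, exp.beta, exp.se, beta_y, out.se,
                             exp.eaf, eaf_y, action=action)
        )
    return HarmonizedSet(records)


def orient_positive(records: HarmonizedSet) -> HarmonizedSet:
    """Re-sign instruments so every exposure effect is positive.

    Records with negative beta_x have both betas jointly negated — the
    standard precondition for MR-Egger regression.  Wald ratios, and hence
    all orientation-invariant estimators, are unchanged.
    """
    out = []
    for r in records:
        if r.action != "dropped" and r.beta_x < 0:
            out.append(replace(r, beta_x=-r.beta_x, beta_y=-r.beta_y))
        else:
            out.append(r)
    return HarmonizedSet(out)
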