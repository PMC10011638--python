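"""Synthetic paired GWAS summary statistics with known causal structure.

The generating model is the standard two-sample MR data model.  Per SNP j:

    maf_j  ~ Uniform(maf_low, maf_high)
    se_x_j = 1 / sqrt(2 · maf_j (1 − maf_j) · n_x)       (standardized trait)
    γ_j    chosen so the expected F statistic spans a weak-to-strong range
    β̂x_j  ~ Normal(γ_j, se_x_j)
    α_j    ~ Normal(pleio_mean, pleio_sd)                 (direct effect)
    β̂y_j  ~ Normal(θ·γ_j + α_j, se_y_j)

with ``n_outliers`` SNPs receiving a fixed pleiotropic offset instead of a
drawn α.  ``pleio_mean = 0`` with ``pleio_sd > 0`` is balanced pleiotropy
(InSIDE holds, IVW stays approximately unbiased while Cochran's Q inflates);
``pleio_mean ≠ 0`` is directional pleiotropy that the Egger intercept should
track.  Binary outcomes reuse the SE formula with an effective sample size
on the log-odds scale.  All randomness flows from the single seed through a
named generator.

``scramble_alleles`` perturbs only the outcome encoding in information-
preserving ways (allele swap with sign/frequency flip; strand complement)
so that harmonization can be tested to invert it exactly, and
``study_fixture`` emits ready-made study regimes — many-instrument
homogeneous, moderate, single-instrument, and few-instrument heterogeneous —
mirroring the instrument counts of published thyroid-function analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .sumstats import SummaryStatSet, VariantAssociation

__all__ = ["SyntheticTruth", "SyntheticStudy", "generate_study", "scramble_alleles", "study_fixture"]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                         ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters of a synthetic two-sample MR study.

    ``theta`` is the true causal effect; ``f_low``/``f_high`` bound the
    log-uniform range of target per-SNP F statistics (instrument strength);
    ``n_x``/``n_y`` are the effective GWAS sample sizes driving standard
    errors.  Defaults describe a well-powered study: 50 independent
    instruments with F between 30 and 500 (the strength range reported for
    thyroid-trait instruments), exposure GWAS of 70,000 and outcome GWAS of
    50,000, common variants (MAF 0.1–0.4), one fifth palindromic.
    """

    seed: int
    theta: float = 0.3
    j: int = 50
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    n_outliers: int = 0
    outlier_offset: float = 0.0
    n_x: float = 70_000.0
    n_y: float = 50_000.0
    maf_low: float = 0.1
    maf_high: float = 0.4
    palindrome_frac: float = 0.2
    f_low: float = 30.0
    f_high: float = 500.0

    def __post_init__(self) -> None:
        if self.j < 1:
            raise ValueError("j must be >= 1")
        if self.pleio_sd < 0:
            raise ValueError("pleio_sd must be >= 0")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.palindrome_frac <= 1:
            raise ValueError("palindrome_frac must lie in [0, 1]")
        if self.n_outliers < 0 or self.n_outliers > self.j:
            raise ValueError("n_outliers must lie in [0, j]")
        if not (0 < self.f_low <= self.f_high):
            raise ValueError("F range must satisfy 0 < f_low <= f_high")


@dataclass
class SyntheticStudy:
    """A generated study: truth, exposure and outcome sets, LD, outlier ids."""

    truth: SyntheticTruth
    exposure: SummaryStatSet
    outcome: SummaryStatSet
    ld: LDMatrix
    outlier_rsids: list[str] = field(default_factory=list)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.finfo(float).tiny)


def generate_study(
    truth: SyntheticTruth,
    f_targets: np.ndarray | None = None,
    alphas: np.ndarray | None = None,
    outcome_type: str = "continuous",
) -> SyntheticStudy:
    """Generate a paired exposure/outcome study from the truth parameters.

    ``f_targets`` optionally fixes each SNP's target F statistic (length j),
    overriding the log-uniform draw — used by fixtures that need a specific
    strong/weak composition.  ``alphas`` likewise fixes the per-SNP direct
    (pleiotropic) effects instead of drawing them.  The LD matrix is the
    identity (independent instruments); attach a block matrix for clumping
    tests.
    """
    rng = np.random.default_rng(truth.seed)
    j = truth.j
    maf = rng.uniform(truth.maf_low, truth.maf_high, size=j)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * truth.n_x)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * truth.n_y)
    if f_targets is None:
        f_targets = np.exp(rng.uniform(np.log(truth.f_low), np.log(truth.f_high), size=j))
    else:
        f_targets = np.asarray(f_targets, dtype=float)
        if f_targets.shape != (j,):
            raise ValueError(f"f_targets must have length {j}")
    gamma = np.sqrt(f_targets) * se_x
    beta_x = rng.normal(gamma, se_x)

    if alphas is not None:
        alpha = np.asarray(alphas, dtype=float).copy()
        if alpha.shape != (j,):
            raise ValueError(f"alphas must have length {j}")
    elif truth.pleio_sd > 0:
        alpha = rng.normal(truth.pleio_mean, truth.pleio_sd, size=j)
    else:
        alpha = np.full(j, truth.pleio_mean)
    outlier_idx = np.sort(rng.choice(j, size=truth.n_outliers, replace=False)) \
        if truth.n_outliers else np.array([], dtype=int)
    alpha[outlier_idx] = truth.outlier_offset
    beta_y = rng.normal(truth.theta * gamma + alpha, se_y)

    n_pal = int(round(truth.palindrome_frac * j))
    pal_mask = np.zeros(j, dtype=bool)
    pal_mask[rng.choice(j, size=n_pal, replace=False)] = True
    pairs = []
    for is_pal in pal_mask:
        pool = _PALINDROMIC_PAIRS if is_pal else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])

    rsids = [f"rs{i + 1}" for i in range(j)]
    chroms = [str(1 + i % 22) for i in range(j)]
    positions = [1_000_000 + 25_000_000 * (i // 22) for i in range(j)]

    def records(betas, ses, n) -> list[VariantAssociation]:
        pvals = _two_sided_p(betas, ses)
        return [
            VariantAssociation(
                rsid=rsids[i], chrom=chroms[i], pos=positions[i],
                effect_allele=pairs[i][0], other_allele=pairs[i][1],
                eaf=float(maf[i]), beta=float(betas[i]), se=float(ses[i]),
                pval=float(pvals[i]), n=n,
            )
            for i in range(j)
        ]

    exposure = SummaryStatSet("exposure", "continuous", records(beta_x, se_x, truth.n_x))
    outcome = SummaryStatSet("outcome", outcome_type, records(beta_y, se_y, truth.n_y))
    return SyntheticStudy(
        truth=truth,
        exposure=exposure,
        outcome=outcome,
        ld=LDMatrix.identity(rsids),
        outlier_rsids=[rsids[i] for i in outlier_idx],
    )


def scramble_alleles(
    study: SyntheticStudy, swap_frac: float, strand_frac: float, seed: int
) -> SyntheticStudy:
    """Scramble the outcome set's allele encoding, information-preserving.

    A seeded fraction of outcome SNPs get their alleles swapped (beta
    negated, eaf complemented) and an independent fraction get strand-
    complemented alleles.  Harmonization inverts both exactly for
    non-palindromic SNPs.
    """
    if not (0 <= swap_frac <= 1 and 0 <= strand_frac <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    new_records = []
    for rec in study.outcome.records:
        swap = rng.random() < swap_frac
        strand = rng.random() < strand_frac
        ea, oa, beta, eaf = rec.effect_allele, rec.other_allele, rec.beta, rec.eaf
        if swap:
            ea, oa = oa, ea
            beta = -beta
            eaf = None if eaf is None else 1.0 - eaf
        if strand:
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        new_records.append(replace(rec, effect_allele=ea, other_allele=oa, beta=beta, eaf=eaf))
    outcome = SummaryStatSet(study.outcome.trait_name, study.outcome.trait_type, new_records)
    return SyntheticStudy(study.truth, study.exposure, outcome, study.ld, list(study.outlier_rsids))


# Fixture regimes mirror the instrument profiles of the thyroid-function
# analyses: TSH-like (many instruments, binary outcome), FT4-like on a
# continuous renal trait (moderate count), FT3:FT4-like (one strong SNP in
# DIO1), and TPOAB-like (few instruments with marked heterogeneity).
_FIXTURES = {
    "tsh_dkd": dict(j=61, n_keep=39, theta=float(np.log(1.44)), n_y=15_000.0,
                    outcome_type="binary", pleio_sd=0.0),
    "ft4_acr": dict(j=31, n_keep=10, theta=-0.078, n_y=52_000.0,
                    outcome_type="continuous", pleio_sd=0.0),
    "ft3ft4_single_snp": dict(j=1, n_keep=1, theta=float(np.log(0.73)), n_y=15_000.0,
                              outcome_type="binary", pleio_sd=0.0),
    "tpoab_heterogeneous": dict(j=5, n_keep=4, theta=float(np.log(1.17)), n_y=15_000.0,
                                outcome_type="binary", pleio_sd=0.0,
                                # balanced ±2-SE direct effects on the strong SNPs:
                                # pervasive heterogeneity that survives outlier removal
                                strong_alpha=0.035),
}


def study_fixture(analysis: str, seed: int) -> SyntheticStudy:
    """Emit a study in one of the named instrument regimes.

    ``analysis`` is one of ``tsh_dkd`` (61 candidates, 39 genome-wide
    significant, homogeneous, binary outcome), ``ft4_acr`` (31 candidates,
    10 significant, continuous outcome), ``ft3ft4_single_snp`` (one strong
    instrument) or ``tpoab_heterogeneous`` (5 candidates, 4 significant,
    strong heterogeneity so penalized IVW is triggered).  Candidates meant
    to survive the genome-wide p < 5e-8 filter get target F in [100, 580];
    the rest get F in [1, 4], far below the significance boundary.
    """
    if analysis not in _FIXTURES:
        raise ValueError(f"unknown fixture {analysis!r}; choose from {sorted(_FIXTURES)}")
    cfg = _FIXTURES[analysis]
    truth = SyntheticTruth(
        seed=seed,
        theta=cfg["theta"],
        j=cfg["j"],
        pleio_sd=cfg["pleio_sd"],
        n_y=cfg["n_y"],
    )
    rng = np.random.default_rng([seed, cfg["j"]])
    n_keep, j = cfg["n_keep"], cfg["j"]
    strong = rng.uniform(100.0, 580.0, size=n_keep)
    weak = rng.uniform(1.0, 4.0, size=j - n_keep)
    f_targets = np.concatenate([strong, weak])
    alphas = None
    if cfg.get("strong_alpha"):
        # alternating-sign direct effects on the strong instruments only
        signs = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n_keep)])
        alphas = np.concatenate([signs * cfg["strong_alpha"], np.zeros(j - n_keep)])
    perm = rng.permutation(j)
    f_targets = f_targets[perm]
    if alphas is not None:
        alphas = alphas[perm]
    return generate_study(truth, f_targets=f_targets, alphas=alphas,
                          outcome_type=cfg["outcome_type"])
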