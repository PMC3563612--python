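"""Detection power: quality index, efficiency curves, planning arithmetic.

The quality index QI = sqrt(RD_exp) / ODF summarizes how well a gene-sample
site supports heterozygous-deletion detection: signal (the read-depth drop
RD_exp/2) over noise (ODF * sqrt(RD_exp/2), up to a constant).  Theoretical
detection efficiency is the probability, under the CN=1 observation model,
that the Bayesian posterior of CN=1 reaches the calling cutoff h; it is a
function of QI alone in the normal model.  This module also carries the
small estimators around the caller: validation-based FDR and the projection
of per-sample event counts onto the whole exome.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .io_and_config import PriorTable
from .calling import posterior

logger = logging.getLogger("exoncnv")

# reference over-dispersion used when mapping QI -> (RD_exp, ODF); efficiency
# depends on the pair only through QI, so the choice is immaterial
_REF_ODF = 4.0


def quality_index(rd_exp, odf):
    """QI = sqrt(RD_exp) / ODF."""
    rd_exp = np.asarray(rd_exp, dtype=float)
    odf = np.asarray(odf, dtype=float)
    if (rd_exp < 0).any():
        raise ValueError("rd_exp must be >= 0")
    if (odf < 1).any():
        raise ValueError("odf must be >= 1")
    out = np.sqrt(rd_exp) / odf
    return float(out) if out.ndim == 0 else out


def detection_interval(
    rd_exp: float,
    odf: float,
    h: float = 0.65,
    priors: PriorTable | None = None,
    hom_residual_fraction: float = 0.01,
    n_grid: int = 3001,
) -> tuple[float, float] | None:
    """Read-depth interval on which P(CN=1 | RD) >= h, or None.

    The CN=1 posterior is unimodal in RD (it peaks near RD_exp/2 and falls
    off toward the CN=0 and CN=2 basins), so the acceptance region is a
    single interval; it is located by grid scan and polished by root-finding
    on the monotone flanks.
    """
    priors = priors or PriorTable.default()
    grid = np.linspace(0.0, 1.5 * rd_exp, n_grid)
    p1 = posterior(grid, np.full_like(grid, rd_exp), np.full_like(grid, odf),
                   priors, hom_residual_fraction)[:, 1]
    above = np.nonzero(p1 >= h)[0]
    if above.size == 0:
        return None

    def f(rd):
        return posterior(rd, rd_exp, odf, priors, hom_residual_fraction)[1] - h

    lo_i, hi_i = above[0], above[-1]
    lo = grid[lo_i] if lo_i == 0 else brentq(f, grid[lo_i - 1], grid[lo_i])
    hi = grid[hi_i] if hi_i == n_grid - 1 else brentq(f, grid[hi_i], grid[hi_i + 1])
    return float(lo), float(hi)


def theoretical_efficiency(
    rd_exp: float,
    odf: float,
    h: float = 0.65,
    priors: PriorTable | None = None,
    hom_residual_fraction: float = 0.01,
) -> float:
    """P(heterozygous deletion is called): mass of the CN=1 observation model
    Normal(RD_exp/2, ODF^2 * RD_exp/2) inside the posterior acceptance region."""
    if rd_exp <= 0:
        return 0.0
    interval = detection_interval(rd_exp, odf, h, priors, hom_residual_fraction)
    if interval is None:
        return 0.0
    mu1 = rd_exp / 2.0
    sd1 = odf * np.sqrt(mu1)
    return float(norm.cdf(interval[1], mu1, sd1) - norm.cdf(interval[0], mu1, sd1))


def efficiency_from_qi(
    qi: float, h: float = 0.65, priors: PriorTable | None = None,
    hom_residual_fraction: float = 0.01,
) -> float:
    if qi <= 0:
        return 0.0
    return theoretical_efficiency(
        (qi * _REF_ODF) ** 2, _REF_ODF, h, priors, hom_residual_fraction
    )


@dataclass
class PowerCurve:
    """Tabulated efficiency as a function of QI at a fixed posterior cutoff."""

    h: float
    qis: np.ndarray
    efficiencies: np.ndarray

    @classmethod
    def build(
        cls,
        h: float = 0.65,
        priors: PriorTable | None = None,
        qi_max: float = 30.0,
        step: float = 0.05,
        hom_residual_fraction: float = 0.01,
    ) -> "PowerCurve":
        qis = np.arange(0.0, qi_max + step / 2, step)
        effs = np.array(
            [efficiency_from_qi(q, h, priors, hom_residual_fraction) for q in qis]
        )
        effs = np.maximum.accumulate(effs)  # guard tiny numeric non-monotonicity
        return cls(h, qis, effs)

    def efficiency_at(self, qi) -> np.ndarray | float:
        return np.interp(qi, self.qis, self.efficiencies)

    @property
    def qi_zero(self) -> float:
        """Largest tabulated QI with zero efficiency."""
        nz = np.nonzero(self.efficiencies > 0)[0]
        if nz.size == 0:
            return float(self.qis[-1])
        return float(self.qis[max(nz[0] - 1, 0)])

    def qi_at(self, p: float) -> float:
        """Smallest QI reaching efficiency p (linear interpolation)."""
        if not (0.0 <= p <= 1.0):
            raise ValueError("efficiency must be in [0, 1]")
        i = int(np.searchsorted(self.efficiencies, p))
        if i >= len(self.qis):
            raise ValueError(f"efficiency {p} not reached on the tabulated range")
        if i == 0 or self.efficiencies[i] == self.efficiencies[i - 1]:
            return float(self.qis[i])
        e0, e1 = self.efficiencies[i - 1], self.efficiencies[i]
        q0, q1 = self.qis[i - 1], self.qis[i]
        return float(q0 + (p - e0) / (e1 - e0) * (q1 - q0))


def qi_thresholds(
    h: float = 0.65,
    priors: PriorTable | None = None,
    hom_residual_fraction: float = 0.01,
    tol: float = 0.01,
) -> tuple[float, float, float]:
    """(qi_zero, qi_50, qi_90): detectability floor and the QI needed for
    50% and 90% heterozygous-deletion sensitivity at cutoff h."""
    if not (0.0 < h < 1.0):
        raise ValueError("h must be in (0, 1)")

    def eff(qi):
        return efficiency_from_qi(qi, h, priors, hom_residual_fraction)

    lo, hi = 0.5, 40.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if eff(mid) > 0.0:
            hi = mid
        else:
            lo = mid
    qi_zero = 0.5 * (lo + hi)
    qi_50 = brentq(lambda q: eff(q) - 0.5, qi_zero, 60.0, xtol=tol)
    qi_90 = brentq(lambda q: eff(q) - 0.9, qi_zero, 80.0, xtol=tol)
    return float(qi_zero), float(qi_50), float(qi_90)


# ---------------------------------------------------------------------------
# Coverage planning
# ---------------------------------------------------------------------------

def coverage_plan(
    target_efficiency: float,
    read_length: float,
    affinities: np.ndarray,
    odfs: np.ndarray,
    h: float = 0.65,
    priors: PriorTable | None = None,
    gene_target_bases: float = 2278.0,
    duplicate_rate: float = 0.0,
    mrd_max: float = 1e7,
) -> dict:
    """Mean base coverage needed for a target mean detection efficiency.

    Searches the MRD scale M such that the mean over the joint (affinity,
    ODF) sample of efficiency(affinity * M, ODF) reaches the target, then
    converts the median gene read count to base coverage:
    coverage = MRD * read_length / gene_target_bases / (1 - duplicate_rate).
    The default targeted bases per gene reflect a capture design of ~13.4
    exons per gene at ~170 bp each.
    """
    if not (0.0 <= target_efficiency <= 1.0):
        raise ValueError("target_efficiency must be in [0, 1]")
    affinities = np.asarray(affinities, dtype=float)
    odfs = np.asarray(odfs, dtype=float)
    if affinities.shape != odfs.shape:
        raise ValueError("affinity and ODF samples must be paired")
    if target_efficiency == 0.0:
        return {"mrd": 0.0, "coverage": 0.0, "mean_efficiency": 0.0}
    curve = PowerCurve.build(h, priors)

    def mean_eff(mrd_scale):
        qi = np.sqrt(affinities * mrd_scale) / odfs
        return float(np.mean(curve.efficiency_at(qi)))

    plateau = mean_eff(mrd_max)
    if plateau < target_efficiency:
        raise ValueError(
            f"target efficiency {target_efficiency} unreachable: "
            f"plateau {plateau:.3f} at MRD {mrd_max:g}"
        )
    mrd = brentq(lambda m: mean_eff(m) - target_efficiency, 1.0, mrd_max, rtol=1e-4)
    coverage = mrd * read_length / gene_target_bases / (1.0 - duplicate_rate)
    return {"mrd": float(mrd), "coverage": float(coverage),
            "mean_efficiency": mean_eff(mrd)}


# ---------------------------------------------------------------------------
# Call-set accuracy arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationCounts:
    n_positive_prior_pub: int
    n_positive_denovo: int
    n_negative: int
    n_inconclusive: int = 0
    n_unvalidated: int = 0

    def __post_init__(self) -> None:
        for f in (self.n_positive_prior_pub, self.n_positive_denovo,
                  self.n_negative, self.n_inconclusive, self.n_unvalidated):
            if f < 0:
                raise ValueError("validation counts must be >= 0")


def estimate_fdr(counts: ValidationCounts) -> float:
    """FDR = invalidated / conclusively validated; inconclusive and
    unvalidated calls are excluded from the denominator."""
    denom = (counts.n_positive_prior_pub + counts.n_positive_denovo
             + counts.n_negative)
    if denom == 0:
        raise ValueError("no conclusively validated calls")
    return counts.n_negative / denom


def project_events(
    n_calls: int,
    fdr: float,
    sensitivity: float,
    n_samples: int,
    genes_analyzed: int,
    genes_exome: int,
) -> tuple[float, float, float]:
    """Project the callset to (true_total, per_sample, per_exome_per_sample).

    true_total = n_calls * (1 - fdr) / sensitivity corrects the tally for
    false discoveries and missed events; the per-sample rate is then scaled
    by the fraction of the exome the capture design covers.
    """
    if not (0.0 < sensitivity <= 1.0):
        raise ValueError("sensitivity must be in (0, 1]")
    if not (0.0 <= fdr < 1.0):
        raise ValueError("fdr must be in [0, 1)")
    true_total = n_calls * (1.0 - fdr) / sensitivity
    per_sample = true_total / n_samples
    per_exome = per_sample * genes_exome / genes_analyzed
    return true_total, per_sample, per_exome
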