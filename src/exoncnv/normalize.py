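"""Gene capture affinities and expected read depth.

The expected read depth of a gene-sample site at normal copy number is
RD_exp = alpha_g * MRD_s, where alpha_g (the gene's capture affinity) is the
slope of a zero-intercept least-squares fit of the gene's read depths
against the per-sample median read depths.  Genes whose single-line fit
explains the data poorly (r^2 below the gate) are re-fit with a tri-linear
model — three lines at slopes alpha, alpha/2 and 0 — which simultaneously
estimates the affinity and assigns copy number 2/1/0 per sample; this is
how common deletions, which corrupt the single-line fit, are handled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_and_config import RunConfig
from .rd_matrix import RDMatrix

logger = logging.getLogger("exoncnv")

UNI, TRI, EXCLUDED = "uni", "tri", "excluded"


@dataclass
class GeneModel:
    gene: str
    affinity: float
    fit_mode: str                       # uni | tri | excluded
    r2_uni: float
    r2_tri: float | None = None
    gene_odf: float | None = None
    tri_cn_assignment: np.ndarray | None = None  # per-sample CN in {0,1,2}


def fit_affinity(rd_gene: np.ndarray, mrd: np.ndarray) -> tuple[float, float]:
    """Zero-intercept least-squares slope of RD against MRD, with centered r^2.

    r^2 is 1 - SS_res / SS_tot with SS_tot taken about the mean of the
    observed read depths: the uncentered convention would report near-1 for
    any positive slope and never trip the quality gate.
    """
    rd_gene = np.asarray(rd_gene, dtype=float)
    mrd = np.asarray(mrd, dtype=float)
    if rd_gene.shape != mrd.shape or rd_gene.size < 2:
        raise ValueError("need matched RD/MRD vectors of length >= 2")
    denom = float(np.sum(mrd * mrd))
    if denom == 0.0:
        raise ValueError("all MRD values are zero; cannot fit affinity")
    affinity = float(np.sum(mrd * rd_gene)) / denom
    ss_res = float(np.sum((rd_gene - affinity * mrd) ** 2))
    ss_tot = float(np.sum((rd_gene - rd_gene.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return affinity, r2


def expected_rd(affinity: float, mrd_s: float | np.ndarray) -> float | np.ndarray:
    """Expected read depth at normal copy number: alpha_g * MRD_s."""
    if affinity < 0:
        raise ValueError("affinity must be >= 0")
    return affinity * mrd_s


def gate_gene(r2_uni: float, r2_min: float = 0.7) -> str:
    """Route a gene by single-line fit quality: uni if r^2 >= gate, else tri."""
    return UNI if r2_uni >= r2_min else TRI


def _tri_error(alpha: float, rd: np.ndarray, mrd: np.ndarray) -> float:
    branches = np.stack(
        [(rd - alpha * mrd) ** 2, (rd - 0.5 * alpha * mrd) ** 2, rd**2]
    )
    return float(branches.min(axis=0).sum())


def trilinear_fit(
    rd_gene: np.ndarray, mrd: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> tuple[float, float, np.ndarray]:
    """Fit three lines (slopes alpha, alpha/2, 0) minimizing the per-sample
    best-branch squared error; returns (alpha, r2_tri, cn_assignment).

    Each sample is assigned CN 2, 1 or 0 by its arg-min branch.  The search
    is a bounded 1-D minimization over alpha seeded at the uni-linear slope,
    then refined by alternating exact weighted-least-squares re-fits for the
    fixed assignment partition until the estimate stabilizes.
    """
    rd = np.asarray(rd_gene, dtype=float)
    mrd = np.asarray(mrd, dtype=float)
    if rd.size < 3:
        raise ValueError("tri-linear fit needs at least 3 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(mrd > 0, rd / np.where(mrd > 0, mrd, 1.0), 0.0)
    hi = 2.0 * max(float(ratios.max()), 1e-6)
    res = minimize_scalar(
        _tri_error, args=(rd, mrd), bounds=(0.0, hi), method="bounded",
        options={"xatol": tol * max(hi, 1.0)},
    )
    if not res.success:
        raise RuntimeError(f"tri-linear minimization failed: {res.message}")
    uni_alpha, _ = fit_affinity(rd, mrd)
    alpha = res.x if _tri_error(res.x, rd, mrd) <= _tri_error(uni_alpha, rd, mrd) \
        else uni_alpha
    assignment = np.zeros(rd.size, dtype=np.int64)
    for _ in range(max_iter):
        branches = np.stack(
            [(rd - alpha * mrd) ** 2, (rd - 0.5 * alpha * mrd) ** 2, rd**2]
        )
        assignment = branches.argmin(axis=0)  # 0 -> CN2, 1 -> CN1, 2 -> CN0
        coef = np.choose(assignment, [1.0, 0.5, 0.0])
        denom = float(np.sum((coef * mrd) ** 2))
        if denom == 0.0:
            break
        alpha_new = float(np.sum(coef * mrd * rd)) / denom
        if abs(alpha_new - alpha) <= tol * max(abs(alpha), 1.0):
            alpha = alpha_new
            break
        alpha = alpha_new
    err = _tri_error(alpha, rd, mrd)
    ss_tot = float(np.sum((rd - rd.mean()) ** 2))
    r2_tri = 1.0 - err / ss_tot if ss_tot > 0 else (1.0 if err == 0 else 0.0)
    branches = np.stack(
        [(rd - alpha * mrd) ** 2, (rd - 0.5 * alpha * mrd) ** 2, rd**2]
    )
    cn = np.array([2, 1, 0])[branches.argmin(axis=0)]
    return float(alpha), float(r2_tri), cn


# minimum distance, in noise sigmas, from each copy-number line to the
# assignment boundary halfway to the next line; below this the "clusters"
# are indistinguishable from dispersion and the fit is noise-chasing
_TRI_MIN_SEPARATION = 1.5


def _tri_supported(rd: np.ndarray, mrd: np.ndarray, tri_alpha: float,
                   cn: np.ndarray) -> bool:
    """Check that the tri-linear branches are resolvable above the noise.

    The tri error is never worse than the single-line SSE — re-assigning any
    outlying sample to the half- or zero-slope branch soaks up noise — so a
    raw r^2 gate would accept spurious three-line fits on high-dispersion
    genes with no CNV and flood the callset.  A real copy-number mixture
    needs separated clusters: the CN2/CN1 assignment boundary sits
    sqrt(alpha*MRD)/4 Poisson sigmas from either line, so with gene noise
    odf_hat (robust spread of assignment-aware z-scores) the boundary is
    sqrt(alpha*MRD)/(4*odf_hat) noise sigmas away.  The fit is kept when
    that median separation reaches 1.5 sigma; otherwise the gene's data
    cannot distinguish a common CNV from over-dispersion.
    """
    if tri_alpha <= 0:
        return False
    if int(np.sum(cn != 2)) == 0:
        return True  # degenerate to the single line; nothing to mis-call
    diploid_like = cn >= 1
    if diploid_like.sum() < 3:
        return False
    coef = np.where(cn == 2, 1.0, 0.5)[diploid_like]
    mu = coef * tri_alpha * mrd[diploid_like]
    if (mu <= 0).any():
        return False
    z = (rd[diploid_like] - mu) / np.sqrt(mu)
    sd0 = float(np.std(z, ddof=1))
    keep = np.abs(z - z.mean()) <= 3.0 * max(sd0, 1e-12)
    odf_hat = max(float(np.std(z[keep], ddof=1)) if keep.sum() > 2 else sd0, 1.0)
    separation = np.sqrt(tri_alpha * mrd[mrd > 0]) / (4.0 * odf_hat)
    return float(np.median(separation)) >= _TRI_MIN_SEPARATION


def fit_gene_models(
    rd: RDMatrix, mrd: np.ndarray | pd.Series, config: RunConfig | None = None
) -> list[GeneModel]:
    """Fit every gene: uni-linear affinity, quality gate, tri-linear fallback.

    Genes passing the gate are 'uni' (calls come from the Bayesian posterior);
    genes failing it but rescued by an acceptable tri-linear fit are 'tri'
    (the fit itself assigns copy number); genes failing both are 'excluded'.
    """
    config = config or RunConfig()
    mrd = np.asarray(mrd, dtype=float)
    models: list[GeneModel] = []
    n_tri = n_excl = 0
    for i, gene in enumerate(rd.genes):
        row = rd.counts[i].astype(float)
        affinity, r2_uni = fit_affinity(row, mrd)
        if gate_gene(r2_uni, config.r2_min) == UNI:
            models.append(GeneModel(gene, affinity, UNI, r2_uni))
            continue
        alpha, r2_tri, cn = trilinear_fit(row, mrd)
        if r2_tri >= config.r2_min and _tri_supported(row, mrd, alpha, cn):
            models.append(GeneModel(gene, alpha, TRI, r2_uni, r2_tri,
                                    tri_cn_assignment=cn))
            n_tri += 1
        else:
            models.append(GeneModel(gene, affinity, EXCLUDED, r2_uni, r2_tri))
            n_excl += 1
    logger.info(
        "fit_gene_models: %d uni, %d tri, %d excluded",
        len(models) - n_tri - n_excl, n_tri, n_excl,
    )
    return models


def models_to_frame(models: list[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [m.gene for m in models],
            "affinity": [m.affinity for m in models],
            "fit_mode": [m.fit_mode for m in models],
            "r2_uni": [m.r2_uni for m in models],
            "r2_tri": [m.r2_tri for m in models],
        }
    )
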