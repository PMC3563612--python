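"""Bayesian copy-number calling.

For every gene-sample site (GSS) the observed read depth is modeled, per
copy number CN in 0..9, as an over-dispersed Poisson approximated by a
normal with mean (CN/2)*RD_exp (a small residual fraction of RD_exp for
CN=0, accounting for erroneously mapped reads) and standard deviation
ODF*sqrt(mean).  The over-dispersion factor (ODF) is the product of a
sample-specific and a gene-specific z-score spread, normalized by the
global spread and clamped to [1, 20].  Posteriors over CN combine these
likelihoods with a nominal prior table; sites where a non-diploid CN
reaches the posterior cutoff h become calls, and low-posterior deletion
candidates can be rescued when an immediately neighboring sequenced gene
(<= 3 Mbp away) is also a candidate — multi-gene deletions leave exactly
that footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io_and_config import PriorTable, RunConfig, TargetSet
from .normalize import TRI, UNI, GeneModel, fit_gene_models
from .rd_matrix import RDMatrix, compute_mrd, filter_matrix

logger = logging.getLogger("exoncnv")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class OdfSet:
    """Sample-, gene- and site-level over-dispersion factors."""

    sample_odf: np.ndarray              # per sample
    gene_odf: np.ndarray                # per gene
    gss_odf: np.ndarray                 # genes x samples, clamped
    global_sd: float = 1.0


@dataclass
class GSSCall:
    """One called gene-sample site."""

    sample: str
    gene: str
    rd_obs: float
    rd_exp: float | None
    called_cn: int
    call_posterior: float | None        # None for direct tri-fit assignments
    odf: float | None = None
    posterior: np.ndarray | None = None
    neighbor_supported: bool = False
    source: str = "posterior"           # "posterior" | "tri"
    chromosome: str = "."
    start: int = 0
    end: int = 0


# ---------------------------------------------------------------------------
# Over-dispersion
# ---------------------------------------------------------------------------

def poisson_zscores(rd_obs: np.ndarray, rd_exp: np.ndarray) -> np.ndarray:
    """z = (RD_obs - RD_exp) / sqrt(RD_exp): unit spread under ideal Poisson."""
    rd_exp = np.asarray(rd_exp, dtype=float)
    if (rd_exp <= 0).any():
        raise ValueError("rd_exp must be > 0 for z-scores; exclude zero sites")
    return (np.asarray(rd_obs, dtype=float) - rd_exp) / np.sqrt(rd_exp)


# variance retained by a normal truncated at +-3 sigma; rescales the
# outlier-trimmed standard deviation back to consistency under normality
_TRUNC3_CORRECTION = 0.9734922136256096


def _robust_sd(z: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """Outlier-trimmed standard deviation, consistent under normality.

    Genuine copy-number events put large outliers into the z-scores; a plain
    standard deviation would absorb them into the dispersion estimate and
    mask the events themselves.  Values beyond 3 initial sigmas are dropped
    and the trimmed sd rescaled for the truncation.
    """
    z = np.asarray(z, dtype=float)
    mean = z.mean(axis=axis, keepdims=axis is not None)
    sd0 = z.std(axis=axis, ddof=1, keepdims=axis is not None)
    keep = np.abs(z - mean) <= 3.0 * np.maximum(sd0, 1e-300)
    n_keep = keep.sum(axis=axis, keepdims=axis is not None)
    zk = np.where(keep, z, np.nan)
    mk = np.nanmean(zk, axis=axis, keepdims=axis is not None)
    var = np.nansum((zk - mk) ** 2, axis=axis, keepdims=axis is not None)
    var = var / np.maximum(n_keep - 1, 1) / _TRUNC3_CORRECTION
    out = np.sqrt(var)
    if axis is None:
        return float(np.squeeze(out))
    return np.squeeze(out, axis=axis)


def compute_odf(
    z: np.ndarray, odf_min: float = 1.0, odf_max: float = 20.0
) -> OdfSet:
    """Estimate per-site over-dispersion from Poisson z-score spreads.

    sample ODF is the per-column z spread, gene ODF the per-row spread; the
    site ODF is their product divided by the global z spread (the product
    alone double-counts dispersion shared by rows and columns: a uniformly
    D-dispersed matrix must map to D, not D^2), clamped to [odf_min, odf_max].
    Spreads are outlier-trimmed so that real events do not mask themselves.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples to estimate ODF")
    sample_odf = _robust_sd(z, axis=0)
    gene_odf = _robust_sd(z, axis=1)
    global_sd = _robust_sd(z)
    if global_sd <= 0:
        # degenerate constant z: every component floors at odf_min
        sample_odf = np.full(z.shape[1], odf_min)
        gene_odf = np.full(z.shape[0], odf_min)
        global_sd = 1.0
    sample_odf = np.maximum(sample_odf, 1e-12)
    gene_odf = np.maximum(gene_odf, 1e-12)
    gss = np.clip(np.outer(gene_odf, sample_odf) / global_sd, odf_min, odf_max)
    return OdfSet(sample_odf, gene_odf, gss, global_sd)


# ---------------------------------------------------------------------------
# Likelihood and posterior
# ---------------------------------------------------------------------------

def cn_means(rd_exp, cn_max: int = 9, hom_residual_fraction: float = 0.01):
    """Model mean read depth per CN: (CN/2)*RD_exp, residual fraction at CN=0."""
    rd_exp = np.asarray(rd_exp, dtype=float)
    scale = np.arange(cn_max + 1) / 2.0
    mu = rd_exp[..., None] * scale
    mu[..., 0] = hom_residual_fraction * rd_exp
    return mu


def log_likelihood(
    rd_obs,
    rd_exp,
    odf,
    cn: int | np.ndarray | None = None,
    hom_residual_fraction: float = 0.01,
    cn_max: int = 9,
    family: str = "normal",
) -> np.ndarray:
    """Log density of the observed RD under each copy number.

    Default family is the continuous normal approximation to the
    over-dispersed Poisson: mean mu_cn, sd ODF*sqrt(mu_cn).  A
    negative-binomial alternative (same mean, variance ODF^2 * mu) is
    available via family="nbinom".
    """
    rd_obs = np.asarray(rd_obs, dtype=float)
    mu = cn_means(rd_exp, cn_max, hom_residual_fraction)
    odf = np.asarray(odf, dtype=float)[..., None]
    if family == "normal":
        sd = odf * np.sqrt(mu)
        ll = -0.5 * ((rd_obs[..., None] - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI
    elif family == "nbinom":
        from scipy.stats import nbinom, poisson

        k = np.round(rd_obs)[..., None]
        var = odf**2 * mu
        ll = np.where(
            odf > 1.0 + 1e-9,
            nbinom.logpmf(k, mu**2 / np.maximum(var - mu, 1e-12),
                          np.clip(mu / var, 1e-12, 1.0)),
            poisson.logpmf(k, mu),
        )
    else:
        raise ValueError(f"unknown likelihood family {family!r}")
    if cn is not None:
        return ll[..., cn]
    return ll


def likelihood(rd_obs, rd_exp, odf, cn, hom_residual_fraction: float = 0.01,
               cn_max: int = 9) -> np.ndarray:
    return np.exp(
        log_likelihood(rd_obs, rd_exp, odf, cn, hom_residual_fraction, cn_max)
    )


def posterior(
    rd_obs,
    rd_exp,
    odf,
    priors: PriorTable | None = None,
    hom_residual_fraction: float = 0.01,
    family: str = "normal",
) -> np.ndarray:
    """Posterior over CN=0..cn_max, computed in log space.

    Accepts scalars or matched arrays; the CN axis is appended last.
    """
    priors = priors or PriorTable.default()
    ll = log_likelihood(
        np.atleast_1d(rd_obs), np.atleast_1d(rd_exp), np.atleast_1d(odf),
        None, hom_residual_fraction, priors.cn_max, family,
    )
    lp = ll + priors.log_probs
    post = np.exp(lp - logsumexp(lp, axis=-1, keepdims=True))
    if np.isscalar(rd_obs) or np.ndim(rd_obs) == 0:
        return post[0]
    return post


# ---------------------------------------------------------------------------
# Thresholding and neighbor rescue
# ---------------------------------------------------------------------------

def _best_non_normal(post: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Most probable CN != 2 and its posterior, along the last axis."""
    masked = post.copy()
    masked[..., 2] = -np.inf
    best = masked.argmax(axis=-1)
    pbest = np.take_along_axis(post, best[..., None], axis=-1)[..., 0]
    return best, pbest


def call_events(
    post: np.ndarray,
    rd_obs: np.ndarray,
    rd_exp: np.ndarray,
    odf: np.ndarray,
    genes: list[str],
    samples: list[str],
    h_call: float = 0.65,
    targets: TargetSet | None = None,
) -> list[GSSCall]:
    """Emit a call wherever a non-diploid CN reaches posterior >= h_call.

    Deletions (CN 0/1) and amplifications (CN > 2) are both emitted; the
    threshold is inclusive.
    """
    if not (0.0 < h_call < 1.0):
        raise ValueError("h_call must be in (0, 1)")
    best, pbest = _best_non_normal(post)
    by_name = targets.by_name() if targets is not None else {}
    calls: list[GSSCall] = []
    for gi, si in zip(*np.nonzero(pbest >= h_call)):
        gene = genes[gi]
        loc = by_name.get(gene)
        calls.append(
            GSSCall(
                sample=samples[si],
                gene=gene,
                rd_obs=float(rd_obs[gi, si]),
                rd_exp=float(rd_exp[gi, si]),
                called_cn=int(best[gi, si]),
                call_posterior=float(pbest[gi, si]),
                odf=float(odf[gi, si]),
                posterior=post[gi, si],
                chromosome=loc.chromosome if loc else ".",
                start=loc.start if loc else 0,
                end=loc.end if loc else 0,
            )
        )
    return calls


def neighbor_rescue(
    post: np.ndarray,
    genes: list[str],
    samples: list[str],
    targets: TargetSet,
    rd_obs: np.ndarray,
    rd_exp: np.ndarray,
    odf: np.ndarray,
    h_neighbor: float = 0.1,
    neighbor_max_distance: int = 3_000_000,
) -> list[GSSCall]:
    """Rescue low-posterior deletion candidates with a deleted neighbor.

    Per sample, genes whose best deletion posterior (CN 0 or 1) reaches
    h_neighbor form a candidate list; a candidate is retained when at least
    one *immediately adjacent* sequenced gene (no analyzed gene in between,
    same chromosome, facing gene boundaries <= the distance cap) is also on
    the list.  Restricted to deletions: multi-gene deletions, not
    amplifications, motivate the rule.
    """
    by_name = targets.by_name()
    order = [g for g in sorted(
        (g for g in genes if g in by_name),
        key=lambda n: (by_name[n].chromosome, by_name[n].start),
    )]
    gene_pos = {g: i for i, g in enumerate(genes)}
    del_best = post[..., :2].argmax(axis=-1)
    del_p = np.take_along_axis(post[..., :2], del_best[..., None], axis=-1)[..., 0]

    def adjacent(a: str, b: str) -> bool:
        ga, gb = by_name[a], by_name[b]
        if ga.chromosome != gb.chromosome:
            return False
        left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
        return right.start - left.end <= neighbor_max_distance

    rescued: list[GSSCall] = []
    for si, sample in enumerate(samples):
        cand = [g for g in order if del_p[gene_pos[g], si] >= h_neighbor]
        cand_set = set(cand)
        for g in cand:
            oi = order.index(g)
            neighbors = [order[oi - 1]] if oi > 0 else []
            if oi + 1 < len(order):
                neighbors.append(order[oi + 1])
            if not any(n in cand_set and adjacent(g, n) for n in neighbors):
                continue
            gi = gene_pos[g]
            loc = by_name[g]
            rescued.append(
                GSSCall(
                    sample=sample,
                    gene=g,
                    rd_obs=float(rd_obs[gi, si]),
                    rd_exp=float(rd_exp[gi, si]),
                    called_cn=int(del_best[gi, si]),
                    call_posterior=float(del_p[gi, si]),
                    odf=float(odf[gi, si]),
                    posterior=post[gi, si],
                    neighbor_supported=True,
                    chromosome=loc.chromosome,
                    start=loc.start,
                    end=loc.end,
                )
            )
    return rescued


def merge_callsets(primary: list[GSSCall], rescued: list[GSSCall]) -> list[GSSCall]:
    """Union of standalone and neighbor-rescued calls, deduplicated by
    (sample, gene); standalone (higher-threshold) provenance wins."""
    seen = {(c.sample, c.gene): c for c in rescued}
    for c in primary:
        seen[(c.sample, c.gene)] = c
    return list(seen.values())


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class CallingResult:
    calls: list[GSSCall]
    models: list[GeneModel]
    rd: RDMatrix
    mrd: np.ndarray
    odf: OdfSet | None
    uni_genes: list[str]
    qi: np.ndarray | None = None        # per uni-mode GSS: sqrt(RD_exp)/ODF


def call_pipeline(
    rd: RDMatrix,
    targets: TargetSet | None = None,
    config: RunConfig | None = None,
    priors: PriorTable | None = None,
    apply_filters: bool = True,
    neighbor: bool = True,
) -> CallingResult:
    """Run the full detection workflow on a read-depth matrix.

    Filters the matrix, computes MRD, fits per-gene affinities (uni gate with
    tri-linear fallback), estimates over-dispersion, computes posteriors for
    uni-mode genes and thresholds them into calls (with optional neighbor
    rescue), and converts tri-mode assignments directly into calls.
    """
    config = config or RunConfig()
    priors = priors or PriorTable.default()
    if apply_filters:
        rd = filter_matrix(
            rd, config.target_median_rd_min, config.sample_median_rd_min
        )
    mrd = compute_mrd(rd).to_numpy()
    models = fit_gene_models(rd, mrd, config)

    uni_idx = [i for i, m in enumerate(models) if m.fit_mode == UNI]
    uni_genes = [rd.genes[i] for i in uni_idx]
    by_name = targets.by_name() if targets is not None else {}

    calls: list[GSSCall] = []
    odf_set = None
    qi = None
    if uni_idx:
        affin = np.array([models[i].affinity for i in uni_idx])
        rd_exp = np.outer(affin, mrd)
        rd_obs = rd.counts[uni_idx].astype(float)
        ok = rd_exp > 0
        if not ok.all():
            logger.info("call_pipeline: %d GSS with zero expected RD excluded",
                        int((~ok).sum()))
        safe_exp = np.where(ok, rd_exp, 1.0)
        z = poisson_zscores(np.where(ok, rd_obs, safe_exp), safe_exp)
        odf_set = compute_odf(z, config.odf_min, config.odf_max)
        for i, gi in enumerate(uni_idx):
            models[gi].gene_odf = float(odf_set.gene_odf[i])
        post = posterior(
            rd_obs, safe_exp, odf_set.gss_odf, priors,
            config.hom_residual_fraction,
        )
        post[~ok] = 0.0
        post[~ok, 2] = 1.0  # excluded sites: forced diploid, never called
        qi = np.sqrt(rd_exp) / odf_set.gss_odf
        primary = call_events(
            post, rd_obs, rd_exp, odf_set.gss_odf, uni_genes, rd.samples,
            config.h_call, targets,
        )
        if neighbor and targets is not None:
            rescued = neighbor_rescue(
                post, uni_genes, rd.samples, targets, rd_obs, rd_exp,
                odf_set.gss_odf, config.h_neighbor, config.neighbor_max_distance,
            )
            calls.extend(merge_callsets(primary, rescued))
        else:
            calls.extend(primary)

    # tri-mode genes: the fit itself assigned CN per sample
    for i, m in enumerate(models):
        if m.fit_mode != TRI:
            continue
        loc = by_name.get(m.gene)
        for si, cn in enumerate(m.tri_cn_assignment):
            if cn == 2:
                continue
            calls.append(
                GSSCall(
                    sample=rd.samples[si],
                    gene=m.gene,
                    rd_obs=float(rd.counts[i, si]),
                    rd_exp=float(m.affinity * mrd[si]),
                    called_cn=int(cn),
                    call_posterior=None,
                    source="tri",
                    chromosome=loc.chromosome if loc else ".",
                    start=loc.start if loc else 0,
                    end=loc.end if loc else 0,
                )
            )
    logger.info("call_pipeline: %d calls", len(calls))
    return CallingResult(calls, models, rd, mrd, odf_set, uni_genes, qi)
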