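"""Effective gene pleiotropy estimation.

The estimator works from two observables of a protein alignment on its
phylogeny: the dN/dS ratio (mean sequence conservation, supplied by the
user from a codon-level analysis) and the H statistic of substitution-rate
variation among sites,

    H = (V - M) / [V + M(M - 1)],

where M and V are the mean and variance over sites of the (multiple-hit
corrected) change counts.  H = 0 for rate-homogeneous (Poisson) counts and
H -> 1 as the among-site rate variance diverges.  The effective pleiotropy
Ke is the root of

    g = 2^(-Ke/2) (1 + phi(Ke)),      g = (dN/dS) / (1 - H),
    phi(Ke) = 0.0208 Ke (Ke + 2) / (1 + 0.289 Ke),

whose left-hand side is the conservation predicted by a K-dimensional
stabilizing-selection model in its strong-selection limit.  From Ke the
effective baseline selection intensity Be (per pleiotropy component) and the
overall effective selection intensity Se = -Ke * Be follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .errors import EstimationError, InputError
from .io import Alignment, EstimateReport
from .phylogeny import (
    distance_matrix,
    nj_tree,
    pairwise_pdistance,
    total_tree_length,
)
from .site_changes import SiteChangeProfile, site_change_profile

logger = logging.getLogger(__name__)

_H_CEIL = 1.0 - 1e-12
KE_MAX = 100.0


@dataclass
class RateRatioInput:
    """dN, dS and their sampling variances (defaults 0, i.e. ignored)."""

    dn: float
    ds: float
    var_dn: float = 0.0
    var_ds: float = 0.0

    def __post_init__(self) -> None:
        if self.dn < 0 or self.ds <= 0:
            raise InputError("require dN >= 0 and dS > 0")
        if self.var_dn < 0 or self.var_ds < 0:
            raise InputError("variances must be >= 0")
        if not 0 < self.ratio < 1:
            raise InputError(
                f"dN/dS = {self.ratio:.4g} must be within (0, 1); genes "
                "without purifying selection are not suitable for this "
                "analysis"
            )

    @property
    def ratio(self) -> float:
        return self.dn / self.ds


@dataclass
class HEstimate:
    """H with the moments it came from and its bootstrap variance."""

    m: float
    v: float
    h: float
    var_h: float
    n_boot: int
    seed: int


@dataclass
class PleiotropyEstimate:
    ke: float
    var_ke: float
    g: float
    se: float
    be: float
    inputs: RateRatioInput
    h: HEstimate


def h_statistic(m: float, v: float) -> float:
    """Among-site rate-variation statistic H = (V - M)/(V + M(M - 1)).

    Clamped into [0, 1): counts underdispersed relative to Poisson (V < M)
    carry no evidence of rate variation and clamp to 0.
    """
    if m <= 0:
        raise EstimationError("mean change count is 0: no substitutions observed")
    denom = v + m * (m - 1.0)
    if denom <= 0:
        logger.warning("H denominator %.4g <= 0; clamping H to 0", denom)
        return 0.0
    h = (v - m) / denom
    if h < 0:
        logger.warning("underdispersed counts (V < M); clamping H to 0")
        return 0.0
    if h >= _H_CEIL:
        logger.warning("H = %.6g at upper bound; clamping", h)
        return _H_CEIL
    return float(h)


def bootstrap_h(
    profile: SiteChangeProfile, n_boot: int = 100, seed: int = 0
) -> HEstimate:
    """Bootstrap alignment columns to get the sampling variance of H.

    The point estimate of H is from the original profile; the bootstrap
    (resampling the cached corrected counts with replacement) serves only
    Var(H).
    """
    if n_boot < 2:
        raise InputError("need at least 2 bootstrap replicates")
    counts = np.asarray(profile.corrected_counts, dtype=float)
    if counts.size < 2:
        raise InputError("need at least 2 sites to bootstrap")
    m = float(counts.mean())
    v = float(counts.var(ddof=1))
    h = h_statistic(m, v)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        c = rng.choice(counts, size=counts.size, replace=True)
        mb, vb = c.mean(), c.var(ddof=1)
        if mb <= 0:
            reps[b] = 0.0
            continue
        db = vb + mb * (mb - 1.0)
        reps[b] = 0.0 if db <= 0 else min(max((vb - mb) / db, 0.0), _H_CEIL)
    return HEstimate(
        m=m, v=v, h=h, var_h=float(reps.var(ddof=1)), n_boot=n_boot, seed=seed
    )


def phi(ke: float) -> float:
    """phi(Ke) = 0.0208 Ke (Ke + 2) / (1 + 0.289 Ke)."""
    ke = np.asarray(ke, dtype=float)
    if np.any(ke < 0):
        raise InputError("Ke must be >= 0")
    out = 0.0208 * ke * (ke + 2.0) / (1.0 + 0.289 * ke)
    return float(out) if out.ndim == 0 else out


def conservation_curve(ke: float) -> float:
    """Model-predicted conservation f(Ke) = 2^(-Ke/2) (1 + phi(Ke)).

    Strictly decreasing from f(0) = 1; ``solve_ke`` is its inverse.
    """
    ke = np.asarray(ke, dtype=float)
    out = 2.0 ** (-ke / 2.0) * (1.0 + 0.0208 * ke * (ke + 2.0) / (1.0 + 0.289 * ke))
    return float(out) if out.ndim == 0 else out


def g_function(ratio: float, h: float) -> float:
    """g = (dN/dS) / (1 - H), the conservation adjusted for rate variation."""
    if not 0 < ratio < 1:
        raise InputError(f"dN/dS = {ratio:.4g} must be within (0, 1)")
    if not 0 <= h < 1:
        raise InputError(f"H = {h:.4g} must be within [0, 1)")
    g = ratio / (1.0 - h)
    if g >= 1.0:
        raise EstimationError(
            f"g = {g:.4g} >= 1: gene too weakly constrained; Ke undefined"
        )
    return g


def solve_ke(g: float) -> float:
    """Invert the conservation curve: the unique Ke with f(Ke) = g.

    Bracketed bisection on (0, 100]; f is strictly decreasing so the root is
    unique.  g at (or numerically above) 1 returns Ke = 0.
    """
    if not 0 < g < 1 + 1e-12:
        raise InputError(f"g = {g:.4g} outside (0, 1)")
    if g >= 1.0 - 1e-12:
        return 0.0
    if conservation_curve(KE_MAX) > g:
        raise EstimationError(f"Ke out of supported range (> {KE_MAX:g})")
    return float(
        bisect(lambda k: conservation_curve(k) - g, 0.0, KE_MAX, xtol=1e-12)
    )


def selection_intensities(ke: float, g: float) -> tuple[float, float]:
    """Effective baseline and overall selection intensities (Be, Se).

    Be = 2 (g^(-2/Ke) - 1) >= 0 per pleiotropy component and
    Se = -Ke * Be <= 0 overall (negative: purifying selection).
    """
    if not 0 < g < 1:
        raise InputError(f"g = {g:.4g} outside (0, 1)")
    if ke < 0:
        raise InputError("Ke must be >= 0")
    if ke == 0:
        logger.warning("Ke = 0: neutral limit, selection intensities are 0")
        return 0.0, 0.0
    be = 2.0 * (g ** (-2.0 / ke) - 1.0)
    return be, -ke * be


def var_ratio(rr: RateRatioInput) -> float:
    """Relative sampling variance of dN/dS: Var(dN)/dN^2 + Var(dS)/dS^2."""
    return rr.var_dn / rr.dn**2 + rr.var_ds / rr.ds**2


def var_ke(rr: RateRatioInput, h: HEstimate) -> float:
    """Delta-method sampling variance of Ke.

    Var(Ke) = (1/1.037) [ Var(dN)/dN^2 + Var(dS)/dS^2 + Var(H)/(1-H)^2 ].
    """
    if h.h >= 1:
        raise InputError("H must be < 1")
    return (var_ratio(rr) + h.var_h / (1.0 - h.h) ** 2) / 1.037


@dataclass
class PipelineOptions:
    correction_mode: str = "tree_length"
    n_boot: int = 100
    seed: int = 0


def mean_pairwise_identity(aln: Alignment) -> float:
    """Mean over pairs of (1 - p-distance); high values flag low power."""
    ps = []
    for a in range(aln.n_taxa):
        for b in range(a + 1, aln.n_taxa):
            p, _ = pairwise_pdistance(aln, aln.taxa[a], aln.taxa[b])
            ps.append(p)
    return 1.0 - float(np.mean(ps))


def estimate_pipeline(
    aln: Alignment,
    tree,
    rr: RateRatioInput,
    options: PipelineOptions | None = None,
    aln_path: str = "",
    tree_path: str = "",
) -> EstimateReport:
    """Full estimation: site counts -> H -> bootstrap -> Ke -> (Be, Se).

    ``tree=None`` triggers neighbor-joining inference from Poisson-corrected
    protein distances.  Warnings (never aborts): mean pairwise identity
    above 90 percent; dS >= 1.
    """
    opts = options or PipelineOptions()
    warnings: list[str] = []
    tree_source = "user"
    if tree is None:
        tree = nj_tree(distance_matrix(aln))
        tree_source = "nj"
    identity = mean_pairwise_identity(aln)
    if identity > 0.90:
        msg = (
            f"mean pairwise identity {identity:.1%} > 90%: low statistical "
            "power, interpret with caution"
        )
        logger.warning(msg)
        warnings.append(msg)
    if rr.ds >= 1.0:
        msg = (
            f"dS = {rr.ds:.3g} >= 1: large sampling variance expected; "
            "prefer more closely related sequences"
        )
        logger.warning(msg)
        warnings.append(msg)
    try:
        profile = site_change_profile(aln, tree, mode=opts.correction_mode)
        h = bootstrap_h(profile, n_boot=opts.n_boot, seed=opts.seed)
        g = g_function(rr.ratio, h.h)
        ke = solve_ke(g)
        be, se = selection_intensities(ke, g)
        vk = var_ke(rr, h)
    except EstimationError as exc:
        raise EstimationError(f"estimation stage: {exc}") from exc
    return EstimateReport(
        ke=ke,
        var_ke=vk,
        g=g,
        se=se,
        be=be,
        h=h.h,
        var_h=h.var_h,
        m=h.m,
        v=h.v,
        dn=rr.dn,
        ds=rr.ds,
        var_dn=rr.var_dn,
        var_ds=rr.var_ds,
        ratio=rr.ratio,
        correction_mode=profile.correction_mode,
        correction_factor=profile.correction_factor,
        tree_length=total_tree_length(tree),
        n_sites_used=profile.n_sites_used,
        n_excluded=len(profile.excluded_sites),
        n_taxa=aln.n_taxa,
        tree_source=tree_source,
        n_boot=opts.n_boot,
        seed=opts.seed,
        aln_path=str(aln_path),
        tree_path=str(tree_path),
        warnings=warnings,
    )
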