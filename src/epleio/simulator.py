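"""Stabilizing-selection pleiotropy simulator.

A site's substitutions are shaped by K pleiotropy components with strengths
w_1..w_K (mean strength = the baseline selection intensity B0, so the total
intensity averages K*B0).  Three component models are provided:

* ``independent_equal`` (a): all components share the strength B0;
* ``independent_unequal`` (b): i.i.d. exponential strengths rescaled to
  mean B0;
* ``random_matrix`` (c): strengths set to the eigenvalue spectrum of a
  Wishart matrix W W'/K (W a K x K standard-normal matrix) rescaled to mean
  B0, inducing the strongly skewed spectra of correlated components.

Per site i, each component contributes a squared standard-normal effect
z_ik^2, and the relative substitution rate is the product of per-component
attenuation factors

    lambda_i = prod_k sqrt( (1 + w_k z_ik^2) / (1 + 2 w_k z_ik^2) ).

Each factor is 1 for an unselected component and falls to sqrt(1/2) as the
component's selection grows, so lambda_i -> 2^(-K/2) in the strong-selection
limit — exactly the leading factor of the estimating equation.  Weakly
selected components attenuate less, which is why the estimator recovers an
*effective* (conservative) pleiotropy below K at moderate B0, with the bias
shrinking as B0 grows.

Counts per site are Poisson(lambda_i * T) for a phylogeny of total length T;
alternatively a full alignment can be evolved on the tree to exercise the
parsimony/NJ pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .errors import EstimationError, InputError
from .estimation import g_function, h_statistic, solve_ke, selection_intensities
from .io import AMINO_ACIDS, Alignment

MODELS = {
    "a": "independent_equal",
    "b": "independent_unequal",
    "c": "random_matrix",
}
_CANON = {v: v for v in MODELS.values()} | MODELS


def canonical_model(model: str) -> str:
    try:
        return _CANON[model]
    except KeyError:
        raise InputError(
            f"unknown model {model!r}; choose one of "
            f"{sorted(set(_CANON.values()))} (aliases a/b/c)"
        ) from None


@dataclass
class SimulationSpec:
    """Parameters of one simulation cell."""

    k: int
    b0: float
    model: str = "independent_equal"
    n_sites: int = 2000
    tree_length: float = 4.0
    n_reps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.model = canonical_model(self.model)
        if not 1 <= self.k:
            raise InputError("K must be a positive integer")
        if self.b0 <= 0:
            raise InputError("B0 must be > 0")
        if self.n_sites < 2 or self.n_reps < 1 or self.tree_length <= 0:
            raise InputError("invalid simulation sizes")


@dataclass
class SiteRates:
    """Per-site total selection intensity and relative substitution rate."""

    intensity: np.ndarray  # S_i = sum_k w_k z_ik^2  (>= 0)
    rate: np.ndarray  # lambda_i in (0, 1]


@dataclass
class SimulationResult:
    spec: SimulationSpec
    per_rep: pd.DataFrame  # columns ke, h, be, se (NaN where not estimable)
    mean_ke: float
    se_ke: float
    mean_h: float
    fail_count: int


def component_weights(
    k: int, b0: float, model: str, rng: np.random.Generator
) -> np.ndarray:
    """Component strengths w_1..w_K, normalized so mean(w) = B0."""
    model = canonical_model(model)
    if model == "independent_equal":
        return np.full(k, float(b0))
    if model == "independent_unequal":
        w = rng.exponential(1.0, size=k)
    else:  # random_matrix
        mat = rng.standard_normal((k, k))
        w = np.linalg.eigvalsh(mat @ mat.T / k)
    w = np.maximum(w, 1e-300)  # eigenvalues are positive a.s.; guard rounding
    return w * (b0 / w.mean())


def fixation_ratio(s) -> np.ndarray | float:
    """Relative fixation rate 2S/(e^(2S) - 1) of a mutation of intensity S.

    Continuous, with the neutral limit lambda(0) = 1; strictly decreasing.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise InputError("selection intensity must be >= 0")
    with np.errstate(invalid="ignore", over="ignore"):
        out = np.where(s < 1e-12, 1.0, 2.0 * s / np.expm1(2.0 * s))
    return float(out) if out.ndim == 0 else out


def draw_site_rates(
    weights: np.ndarray, n_sites: int, rng: np.random.Generator
) -> SiteRates:
    """Draw per-site component effects and reduce them to intensities/rates.

    Effects are squared standard normals; the rate law is the per-component
    attenuation product documented in the module docstring.
    """
    weights = np.asarray(weights, dtype=float)
    z2 = rng.standard_normal((n_sites, weights.size)) ** 2
    intensity = z2 @ weights
    wz = weights * z2
    rate = np.sqrt((1.0 + wz) / (1.0 + 2.0 * wz)).prod(axis=1)
    return SiteRates(intensity=intensity, rate=rate)


def simulate_counts(
    rates: SiteRates, tree_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-site substitution counts X_i ~ Poisson(lambda_i * T)."""
    if tree_length <= 0:
        raise InputError("tree length must be > 0")
    return rng.poisson(rates.rate * tree_length)


def default_tree(n_leaves: int = 8, total_length: float = 4.0) -> dendropy.Tree:
    """Symmetric bifurcating tree with equal branch lengths summing to T."""
    if n_leaves < 4 or n_leaves & (n_leaves - 1):
        raise InputError("n_leaves must be a power of two >= 4")
    labels = [f"s{i + 1}" for i in range(n_leaves)]
    items = list(labels)
    while len(items) > 1:
        items = [
            f"({items[i]}:L,{items[i + 1]}:L)" for i in range(0, len(items), 2)
        ]
    n_edges = 2 * n_leaves - 2
    newick = items[0].replace(":L", f":{total_length / n_edges!r}") + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


def simulate_alignment(
    tree: dendropy.Tree, rates: SiteRates, rng: np.random.Generator
) -> Alignment:
    """Evolve residues over the tree at the given per-site rates.

    The root sequence is uniform over the 20 amino acids; along a branch of
    length b, site i receives Poisson(lambda_i * b) replacement events, each
    to a uniformly chosen different residue.
    """
    lam = np.asarray(rates.rate, dtype=float)
    n_sites = lam.size
    aa = np.array(list(AMINO_ACIDS))
    seqs: dict = {}
    root = tree.seed_node
    states: dict = {root: rng.integers(0, 20, size=n_sites)}
    for node in tree.preorder_node_iter():
        if node is root:
            cur = states[root]
        else:
            b = node.edge.length or 0.0
            cur = states[node.parent_node].copy()
            events = rng.poisson(lam * b)
            for _ in range(int(events.max(initial=0))):
                mask = events > 0
                cur[mask] = (cur[mask] + rng.integers(1, 20, mask.sum())) % 20
                events -= 1
            states[node] = cur
        if node.is_leaf():
            seqs[node.taxon.label] = aa[cur]
    taxa = sorted(seqs)
    return Alignment(taxa=taxa, data=np.array([seqs[t] for t in taxa]))


def _estimate_from_counts(counts: np.ndarray, tree_length: float) -> dict:
    """Ke/H/Be/Se from simulated counts; raises EstimationError when g >= 1
    or no substitutions landed."""
    m = counts.mean()
    v = counts.var(ddof=1)
    h = h_statistic(m, v)
    ratio = m / tree_length
    if not 0.0 < ratio < 1.0:
        raise EstimationError(f"observed rate ratio {ratio:.3g} outside (0,1)")
    g = g_function(ratio, h)
    ke = solve_ke(g)
    be, se = selection_intensities(ke, g)
    return {"ke": ke, "h": h, "be": be, "se": se}


def simulate_cell(spec: SimulationSpec) -> SimulationResult:
    """Run all replicates of one (model, K, B0) cell."""
    root = np.random.SeedSequence(spec.seed)
    rows = []
    fails = 0
    for child in root.spawn(spec.n_reps):
        rng = np.random.default_rng(child)
        w = component_weights(spec.k, spec.b0, spec.model, rng)
        rates = draw_site_rates(w, spec.n_sites, rng)
        counts = simulate_counts(rates, spec.tree_length, rng)
        try:
            rows.append(_estimate_from_counts(counts, spec.tree_length))
        except EstimationError:
            fails += 1
            rows.append({"ke": np.nan, "h": np.nan, "be": np.nan, "se": np.nan})
    per_rep = pd.DataFrame(rows)
    ok = per_rep["ke"].dropna()
    n = len(ok)
    return SimulationResult(
        spec=spec,
        per_rep=per_rep,
        mean_ke=float(ok.mean()) if n else float("nan"),
        se_ke=float(ok.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        mean_h=float(per_rep["h"].mean()),
        fail_count=fails,
    )


def run_grid(
    k_values,
    b0_values,
    models,
    n_sites: int = 2000,
    n_reps: int = 50,
    seed: int = 0,
    tree_length: float = 4.0,
) -> pd.DataFrame:
    """Estimator evaluation grid; one summary row per (model, K, B0) cell."""
    models = [canonical_model(m) for m in np.atleast_1d(models)]
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(models) * len(list(k_values)) * len(list(b0_values)))
    rows = []
    i = 0
    for model in models:
        for b0 in b0_values:
            for k in k_values:
                spec = SimulationSpec(
                    k=int(k),
                    b0=float(b0),
                    model=model,
                    n_sites=n_sites,
                    tree_length=tree_length,
                    n_reps=n_reps,
                    seed=cell_seeds[i].generate_state(1)[0] % (2**31),
                )
                i += 1
                res = simulate_cell(spec)
                rows.append(
                    {
                        "model": model,
                        "K": spec.k,
                        "B0": spec.b0,
                        "n_sites": n_sites,
                        "n_reps": n_reps,
                        "mean_Ke": res.mean_ke,
                        "se_Ke": res.se_ke,
                        "mean_H": res.mean_h,
                        "fail_count": res.fail_count,
                    }
                )
    return pd.DataFrame(rows)
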