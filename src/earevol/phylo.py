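"""Continuous-trait evolutionary models on time-calibrated trees.

Implements maximum-likelihood fitting of Gaussian trait-evolution models
(Brownian motion, Brownian motion with branch-local rate shifts, Pagel's
lambda/delta/kappa, Ornstein-Uhlenbeck with a fixed root, and
accelerating/decelerating rates), small-sample AIC (AICc) model
selection, and GLS/ML ancestral-state reconstruction.

Every model is a multivariate normal for the tip values with mean
``z0 * 1`` and a covariance matrix that is a transform of the
Brownian-motion matrix C (shared root-to-MRCA path lengths):

* BM:      ``sigma2 * C``
* lambda:  off-diagonal entries multiplied by ``lam`` (signal strength)
* delta:   entries raised to ``delta`` (node-depth-dependent rates)
* kappa:   branch lengths raised to ``kappa`` before summing paths
* OU:      ``sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij))``
           with ``d_ij`` the patristic tip distance and ``s_ij`` the
           shared depth (fixed-root, non-stationary form)
* ACDC:    ``sigma2 * (exp(r s_ij) - 1) / r`` (exponential rate change)
* BMS:     branch lengths multiplied by per-branch rate scalars

``z0`` and ``sigma2`` are profiled analytically via GLS; the remaining
shape parameter is optimized numerically on a deterministic multi-start
grid followed by bounded refinement.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .trees import TreeArrays, as_tree_arrays

__all__ = [
    "MODEL_NAMES", "ModelSpec", "ModelFit", "AncestralStates",
    "phylo_vcv", "model_vcv", "transformed_blens", "loglik", "aicc",
    "fit_model", "search_rate_shifts", "fit_all_scenarios",
    "ancestral_states",
]

MODEL_NAMES = ("BM", "BMS", "lambda", "delta", "kappa", "OU", "ACDC")

# admissible ranges for the shape parameters (per-Myr units where rates
# are involved); the grid start points for the multi-start optimizer are
# spread over these ranges
_BOUNDS = {
    "lambda": (0.0, 1.0),
    "delta": (1e-2, 3.0),
    "kappa": (0.0, 3.0),
    "OU": (1e-8, 50.0),
    "ACDC": (-0.1, 0.1),
}
_PARAM_KEY = {"lambda": "lambda", "delta": "delta", "kappa": "kappa",
              "OU": "alpha", "ACDC": "r"}


@dataclass
class ModelSpec:
    """Which evolutionary scenario to fit.

    ``n_shifts``/``shift_locations`` only apply to BMS; locations are
    branch keys (tuples of descendant tip labels, see
    ``TreeArrays.branch_key``).  If locations are omitted they are
    searched, which costs extra AICc parameters.  ``regime`` controls
    whether a shift rescales the named branch plus its whole descendant
    clade (``"clade"``, the default and the usual rate-shift semantics)
    or the named branch alone (``"branch"``); the two coincide on
    terminal branches.
    """
    name: str
    n_shifts: int = 0
    shift_locations: list = field(default_factory=list)
    regime: str = "clade"

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")
        if self.name == "BMS" and not (0 <= self.n_shifts <= 4):
            raise ValueError("BMS supports 0-4 rate shifts")
        if self.regime not in ("clade", "branch"):
            raise ValueError("regime must be 'clade' or 'branch'")


@dataclass
class ModelFit:
    """A fitted model: parameter estimates, log-likelihood and AICc."""
    spec: ModelSpec
    params: dict
    loglik: float
    k: int
    n: int
    aicc: float

    def to_dict(self):
        d = {"model": self.spec.name, "params": dict(self.params),
             "loglik": self.loglik, "k": self.k, "n": self.n, "aicc": self.aicc}
        if self.spec.name == "BMS":
            d["n_shifts"] = self.spec.n_shifts
            d["shift_branches"] = ["+".join(key) for key in self.spec.shift_locations]
        return d


def _trait_vector(ta: TreeArrays, traits) -> np.ndarray:
    """Align a mapping/Series of species -> value with the tip order."""
    missing = [l for l in ta.tip_labels if l not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing}")
    return np.array([float(traits[l]) for l in ta.tip_labels])


# ----------------------------------------------------------------------
# covariance construction
# ----------------------------------------------------------------------

def phylo_vcv(tree) -> np.ndarray:
    """Brownian-motion design matrix: shared root-to-MRCA path lengths."""
    return as_tree_arrays(tree).vcv()


def _shift_masks(ta: TreeArrays, spec: ModelSpec):
    """Per-shift boolean masks over nodes whose subtending branch the
    shift rescales (the branch alone, or the branch plus its clade)."""
    masks = []
    for key in spec.shift_locations:
        node = None
        for v in range(1, ta.n_nodes):
            if ta.branch_key(v) == tuple(key):
                node = v
                break
        if node is None:
            raise ValueError(f"shift branch {key!r} not found in tree")
        if spec.regime == "clade":
            masks.append(ta.anc[node].copy())
        else:
            m = np.zeros(ta.n_nodes, dtype=bool)
            m[node] = True
            masks.append(m)
    return masks


def _rates_vector(ta: TreeArrays, spec: ModelSpec, params) -> np.ndarray:
    rates = np.ones(ta.n_nodes)
    for j, mask in enumerate(_shift_masks(ta, spec)):
        rates[mask] *= float(params[f"rate_{j + 1}"])
    return rates


def transformed_blens(ta: TreeArrays, name: str, params, spec: ModelSpec = None):
    """Branch lengths whose path sums realize the model covariance.

    For OU/delta/ACDC the transform is depth-based and exact on
    ultrametric trees (the study trees are time-calibrated, hence
    ultrametric).
    """
    d_par = ta.depth[ta.parent]
    d_par[0] = 0.0
    if name == "BM":
        return ta.blen.copy()
    if name == "BMS":
        return ta.blen * _rates_vector(ta, spec, params)
    if name == "kappa":
        k = float(params["kappa"])
        out = ta.blen ** k
        out[0] = 0.0
        return out
    if name == "lambda":
        lam = float(params["lambda"])
        out = lam * ta.blen
        # tip branches are stretched so tip depths are preserved
        out[ta.is_tip] = ta.blen[ta.is_tip] + (1 - lam) * d_par[ta.is_tip]
        return out
    if name == "delta":
        dl = float(params["delta"])
        return ta.depth ** dl - d_par ** dl
    if name == "ACDC":
        r = float(params["r"])
        if abs(r) < 1e-12:
            return ta.blen.copy()
        return (np.expm1(r * ta.depth) - np.expm1(r * d_par)) / r
    if name == "OU":
        a = float(params["alpha"])
        if a < 1e-12:
            return ta.blen.copy()
        T = ta.depth[ta.tip_nodes].max()
        g = np.exp(2 * a * (ta.depth - T)) - np.exp(2 * a * (d_par - T))
        return g / (2 * a)
    raise ValueError(f"unknown model {name!r}")


def model_vcv(tree, spec, params) -> np.ndarray:
    """Tip covariance matrix implied by a model and its parameters.

    ``spec`` may be a ModelSpec or a model name.  ``params`` must
    contain ``sigma2`` plus the model's shape parameters; at neutral
    shape values every model reduces to ``sigma2 * phylo_vcv``.
    """
    ta = as_tree_arrays(tree)
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    s2 = float(params.get("sigma2", 1.0))
    if s2 <= 0:
        raise ValueError("sigma2 must be positive")
    name = spec.name
    if name == "lambda":
        lam = float(params["lambda"])
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        C = ta.vcv()
        V = lam * C + (1 - lam) * np.diag(np.diag(C))
        return s2 * V
    if name == "delta":
        dl = float(params["delta"])
        if dl <= 0:
            raise ValueError("delta must be positive")
        return s2 * ta.vcv() ** dl
    if name == "kappa":
        if float(params["kappa"]) < 0:
            raise ValueError("kappa must be non-negative")
    if name == "OU":
        a = float(params["alpha"])
        if a < 0:
            raise ValueError("alpha must be non-negative")
        if a >= 1e-12:
            C = ta.vcv()
            t = np.diag(C)
            d = t[:, None] + t[None, :] - 2 * C
            return s2 / (2 * a) * np.exp(-a * d) * (1 - np.exp(-2 * a * C))
    if name == "ACDC":
        r = float(params["r"])
        if abs(r) >= 1e-12:
            return s2 * np.expm1(r * ta.vcv()) / r
    bl = transformed_blens(ta, name, params, spec)
    return s2 * ta.vcv(bl)


# ----------------------------------------------------------------------
# likelihood, AICc
# ----------------------------------------------------------------------

def _mvn_profile(V0: np.ndarray, x: np.ndarray):
    """Profile z0 and sigma2 out of a MVN with covariance sigma2*V0.

    Returns (loglik at the profile optimum, z0_hat, sigma2_hat).
    """
    n = x.size
    try:
        cf = linalg.cho_factor(V0, lower=True)
    except linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    logdet = 2 * np.log(np.diag(cf[0])).sum()
    one = np.ones(n)
    Vi1 = linalg.cho_solve(cf, one)
    z0 = float(Vi1 @ x / (Vi1 @ one))
    r = x - z0
    s2 = float(r @ linalg.cho_solve(cf, r) / n)
    if not np.isfinite(s2) or s2 <= 0:
        return -np.inf, z0, s2
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, z0, s2


def loglik(tree, traits, spec, params) -> float:
    """Multivariate-normal log density (nats) of the tip values.

    Mean is ``params['z0']`` (GLS-profiled if absent), covariance is
    ``model_vcv(tree, spec, params)``; ``sigma2`` likewise profiled if
    absent.
    """
    ta = as_tree_arrays(tree)
    x = _trait_vector(ta, traits)
    if "sigma2" not in params or "z0" not in params:
        V0 = model_vcv(ta, spec, {**params, "sigma2": 1.0})
        ll, _, _ = _mvn_profile(V0, x)
        return ll
    V = model_vcv(ta, spec, params)
    n = x.size
    try:
        cf = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular model covariance") from e
    logdet = 2 * np.log(np.diag(cf[0])).sum()
    r = x - float(params["z0"])
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ linalg.cho_solve(cf, r)))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: need n - k - 1 > 0")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _fit_shape_model(ta, x, name, n_starts=5, refine=True):
    lo, hi = _BOUNDS[name]
    key = _PARAM_KEY[name]
    if name in ("delta", "OU"):
        grid = np.geomspace(lo, hi, 21)
    else:
        grid = np.linspace(lo, hi, 21)

    def profile(theta):
        V0 = model_vcv(ta, name, {key: theta, "sigma2": 1.0})
        return _mvn_profile(V0, x)[0]

    vals = np.array([profile(t) for t in grid])
    best = int(np.nanargmax(vals))
    theta = grid[best]
    if refine:
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, grid.size - 1)]
        if b > a:
            res = optimize.minimize_scalar(
                lambda t: -profile(t), bounds=(a, b), method="bounded",
                options={"xatol": 1e-8})
            if np.isfinite(res.fun) and -res.fun >= vals[best]:
                theta = float(res.x)
    V0 = model_vcv(ta, name, {key: theta, "sigma2": 1.0})
    ll, z0, s2 = _mvn_profile(V0, x)
    return {key: theta, "sigma2": s2, "z0": z0}, ll


def _fit_bms(ta, x, spec, n_starts=3):
    s = len(spec.shift_locations)
    if s == 0:
        V0 = ta.vcv()
        ll, z0, s2 = _mvn_profile(V0, x)
        return {"sigma2": s2, "z0": z0}, ll
    masks = _shift_masks(ta, spec)

    def profile(logr):
        bl = ta.blen.copy()
        for m, lr in zip(masks, logr):
            bl[m] *= np.exp(lr)
        return _mvn_profile(ta.vcv(bl), x)[0]

    starts = [np.zeros(s), np.full(s, np.log(10.0)), np.full(s, -np.log(10.0))][:n_starts]
    best_ll, best_logr = -np.inf, np.zeros(s)
    for x0 in starts:
        res = optimize.minimize(lambda v: -profile(v), x0, method="L-BFGS-B",
                                bounds=[(-12.0, 12.0)] * s)
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll, best_logr = -res.fun, res.x
    bl = ta.blen.copy()
    for m, lr in zip(masks, best_logr):
        bl[m] *= np.exp(lr)
    ll, z0, s2 = _mvn_profile(ta.vcv(bl), x)
    params = {"sigma2": s2, "z0": z0}
    for j in range(s):
        params[f"rate_{j+1}"] = float(np.exp(best_logr[j]))
        # relative sd on the shifted branch, background normalized to 1
        params[f"sigma_rel_{j+1}"] = float(np.exp(best_logr[j] / 2.0))
    return params, ll


def _k_params(spec: ModelSpec, locations_searched: bool) -> int:
    if spec.name == "BM":
        return 2
    if spec.name == "BMS":
        per_shift = 2 if locations_searched else 1
        return 2 + per_shift * len(spec.shift_locations)
    return 3


def fit_model(tree, traits, spec, locations_searched=False) -> ModelFit:
    """Maximum-likelihood fit of one evolutionary scenario.

    ``z0`` and ``sigma2`` are profiled analytically (GLS); shape
    parameters are optimized numerically.  ``locations_searched``
    controls whether BMS shift positions count as free parameters in
    AICc (they do when chosen by :func:`search_rate_shifts`).
    """
    ta = as_tree_arrays(tree)
    if isinstance(spec, str):
        spec = ModelSpec(spec)
    x = _trait_vector(ta, traits)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 tips to fit a model")
    if spec.name == "BM":
        ll, z0, s2 = _mvn_profile(ta.vcv(), x)
        params = {"sigma2": s2, "z0": z0}
    elif spec.name == "BMS":
        params, ll = _fit_bms(ta, x, spec)
    else:
        params, ll = _fit_shape_model(ta, x, spec.name)
    if not np.isfinite(ll):
        raise RuntimeError(f"optimizer failed to converge for model {spec.name}")
    # the ML variance divides by n although the root state is estimated;
    # report the df-corrected value as the headline rate (REML-style),
    # keeping the ML value used by the likelihood alongside
    s2_ml = params["sigma2"]
    params["sigma2_ml"] = s2_ml
    params["sigma2"] = s2_ml * n / (n - 1)
    k = _k_params(spec, locations_searched)
    return ModelFit(spec=spec, params=params, loglik=float(ll), k=k, n=n,
                    aicc=aicc(float(ll), k, n))


def search_rate_shifts(tree, traits, max_shifts=4, regime="clade") -> list:
    """Brownian motion with 0..max_shifts rate shifts.

    One shift: exhaustive scan over every branch as the shift location.
    More shifts: greedy forward addition.  Each shift multiplies the
    variance rate on its branch and (under the default clade regime)
    its descendants, and counts 2 AICc parameters (rate + searched
    location).  Returns one ModelFit per shift count: index 0 is plain
    BM, index s the best s-shift model.
    """
    if not 0 <= max_shifts <= 4:
        raise ValueError("max_shifts must be in 0..4")
    ta = as_tree_arrays(tree)
    fits = [fit_model(ta, traits, ModelSpec("BM"))]
    chosen: list = []
    all_keys = [ta.branch_key(v) for v in range(1, ta.n_nodes)]
    for s in range(1, max_shifts + 1):
        best = None
        for key in all_keys:
            if key in chosen:
                continue
            spec = ModelSpec("BMS", s, chosen + [key], regime=regime)
            fit = fit_model(ta, traits, spec, locations_searched=True)
            if best is None or fit.loglik > best.loglik:
                best = fit
        if best is None:
            break
        chosen = list(best.spec.shift_locations)
        fits.append(best)
    return fits


def fit_all_scenarios(tree, traits, max_shifts=4, regime="clade") -> list:
    """The ten standard scenarios: BM, BMS with 1-4 shifts, Pagel's
    lambda/delta/kappa, OU and ACDC, each as a ModelFit."""
    fits = search_rate_shifts(tree, traits, max_shifts, regime=regime)
    for name in ("lambda", "delta", "kappa", "OU", "ACDC"):
        fits.append(fit_model(tree, traits, ModelSpec(name)))
    return fits


# ----------------------------------------------------------------------
# ancestral states
# ----------------------------------------------------------------------

@dataclass
class AncestralStates:
    """GLS/ML trait estimates (and variances) for every node.

    ``estimates``/``variances`` are indexed by preorder node index;
    ``by_key`` maps branch keys (tuples of descendant tip labels) to
    (estimate, variance).  Tip entries reproduce the observed values
    with zero variance.
    """
    tree: TreeArrays
    estimates: np.ndarray
    variances: np.ndarray

    def at_node(self, node):
        return float(self.estimates[node]), float(self.variances[node])

    def at_mrca(self, labels):
        return self.at_node(self.tree.mrca_of_tips(labels))

    @property
    def root(self):
        return self.at_node(0)

    def by_key(self):
        return {self.tree.branch_key(v): self.at_node(v)
                for v in range(self.tree.n_nodes)}


def ancestral_states(tree, traits, fit: ModelFit) -> AncestralStates:
    """Maximum-likelihood ancestral values under a fitted model.

    Internal-node values maximize the joint Gaussian likelihood of the
    tree-structured model given the tips (the quadratic optimum of the
    sum of branchwise Gaussian increments), which coincides with the
    GLS/BLUP estimates; the root estimate equals the GLS mean
    ``(1' V^-1 x) / (1' V^-1 1)``.  Variances are prediction variances
    that account for the estimated root mean.
    """
    ta = as_tree_arrays(tree)
    x = _trait_vector(ta, traits)
    s2 = float(fit.params.get("sigma2", 1.0))
    bl = transformed_blens(ta, fit.spec.name, fit.params, fit.spec)
    bl = np.maximum(bl, 1e-12)

    internal = np.where(~ta.is_tip)[0]
    pos = {v: i for i, v in enumerate(internal)}
    m = internal.size
    A = np.zeros((m, m))
    b = np.zeros(m)
    tipval = np.zeros(ta.n_nodes)
    tipval[ta.tip_nodes] = x
    for v in range(1, ta.n_nodes):
        p = ta.parent[v]
        w = 1.0 / bl[v]
        if ta.is_tip[v]:
            A[pos[p], pos[p]] += w
            b[pos[p]] += w * tipval[v]
        else:
            A[pos[p], pos[p]] += w
            A[pos[v], pos[v]] += w
            A[pos[p], pos[v]] -= w
            A[pos[v], pos[p]] -= w
    try:
        u = linalg.solve(A, b, assume_a="pos")
    except linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular ancestral-state system") from e

    est = np.zeros(ta.n_nodes)
    est[ta.tip_nodes] = x
    est[internal] = u

    # prediction variances under the transformed-tree covariance
    tdep = ta.path_depths(bl)
    V0 = tdep[ta.mrca_tips]
    cf = linalg.cho_factor(V0, lower=True)
    one = np.ones(ta.n_tips)
    Vi1 = linalg.cho_solve(cf, one)
    denom = float(one @ Vi1)
    var = np.zeros(ta.n_nodes)
    mrca_nt = ta.mrca_nodes[:, ta.tip_nodes]      # (n_nodes, n_tips)
    for v in internal:
        c = tdep[mrca_nt[v]]
        Vic = linalg.cho_solve(cf, c)
        var[v] = s2 * max(
            tdep[v] - c @ Vic + (1.0 - one @ Vic) ** 2 / denom, 0.0)
    return AncestralStates(tree=ta, estimates=est, variances=var)
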