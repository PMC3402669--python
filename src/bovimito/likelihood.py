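"""Fixed-topology GTR+Gamma likelihood, clock tests and branch support.

The engine evaluates alignment likelihoods by Felsenstein pruning over
unique site patterns under a general time-reversible model with discrete
gamma rate heterogeneity, optimizes branch lengths (and optionally model
parameters) on a fixed topology, performs the likelihood-ratio test of the
molecular clock (free branch lengths vs an ultrametric height
parameterization), computes aLRT branch supports against the best NNI
alternative, and provides the harmonic-mean marginal-likelihood / Bayes
factor arithmetic for externally produced MCMC traces.

Branch lengths are expected substitutions per site: the rate matrix is
normalized so the mean substitution rate at stationarity is one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .genome import GAP, IUPAC, MultiAlignment
from .trees import Node, RootedTree

ACGT = "ACGT"
RATE_KEYS = ("AC", "AG", "AT", "CG", "CT", "GT")
_TRANSITIONS = {"AG", "CT"}


# ---------------------------------------------------------------------------
# substitution model

@dataclass
class SubstitutionModel:
    """GTR exchangeabilities + base frequencies + discrete gamma shape.

    ``rates`` maps the six unordered pairs to non-negative exchangeabilities
    with GT fixed at 1 for identifiability.  ``alpha`` is the gamma shape;
    ``n_categories`` discrete categories approximate the gamma by the mean
    of equal-probability quantile bins.
    """

    rates: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in RATE_KEYS})
    pi: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (4,) or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must be 4 frequencies summing to 1")
        if any(self.rates.get(k, -1) < 0 for k in RATE_KEYS):
            raise ValueError("exchangeabilities must be non-negative")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        self._decomp: tuple | None = None

    # -- construction helpers ------------------------------------------

    @classmethod
    def jc(cls, alpha: float | None = None, n_categories: int = 1
           ) -> "SubstitutionModel":
        """Jukes-Cantor: equal rates, equal frequencies."""
        if alpha is None:
            return cls(alpha=1.0, n_categories=1)
        return cls(alpha=alpha, n_categories=n_categories)

    @classmethod
    def from_alignment(cls, aln: MultiAlignment, rates=None,
                       alpha: float = 1.0, n_categories: int = 4
                       ) -> "SubstitutionModel":
        """Model with empirical base frequencies counted from the alignment."""
        counts = np.zeros(4)
        for row in aln.rows:
            for i, b in enumerate(ACGT):
                counts[i] += row.count(b)
        pi = counts / counts.sum()
        return cls(rates=dict(rates) if rates else
                   {k: 1.0 for k in RATE_KEYS},
                   pi=pi, alpha=alpha, n_categories=n_categories)

    # -- derived quantities --------------------------------------------

    @property
    def kappa(self) -> float:
        """Transition/transversion ratio implied by rates and frequencies."""
        idx = {b: i for i, b in enumerate(ACGT)}
        ts = tv = 0.0
        for key, s in self.rates.items():
            i, j = idx[key[0]], idx[key[1]]
            flux = self.pi[i] * self.pi[j] * s
            if key in _TRANSITIONS:
                ts += flux
            else:
                tv += flux
        return ts / tv

    def q_matrix(self) -> np.ndarray:
        """Normalized GTR rate matrix (rows sum to zero, mean rate 1)."""
        idx = {b: i for i, b in enumerate(ACGT)}
        Q = np.zeros((4, 4))
        for key, s in self.rates.items():
            i, j = idx[key[0]], idx[key[1]]
            Q[i, j] = s * self.pi[j]
            Q[j, i] = s * self.pi[i]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.pi, np.diag(Q)))
        return Q / mu

    def category_rates(self) -> np.ndarray:
        """Mean-of-quantile-bin discrete gamma rates (mean exactly 1)."""
        k = self.n_categories
        if k == 1:
            return np.ones(1)
        a = self.alpha
        bounds = stats.gamma.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        edges = np.concatenate([[0.0], bounds * a, [np.inf]])
        # mean within each bin of Gamma(a, rate a): uses the shape a+1 CDF
        upper = special.gammainc(a + 1, edges[1:])
        lower = special.gammainc(a + 1, edges[:-1])
        rates = k * (upper - lower)
        return rates / rates.mean()

    def _decomposition(self):
        if self._decomp is None:
            Q = self.q_matrix()
            sq = np.sqrt(self.pi)
            B = (Q * sq[:, None]) / sq[None, :]
            B = (B + B.T) / 2.0  # symmetric by reversibility; enforce exactly
            w, U = np.linalg.eigh(B)
            left = U.T * sq[None, :]
            right = U / sq[:, None]
            self._decomp = (w, right, left)
        return self._decomp

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t * r_c) for every gamma category; shape (ncat, 4, 4)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        w, right, left = self._decomposition()
        rates = self.category_rates()
        expw = np.exp(np.outer(rates * t, w))           # (ncat, 4)
        P = np.einsum("ik,ck,kj->cij", right, expw, left)
        P[np.abs(P) < 1e-12] = 0.0  # decomposition noise, not probability
        return np.clip(P, 0.0, 1.0, out=P)

    def invalidate(self) -> None:
        self._decomp = None


# ---------------------------------------------------------------------------
# alignment encoding

def _char_partial(c: str) -> np.ndarray:
    v = np.zeros(4)
    if c == GAP or c not in IUPAC:
        return np.ones(4)
    for b in IUPAC[c]:
        v[ACGT.index(b)] = 1.0
    return v


@dataclass
class PatternData:
    """Pattern-compressed alignment ready for pruning."""

    taxa: list[str]
    partials: dict[str, np.ndarray]   # taxon -> (npat, 4)
    weights: np.ndarray               # (npat,)
    first_column: np.ndarray          # representative column per pattern

    @classmethod
    def from_alignment(cls, aln: MultiAlignment,
                       compress: bool = True) -> "PatternData":
        rows = np.array([list(r) for r in aln.rows])
        if compress:
            cols, first, counts = np.unique(
                rows, axis=1, return_index=True, return_counts=True)
        else:
            cols = rows
            first = np.arange(rows.shape[1])
            counts = np.ones(rows.shape[1])
        lut = {}
        partials = {}
        for i, taxon in enumerate(aln.taxa):
            mats = []
            for c in cols[i]:
                if c not in lut:
                    lut[c] = _char_partial(c)
                mats.append(lut[c])
            partials[taxon] = np.array(mats)
        return cls(list(aln.taxa), partials, counts.astype(float), first)


# ---------------------------------------------------------------------------
# pruning

class ZeroLikelihoodSite(ValueError):
    pass


def _pruning_lnl(data: PatternData, tree: RootedTree,
                 model: SubstitutionModel) -> float:
    ncat = model.n_categories
    npat = len(data.weights)
    log_scale = np.zeros(npat)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in data.partials:
                raise KeyError(f"leaf {node.label!r} missing from alignment")
            partial[id(node)] = np.broadcast_to(
                data.partials[node.label], (ncat, npat, 4))
            continue
        acc = np.ones((ncat, npat, 4))
        for child in node.children:
            P = model.transition_matrices(child.length)
            acc = acc * np.einsum("cij,cpj->cpi", P, partial[id(child)])
        if node is not tree.root:
            mx = acc.max(axis=(0, 2))
            bad = mx <= 0
            if np.any(bad):
                col = int(data.first_column[np.argmax(bad)])
                raise ZeroLikelihoodSite(
                    f"zero likelihood at alignment column {col + 1}")
            acc = acc / mx[None, :, None]
            log_scale += np.log(mx)
        partial[id(node)] = acc
        for child in node.children:
            del partial[id(child)]
    root = partial[id(tree.root)]
    site = np.einsum("cpi,i->p", root, model.pi) / ncat
    if np.any(site <= 0):
        col = int(data.first_column[int(np.argmax(site <= 0))])
        raise ZeroLikelihoodSite(
            f"zero likelihood at alignment column {col + 1}")
    return float(np.dot(data.weights, np.log(site) + log_scale))


def log_likelihood(aln: MultiAlignment, tree: RootedTree,
                   model: SubstitutionModel, compress: bool = True) -> float:
    """Log-likelihood of the alignment on the tree under GTR+Gamma.

    Gap and ambiguity characters are treated as missing data (all-ones
    partial likelihoods); the gamma mixture is averaged with equal category
    weights.
    """
    data = PatternData.from_alignment(aln, compress=compress)
    return _pruning_lnl(data, tree, model)


# ---------------------------------------------------------------------------
# branch-length / model optimization

MAX_BRANCH = 20.0


def optimize_branch_lengths(
    aln: MultiAlignment, tree: RootedTree, model: SubstitutionModel,
    optimize_model: bool = False, max_sweeps: int = 100,
    tol: float = 1e-6,
) -> tuple[RootedTree, SubstitutionModel, float]:
    """Cyclic univariate branch optimization, optionally with model fitting.

    Each sweep optimizes every branch in turn by bounded scalar search;
    when ``optimize_model`` is set, the gamma shape and exchangeabilities
    are refit after each sweep.  The log-likelihood is non-decreasing
    across sweeps and iteration stops once a full sweep improves it by
    less than ``tol``.
    """
    tree = tree.copy()
    model = SubstitutionModel(rates=dict(model.rates), pi=model.pi.copy(),
                              alpha=model.alpha,
                              n_categories=model.n_categories)
    data = PatternData.from_alignment(aln)
    nodes = [n for n in tree.postorder() if n is not tree.root]
    lnl = _pruning_lnl(data, tree, model)
    for _ in range(max_sweeps):
        prev = lnl
        for node in nodes:
            def neg(t: float, node=node) -> float:
                node.length = t
                return -_pruning_lnl(data, tree, model)

            res = optimize.minimize_scalar(
                neg, bounds=(1e-9, MAX_BRANCH), method="bounded",
                options={"xatol": 1e-9})
            node.length = float(res.x)
            lnl = -float(res.fun)
        if optimize_model:
            lnl = _fit_model(data, tree, model, lnl)
        if lnl - prev < tol:
            break
    else:
        import warnings
        warnings.warn("branch-length optimization did not converge; "
                      "returning best-so-far", RuntimeWarning)
    return tree, model, lnl


def _fit_model(data: PatternData, tree: RootedTree,
               model: SubstitutionModel, lnl: float) -> float:
    if model.n_categories > 1:
        def neg_alpha(la: float) -> float:
            model.alpha = math.exp(la)
            model.invalidate()
            return -_pruning_lnl(data, tree, model)

        res = optimize.minimize_scalar(neg_alpha, bounds=(-4.0, 5.0),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        model.alpha = math.exp(float(res.x))
        model.invalidate()
        lnl = -float(res.fun)

    free = [k for k in RATE_KEYS if k != "GT"]

    def neg_rates(x: np.ndarray) -> float:
        for k, v in zip(free, x):
            model.rates[k] = math.exp(v)
        model.invalidate()
        return -_pruning_lnl(data, tree, model)

    x0 = np.clip(np.log([max(model.rates[k], 1e-8) for k in free]), -7, 7)
    res = optimize.minimize(neg_rates, x0, method="L-BFGS-B",
                            bounds=[(-7.0, 7.0)] * len(free),
                            options={"maxiter": 50})
    for k, v in zip(free, res.x):
        model.rates[k] = math.exp(v)
    model.invalidate()
    return -float(res.fun)


# ---------------------------------------------------------------------------
# molecular clock LRT

@dataclass(frozen=True)
class ClockTestResult:
    lnl_free: float
    lnl_clock: float
    statistic: float
    df: int
    p_value: float
    free_tree: RootedTree
    clock_tree: RootedTree


def _apply_heights(tree: RootedTree, x: np.ndarray,
                   internals: list[Node]) -> None:
    """Map unconstrained parameters to an ultrametric branch assignment."""
    heights: dict[int, float] = {}
    root_h = math.exp(x[0])
    heights[id(tree.root)] = root_h
    for node, xi in zip(internals[1:], x[1:]):
        frac = 1.0 / (1.0 + math.exp(-xi))
        heights[id(node)] = frac * heights[id(node.parent)]
    for node in tree.preorder():
        if node is tree.root:
            continue
        h = 0.0 if node.is_leaf else heights[id(node)]
        node.length = max(heights[id(node.parent)] - h, 1e-12)


def clock_lrt(aln: MultiAlignment, topology: RootedTree,
              model: SubstitutionModel,
              optimize_model: bool = False) -> ClockTestResult:
    """Likelihood-ratio test of rate constancy on a fixed topology.

    The free model has one length per branch (2n-3 effective parameters);
    the clock model constrains the tree to be ultrametric, parameterized by
    n-1 node heights.  The statistic 2(lnL_free - lnL_clock) is referred to
    a chi-square with n-2 degrees of freedom.
    """
    n_taxa = len(topology.leaves())
    if n_taxa < 3:
        raise ValueError("clock test needs at least 3 taxa")
    free_tree, fit_model, lnl_free = optimize_branch_lengths(
        aln, topology, model, optimize_model=optimize_model)

    clock = free_tree.copy()
    data = PatternData.from_alignment(aln)
    internals = [n for n in clock.preorder() if not n.is_leaf]
    # initial heights from the free tree's mean depths
    x0 = []
    h0: dict[int, float] = {}
    for node in internals:
        depths = clock.depths_to_tips(node)
        h0[id(node)] = max(float(np.mean(depths)), 1e-8)
    x0.append(math.log(h0[id(clock.root)]))
    for node in internals[1:]:
        frac = min(max(h0[id(node)] / h0[id(node.parent)], 1e-6), 1 - 1e-6)
        x0.append(math.log(frac / (1 - frac)))

    def neg(x: np.ndarray) -> float:
        _apply_heights(clock, x, internals)
        return -_pruning_lnl(data, clock, fit_model)

    res = optimize.minimize(neg, np.array(x0), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-9,
                                     "maxiter": 4000})
    res2 = optimize.minimize(neg, res.x, method="L-BFGS-B",
                             options={"maxiter": 200})
    best = res2 if res2.fun < res.fun else res
    _apply_heights(clock, best.x, internals)
    lnl_clock = -float(best.fun)

    if lnl_clock > lnl_free + 1e-6:
        raise RuntimeError(
            "clock likelihood exceeds free likelihood: optimizer failure "
            f"({lnl_clock:.6f} > {lnl_free:.6f})")
    stat = max(2.0 * (lnl_free - lnl_clock), 0.0)
    df = n_taxa - 2
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return ClockTestResult(lnl_free, lnl_clock, stat, df, p,
                           free_tree, clock)


# ---------------------------------------------------------------------------
# aLRT branch support

def _nni_swaps(tree: RootedTree, v: Node) -> list[RootedTree] | None:
    """The two NNI rearrangements across the (unrooted) edge above ``v``."""
    u = v.parent
    assert u is not None and not v.is_leaf
    if u is tree.root and len(u.children) == 2:
        s = next(c for c in u.children if c is not v)
        if s.is_leaf:
            return None  # pendant edge in unrooted terms
        donors = [(v, v.children[0]), (v, v.children[0])]
        partners = [(s, s.children[0]), (s, s.children[1])]
    else:
        others = [c for c in u.children if c is not v]
        if not others:
            return None
        w = others[0]
        donors = [(u, w), (u, w)]
        partners = [(v, v.children[0]), (v, v.children[1])]
    alts = []
    for (pa, ca), (pb, cb) in zip(donors, partners):
        alt = tree.copy()
        # relocate nodes in the copy via their leaf sets
        def find(orig: Node) -> Node:
            target = tree.clade_leaves(orig) if not orig.is_leaf \
                else frozenset([orig.label])
            for n in alt.postorder():
                key = alt.clade_leaves(n) if not n.is_leaf \
                    else frozenset([n.label])
                if key == target:
                    return n
            raise RuntimeError("node not found in copy")

        na, nb = find(ca), find(cb)
        qa, qb = na.parent, nb.parent
        qa.children[qa.children.index(na)] = nb
        qb.children[qb.children.index(nb)] = na
        na.parent, nb.parent = qb, qa
        alts.append(RootedTree(alt.root))
    return alts


def alrt_support(aln: MultiAlignment, tree: RootedTree,
                 model: SubstitutionModel) -> dict[str, float | None]:
    """Approximate likelihood-ratio branch supports.

    For each internal branch the statistic is twice the log-likelihood gap
    between the optimized tree and its best NNI rearrangement of that
    branch; support is 1 - p under the half-and-half chi-square mixture
    (one half point mass at zero, one half chi-square with 1 df).
    Degenerate branches (no NNI alternative) are reported as None.
    """
    opt_tree, opt_model, lnl_best = optimize_branch_lengths(aln, tree, model)
    supports: dict[str, float | None] = {}
    seen_root_edge = False
    for v in list(opt_tree.postorder()):
        if v.is_leaf or v is opt_tree.root:
            continue
        if v.parent is opt_tree.root and len(opt_tree.root.children) == 2:
            if seen_root_edge:
                continue  # both root children name the same unrooted edge
            seen_root_edge = True
        bid = opt_tree.branch_id(v)
        alts = _nni_swaps(opt_tree, v)
        if alts is None:
            supports[bid] = None
            continue
        alt_lnls = []
        for alt in alts:
            _, _, l = optimize_branch_lengths(aln, alt, opt_model)
            alt_lnls.append(l)
        stat = max(2.0 * (lnl_best - max(alt_lnls)), 0.0)
        p = 0.5 * float(stats.chi2.sf(stat, 1)) if stat > 0 else 1.0
        supports[bid] = 1.0 - p
        v.support = 1.0 - p
    return supports


# ---------------------------------------------------------------------------
# harmonic-mean model likelihoods / Bayes factors

def harmonic_mean_loglik(samples: Sequence[float]) -> float:
    """Log harmonic mean of likelihoods given per-draw log-likelihoods.

    Computed stably in log space: log HM = log n - logsumexp(-x).
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size == 0:
        raise ValueError("no likelihood samples supplied")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite log-likelihood samples")
    return float(math.log(x.size) - special.logsumexp(-x))


def bayes_factor(loglik_a: float, loglik_b: float) -> float:
    """Log Bayes factor of model A over model B from harmonic-mean values."""
    return loglik_a - loglik_b


def read_trace(path: str | Path) -> list[float]:
    """Read a likelihood trace: one float per line, '#' starts a comment."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(float(line))
    return out
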