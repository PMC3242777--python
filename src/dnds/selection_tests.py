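"""Likelihood-ratio tests between nested codon models and Bayes Empirical
Bayes identification of positively selected sites.

The LRT statistic is twice the log-likelihood difference of a nested model
pair, referred to a chi-square distribution whose degrees of freedom equal
the difference in free omega-structure parameters. The plain chi-square is
used for every comparison, including those whose null places a parameter on
a boundary; this is conservative for the branch-site test.

BEB integrates the branch-site site-class posteriors over a discrete prior
grid on the mixture parameters (p0, p1, omega0, omega2), with kappa and the
branch lengths fixed at their maximum-likelihood estimates, so that sampling
error in the mixture parameters is accounted for without assigning them a
point estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .codon_models import (
    FitResult,
    LikelihoodEngine,
    MODEL_CATALOG,
    fit_model,
    raw_substitution_rate,
)
from .seqdata import CodonAlignment, PhyloTree

__all__ = [
    "NESTED_PAIRS",
    "LRTResult",
    "BEBResult",
    "lrt",
    "beb_site_posteriors",
    "classify_sites",
    "fit_nested_pair",
    "foreground_candidate_report",
    "BEB_GRID_SIZE",
]

#: number of prior categories per BEB grid dimension
BEB_GRID_SIZE = 10

#: registered nested pairs: (null, alternative) -> degrees of freedom;
#: "n_branches-1" is resolved at test time for the branch-model comparison
NESTED_PAIRS: dict[tuple[str, str], object] = {
    ("M1a", "M2a"): 2,
    ("M7", "M8"): 2,
    ("M8a", "M8"): 1,
    ("branch0", "branch1"): "n_branches-1",
    ("branch0", "branch2_strict"): 1,
    ("branch2_relaxed", "branch2_strict"): 1,
    ("A1", "A2"): 1,
}

_NEG_TOL = 1e-4


@dataclass
class LRTResult:
    null_model: str
    alt_model: str
    two_delta: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "null": self.null_model,
            "alt": self.alt_model,
            "two_delta": self.two_delta,
            "df": self.df,
            "p_value": self.p_value,
        }


def lrt(null_fit: FitResult, alt_fit: FitResult) -> LRTResult:
    """Chi-square LRT between a registered nested model pair."""
    pair = (null_fit.model_name, alt_fit.model_name)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"{pair[0]} and {pair[1]} are not a registered nested pair")
    df = NESTED_PAIRS[pair]
    if df == "n_branches-1":
        df = alt_fit.tree.n_branches - 1
    two_delta = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if two_delta < 0:
        if two_delta < -_NEG_TOL:
            warnings.warn(
                f"negative LRT statistic {two_delta:.6g} "
                f"({pair[0]} vs {pair[1]}); clamping to 0 — optimiser noise "
                "or non-convergence",
                RuntimeWarning,
            )
        two_delta = 0.0
    p = float(chi2.sf(two_delta, df))
    return LRTResult(pair[0], pair[1], float(two_delta), int(df), p)


# ---------------------------------------------------------------------------
# Warm-started nested fitting
# ---------------------------------------------------------------------------


def _embed_null_params(null_fit: FitResult, alt_model: str) -> dict:
    """Express a null model's MLE as a starting point inside the alternative."""
    p = dict(null_fit.params)
    name = null_fit.model_name
    start: dict = {"kappa": null_fit.kappa, "lengths": null_fit.branch_lengths}
    if (name, alt_model) == ("M1a", "M2a"):
        start.update(p0=p["p0"], s1=1.0 - 1e-6, omega0=p["omega0"], omega2=2.0)
    elif (name, alt_model) == ("M7", "M8"):
        start.update(p=p["p"], q=p["q"], p0=1.0 - 1e-3, omega_s=2.0)
    elif (name, alt_model) == ("M8a", "M8"):
        start.update(p=p["p"], q=p["q"], p0=p["p0"], omega_s=1.0)
    elif (name, alt_model) == ("branch0", "branch1"):
        start.update(
            {f"omega_b{i}": p["omega"] for i in range(null_fit.tree.n_branches)}
        )
    elif (name, alt_model) == ("branch0", "branch2_strict"):
        w = min(p["omega"], 1.0)
        start.update(omega_bg=w, omega_fg=p["omega"])
    elif (name, alt_model) == ("branch2_relaxed", "branch2_strict"):
        start.update(omega_bg=p["omega_bg"], omega_fg=1.0)
    elif (name, alt_model) == ("A1", "A2"):
        start.update(p0=p["p0"], s1=p["s1"], omega0=p["omega0"], omega2=1.0)
    else:
        raise ValueError(f"no embedding registered for {name} in {alt_model}")
    return start


def fit_nested_pair(
    alignment: CodonAlignment,
    tree: PhyloTree,
    null_model: str,
    alt_model: str,
    *,
    restarts: int = 3,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[FitResult, FitResult, LRTResult]:
    """Fit a registered nested pair and test it.

    The alternative is additionally started from the null MLE embedded in the
    alternative's parameter space, which guarantees the optimised alternative
    log-likelihood is at least the null's (up to optimiser tolerance).
    """
    if (null_model, alt_model) not in NESTED_PAIRS:
        raise ValueError(f"{null_model} and {alt_model} are not a registered nested pair")
    null_fit = fit_model(
        alignment, tree, null_model, restarts=restarts, seed=seed, **fit_kwargs
    )
    embed = _embed_null_params(null_fit, alt_model)
    if not fit_kwargs.get("optimize_branches", True):
        embed.pop("lengths", None)
    alt_fit = fit_model(
        alignment,
        tree,
        alt_model,
        restarts=restarts + 1,
        seed=seed + 1,
        extra_starts=[embed],
        **fit_kwargs,
    )
    return null_fit, alt_fit, lrt(null_fit, alt_fit)


# ---------------------------------------------------------------------------
# Bayes Empirical Bayes
# ---------------------------------------------------------------------------


@dataclass
class BEBResult:
    """Per-site posteriors over the four branch-site classes.

    ``positive_posterior`` is the probability that a site belongs to a class
    with foreground omega > 1 (classes 2a + 2b); ``omega_mean`` is the
    posterior mean foreground omega at the site.
    """

    site_posteriors: np.ndarray  # (n_sites, 4)
    positive_posterior: np.ndarray  # (n_sites,)
    omega_mean: np.ndarray  # (n_sites,)
    class_labels: tuple[str, ...] = ("0", "1", "2a", "2b")

    @property
    def n_sites(self) -> int:
        return len(self.positive_posterior)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.site_posteriors, columns=[f"P(class {c})" for c in self.class_labels]
        )
        df.insert(0, "site", np.arange(1, self.n_sites + 1))
        df["P(omega>1)"] = self.positive_posterior
        df["mean_omega"] = self.omega_mean
        tiers = classify_sites(self)
        tier = np.full(self.n_sites, "", dtype=object)
        for s in tiers["0.95<P<=0.99"]:
            tier[s] = "*"
        for s in tiers["P>0.99"]:
            tier[s] = "**"
        df["flag"] = tier
        return df


def _beb_grid(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Prior grid: (p0, p1) uniform over the simplex via the square-to-triangle
    map on midpoint categories; omega0 uniform on (0,1); omega2 uniform on
    (1,11). Equal prior weight per grid point."""
    mid = (np.arange(n) + 0.5) / n
    u, v = np.meshgrid(mid, mid, indexing="ij")
    r = np.sqrt(u)
    p0 = (1.0 - r).ravel()
    p1 = (r * v).ravel()
    w0 = mid.copy()
    w2 = 1.0 + 10.0 * mid
    return p0, p1, w0, w2


def _class_weights(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    p2 = np.clip(1.0 - p0 - p1, 0.0, 1.0)
    denom = np.maximum(p0 + p1, 1e-12)
    return np.stack([p0, p1, p2 * p0 / denom, p2 * p1 / denom], axis=1)


def beb_site_posteriors(
    alignment: CodonAlignment,
    tree: PhyloTree,
    a2_fit: FitResult,
    n_grid: int = BEB_GRID_SIZE,
    require_converged: bool = True,
) -> BEBResult:
    """BEB site-class posteriors under the branch-site alternative model.

    The mixture parameters are integrated over the prior grid, with kappa and
    branch lengths fixed at the MLEs carried by ``a2_fit`` (which must be a
    branch-site fit on a tree with a designated foreground branch).
    """
    if a2_fit.model_name not in ("A1", "A2"):
        raise ValueError("BEB requires a branch-site (A1/A2) fit")
    if require_converged and not a2_fit.converged:
        raise ValueError("BEB requires a converged branch-site fit")
    work_tree = a2_fit.tree
    if not work_tree.foreground.any():
        raise ValueError("tree has no foreground branch")
    engine = LikelihoodEngine(alignment, work_tree, a2_fit.frequencies)
    kappa = a2_fit.kappa

    p0g, p1g, w0g, w2g = _beb_grid(n_grid)
    n_pp = len(p0g)
    weights = _class_weights(p0g, p1g)  # (n_pp, 4)
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(weights, 1e-300))

    npat = engine.n_patterns
    counts = engine.pattern_counts.astype(float)
    # class log-likelihood vectors on the omega grids; classes share the
    # fitted model's generator scaling (rates relative to a neutral class)
    rho1 = raw_substitution_rate(kappa, 1.0, engine.frequencies)

    def mult(w: float) -> float:
        return raw_substitution_rate(kappa, float(w), engine.frequencies) / rho1

    ll0 = np.stack(
        [
            engine.class_pattern_loglik(kappa, float(w), mult=(mult(w), mult(w)))
            for w in w0g
        ]
    )
    ll1 = engine.class_pattern_loglik(kappa, 1.0)
    ll2b = np.stack(
        [
            engine.class_pattern_loglik(kappa, (1.0, float(w)), mult=(1.0, mult(w)))
            for w in w2g
        ]
    )
    ll2a = np.empty((n_grid, n_grid, npat))
    for i, w0 in enumerate(w0g):
        for j, w2 in enumerate(w2g):
            ll2a[i, j] = engine.class_pattern_loglik(
                kappa, (float(w0), float(w2)), mult=(mult(w0), mult(w2))
            )

    # total data log-likelihood for every grid combination (block over omegas)
    n_combo = n_pp * n_grid * n_grid
    total_ll = np.empty((n_grid, n_grid, n_pp))
    for i in range(n_grid):
        for j in range(n_grid):
            lls = np.stack([ll0[i], ll1, ll2a[i, j], ll2b[j]])  # (4, npat)
            site_ll = logsumexp(logw[:, :, None] + lls[None, :, :], axis=1)
            total_ll[i, j] = site_ll @ counts
    flat = total_ll.reshape(n_grid * n_grid, n_pp)
    log_post = flat - logsumexp(flat)  # uniform prior cancels

    post_pat = np.zeros((npat, 4))
    omega_num = np.zeros(npat)
    for i in range(n_grid):
        for j in range(n_grid):
            lls = np.stack([ll0[i], ll1, ll2a[i, j], ll2b[j]])
            log_num = logw[:, :, None] + lls[None, :, :]  # (n_pp, 4, npat)
            site_ll = logsumexp(log_num, axis=1)  # (n_pp, npat)
            cls_post = np.exp(log_num - site_ll[:, None, :])  # (n_pp, 4, npat)
            gp = np.exp(log_post[i * n_grid + j])  # (n_pp,)
            contrib = np.einsum("g,gkp->pk", gp, cls_post)
            post_pat += contrib
            om = np.array([w0g[i], 1.0, w2g[j], w2g[j]])
            omega_num += contrib @ om
    row_sum = post_pat.sum(axis=1, keepdims=True)
    post_pat /= np.maximum(row_sum, 1e-300)

    idx = engine.pattern_of_site
    site_post = post_pat[idx]
    return BEBResult(
        site_posteriors=site_post,
        positive_posterior=site_post[:, 2] + site_post[:, 3],
        omega_mean=omega_num[idx] / np.maximum(row_sum.ravel()[idx], 1e-300),
    )


def classify_sites(
    beb, thresholds: tuple[float, float] = (0.95, 0.99)
) -> dict[str, list[int]]:
    """Partition sites by positive-selection posterior into tiers.

    Accepts a :class:`BEBResult` or a raw posterior array. Returns 0-based
    site indices in ``P>0.99``, ``0.95<P<=0.99`` and their union ``P>0.95``
    (thresholds configurable).
    """
    lo, hi = sorted(thresholds)
    post = np.asarray(
        beb.positive_posterior if isinstance(beb, BEBResult) else beb, dtype=float
    )
    top = np.where(post > hi)[0]
    mid = np.where((post > lo) & (post <= hi))[0]
    return {
        f"P>{hi:g}": top.tolist(),
        f"{lo:g}<P<={hi:g}": mid.tolist(),
        f"P>{lo:g}": np.where(post > lo)[0].tolist(),
    }


def foreground_candidate_report(branch1_fit: FitResult) -> pd.DataFrame:
    """Rank branches by dN to support choosing a foreground branch.

    Intended for a branch-model-1 fit (free omega per branch): branches with
    high dN and non-trivial dS are the credible candidates, whereas very
    short branches can show spuriously large omega.
    """
    df = branch1_fit.per_branch_dn_ds
    if df is None:
        raise ValueError("fit was run without compute_branch_rates=True")
    return df.sort_values("dN", ascending=False).reset_index(drop=True)
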