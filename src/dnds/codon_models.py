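"""Codon substitution models, pruning likelihood, and maximum-likelihood fits.

The substitution process is the standard reversible Markov model on the 61
sense codons: instantaneous rates are zero between codons differing at more
than one position and otherwise proportional to the target codon frequency,
multiplied by the transition/transversion ratio ``kappa`` for transitions and
by ``omega`` (dN/dS) for nonsynonymous changes. The generator is scaled so
one unit of branch length equals one expected substitution per codon at
stationarity.

Heterogeneity in omega is expressed through a mixture of site classes; each
class may use different omega values on "foreground" (flagged) and background
branches, which covers every model in the catalogue: the site models M0,
M1a, M2a, M7, M8, M8a; the branch models 0, 1, strict/relaxed 2; and the
branch-site models A1/A2. Likelihoods are computed with Felsenstein pruning
on pattern-compressed alignments, with per-node rescaling for numerical
stability, and an analytic branch-length gradient so that joint optimisation
of branch lengths, kappa, and the mixture parameters is practical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.special import betainc, logsumexp
from scipy.stats import beta as _beta_dist

from .seqdata import (
    CODONS,
    CODON_AA,
    CODON_INDEX,
    CodonAlignment,
    PhyloTree,
    codon_state_mask,
)

__all__ = [
    "OMEGA_MIN",
    "OMEGA_MAX",
    "KAPPA_MIN",
    "KAPPA_MAX",
    "BRANCH_MIN",
    "BRANCH_MAX",
    "N_BETA_CATEGORIES",
    "SiteClass",
    "SiteClassMixture",
    "CodonModelSpec",
    "FitResult",
    "MODEL_CATALOG",
    "build_rate_matrix",
    "transition_matrix",
    "equal_frequencies",
    "f3x4_frequencies",
    "f1x4_frequencies",
    "f61_frequencies",
    "codon_frequencies",
    "beta_category_means",
    "branch_site_classes",
    "LikelihoodEngine",
    "log_likelihood",
    "fit_model",
    "m0_model",
    "branch_site_model",
    "per_branch_rates",
]

# Optimisation bounds. The omega ceiling of 999 mirrors the convention of
# reporting boundary estimates as 999 in selection analyses.
OMEGA_MIN = 1e-6
OMEGA_MAX = 999.0
KAPPA_MIN = 1e-3
KAPPA_MAX = 100.0
BRANCH_MIN = 1e-6
BRANCH_MAX = 50.0
N_BETA_CATEGORIES = 10

# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


def _single_step_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            pair = {ci[p], cj[p]}
            ii.append(i)
            jj.append(j)
            ts.append(pair in _TRANSITIONS)
            syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


_STEP_I, _STEP_J, _STEP_TS, _STEP_SYN = _single_step_structure()


def build_rate_matrix(
    kappa: float, omega: float, frequencies: np.ndarray
) -> np.ndarray:
    """Scaled 61x61 generator; rows sum to zero, mean rate 1 at stationarity."""
    pi = np.asarray(frequencies, dtype=float)
    if pi.shape != (61,):
        raise ValueError("frequencies must be a 61-vector over the sense codons")
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must be non-negative and sum to 1")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rates = pi[_STEP_J].copy()
    rates[_STEP_TS] *= kappa
    rates[~_STEP_SYN] *= omega
    Q = np.zeros((61, 61))
    Q[_STEP_I, _STEP_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate > 0:
        Q /= mean_rate
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    P = linalg.expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    return P


def _flux_constants(frequencies: np.ndarray) -> tuple[float, float, float, float]:
    """Stationary flux sums (syn-tv, syn-ts, nonsyn-tv, nonsyn-ts) for pi."""
    flux = frequencies[_STEP_I] * frequencies[_STEP_J]
    return (
        float(flux[_STEP_SYN & ~_STEP_TS].sum()),
        float(flux[_STEP_SYN & _STEP_TS].sum()),
        float(flux[~_STEP_SYN & ~_STEP_TS].sum()),
        float(flux[~_STEP_SYN & _STEP_TS].sum()),
    )


def raw_substitution_rate(
    kappa: float, omega: float, frequencies: np.ndarray
) -> float:
    """Expected substitution rate of the *unnormalised* generator at
    stationarity. Linear in omega; used to scale site classes relative to
    one another so that classes with higher omega genuinely evolve faster."""
    s_tv, s_ts, n_tv, n_ts = _flux_constants(frequencies)
    return (s_tv + kappa * s_ts) + omega * (n_tv + kappa * n_ts)


def class_rate_multipliers(
    kappa: float,
    classes: "Sequence[tuple[float, object]]",
    frequencies: np.ndarray,
    convention: str = "mixture",
) -> list[tuple[float, float] | None]:
    """Relative rate multiplier (background, foreground) per site class.

    Site classes share one generator scaling rather than being normalised
    individually. Under the ``mixture`` convention a branch length is the
    expected number of substitutions per codon averaged over site classes on
    that branch (separately for foreground and background, the field's
    reporting convention). Under the ``neutral`` convention rates are
    expressed relative to a neutral (omega = 1) class, which leaves the
    multipliers independent of the mixture proportions; the two conventions
    differ only by a per-branch-category rescaling absorbed by free branch
    lengths during optimisation.
    """
    s_tv, s_ts, n_tv, n_ts = _flux_constants(frequencies)
    syn = s_tv + kappa * s_ts
    nsyn = n_tv + kappa * n_ts

    def rho(om: float) -> float:
        return syn + om * nsyn

    pairs: list[tuple[float, float] | None] = []
    bgs, fgs, props = [], [], []
    for p, om in classes:
        if np.isscalar(om):
            bg = fg = float(om)
        elif isinstance(om, tuple) and len(om) == 2 and np.isscalar(om[0]):
            bg, fg = float(om[0]), float(om[1])
        else:
            # per-branch omega (branch model): each branch normalised on its
            # own, the branch-model convention
            pairs.append(None)
            continue
        bgs.append(bg)
        fgs.append(fg)
        props.append(p)
        pairs.append((bg, fg))
    if not bgs:
        return pairs
    if convention == "neutral":
        ref_bg = ref_fg = rho(1.0)
    elif convention == "mixture":
        total = sum(props)
        ref_bg = sum(p * rho(b) for p, b in zip(props, bgs)) / max(total, 1e-300)
        ref_fg = sum(p * rho(f) for p, f in zip(props, fgs)) / max(total, 1e-300)
    else:
        raise ValueError(f"unknown scaling convention {convention!r}")
    out: list[tuple[float, float] | None] = []
    i = 0
    for item in pairs:
        if item is None:
            out.append(None)
        else:
            bg, fg = item
            out.append((rho(bg) / ref_bg, rho(fg) / ref_fg))
            i += 1
    return out


# ---------------------------------------------------------------------------
# Codon frequencies
# ---------------------------------------------------------------------------


def equal_frequencies() -> np.ndarray:
    return np.full(61, 1.0 / 61.0)


def _position_nuc_counts(alignment: CodonAlignment) -> np.ndarray:
    counts = np.zeros((3, 4))
    order = {"T": 0, "C": 1, "A": 2, "G": 3}
    for row in alignment.codons:
        for codon in row:
            if codon in CODON_INDEX:
                for p, ch in enumerate(codon):
                    counts[p, order[ch]] += 1
    return counts


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Codon frequencies from observed nucleotide frequencies per codon position."""
    counts = _position_nuc_counts(alignment)
    counts += 0.5  # avoid zero positional frequencies on tiny alignments
    pos = counts / counts.sum(axis=1, keepdims=True)
    order = {"T": 0, "C": 1, "A": 2, "G": 3}
    freqs = np.array(
        [pos[0, order[c[0]]] * pos[1, order[c[1]]] * pos[2, order[c[2]]] for c in CODONS]
    )
    return freqs / freqs.sum()


def f1x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    counts = _position_nuc_counts(alignment).sum(axis=0) + 0.5
    nuc = counts / counts.sum()
    order = {"T": 0, "C": 1, "A": 2, "G": 3}
    freqs = np.array(
        [nuc[order[c[0]]] * nuc[order[c[1]]] * nuc[order[c[2]]] for c in CODONS]
    )
    return freqs / freqs.sum()


def f61_frequencies(alignment: CodonAlignment, pseudocount: float = 0.5) -> np.ndarray:
    counts = np.full(61, pseudocount)
    for row in alignment.codons:
        for codon in row:
            idx = CODON_INDEX.get(codon)
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def codon_frequencies(alignment: CodonAlignment, mode: str = "F3x4") -> np.ndarray:
    mode = mode.lower()
    if mode == "equal":
        return equal_frequencies()
    if mode == "f3x4":
        return f3x4_frequencies(alignment)
    if mode == "f1x4":
        return f1x4_frequencies(alignment)
    if mode == "f61":
        return f61_frequencies(alignment)
    raise ValueError(f"unknown frequency mode {mode!r}")


# ---------------------------------------------------------------------------
# Model specification containers
# ---------------------------------------------------------------------------


@dataclass
class SiteClass:
    """One mixture component: proportion plus background/foreground omega."""

    proportion: float
    omega_background: float
    omega_foreground: float
    label: str = ""


@dataclass
class SiteClassMixture:
    classes: list[SiteClass]
    model_name: str = "custom"
    beta_params: tuple[float, float] | None = None
    n_discrete: int | None = None

    def __post_init__(self) -> None:
        total = sum(c.proportion for c in self.classes)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class proportions sum to {total}, not 1")
        for c in self.classes:
            if c.proportion < -1e-12:
                raise ValueError("negative class proportion")
            if c.omega_background < 0 or c.omega_foreground < 0:
                raise ValueError("negative omega")

    @property
    def uses_foreground(self) -> bool:
        return any(
            abs(c.omega_background - c.omega_foreground) > 1e-12 for c in self.classes
        )


@dataclass
class CodonModelSpec:
    kappa: float
    frequencies: np.ndarray
    mixture: SiteClassMixture
    frequency_mode: str = "custom"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.frequencies.shape != (61,) or abs(self.frequencies.sum() - 1) > 1e-6:
            raise ValueError("frequencies must be a normalised 61-vector")


def m0_model(kappa: float, omega: float, frequencies: np.ndarray) -> CodonModelSpec:
    return CodonModelSpec(
        kappa=kappa,
        frequencies=frequencies,
        mixture=SiteClassMixture([SiteClass(1.0, omega, omega, "0")], "M0"),
    )


def branch_site_classes(
    p0: float, p1: float, omega0: float, omega2: float
) -> list[SiteClass]:
    """The four-class branch-site structure.

    Classes 0 and 1 evolve with omega0 (purifying) and 1 (neutral) on all
    branches; classes 2a/2b take their background omega from classes 0/1 but
    omega2 on the foreground branch. The leftover mass 1-p0-p1 is split
    between 2a and 2b in proportion p0:p1.
    """
    p2 = max(0.0, 1.0 - p0 - p1)
    denom = p0 + p1
    if denom < 1e-12:
        p2a = p2b = p2 / 2.0
    else:
        p2a = p2 * p0 / denom
        p2b = p2 * p1 / denom
    return [
        SiteClass(p0, omega0, omega0, "0"),
        SiteClass(p1, 1.0, 1.0, "1"),
        SiteClass(p2a, omega0, omega2, "2a"),
        SiteClass(p2b, 1.0, omega2, "2b"),
    ]


def branch_site_model(
    kappa: float,
    frequencies: np.ndarray,
    p0: float,
    p1: float,
    omega0: float,
    omega2: float = 1.0,
    model_name: str | None = None,
) -> CodonModelSpec:
    if model_name is None:
        model_name = "A1" if abs(omega2 - 1.0) < 1e-12 else "A2"
    return CodonModelSpec(
        kappa=kappa,
        frequencies=frequencies,
        mixture=SiteClassMixture(
            branch_site_classes(p0, p1, omega0, omega2), model_name
        ),
    )


def beta_category_means(p: float, q: float, n: int = N_BETA_CATEGORIES) -> np.ndarray:
    """Means of ``n`` equal-probability categories of a Beta(p, q) distribution."""
    edges = _beta_dist.ppf(np.linspace(0.0, 1.0, n + 1), p, q)
    cum = betainc(p + 1.0, q, np.clip(edges, 0.0, 1.0))
    means = (cum[1:] - cum[:-1]) * n * p / (p + q)
    return np.clip(means, 1e-9, 1.0 - 1e-9)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------


class LikelihoodEngine:
    """Pruning likelihood on a pattern-compressed codon alignment.

    One engine is bound to an alignment/tree/frequency triple; branch lengths
    are mutable state so a fitting loop can update them cheaply. Per-class
    site log-likelihood vectors are cached keyed on the parameters that
    produced them, which makes mixture-weight derivatives essentially free.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        frequencies: np.ndarray,
    ) -> None:
        if set(tree.taxa) != set(alignment.taxa):
            raise ValueError(
                "tree leaves and alignment taxa differ: "
                f"{sorted(set(tree.taxa) ^ set(alignment.taxa))}"
            )
        self.tree = tree
        self.alignment = alignment
        pi = np.asarray(frequencies, dtype=float)
        pi = np.clip(pi, 1e-10, None)
        self.frequencies = pi / pi.sum()
        self._sqrt_pi = np.sqrt(self.frequencies)

        self._leaf_nodes = tree.leaves
        rows = [alignment.taxa.index(tree.labels[v]) for v in self._leaf_nodes]
        cols = alignment.codons[rows, :]  # leaf-node order
        # pattern compression
        keys = [tuple(cols[:, s]) for s in range(alignment.n_codons)]
        uniq: dict[tuple, int] = {}
        pattern_of_site = np.zeros(alignment.n_codons, dtype=int)
        for s, key in enumerate(keys):
            pattern_of_site[s] = uniq.setdefault(key, len(uniq))
        self.pattern_of_site = pattern_of_site
        self.n_patterns = len(uniq)
        self.pattern_counts = np.bincount(pattern_of_site, minlength=self.n_patterns)
        pat_cols = {idx: key for key, idx in uniq.items()}
        self._leaf_partials: dict[int, np.ndarray] = {}
        for k, v in enumerate(self._leaf_nodes):
            part = np.empty((self.n_patterns, 61))
            for p in range(self.n_patterns):
                part[p] = codon_state_mask(pat_cols[p][k]).astype(float)
            self._leaf_partials[v] = part

        self.lengths = tree.lengths.copy()
        self._version = 0
        self._class_cache: dict[tuple, np.ndarray] = {}
        self._spectral_cache: dict[tuple[float, float], tuple] = {}
        self._postorder = tree.postorder()
        self._preorder = tree.preorder()

    # -- state --------------------------------------------------------------

    def set_lengths(self, lengths: np.ndarray) -> None:
        lengths = np.asarray(lengths, dtype=float)
        if np.array_equal(lengths, self.lengths):
            return
        self.lengths = lengths
        self._version += 1
        self._class_cache.clear()

    # -- spectral machinery -------------------------------------------------

    def _spectral(self, kappa: float, omega: float):
        key = (kappa, omega)
        hit = self._spectral_cache.get(key)
        if hit is not None:
            return hit
        Q = build_rate_matrix(kappa, omega, self.frequencies)
        S = Q * self._sqrt_pi[:, None] / self._sqrt_pi[None, :]
        S = 0.5 * (S + S.T)
        lam, V = np.linalg.eigh(S)
        left = V / self._sqrt_pi[:, None]  # P(t) = left @ diag(e^{lam t}) @ right
        right = V.T * self._sqrt_pi[None, :]
        if len(self._spectral_cache) > 256:
            self._spectral_cache.clear()
        self._spectral_cache[key] = (lam, left, right)
        return lam, left, right

    def _edge_matrices(self, kappa, omega_of_node, scale, mult_of_node, with_qp=False):
        P: dict[int, np.ndarray] = {}
        QP: dict[int, np.ndarray] = {}
        for v in range(self.tree.n_nodes):
            if self.tree.parent[v] < 0:
                continue
            lam, left, right = self._spectral(kappa, omega_of_node[v])
            t = self.lengths[v] * scale * mult_of_node[v]
            elt = np.exp(lam * t)
            Pv = (left * elt[None, :]) @ right
            np.clip(Pv, 0.0, None, out=Pv)  # spectral round-off can go sub-zero
            P[v] = Pv
            if with_qp:
                QP[v] = (left * (lam * elt)[None, :]) @ right
        return P, QP

    def _omega_of_node(self, omega) -> np.ndarray:
        n = self.tree.n_nodes
        if np.isscalar(omega):
            return np.full(n, float(omega))
        omega = tuple(np.atleast_1d(omega)) if not isinstance(omega, tuple) else omega
        if len(omega) == 2 and np.isscalar(omega[0]):
            bg, fg = float(omega[0]), float(omega[1])
            out = np.full(n, bg)
            out[self.tree.foreground] = fg
            return out
        arr = np.asarray(omega, dtype=float)
        if arr.shape != (n,):
            raise ValueError("per-branch omega must have one entry per node")
        return arr

    def _mult_of_node(self, mult) -> np.ndarray:
        n = self.tree.n_nodes
        if mult is None:
            return np.ones(n)
        m_bg, m_fg = mult
        out = np.full(n, float(m_bg))
        out[self.tree.foreground] = float(m_fg)
        return out

    @staticmethod
    def _omega_key(omega):
        if np.isscalar(omega):
            return float(omega)
        arr = np.asarray(omega, dtype=float).ravel()
        return tuple(arr.tolist())

    # -- core passes --------------------------------------------------------

    def class_pattern_loglik(
        self, kappa: float, omega, scale: float = 1.0, mult=None
    ) -> np.ndarray:
        """Per-pattern log-likelihood for a single site class.

        ``mult`` is an optional (background, foreground) relative-rate pair
        from :func:`class_rate_multipliers`; branch lengths are multiplied by
        it so site classes share a common generator scaling.
        """
        key = (
            "ll", self._version, kappa, scale, self._omega_key(omega),
            None if mult is None else (float(mult[0]), float(mult[1])),
        )
        hit = self._class_cache.get(key)
        if hit is not None:
            return hit
        om = self._omega_of_node(omega)
        P, _ = self._edge_matrices(kappa, om, scale, self._mult_of_node(mult))
        ll = self._postorder_loglik(P)
        self._class_cache[key] = ll
        return ll

    def _postorder_loglik(self, P: dict[int, np.ndarray]) -> np.ndarray:
        logscale = np.zeros(self.n_patterns)
        partial: dict[int, np.ndarray] = {}
        for v in self._postorder:
            kids = self.tree.children(v)
            if not kids:
                partial[v] = self._leaf_partials[v]
                continue
            M = np.ones((self.n_patterns, 61))
            for c in kids:
                M *= partial[c] @ P[c].T
                del partial[c]
            m = M.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            M /= m[:, None]
            logscale += np.log(m)
            partial[v] = M
        root = self.tree.root
        lik = partial[root] @ self.frequencies
        with np.errstate(divide="ignore"):
            return np.log(lik) + logscale

    def class_edge_stats(
        self, kappa: float, omega, scale: float = 1.0, mult=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-pattern log-likelihood and per-edge derivative ratios.

        Returns ``(loglik, ratio)`` where ``ratio[v, p]`` is the derivative of
        the pattern-``p`` log-likelihood with respect to the *unscaled* length
        of the branch above node ``v`` (foreground-aware, class-specific).
        """
        om = self._omega_of_node(omega)
        mult_arr = self._mult_of_node(mult)
        P, QP = self._edge_matrices(kappa, om, scale, mult_arr, with_qp=True)
        tree = self.tree
        logscale = np.zeros(self.n_patterns)
        partial: dict[int, np.ndarray] = {}
        D: dict[int, np.ndarray] = {}
        for v in self._postorder:
            kids = tree.children(v)
            if not kids:
                partial[v] = self._leaf_partials[v]
            else:
                M = np.ones((self.n_patterns, 61))
                for c in kids:
                    M *= D[c]
                m = M.max(axis=1)
                m = np.where(m > 0, m, 1.0)
                M /= m[:, None]
                logscale += np.log(m)
                partial[v] = M
            if tree.parent[v] >= 0:
                D[v] = partial[v] @ P[v].T
        root = tree.root
        lik_root = partial[root] @ self.frequencies
        with np.errstate(divide="ignore"):
            loglik = np.log(lik_root) + logscale

        ratio = np.zeros((tree.n_nodes, self.n_patterns))
        W: dict[int, np.ndarray] = {root: np.broadcast_to(self.frequencies, (self.n_patterns, 61))}
        for u in self._preorder:
            kids = tree.children(u)
            if not kids:
                continue
            Wu = W.pop(u)
            for c in kids:
                Wc = Wu.copy()
                for s in kids:
                    if s is not c:
                        Wc *= D[s]
                denom = np.einsum("ps,ps->p", Wc, D[c])
                numer = np.einsum("ps,ps->p", Wc @ QP[c], partial[c])
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio[c] = (
                        np.where(denom > 0, numer / denom, 0.0)
                        * scale
                        * mult_arr[c]
                    )
                if tree.children(c):
                    Wdown = Wc @ P[c]
                    m = Wdown.max(axis=1)
                    m = np.where(m > 0, m, 1.0)
                    W[c] = Wdown / m[:, None]
        return loglik, ratio

    # -- mixtures -----------------------------------------------------------

    def class_multipliers(
        self,
        kappa: float,
        classes: Sequence[tuple[float, object]],
        convention: str = "mixture",
    ) -> list[tuple[float, float] | None]:
        return class_rate_multipliers(kappa, classes, self.frequencies, convention)

    def mixture_pattern_logliks(
        self,
        kappa: float,
        classes: Sequence[tuple[float, object]],
        scale: float = 1.0,
        convention: str = "mixture",
    ) -> tuple[np.ndarray, np.ndarray]:
        """Stacked per-class log-likelihoods and the mixture log-likelihood."""
        mults = self.class_multipliers(kappa, classes, convention)
        lls = np.stack(
            [
                self.class_pattern_loglik(kappa, om, scale, mult)
                for (_, om), mult in zip(classes, mults)
            ]
        )
        props = np.array([max(p, 0.0) for p, _ in classes])
        with np.errstate(divide="ignore"):
            logp = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
        mix = logsumexp(lls + logp[:, None], axis=0)
        return lls, mix

    def loglik(
        self,
        kappa: float,
        classes: Sequence[tuple[float, object]],
        scale: float = 1.0,
        convention: str = "mixture",
    ) -> float:
        _, mix = self.mixture_pattern_logliks(kappa, classes, scale, convention)
        return float(self.pattern_counts @ mix)


def _mixture_classes(mixture: SiteClassMixture) -> list[tuple[float, object]]:
    out: list[tuple[float, object]] = []
    for c in mixture.classes:
        if abs(c.omega_background - c.omega_foreground) < 1e-12:
            out.append((c.proportion, float(c.omega_background)))
        else:
            out.append((c.proportion, (c.omega_background, c.omega_foreground)))
    return out


def log_likelihood(
    alignment: CodonAlignment, tree: PhyloTree, model: CodonModelSpec
) -> float:
    """Mixture log-likelihood of an alignment on a tree under a codon model."""
    if model.mixture.uses_foreground and not tree.foreground.any():
        raise ValueError(
            "model distinguishes foreground omega but the tree has no "
            "foreground (#1) branch"
        )
    engine = LikelihoodEngine(alignment, tree, model.frequencies)
    return engine.loglik(model.kappa, _mixture_classes(model.mixture))


# ---------------------------------------------------------------------------
# Model catalogue
# ---------------------------------------------------------------------------


@dataclass
class ParamSpec:
    name: str
    lo: float
    hi: float
    log: bool
    inits: tuple[float, ...]


@dataclass
class ModelDef:
    name: str
    requires_foreground: bool
    specs: Callable[[int], list[ParamSpec]]
    build: Callable[[dict, PhyloTree], list[tuple[float, object]]]
    omega_param_count: Callable[[int], int]
    describe: Callable[[dict], dict]


def _stick2(p0: float, s1: float) -> tuple[float, float, float]:
    p1 = (1.0 - p0) * s1
    return p0, p1, max(0.0, 1.0 - p0 - p1)


def _cls(classes: list[SiteClass]) -> list[tuple[float, object]]:
    return _mixture_classes(SiteClassMixture(classes, "tmp"))


def _beta_classes(p: float, q: float) -> list[tuple[float, float]]:
    means = beta_category_means(p, q)
    w = 1.0 / N_BETA_CATEGORIES
    return [(w, float(m)) for m in means]


def _make_catalog() -> dict[str, ModelDef]:
    cat: dict[str, ModelDef] = {}

    omega_free = ParamSpec("omega", OMEGA_MIN, OMEGA_MAX, True, (0.3, 1.5, 0.05))
    omega_le1 = ParamSpec("omega0", OMEGA_MIN, 1.0, True, (0.2, 0.05, 0.6))
    omega_pos = ParamSpec("omega2", 1.0, OMEGA_MAX, True, (2.0, 10.0, 1.2))

    cat["M0"] = ModelDef(
        "M0",
        False,
        lambda B: [omega_free],
        lambda p, t: [(1.0, p["omega"])],
        lambda B: 1,
        lambda p: {"omega": p["omega"]},
    )
    cat["M1a"] = ModelDef(
        "M1a",
        False,
        lambda B: [
            ParamSpec("p0", 0.0, 1.0, False, (0.7, 0.4, 0.9)),
            omega_le1,
        ],
        lambda p, t: [(p["p0"], p["omega0"]), (1.0 - p["p0"], 1.0)],
        lambda B: 2,
        lambda p: {"p0": p["p0"], "p1": 1 - p["p0"], "omega0": p["omega0"]},
    )
    cat["M2a"] = ModelDef(
        "M2a",
        False,
        lambda B: [
            ParamSpec("p0", 0.0, 1.0, False, (0.7, 0.5)),
            ParamSpec("s1", 0.0, 1.0, False, (0.8, 0.5)),
            omega_le1,
            omega_pos,
        ],
        lambda p, t: (
            lambda p0, p1, p2: [
                (p0, p["omega0"]),
                (p1, 1.0),
                (p2, p["omega2"]),
            ]
        )(*_stick2(p["p0"], p["s1"])),
        lambda B: 4,
        lambda p: dict(
            zip(("p0", "p1", "p2"), _stick2(p["p0"], p["s1"])),
            omega0=p["omega0"],
            omega2=p["omega2"],
        ),
    )
    beta_p = ParamSpec("p", 0.005, 99.0, True, (0.5, 2.0))
    beta_q = ParamSpec("q", 0.005, 99.0, True, (1.5, 2.0))
    cat["M7"] = ModelDef(
        "M7",
        False,
        lambda B: [beta_p, beta_q],
        lambda p, t: _beta_classes(p["p"], p["q"]),
        lambda B: 2,
        lambda p: {"p": p["p"], "q": p["q"]},
    )

    def _m8_classes(p, t, omega_s):
        p0 = p["p0"]
        return [
            (p0 * w, om) for w, om in _beta_classes(p["p"], p["q"])
        ] + [(1.0 - p0, omega_s)]

    cat["M8"] = ModelDef(
        "M8",
        False,
        lambda B: [
            beta_p,
            beta_q,
            ParamSpec("p0", 0.0, 1.0, False, (0.9, 0.7)),
            ParamSpec("omega_s", 1.0, OMEGA_MAX, True, (2.0, 5.0)),
        ],
        lambda p, t: _m8_classes(p, t, p["omega_s"]),
        lambda B: 4,
        lambda p: {k: p[k] for k in ("p", "q", "p0", "omega_s")},
    )
    cat["M8a"] = ModelDef(
        "M8a",
        False,
        lambda B: [beta_p, beta_q, ParamSpec("p0", 0.0, 1.0, False, (0.9, 0.7))],
        lambda p, t: _m8_classes(p, t, 1.0),
        lambda B: 3,
        lambda p: {k: p[k] for k in ("p", "q", "p0")},
    )

    cat["branch0"] = ModelDef(
        "branch0",
        False,
        lambda B: [omega_free],
        lambda p, t: [(1.0, p["omega"])],
        lambda B: 1,
        lambda p: {"omega": p["omega"]},
    )

    def _branch1_specs(B: int) -> list[ParamSpec]:
        return [
            ParamSpec(f"omega_b{i}", OMEGA_MIN, OMEGA_MAX, True, (0.3, 1.0))
            for i in range(B)
        ]

    def _branch1_build(p: dict, tree: PhyloTree):
        om = np.zeros(tree.n_nodes)
        i = 0
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                om[v] = p[f"omega_b{i}"]
                i += 1
        return [(1.0, om)]

    cat["branch1"] = ModelDef(
        "branch1",
        False,
        _branch1_specs,
        _branch1_build,
        lambda B: B,
        lambda p: dict(p),
    )
    cat["branch2_strict"] = ModelDef(
        "branch2_strict",
        True,
        lambda B: [
            ParamSpec("omega_bg", OMEGA_MIN, 1.0, True, (0.2, 0.05)),
            ParamSpec("omega_fg", OMEGA_MIN, OMEGA_MAX, True, (1.5, 0.3)),
        ],
        lambda p, t: [(1.0, (p["omega_bg"], p["omega_fg"]))],
        lambda B: 2,
        lambda p: dict(p),
    )
    cat["branch2_relaxed"] = ModelDef(
        "branch2_relaxed",
        True,
        lambda B: [ParamSpec("omega_bg", OMEGA_MIN, 1.0, True, (0.2, 0.05))],
        lambda p, t: [(1.0, (p["omega_bg"], 1.0))],
        lambda B: 1,
        lambda p: dict(p),
    )

    def _bs_build(omega2_of):
        def build(p: dict, t: PhyloTree):
            p0, p1, _ = _stick2(p["p0"], p["s1"])
            return _cls(branch_site_classes(p0, p1, p["omega0"], omega2_of(p)))

        return build

    def _bs_describe(omega2_of):
        def describe(p: dict) -> dict:
            p0, p1, p2 = _stick2(p["p0"], p["s1"])
            return {
                "p0": p0,
                "p1": p1,
                "p2": p2,
                "omega0": p["omega0"],
                "omega2": omega2_of(p),
            }

        return describe

    cat["A1"] = ModelDef(
        "A1",
        True,
        lambda B: [
            ParamSpec("p0", 0.0, 1.0, False, (0.75, 0.5)),
            ParamSpec("s1", 0.0, 1.0, False, (0.8, 0.5)),
            omega_le1,
        ],
        _bs_build(lambda p: 1.0),
        lambda B: 3,
        _bs_describe(lambda p: 1.0),
    )
    cat["A2"] = ModelDef(
        "A2",
        True,
        lambda B: [
            ParamSpec("p0", 0.0, 1.0, False, (0.75, 0.5)),
            ParamSpec("s1", 0.0, 1.0, False, (0.8, 0.5)),
            omega_le1,
            omega_pos,
        ],
        _bs_build(lambda p: p["omega2"]),
        lambda B: 4,
        _bs_describe(lambda p: p["omega2"]),
    )
    return cat


MODEL_CATALOG = _make_catalog()

#: omega-structure free-parameter counts used for LRT degrees of freedom
OMEGA_PARAM_COUNTS = {
    name: MODEL_CATALOG[name].omega_param_count for name in MODEL_CATALOG
}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A maximum-likelihood fit of one catalogue model."""

    model_name: str
    lnL: float
    kappa: float
    params: dict
    mixture: dict
    branch_lengths: np.ndarray  # per-node, already including any fitted scale
    frequencies: np.ndarray
    tree: PhyloTree  # fitted branch lengths, original flags
    classes: list[tuple[float, object]]
    n_free_params: int
    mixture_free_params: int
    convergence: dict
    scaling_convention: str = "neutral"
    per_branch_dn_ds: "object | None" = None

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("converged", False))

    def model_spec(self) -> CodonModelSpec:
        classes = []
        for p, om in self.classes:
            if np.isscalar(om):
                classes.append(SiteClass(p, float(om), float(om)))
            elif isinstance(om, tuple) and len(om) == 2:
                classes.append(SiteClass(p, float(om[0]), float(om[1])))
            else:
                raise ValueError(
                    "per-branch omega models cannot be expressed as a "
                    "foreground/background CodonModelSpec"
                )
        return CodonModelSpec(
            kappa=self.kappa,
            frequencies=self.frequencies,
            mixture=SiteClassMixture(classes, self.model_name),
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "lnL": self.lnL,
            "kappa": self.kappa,
            "params": {k: float(v) for k, v in self.params.items()},
            "mixture": {k: float(v) for k, v in self.mixture.items()},
            "branch_lengths": [float(x) for x in self.branch_lengths],
            "n_free_params": self.n_free_params,
            "mixture_free_params": self.mixture_free_params,
            "convergence": self.convergence,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _transform(x: float, spec: ParamSpec) -> float:
    return float(np.log(x)) if spec.log else float(x)


def _untransform(y: float, spec: ParamSpec) -> float:
    return float(np.exp(y)) if spec.log else float(y)


def _bounds(spec: ParamSpec) -> tuple[float, float]:
    if spec.log:
        return (np.log(spec.lo), np.log(spec.hi))
    return (spec.lo, spec.hi)


def fit_model(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model_name: str,
    *,
    frequencies: np.ndarray | None = None,
    freq_mode: str = "F3x4",
    restarts: int = 3,
    seed: int = 0,
    optimize_branches: bool = True,
    optimize_scale: bool = False,
    optimize_fg_scale: bool = False,
    extra_starts: list[dict] | None = None,
    init_kappa: float | None = None,
    init_lengths: np.ndarray | None = None,
    maxiter: int = 500,
    engine: LikelihoodEngine | None = None,
    compute_branch_rates: bool = False,
) -> FitResult:
    """Maximum-likelihood fit of a catalogue model.

    Branch lengths, kappa and the model's free mixture parameters are
    optimised jointly by bounded quasi-Newton (L-BFGS-B) on transformed
    parameters — log scale for rates and branch lengths, stick-breaking on
    [0, 1] for proportions — with an analytic gradient for branch lengths and
    cached finite differences for the scalar parameters. ``restarts``
    independent starting points are tried and the best retained.

    When ``optimize_branches`` is False the input tree's lengths are held
    fixed; ``optimize_scale`` then adds a single shared rescaling factor and
    ``optimize_fg_scale`` a separate factor on the foreground branch(es) —
    the branch whose length interacts directly with the foreground omega —
    both folded into the reported branch lengths.
    """
    if model_name not in MODEL_CATALOG:
        raise ValueError(f"unknown model {model_name!r}")
    mdef = MODEL_CATALOG[model_name]
    if mdef.requires_foreground and not tree.foreground.any():
        raise ValueError(
            f"model {model_name} requires a foreground (#1) branch in the tree"
        )
    if frequencies is None:
        frequencies = codon_frequencies(alignment, freq_mode)
    if engine is None:
        engine = LikelihoodEngine(alignment, tree, frequencies)

    n_nodes = tree.n_nodes
    edge_nodes = [v for v in range(n_nodes) if tree.parent[v] >= 0]
    B = len(edge_nodes)
    specs = mdef.specs(B)
    rng = np.random.default_rng(seed)

    if init_lengths is not None:
        base_lengths = np.asarray(init_lengths, dtype=float).copy()
    else:
        base_lengths = tree.lengths.copy()
    base_lengths = np.clip(base_lengths, BRANCH_MIN, BRANCH_MAX)
    if optimize_branches and not (tree.lengths[edge_nodes] > 1e-9).any():
        base_lengths[:] = 0.2

    scale_spec = ParamSpec("scale", 1e-3, 100.0, True, (1.0,))
    fg_spec = ParamSpec("fg_scale", 1e-3, 100.0, True, (1.0,))
    kappa_spec = ParamSpec("kappa", KAPPA_MIN, KAPPA_MAX, True, (2.0, 1.2, 4.0))
    if optimize_fg_scale and not tree.foreground.any():
        raise ValueError("optimize_fg_scale requires a foreground branch")

    n_bl = B if optimize_branches else 0
    idx_scale = n_bl + 1 + len(specs) if optimize_scale else None
    idx_fg = (
        n_bl + 1 + len(specs) + (1 if optimize_scale else 0)
        if optimize_fg_scale
        else None
    )
    n_par = n_bl + 1 + len(specs) + (idx_scale is not None) + (idx_fg is not None)
    bounds = (
        [(np.log(BRANCH_MIN), np.log(BRANCH_MAX))] * n_bl
        + [_bounds(kappa_spec)]
        + [_bounds(s) for s in specs]
        + ([_bounds(scale_spec)] if optimize_scale else [])
        + ([_bounds(fg_spec)] if optimize_fg_scale else [])
    )
    fg_mask = tree.foreground.copy()

    def decode(vec: np.ndarray) -> tuple[np.ndarray, float, dict, float]:
        lengths = np.zeros(n_nodes)
        if optimize_branches:
            lengths[edge_nodes] = np.exp(vec[:n_bl])
        else:
            lengths = base_lengths.copy()
        kappa = float(np.exp(vec[n_bl]))
        params = {
            s.name: _untransform(vec[n_bl + 1 + i], s) for i, s in enumerate(specs)
        }
        scale = float(np.exp(vec[idx_scale])) if idx_scale is not None else 1.0
        if idx_fg is not None:
            lengths = lengths.copy()
            lengths[fg_mask] *= float(np.exp(vec[idx_fg]))
        return lengths, kappa, params, scale

    # Scaling convention: single-class models use the standard per-model
    # normalisation; mixtures share one generator scaling expressed relative
    # to a neutral class, which keeps the class likelihood vectors (and the
    # cache) independent of the mixture proportions. Free branch lengths /
    # tree scale absorb the difference between the conventions.
    n_classes_probe = len(mdef.build({s.name: s.inits[0] for s in specs}, tree))
    convention = "mixture" if n_classes_probe == 1 else "neutral"

    def objective(vec: np.ndarray) -> tuple[float, np.ndarray]:
        lengths, kappa, params, scale = decode(vec)
        engine.set_lengths(lengths)
        classes = mdef.build(params, tree)
        lls, mix = engine.mixture_pattern_logliks(kappa, classes, scale, convention)
        f = -float(engine.pattern_counts @ mix)
        grad = np.zeros_like(vec)

        if optimize_branches:
            mults = engine.class_multipliers(kappa, classes, convention)
            props = np.array([max(p, 0.0) for p, _ in classes])
            with np.errstate(divide="ignore"):
                logp = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
            post = np.exp(lls + logp[:, None] - mix[None, :])  # (K, n_pat)
            dldt = np.zeros((n_nodes, engine.n_patterns))
            for k, (_, om) in enumerate(classes):
                if props[k] <= 0:
                    continue
                _, ratio = engine.class_edge_stats(kappa, om, scale, mults[k])
                dldt += post[k][None, :] * ratio
            dldt_total = dldt @ engine.pattern_counts  # (n_nodes,)
            # chain rule: vec holds log(t); dt/dlog t = t
            grad[:n_bl] = -dldt_total[edge_nodes] * lengths[edge_nodes]

        # finite differences for the scalar block; the per-class cache makes
        # perturbations that leave a class's omega unchanged nearly free
        h = 1e-6
        for i in range(n_bl, n_par):
            pert = vec.copy()
            step = h if pert[i] + h <= bounds[i][1] else -h
            pert[i] += step
            _, kappa_p, params_p, scale_p = decode(pert)
            classes_p = mdef.build(params_p, tree)
            f_p = -engine.loglik(kappa_p, classes_p, scale_p, convention)
            grad[i] = (f_p - f) / step
        return f, grad

    def start_vector(init: dict, jitter: bool) -> np.ndarray:
        vec = np.zeros(n_par)
        if optimize_branches:
            lens = init.get("lengths", base_lengths)[edge_nodes]
            lens = np.clip(np.asarray(lens, float), BRANCH_MIN, BRANCH_MAX)
            if jitter:
                lens = np.clip(
                    lens * np.exp(rng.uniform(-0.5, 0.5, size=B)),
                    BRANCH_MIN,
                    BRANCH_MAX,
                )
            vec[:n_bl] = np.log(lens)
        kappa0 = init.get("kappa", init_kappa or kappa_spec.inits[0])
        vec[n_bl] = np.log(np.clip(kappa0, KAPPA_MIN, KAPPA_MAX))
        for i, s in enumerate(specs):
            x0 = init.get(s.name, s.inits[min(len(s.inits) - 1, init.get("_round", 0))])
            if jitter and s.name not in init:
                lo, hi = s.lo, s.hi
                if s.log:
                    x0 = np.clip(x0 * np.exp(rng.uniform(-1, 1)), lo, hi)
                else:
                    x0 = np.clip(x0 + rng.uniform(-0.2, 0.2), lo, hi)
            vec[n_bl + 1 + i] = _transform(np.clip(x0, s.lo, s.hi), s)
        if idx_scale is not None:
            vec[idx_scale] = np.log(init.get("scale", 1.0))
        if idx_fg is not None:
            vec[idx_fg] = np.log(init.get("fg_scale", 1.0))
        return vec

    starts: list[np.ndarray] = []
    if extra_starts:
        for st in extra_starts:
            starts.append(start_vector(st, jitter=False))
    r = 0
    while len(starts) < max(restarts, len(starts)):
        starts.append(start_vector({"_round": r}, jitter=r > 0))
        r += 1

    best = None
    restart_lnls = []
    any_success = False
    for vec0 in starts:
        res = optimize.minimize(
            objective,
            vec0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        restart_lnls.append(-float(res.fun))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    lengths, kappa, params, scale = decode(best.x)
    engine.set_lengths(lengths)
    classes = mdef.build(params, tree)
    lnl = engine.loglik(kappa, classes, scale, convention)
    fitted_lengths = lengths * scale
    fitted_tree = tree.with_lengths(fitted_lengths)
    if not any_success:
        warnings.warn(
            f"fit of {model_name} did not report convergence after "
            f"{len(starts)} restart(s); best lnL {lnl:.4f}",
            RuntimeWarning,
        )
    convergence = {
        "converged": any_success,
        "restart_lnls": restart_lnls,
        "n_starts": len(starts),
        "message": str(best.message),
    }
    branch_rates = None
    if compute_branch_rates:
        if model_name == "branch1":
            om_arr = MODEL_CATALOG["branch1"].build(params, tree)[0][1]
        else:
            om = classes[0][1]
            om_arr = engine._omega_of_node(om if len(classes) == 1 else 1.0)
        branch_rates = per_branch_rates(kappa, om_arr, engine.frequencies, fitted_tree)
    mixture = mdef.describe(params)
    return FitResult(
        model_name=model_name,
        lnL=lnl,
        kappa=kappa,
        params=params,
        mixture=mixture,
        branch_lengths=fitted_lengths,
        frequencies=engine.frequencies,
        tree=fitted_tree,
        classes=classes,
        n_free_params=mdef.omega_param_count(B) + 1 + B,
        mixture_free_params=mdef.omega_param_count(B),
        convergence=convergence,
        scaling_convention=convention,
        per_branch_dn_ds=branch_rates,
    )


# ---------------------------------------------------------------------------
# Per-branch dN / dS
# ---------------------------------------------------------------------------


def _flux_fractions(kappa: float, frequencies: np.ndarray) -> tuple[float, float]:
    """Proportions of synonymous and nonsynonymous mutational opportunity
    (flux under omega = 1), the standard 'sites' normalisation."""
    Q1 = build_rate_matrix(kappa, 1.0, frequencies)
    pi = frequencies
    flux = pi[_STEP_I] * Q1[_STEP_I, _STEP_J]
    fs = flux[_STEP_SYN].sum()
    fn = flux[~_STEP_SYN].sum()
    total = fs + fn
    return fs / total, fn / total


def per_branch_rates(
    kappa: float,
    omega_per_node: np.ndarray,
    frequencies: np.ndarray,
    tree: PhyloTree,
):
    """dN and dS per branch from branch length, kappa and the branch's omega."""
    import pandas as pd

    f_s, f_n = _flux_fractions(kappa, frequencies)
    rows = []
    for v in range(tree.n_nodes):
        if tree.parent[v] < 0:
            continue
        om = float(omega_per_node[v])
        Q = build_rate_matrix(kappa, om, frequencies)
        flux = frequencies[_STEP_I] * Q[_STEP_I, _STEP_J]
        rho_s = flux[_STEP_SYN].sum()
        rho_n = flux[~_STEP_SYN].sum()
        t = float(tree.lengths[v])
        ds = t * rho_s / (3.0 * f_s)
        dn = t * rho_n / (3.0 * f_n)
        rows.append(
            {
                "node": v,
                "leaf": tree.labels[v] or "",
                "foreground": bool(tree.foreground[v]),
                "t": t,
                "omega": om,
                "dN": dn,
                "dS": ds,
            }
        )
    df = pd.DataFrame(rows)
    df["dN_rank"] = df["dN"].rank(ascending=False, method="min").astype(int)
    return df
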