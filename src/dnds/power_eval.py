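"""Simulation study of the branch-site test: power, accuracy, false positives.

For each replicate the study simulates a dataset under the configured
generating model (null branch-site A1 or alternative A2), fits both models,
performs the chi-square LRT at the configured level, and — on significant
replicates generated under A2 — runs BEB and scores the flagged sites
against the simulated truth. Site-level confusion counts are pooled over
replicates (micro-average); per-replicate averages are reported alongside.

Fitting inside the study uses a two-stage scheme for speed: branch lengths
and kappa are first estimated under the single-ratio model M0, then held
fixed (up to a shared rescaling factor re-optimised per model) while each
branch-site model's kappa and mixture parameters are maximised. The
alternative is warm-started from the null solution, so the LRT statistic is
non-negative up to optimiser tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_models import FitResult, LikelihoodEngine, codon_frequencies, fit_model
from .evolver_sim import scale_branches, simulate
from .selection_tests import beb_site_posteriors, classify_sites, lrt
from .seqdata import CodonAlignment, PhyloTree
from .synthetic_data import DatasetTemplate, gstall_like_tree

__all__ = [
    "StudyConfig",
    "PowerSummary",
    "ReplicateRecord",
    "run_power_study",
    "site_detection_metrics",
    "fit_branch_site_pair",
    "fast_profile",
    "full_profile",
]


@dataclass
class StudyConfig:
    """One simulation condition of the power study."""

    tree: PhyloTree
    template: DatasetTemplate
    generating_model: str = "A2"  # "A1" (null) or "A2"
    omega2: float = 9.0  # foreground omega for A2 generation
    n_replicates: int = 100
    alpha: float = 0.05
    beb_thresholds: tuple[float, float] = (0.95, 0.99)
    branch_scale: float = 1.0
    restarts: int = 1
    fit_mode: str = "two_stage"  # or "joint"
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.generating_model not in ("A1", "A2"):
            raise ValueError("generating_model must be 'A1' or 'A2'")
        if not self.label:
            if self.generating_model == "A1":
                self.label = f"A1 x{self.branch_scale:g}"
            else:
                self.label = f"A2 w2={self.omega2:g} x{self.branch_scale:g}"


@dataclass
class ReplicateRecord:
    replicate: int
    seed: int
    lnl_null: float
    lnl_alt: float
    two_delta: float
    p_value: float
    significant: bool
    converged: bool
    n_true_sites: int = 0
    detected: dict = field(default_factory=dict)


@dataclass
class PowerSummary:
    """Aggregated study results for one condition.

    ``test_rate`` is the fraction of replicates with LRT p <= alpha — the
    test's power when generating under A2, its false-positive rate under A1.
    BEB metrics are pooled confusion-count ratios at each posterior
    threshold; per-replicate means are included for comparison. Metrics that
    are undefined (no sites detected in any scored replicate) are None.
    """

    condition: str
    generating_model: str
    omega2: float | None
    branch_scale: float
    alpha: float
    n_replicates: int
    n_failed: int
    test_rate: float
    beb_pooled: dict
    beb_mean: dict
    records: list[ReplicateRecord] = field(repr=False, default_factory=list)

    @property
    def test_power(self) -> float | None:
        return self.test_rate if self.generating_model == "A2" else None

    @property
    def test_fpr(self) -> float | None:
        return self.test_rate if self.generating_model == "A1" else None

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "generating_model": self.generating_model,
            "omega2": self.omega2,
            "branch_scale": self.branch_scale,
            "alpha": self.alpha,
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "test_rate": self.test_rate,
            "beb_pooled": self.beb_pooled,
            "beb_mean": self.beb_mean,
        }

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = dataclasses.asdict(r)
            det = row.pop("detected")
            for thr, d in det.items():
                for k, v in d.items():
                    row[f"{k}@{thr}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def site_detection_metrics(
    flagged_sites, true_classes, positive_labels=("2a", "2b"), class_labels=None
) -> tuple[float, float | None, float]:
    """Power, accuracy and false-positive rate of site detection.

    ``flagged_sites`` are 0-based detected site indices; ``true_classes`` is
    either an array of label strings or of class indices (with
    ``class_labels`` giving the label of each index). Power is the fraction
    of truly positive sites detected; accuracy the fraction of detected
    sites that are truly positive (None when nothing is detected); FPR the
    fraction of non-positive sites that were flagged.
    """
    true_classes = np.asarray(true_classes)
    flagged = np.asarray(flagged_sites, dtype=int)
    if flagged.size and (flagged.min() < 0 or flagged.max() >= len(true_classes)):
        raise ValueError("flagged site index outside the alignment")
    if class_labels is not None:
        labels = np.asarray([class_labels[i] for i in true_classes])
    else:
        labels = true_classes.astype(str)
    is_positive = np.isin(labels, list(positive_labels))
    n_true = int(is_positive.sum())
    n_neg = len(labels) - n_true
    detected_true = int(is_positive[flagged].sum()) if flagged.size else 0
    detected_false = int(flagged.size) - detected_true
    power = detected_true / n_true if n_true else float("nan")
    accuracy = detected_true / flagged.size if flagged.size else None
    fpr = detected_false / n_neg if n_neg else float("nan")
    return power, accuracy, fpr


def fit_branch_site_pair(
    alignment: CodonAlignment,
    tree: PhyloTree,
    *,
    frequencies: np.ndarray | None = None,
    restarts: int = 1,
    seed: int = 0,
    mode: str = "two_stage",
) -> tuple[FitResult, FitResult]:
    """Fit branch-site A1 and A2 with the A2 fit warm-started from A1."""
    if frequencies is None:
        frequencies = codon_frequencies(alignment, "F3x4")
    if mode == "joint":
        a1 = fit_model(
            alignment, tree, "A1", frequencies=frequencies,
            restarts=restarts, seed=seed,
        )
        embed = {
            "kappa": a1.kappa,
            "lengths": a1.branch_lengths,
            "p0": a1.params["p0"],
            "s1": a1.params["s1"],
            "omega0": a1.params["omega0"],
            "omega2": 1.0,
        }
        a2 = fit_model(
            alignment, tree, "A2", frequencies=frequencies,
            restarts=restarts + 1, seed=seed + 1, extra_starts=[embed],
        )
        return a1, a2

    # two-stage: M0 for branch lengths and kappa, then mixture + tree scale
    engine = LikelihoodEngine(alignment, tree, frequencies)
    # data-driven starting point for the tree scale
    init = tree.lengths.copy()
    if not (init > 1e-9).any():
        init[:] = 0.2
    m0 = fit_model(
        alignment, tree, "M0",
        frequencies=frequencies, restarts=1, seed=seed,
        optimize_branches=True, init_lengths=init, engine=engine, maxiter=300,
    )
    base_tree = tree.with_lengths(m0.branch_lengths)
    engine2 = LikelihoodEngine(alignment, base_tree, frequencies)
    a1 = fit_model(
        alignment, base_tree, "A1",
        frequencies=frequencies, restarts=restarts, seed=seed + 1,
        optimize_branches=False, optimize_scale=True, optimize_fg_scale=True,
        init_kappa=m0.kappa, engine=engine2, maxiter=300,
    )
    # recover A1's fitted global and foreground scale factors for warm starts
    bg_edges = (base_tree.parent >= 0) & ~base_tree.foreground
    fg_edges = base_tree.foreground
    a1_scale = float(
        np.median(a1.branch_lengths[bg_edges] / np.maximum(base_tree.lengths[bg_edges], 1e-12))
    )
    a1_fg = float(
        (a1.branch_lengths[fg_edges] / np.maximum(base_tree.lengths[fg_edges], 1e-12)).mean()
        / max(a1_scale, 1e-12)
    )
    embed = {
        "kappa": a1.kappa,
        "p0": a1.params["p0"],
        "s1": a1.params["s1"],
        "omega0": a1.params["omega0"],
        "omega2": 1.0,
        "scale": a1_scale,
        "fg_scale": a1_fg,
    }
    # two warm starts: at the null solution (guarantees 2*delta >= 0) and
    # pushed away from the omega2 = 1 boundary
    away = dict(embed, omega2=8.0)
    a2 = fit_model(
        alignment, base_tree, "A2",
        frequencies=frequencies, restarts=0, seed=seed + 2,
        optimize_branches=False, optimize_scale=True, optimize_fg_scale=True,
        init_kappa=a1.kappa, extra_starts=[embed, away], engine=engine2,
        maxiter=300,
    )
    return a1, a2


def run_power_study(config: StudyConfig, seed: int = 0) -> PowerSummary:
    """Run one condition of the simulation study."""
    tree = scale_branches(config.tree, config.branch_scale)
    template = config.template
    w2 = 1.0 if config.generating_model == "A1" else config.omega2
    model = template.model(w2)

    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(config.n_replicates)
    ]
    records: list[ReplicateRecord] = []
    n_failed = 0
    pooled: dict[float, dict[str, int]] = {
        thr: {"detected_true": 0, "detected_false": 0, "n_true": 0, "n_neg": 0}
        for thr in config.beb_thresholds
    }
    per_rep: dict[float, dict[str, list]] = {
        thr: {"power": [], "accuracy": [], "fpr": []} for thr in config.beb_thresholds
    }

    for r, rep_seed in enumerate(child_seeds):
        rep = simulate(tree, model, template.n_codons, rep_seed)
        try:
            a1, a2 = fit_branch_site_pair(
                rep.alignment,
                tree,
                restarts=config.restarts,
                seed=rep_seed,
                mode=config.fit_mode,
            )
            test = lrt(a1, a2)
        except Exception as exc:  # noqa: BLE001 — replicate-level failure
            n_failed += 1
            records.append(
                ReplicateRecord(
                    r, rep_seed, float("nan"), float("nan"), float("nan"),
                    float("nan"), False, False,
                )
            )
            continue
        significant = test.p_value <= config.alpha
        true_pos = rep.positive_sites()
        record = ReplicateRecord(
            replicate=r,
            seed=rep_seed,
            lnl_null=a1.lnL,
            lnl_alt=a2.lnL,
            two_delta=test.two_delta,
            p_value=test.p_value,
            significant=significant,
            converged=a1.converged and a2.converged,
            n_true_sites=len(true_pos),
        )
        if significant and config.generating_model == "A2":
            beb = beb_site_posteriors(
                rep.alignment, tree, a2, require_converged=False
            )
            tiers = classify_sites(beb, config.beb_thresholds)
            lo, hi = sorted(config.beb_thresholds)
            flagged_by_thr = {lo: tiers[f"P>{lo:g}"], hi: tiers[f"P>{hi:g}"]}
            is_pos = np.zeros(template.n_codons, dtype=bool)
            is_pos[true_pos] = True
            for thr, flagged in flagged_by_thr.items():
                flagged = np.asarray(flagged, dtype=int)
                dt = int(is_pos[flagged].sum()) if flagged.size else 0
                dfalse = int(flagged.size) - dt
                pooled[thr]["detected_true"] += dt
                pooled[thr]["detected_false"] += dfalse
                pooled[thr]["n_true"] += int(is_pos.sum())
                pooled[thr]["n_neg"] += int((~is_pos).sum())
                p, a, f = site_detection_metrics(
                    flagged, rep.true_classes, class_labels=rep.class_labels
                )
                per_rep[thr]["power"].append(p)
                if a is not None:
                    per_rep[thr]["accuracy"].append(a)
                per_rep[thr]["fpr"].append(f)
                record.detected[thr] = {
                    "n_flagged": int(flagged.size),
                    "detected_true": dt,
                    "detected_false": dfalse,
                }
        records.append(record)

    n_ok = config.n_replicates - n_failed
    n_sig = sum(1 for rec in records if rec.significant)
    test_rate = n_sig / n_ok if n_ok else float("nan")

    def _ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    beb_pooled = {}
    beb_mean = {}
    for thr, c in pooled.items():
        detected = c["detected_true"] + c["detected_false"]
        beb_pooled[thr] = {
            "power": _ratio(c["detected_true"], c["n_true"]),
            "accuracy": _ratio(c["detected_true"], detected),
            "fpr": _ratio(c["detected_false"], c["n_neg"]),
            "counts": dict(c),
        }
        vals = per_rep[thr]
        beb_mean[thr] = {
            "power": float(np.mean(vals["power"])) if vals["power"] else None,
            "accuracy": float(np.mean(vals["accuracy"])) if vals["accuracy"] else None,
            "fpr": float(np.mean(vals["fpr"])) if vals["fpr"] else None,
        }

    return PowerSummary(
        condition=config.label,
        generating_model=config.generating_model,
        omega2=None if config.generating_model == "A1" else config.omega2,
        branch_scale=config.branch_scale,
        alpha=config.alpha,
        n_replicates=n_ok,
        n_failed=n_failed,
        test_rate=test_rate,
        beb_pooled=beb_pooled,
        beb_mean=beb_mean,
        records=records,
    )


# ---------------------------------------------------------------------------
# Study profiles
# ---------------------------------------------------------------------------


def fast_profile(
    seed: int,
    n_taxa: int = 12,
    n_codons: int = 257,
    n_replicates: int = 50,
) -> tuple[PhyloTree, DatasetTemplate]:
    """Reduced-taxa profile: same codon count and divergence calibration as
    the full-size dataset but a smaller tree, sized for interactive runs."""
    template = DatasetTemplate(n_taxa=n_taxa, n_codons=n_codons)
    tree = gstall_like_tree(seed, n_taxa=n_taxa, template=template)
    template = dataclasses.replace(template, tree=tree)
    return tree, template


def full_profile(seed: int) -> tuple[PhyloTree, DatasetTemplate]:
    """Full-size profile: 31 taxa, 257 codons (a batch-scale run)."""
    return fast_profile(seed, n_taxa=31, n_codons=257, n_replicates=100)


#: the study's standard condition grid: a null condition at each of the
#: original and doubled branch lengths, and alternative conditions with
#: foreground omega2 in {4, 9, 999} plus a halved-branch-length variant at
#: omega2 = 9
STANDARD_CONDITIONS: tuple[tuple[str, str, float | None, float], ...] = (
    ("null", "A1", None, 1.0),
    ("null_double", "A1", None, 2.0),
    ("w4", "A2", 4.0, 1.0),
    ("w9", "A2", 9.0, 1.0),
    ("w9_half", "A2", 9.0, 0.5),
    ("w999", "A2", 999.0, 1.0),
)


def run_standard_study(
    seed: int,
    n_taxa: int = 12,
    n_codons: int = 257,
    n_replicates: int = 50,
    alpha: float = 0.05,
) -> dict[str, PowerSummary]:
    """Run the full standard condition grid on one calibrated tree.

    Returns one :class:`PowerSummary` per condition keyed by the condition
    names in :data:`STANDARD_CONDITIONS`.
    """
    ss = np.random.SeedSequence(seed)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(
        len(STANDARD_CONDITIONS) + 1
    )]
    tree, template = fast_profile(child[0], n_taxa=n_taxa, n_codons=n_codons)
    results: dict[str, PowerSummary] = {}
    for i, (name, gen, omega2, branch_scale) in enumerate(STANDARD_CONDITIONS):
        config = StudyConfig(
            tree=tree,
            template=template,
            generating_model=gen,
            omega2=omega2 if omega2 is not None else 9.0,
            branch_scale=branch_scale,
            n_replicates=n_replicates,
            alpha=alpha,
        )
        results[name] = run_power_study(config, seed=child[i + 1])
    return results
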