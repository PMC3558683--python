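"""Morphometric descriptors for comparing generated and reconstructed cells.

Scalar and distributional measures of a single morphology: total fiber
length, counts of bifurcations and terminal tips, tip-path contraction,
per-branch Hausdorff fractal dimension, van Pelt partition asymmetry,
centrifugal branch order, soma-to-tip path lengths, and a Sholl profile
of shell crossings.  All measures are geometric or topological, hence
invariant under rigid motion of the morphology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import Morphology, MorphologyError, iter_segments

__all__ = [
    "MorphometricReport",
    "contraction",
    "hausdorff_fractal_dimension",
    "fractal_dimension_twopoint",
    "partition_asymmetry",
    "sholl_profile",
    "branch_order_and_path_lengths",
    "report",
    "population_table",
    "population_summary",
]


# -- per-path measures ----------------------------------------------------


def _as_path(path) -> np.ndarray:
    arr = np.asarray(path, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("a path must be an (n, 3) array of points")
    return arr


def contraction(path) -> float:
    """Euclidean distance over path length from first to last point.

    Equals 1 exactly for a collinear path, 0 for a path returning to its
    start; undefined (raises) for zero path length.
    """
    arr = _as_path(path)
    if arr.shape[0] < 2:
        raise ValueError("contraction needs at least 2 points")
    steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    path_length = float(steps.sum())
    if path_length <= 0:
        raise ValueError("contraction is undefined for zero path length")
    return float(np.linalg.norm(arr[-1] - arr[0])) / path_length


def hausdorff_fractal_dimension(branch_path) -> float:
    """Per-branch Hausdorff dimension D from <E>^D = t.

    Over a stretch of path length t, the mean Euclidean excursion <E>
    grows like t^(1/D): D = 1 for straight paths, 2 for planar random
    walks.  Estimated by the structure-function (divider) method: for
    log-spaced window sizes tau (in steps, up to a quarter of the path)
    the excursion |p(i+tau) - p(i)| is averaged over every window start i,
    and D is the inverse least-squares slope of ln<E(tau)> against ln tau,
    clamped to [1, 3].  Averaging over windows keeps the estimator
    low-variance on a single branch; on a perfectly straight path the fit
    is exact and D = 1.  Raises on degenerate (coincident-point) paths.
    """
    arr = _as_path(branch_path)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("fractal dimension needs at least 3 points")
    steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    total = float(steps.sum())
    if total <= 0:
        raise ValueError("fractal dimension is undefined for zero path length")
    scale = total / (n - 1)  # mean step length
    tau_max = max(2, (n - 1) // 4)
    taus = np.unique(np.geomspace(1, tau_max, num=12).round().astype(int))
    log_tau, log_e = [], []
    for tau in taus:
        exc = np.linalg.norm(arr[tau:] - arr[:-tau], axis=1)
        mean_exc = float(exc.mean())
        if mean_exc > 0:
            log_tau.append(math.log(tau))
            log_e.append(math.log(mean_exc / scale))
    if len(log_tau) < 2:
        raise ValueError("fractal dimension is undefined: degenerate path")
    slope = float(np.polyfit(log_tau, log_e, 1)[0])
    if slope <= 0:
        return 3.0
    return float(np.clip(1.0 / slope, 1.0, 3.0))


def fractal_dimension_twopoint(branch_path) -> float:
    """Two-point variant D = ln t / ln E at the branch endpoint.

    Distances are in units of the mean step length.  Requires a Euclidean
    excursion above one step so the logarithm is informative.
    """
    arr = _as_path(branch_path)
    if arr.shape[0] < 3:
        raise ValueError("fractal dimension needs at least 3 points")
    steps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    t = float(steps.sum())
    if t <= 0:
        raise ValueError("fractal dimension is undefined for zero path length")
    scale = t / (arr.shape[0] - 1)
    e = float(np.linalg.norm(arr[-1] - arr[0])) / scale
    if e <= 1.0:
        raise ValueError("fractal dimension is undefined: excursion below one step")
    return float(np.clip(math.log(t / scale) / math.log(e), 1.0, 3.0))


# -- tree measures --------------------------------------------------------


def _tip_counts(morphology: Morphology) -> dict[int, int]:
    """Terminal-segment count of the subtree rooted at every node."""
    counts = {n.node_id: 0 for n in morphology.nodes}
    for node in reversed(morphology.nodes):
        kids = morphology.children(node.node_id)
        if not kids:
            counts[node.node_id] = 1
        else:
            counts[node.node_id] = sum(counts[k] for k in kids)
    return counts


def partition_asymmetry(tree: Morphology) -> float:
    """Van Pelt tree-balance index A in [0, 1].

    At each of the n - 1 bifurcations of a binary tree with n terminal
    tips, the two subtrees hold r and s terminal segments and contribute
    A_p(r, s) = |r - s| / (r + s - 2), defined as 0 when r = s = 1; A is
    the plain average over bifurcations.  0 for perfectly balanced trees,
    (n - 2)/(n - 1) for caterpillars.
    """
    bifs = tree.bifurcations()
    if not bifs:
        raise MorphologyError("partition asymmetry needs at least one bifurcation")
    counts = _tip_counts(tree)
    total = 0.0
    for nid in bifs:
        r, s = (counts[k] for k in tree.children(nid))
        if r == 1 and s == 1:
            continue
        total += abs(r - s) / (r + s - 2)
    return total / len(bifs)


def sholl_profile(morphology: Morphology, radii=None) -> dict[float, int]:
    """Shell-crossing counts of the classic Sholl analysis.

    For each radius, the number of segments whose endpoint distances from
    the soma straddle the shell; a segment crossing k shells contributes to
    each.  Defaults to 20 equal steps from the soma radius to the farthest
    tip.
    """
    soma = morphology.soma_position
    if radii is None:
        dists = np.linalg.norm(morphology.positions - soma, axis=1)
        r_max = float(dists.max())
        if r_max <= morphology.soma_radius:
            return {}
        radii = np.linspace(morphology.soma_radius, r_max, 21)[1:]
    radii = np.asarray(radii, dtype=float)
    if radii.size and (np.any(np.diff(radii) <= 0) or radii[0] <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    profile = {float(r): 0 for r in radii}
    for seg in iter_segments(morphology):
        r0 = float(np.linalg.norm(seg.start - soma))
        r1 = float(np.linalg.norm(seg.end - soma))
        lo, hi = min(r0, r1), max(r0, r1)
        for r in radii:
            if lo < r <= hi:
                profile[float(r)] += 1
    return profile


def branch_order_and_path_lengths(
    morphology: Morphology,
) -> tuple[dict[int, int], list[float]]:
    """Centrifugal order histogram over tips, and soma-to-tip path lengths.

    Stems are order 0; the order increments at every bifurcation passed.
    """
    bif_set = set(morphology.bifurcations())
    histogram: dict[int, int] = {}
    path_lengths: list[float] = []
    for tip in morphology.tips():
        path = morphology.path_to_root(tip)
        order = sum(1 for nid in path[:-1] if nid in bif_set)
        histogram[order] = histogram.get(order, 0) + 1
        pos = morphology.path_positions(tip)
        path_lengths.append(float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum()))
    return dict(sorted(histogram.items())), path_lengths


# -- aggregate report -----------------------------------------------------


@dataclass
class MorphometricReport:
    """Scalar metrics and distributions for one morphology."""

    total_length: float
    n_bifurcations: int
    n_tips: int
    n_stems: int
    contraction_mean: float
    contraction_sd: float
    fractal_dimension_mean: float
    fractal_dimension_sd: float
    n_fractal_branches: int
    partition_asymmetry: float
    path_length_mean: float
    path_length_sd: float
    branch_order_histogram: dict[int, int] = field(default_factory=dict)
    sholl_profile: dict[float, int] = field(default_factory=dict)

    def to_dict(self, flatten: bool = False) -> dict:
        d = {
            "total_length": self.total_length,
            "n_bifurcations": self.n_bifurcations,
            "n_tips": self.n_tips,
            "n_stems": self.n_stems,
            "contraction_mean": self.contraction_mean,
            "contraction_sd": self.contraction_sd,
            "fractal_dimension_mean": self.fractal_dimension_mean,
            "fractal_dimension_sd": self.fractal_dimension_sd,
            "n_fractal_branches": self.n_fractal_branches,
            "partition_asymmetry": self.partition_asymmetry,
            "path_length_mean": self.path_length_mean,
            "path_length_sd": self.path_length_sd,
            "branch_order_histogram": self.branch_order_histogram,
            "sholl_profile": self.sholl_profile,
        }
        if flatten:
            d["branch_order_histogram"] = json.dumps(self.branch_order_histogram)
            d["sholl_profile"] = json.dumps(
                {f"{r:g}": c for r, c in self.sholl_profile.items()}
            )
        return d


def _mean_sd(values) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def report(morphology: Morphology, sholl_radii=None) -> MorphometricReport:
    """Compute every descriptor for one morphology.

    Tip paths whose Euclidean excursion does not exceed one mean step are
    excluded from the fractal-dimension mean (the estimator is not defined
    there); tips with fewer than 3 path points are likewise skipped.
    """
    tips = morphology.tips()
    n_stems = len(morphology.children(1))
    contractions = []
    fractals = []
    for tip in tips:
        pos = morphology.path_positions(tip)
        try:
            contractions.append(contraction(pos))
        except ValueError:
            pass
        if pos.shape[0] >= 3:
            steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            mean_step = float(steps.mean())
            excursion = float(np.linalg.norm(pos[-1] - pos[0]))
            if excursion > mean_step:
                try:
                    fractals.append(hausdorff_fractal_dimension(pos))
                except ValueError:
                    pass
    try:
        asym = partition_asymmetry(morphology)
    except MorphologyError:
        asym = float("nan")
    order_hist, path_lengths = branch_order_and_path_lengths(morphology)
    c_mean, c_sd = _mean_sd(contractions)
    f_mean, f_sd = _mean_sd(fractals)
    p_mean, p_sd = _mean_sd(path_lengths)
    return MorphometricReport(
        total_length=morphology.total_length(),
        n_bifurcations=len(morphology.bifurcations()),
        n_tips=len(tips),
        n_stems=n_stems,
        contraction_mean=c_mean,
        contraction_sd=c_sd,
        fractal_dimension_mean=f_mean,
        fractal_dimension_sd=f_sd,
        n_fractal_branches=len(fractals),
        partition_asymmetry=asym,
        path_length_mean=p_mean,
        path_length_sd=p_sd,
        branch_order_histogram=order_hist,
        sholl_profile=sholl_profile(morphology, sholl_radii),
    )


# -- population aggregation ----------------------------------------------

_SCALAR_FIELDS = [
    "total_length",
    "n_bifurcations",
    "n_tips",
    "n_stems",
    "contraction_mean",
    "fractal_dimension_mean",
    "partition_asymmetry",
    "path_length_mean",
]


def population_table(reports, labels=None) -> pd.DataFrame:
    """One flat row per morphology (distributions JSON-encoded)."""
    rows = [r.to_dict(flatten=True) for r in reports]
    df = pd.DataFrame(rows)
    if labels is not None:
        df.insert(0, "label", list(labels))
    return df


def population_summary(reports) -> pd.DataFrame:
    """Mean and sd of every scalar metric across a population."""
    rows = []
    for name in _SCALAR_FIELDS:
        mean, sd = _mean_sd([getattr(r, name) for r in reports])
        rows.append({"metric": name, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)
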