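"""Evaluation metrics and selection of the number of ancestries.

Metrics compare inferred ancestor locations and decoded locus-level
ancestry against simulation truth. Because ancestry labels are arbitrary,
every metric first matches inferred to true ancestries by the label
permutation minimizing total paired distance.

* prediction error: mean distance between each inferred location and its
  matched true location.
* relative prediction error: the same, divided by the mean pairwise
  distance among the true locations (undefined for a single ancestry).
* local ancestry accuracy: fraction of loci whose matched decoded label
  equals the true label.
* local ancestry error: mean, over loci, of the distance between the
  location of the decoded ancestry and the location of the true ancestry.

The number of ancestries is chosen by AIC = 2k - 2 log L, with k counting
two coordinates per distinct inferred location plus (M - 1) free
proportions when those are optimized.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .em import run_em
from .gradients import GradientSet
from .hmm import TransitionModel

__all__ = [
    "EARTH_RADIUS_KM",
    "EvalReport",
    "geo_distance",
    "distance_matrix",
    "match_ancestries",
    "prediction_errors",
    "local_ancestry_metrics",
    "aic_select",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class EvalReport:
    """Bundle of the four evaluation metrics plus the matching used."""

    prediction_error: float
    relative_prediction_error: float
    local_accuracy: float
    local_error: float
    matching: tuple


def geo_distance(p, q, mode: str = "euclidean") -> float:
    """Distance between two map points.

    ``haversine`` treats coordinates as (longitude, latitude) in degrees
    and returns great-circle km on a sphere of radius 6371.0088 km;
    ``euclidean`` returns planar distance in map units.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (2,) or q.shape != (2,):
        raise ValueError("locations must be 2-D points")
    if mode == "euclidean":
        return float(np.hypot(*(p - q)))
    if mode == "haversine":
        for pt in (p, q):
            if not (-180.0 <= pt[0] <= 180.0 and -90.0 <= pt[1] <= 90.0):
                raise ValueError(f"invalid longitude/latitude: {pt}")
        lon1, lat1, lon2, lat2 = map(math.radians, (p[0], p[1], q[0], q[1]))
        s = (math.sin((lat2 - lat1) / 2) ** 2
             + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2)
        return float(2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s))))
    raise ValueError(f"unknown distance mode {mode!r}")


def distance_matrix(P, Q, mode: str = "euclidean") -> np.ndarray:
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    return np.array([[geo_distance(p, q, mode) for q in Q] for p in P])


def match_ancestries(inferred, truth, mode: str = "euclidean") -> tuple:
    """Label permutation matching inferred to true ancestries.

    Returns a tuple ``perm`` with ``perm[j]`` the true index assigned to
    inferred ancestry j, minimizing the total paired distance. Exhaustive
    search in lexicographic order (deterministic tie-break) up to 6
    ancestries, Hungarian assignment beyond.
    """
    D = distance_matrix(inferred, truth, mode)
    if D.shape[0] != D.shape[1]:
        raise ValueError("inferred and true location counts differ")
    M = D.shape[0]
    if M <= 6:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(M)):
            cost = sum(D[j, perm[j]] for j in range(M))
            if cost < best_cost:  # strict: first (lexicographic) optimum kept
                best, best_cost = perm, cost
        return best
    rows, cols = linear_sum_assignment(D)
    return tuple(int(cols[np.argwhere(rows == j)[0, 0]]) for j in range(M))


def prediction_errors(inferred, truth, mode: str = "euclidean"):
    """(prediction error, relative prediction error) after label matching.

    The relative error divides by the mean pairwise distance among the true
    locations; with a single ancestry it is undefined and returned as NaN.
    """
    inferred = np.atleast_2d(np.asarray(inferred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    perm = match_ancestries(inferred, truth, mode)
    M = inferred.shape[0]
    err = float(np.mean([geo_distance(inferred[j], truth[perm[j]], mode) for j in range(M)]))
    if M == 1:
        return err, float("nan")
    pair = [geo_distance(truth[j], truth[k], mode)
            for j in range(M) for k in range(j + 1, M)]
    return err, err / float(np.mean(pair))


def local_ancestry_metrics(decoded_path, true_path, inferred_locations,
                           true_locations, mode: str = "euclidean"):
    """(accuracy, mean per-locus location error) after label matching."""
    decoded = np.asarray(decoded_path, dtype=np.int64)
    true = np.asarray(true_path, dtype=np.int64)
    if decoded.shape != true.shape:
        raise ValueError("decoded and true paths have different lengths")
    inferred_locations = np.atleast_2d(np.asarray(inferred_locations, dtype=float))
    true_locations = np.atleast_2d(np.asarray(true_locations, dtype=float))
    perm = np.asarray(match_ancestries(inferred_locations, true_locations, mode))
    accuracy = float(np.mean(perm[decoded] == true))
    D = distance_matrix(inferred_locations, true_locations, mode)
    error = float(np.mean(D[decoded, true]))
    return accuracy, error


def evaluate(inferred_locations, true_locations, decoded_path, true_path,
             mode: str = "euclidean") -> EvalReport:
    """All four metrics in one report."""
    pe, rpe = prediction_errors(inferred_locations, true_locations, mode)
    acc, lerr = local_ancestry_metrics(decoded_path, true_path,
                                       inferred_locations, true_locations, mode)
    perm = match_ancestries(inferred_locations, true_locations, mode)
    return EvalReport(prediction_error=pe, relative_prediction_error=rpe,
                      local_accuracy=acc, local_error=lerr, matching=perm)


def aic_for(loglik: float, n_locations: int, n_free_proportions: int = 0) -> float:
    """AIC = 2k - 2 log L with k = 2 coordinates per location + free
    proportions."""
    k = 2 * n_locations + n_free_proportions
    return 2.0 * k - 2.0 * loglik


def aic_select(h, grad: GradientSet, trans: TransitionModel, candidate_counts, *,
               pi_fixed: bool = True, restarts: int = 3, seed=None,
               tol: float = 1e-6, max_iter: int = 200, init_box=None):
    """Choose the number of ancestries by AIC over candidate counts.

    Runs the haploid EM once per candidate M and scores
    AIC = 2k - 2 log L. Candidates whose EM raises are flagged and excluded.
    Returns (selected count, table); ties go to the smaller count.
    """
    candidates = sorted(set(int(m) for m in candidate_counts))
    if not candidates:
        raise ValueError("no candidate counts supplied")
    rows = []
    rng = np.random.default_rng(seed)
    for M in candidates:
        sub = int(rng.integers(0, 2**31 - 1))
        try:
            res = run_em(h, grad, M, trans, pi_fixed=pi_fixed, restarts=restarts,
                         seed=sub, tol=tol, max_iter=max_iter, init_box=init_box)
        except Exception as exc:  # noqa: BLE001 - candidate-level containment
            rows.append({"count": M, "loglik": np.nan, "k": np.nan, "aic": np.nan,
                         "converged": False, "error": str(exc)})
            continue
        n_free = (M - 1) if not pi_fixed else 0
        rows.append({"count": M, "loglik": res.loglik, "k": 2 * M + n_free,
                     "aic": aic_for(res.loglik, M, n_free),
                     "converged": res.converged, "error": ""})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["aic"])
    if valid.empty:
        raise RuntimeError("every candidate count failed to fit")
    # idxmin returns the first (smallest-count) row among ties
    selected = int(valid.sort_values("count").loc[valid["aic"].idxmin(), "count"])
    return selected, table
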