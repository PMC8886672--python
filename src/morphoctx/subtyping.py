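"""Cellular morphometric subtype discovery and cross-cohort transfer.

Subtypes are discovered by consensus clustering of per-sample context
vectors: repeated k-means on bootstrap subsamples, aggregated into a
co-clustering (consensus) matrix; final labels come from an average-linkage
cut of the consensus dissimilarity. The number of subtypes is chosen by the
proportion of ambiguous clustering (PAC, lower = more stable), with
prognostic impact as a tie-break. A trained model transfers to new cohorts
by nearest centroid in Euclidean distance and can be refined by re-running
consensus clustering with an agreement check against the transferred labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans


@dataclass
class ConsensusResult:
    """Consensus clustering output at one candidate k."""

    k: int
    consensus: np.ndarray  # (n, n), symmetric, unit diagonal
    assignments: np.ndarray  # labels 1..k
    pac: float
    never_cosampled: int = 0  # pairs with zero co-subsample count (flagged 0)


@dataclass
class SubtypeModel:
    """Trained subtype model: centroids in context space plus provenance."""

    k: int
    centroids: np.ndarray  # (k, n_atoms)
    assignments: np.ndarray  # training labels 1..k
    sample_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("a subtype model needs k >= 2")
        counts = np.bincount(np.asarray(self.assignments), minlength=self.k + 1)[1:]
        if (counts == 0).any():
            raise ValueError("every subtype needs at least one training sample")


def _as_matrix(contexts) -> tuple[np.ndarray, list[str]]:
    if isinstance(contexts, pd.DataFrame):
        return contexts.to_numpy(float), [str(i) for i in contexts.index]
    X = np.asarray(contexts, dtype=float)
    return X, [str(i) for i in range(len(X))]


def consensus_cluster(
    contexts,
    k: int,
    n_boot: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
    n_restarts: int = 10,
) -> ConsensusResult:
    """Consensus k-means clustering over bootstrap subsamples.

    Per iteration, ``ceil(subsample * n)`` samples are drawn without
    replacement and clustered by Euclidean k-means (k-means++, ``n_restarts``
    initializations). consensus(i, j) is the fraction of co-subsampled
    iterations in which i and j landed in the same cluster (pairs never
    co-subsampled get 0 and are counted in ``never_cosampled``). Final
    assignments cut the average-linkage tree of 1 - consensus into k groups.
    """
    X, _ids = _as_matrix(contexts)
    n = len(X)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} samples, got {n}")
    m = int(np.ceil(subsample * n))
    rng = np.random.default_rng(seed)
    km_seeds = rng.integers(0, 2**31 - 1, size=n_boot)

    together = np.zeros((n, n))
    cosampled = np.zeros((n, n))
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        labels = KMeans(
            n_clusters=k, n_init=n_restarts, random_state=int(km_seeds[b])
        ).fit_predict(X[idx])
        ind = np.zeros((n,), dtype=bool)
        ind[idx] = True
        cosampled[np.ix_(idx, idx)] += 1
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
    never = int(((cosampled == 0).sum() - n) // 2) if (cosampled == 0).any() else 0
    consensus = (consensus + consensus.T) / 2
    np.fill_diagonal(consensus, 1.0)

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assignments = fcluster(Z, t=k, criterion="maxclust")
    return ConsensusResult(
        k=k,
        consensus=consensus,
        assignments=assignments.astype(int),
        pac=compute_pac(consensus),
        never_cosampled=never,
    )


def compute_pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering.

    Fraction of off-diagonal consensus entries strictly inside
    ``(lower, upper)`` — pairs the bootstrap neither firmly joins nor firmly
    separates. 0 means perfectly stable clustering.
    """
    C = np.asarray(consensus, float)
    n = C.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = C[off]
    return float(((vals > lower) & (vals < upper)).mean())


def select_k(
    results: list[ConsensusResult],
    survival: pd.DataFrame | None = None,
    pac_tie: float = 0.01,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of subtypes from a sweep of consensus results.

    Primary criterion: minimal PAC. Results whose PAC is within ``pac_tie``
    of the minimum are tied; ties break by the smallest log-rank p of the
    candidate's assignments on ``survival`` (a table with ``time`` and
    ``event`` columns, row order matching the contexts) when supplied, else
    by the smallest k. Returns the chosen k and the full decision trace.
    """
    if not results:
        raise ValueError("no consensus results supplied")
    rows = []
    for res in results:
        p = np.nan
        if survival is not None:
            from lifelines.statistics import multivariate_logrank_test

            test = multivariate_logrank_test(
                survival["time"].to_numpy(float),
                res.assignments,
                survival["event"].to_numpy(int),
            )
            p = float(test.p_value)
        rows.append({"k": res.k, "pac": res.pac, "logrank_p": p})
    trace = pd.DataFrame(rows).sort_values("k").reset_index(drop=True)
    best_pac = trace["pac"].min()
    tied = trace[trace["pac"] <= best_pac + pac_tie]
    if survival is not None and tied["logrank_p"].notna().any():
        chosen = int(tied.loc[tied["logrank_p"].idxmin(), "k"])
    else:
        chosen = int(tied["k"].min())
    trace["chosen"] = trace["k"] == chosen
    return chosen, trace


def finalize_subtypes(
    contexts,
    k: int,
    assignments: np.ndarray,
    survival: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> SubtypeModel:
    """Build the transferable model: per-subtype mean context vectors.

    Subtype indices are renumbered so that outcome ordering is reproducible:
    with ``survival`` supplied, index increases as mean survival time
    decreases (subtype 2 is the worse-outcome group); otherwise clusters are
    numbered by decreasing size.
    """
    X, ids = _as_matrix(contexts)
    assignments = np.asarray(assignments, dtype=int)
    if assignments.min() < 1 or assignments.max() > k:
        raise ValueError("assignments must lie in 1..k")
    for g in range(1, k + 1):
        if not (assignments == g).any():
            raise ValueError(f"subtype {g} has no samples")

    if survival is not None:
        times = survival["time"].to_numpy(float)
        key = [-times[assignments == g].mean() for g in range(1, k + 1)]
    else:
        key = [-(assignments == g).sum() for g in range(1, k + 1)]
    order = np.argsort(np.asarray(key), kind="stable")  # old labels, new order
    relabel = np.empty(k + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        relabel[old + 1] = new
    new_assignments = relabel[assignments]

    centroids = np.vstack(
        [X[new_assignments == g].mean(axis=0) for g in range(1, k + 1)]
    )
    return SubtypeModel(
        k=k,
        centroids=centroids,
        assignments=new_assignments,
        sample_ids=ids,
        provenance=provenance or {},
    )


def assign_subtype(context, model: SubtypeModel) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid transfer: label = argmin Euclidean distance.

    Accepts one context vector or an (n, d) matrix. Exact ties go to the
    lowest-index subtype. Returns (labels in 1..k, distance matrix with one
    column per subtype).
    """
    X = np.atleast_2d(np.asarray(context, float) if not isinstance(context, pd.DataFrame) else context.to_numpy(float))
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"context dimension {X.shape[1]} does not match centroids "
            f"{model.centroids.shape[1]}"
        )
    dists = np.sqrt(((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2))
    labels = dists.argmin(axis=1) + 1  # argmin takes the first minimum: lowest index
    if np.ndim(context) == 1 or (isinstance(context, pd.Series)):
        return labels[0], dists[0]
    return labels, dists


def refine_subtypes(
    new_contexts,
    model: SubtypeModel,
    n_boot: int = 500,
    seed: int = 0,
    subsample: float = 0.8,
) -> tuple[SubtypeModel, dict]:
    """Refine a transferred model by re-clustering the new cohort.

    Runs consensus clustering at the transferred model's k, matches refined
    clusters to transferred labels by maximal contingency overlap (optimal
    one-to-one matching on the k x k table), and reports the contingency
    table, agreement fraction, and the chi-square test of independence
    between transferred and refined labels.
    """
    X, ids = _as_matrix(new_contexts)
    transferred, _ = assign_subtype(X, model)
    res = consensus_cluster(X, model.k, n_boot=n_boot, subsample=subsample, seed=seed)

    k = model.k
    table = np.zeros((k, k), dtype=int)
    for t, r in zip(transferred, res.assignments):
        table[t - 1, r - 1] += 1
    # match refined labels to transferred labels (maximize overlap)
    row, col = linear_sum_assignment(-table)
    relabel = np.empty(k + 1, dtype=int)
    for t_idx, r_idx in zip(row, col):
        relabel[r_idx + 1] = t_idx + 1
    refined = relabel[res.assignments]
    agreement = float((refined == transferred).mean())

    nonzero_rows = table.sum(axis=1) > 0
    nonzero_cols = table.sum(axis=0) > 0
    sub = table[np.ix_(nonzero_rows, nonzero_cols)]
    if sub.shape[0] > 1 and sub.shape[1] > 1:
        chi2, p, _, _ = chi2_contingency(sub)
    else:
        chi2, p = np.nan, np.nan

    # labels already matched to the transferred numbering; do not renumber.
    # an empty refined class would be a degenerate refinement — surface it.
    centroids = np.vstack([
        X[refined == g].mean(axis=0) if (refined == g).any() else model.centroids[g - 1]
        for g in range(1, k + 1)
    ])
    refined_model = SubtypeModel(
        k=k,
        centroids=centroids,
        assignments=refined,
        sample_ids=ids,
        provenance={"refined_from": model.provenance, "seed": seed, "n_boot": n_boot},
    )
    report = {
        "contingency": table,
        "agreement": agreement,
        "chi2": float(chi2),
        "chi2_p": float(p),
        "pac": res.pac,
        "transferred": transferred,
        "refined": refined,
    }
    return refined_model, report
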