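"""Sparse decomposition of cellular morphometry.

Learns a bank of 256 unit-norm dictionary atoms ("cellular morphometric
biomarkers", CMB) in standardized 15-feature space, represents every cell as
a nonnegative sparse code over the bank (at most ``sparsity`` = 30 active
atoms), and max-pools codes into one 256-dimensional context vector per
sample. A ridge-regression fast encoder provides an optional approximate
coding path; the greedy pursuit is the reference encoder.

Encoding is a truncated nonnegative greedy pursuit: atoms enter the active
set by maximal positive correlation with the residual, active coefficients
are re-fit by nonnegative least squares after every selection, and pursuit
stops at the atom budget or when the residual stops improving. Coefficients
are nonnegative throughout so pooled values read as biomarker abundances.
"""

from __future__ import annotations

import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

MODEL_FORMAT_VERSION = 1


@dataclass
class FastEncoder:
    """Feed-forward map from features to approximate codes.

    ``layers`` holds (weights, bias) per layer with ``activation`` applied
    between layers (none for a single affine layer). Outputs are clipped at 0
    to keep the abundance reading.
    """

    layers: list[tuple[np.ndarray, np.ndarray]]
    activation: str = "relu"

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, float)
        for W, b in self.layers[:-1]:
            h = h @ W + b
            if self.activation == "relu":
                h = np.maximum(h, 0.0)
            elif self.activation == "tanh":
                h = np.tanh(h)
        W, b = self.layers[-1]
        return np.maximum(h @ W + b, 0.0)


@dataclass
class CMBDictionary:
    """Learned biomarker bank: unit-norm atoms plus standardization stats."""

    atoms: np.ndarray  # (n_atoms, n_features), rows unit norm
    sparsity: int = 30
    feature_means: np.ndarray = field(default_factory=lambda: np.zeros(0))
    feature_sds: np.ndarray = field(default_factory=lambda: np.ones(0))
    objective_trace: list[float] = field(default_factory=list)
    seed: int | None = None
    encoder: FastEncoder | None = None

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        norms = np.linalg.norm(self.atoms, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("dictionary atoms must have unit Euclidean norm")
        if self.sparsity > self.n_atoms:
            raise ValueError("sparsity cannot exceed the number of atoms")

    def save(self, path: str | Path) -> None:
        """Serialize to a single JSON file (versioned layout)."""
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "atoms": self.atoms.tolist(),
            "sparsity": int(self.sparsity),
            "feature_means": np.asarray(self.feature_means, float).tolist(),
            "feature_sds": np.asarray(self.feature_sds, float).tolist(),
            "objective_trace": [float(v) for v in self.objective_trace],
            "seed": self.seed,
            "encoder": None
            if self.encoder is None
            else {
                "layers": [[W.tolist(), b.tolist()] for W, b in self.encoder.layers],
                "activation": self.encoder.activation,
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CMBDictionary":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        enc = payload.get("encoder")
        return cls(
            atoms=np.asarray(payload["atoms"], float),
            sparsity=int(payload["sparsity"]),
            feature_means=np.asarray(payload["feature_means"], float),
            feature_sds=np.asarray(payload["feature_sds"], float),
            objective_trace=list(payload["objective_trace"]),
            seed=payload.get("seed"),
            encoder=None
            if enc is None
            else FastEncoder(
                layers=[
                    (np.asarray(W, float), np.asarray(b, float))
                    for W, b in enc["layers"]
                ],
                activation=enc["activation"],
            ),
        )


# ---------------------------------------------------------------------------
# sampling


def sample_objects(
    tables: Mapping[str, pd.DataFrame], rate: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Sample up to ``rate`` cellular objects per slide, without replacement.

    Returns the sampled rows stacked into one table with a ``slide_id`` column
    tagging provenance; slides with fewer than ``rate`` objects contribute all
    of theirs. Deterministic under ``seed`` (slides processed in sorted-id
    order with independent child streams).
    """
    if rate < 1:
        raise ValueError("rate must be >= 1")
    if not tables:
        raise ValueError("no feature tables supplied")
    slide_ids = sorted(tables)
    children = np.random.SeedSequence(seed).spawn(len(slide_ids))
    parts = []
    for sid, child in zip(slide_ids, children):
        table = tables[sid]
        n = len(table)
        take = min(rate, n)
        idx = np.sort(np.random.default_rng(child).choice(n, size=take, replace=False))
        part = table.iloc[idx].copy()
        if "slide_id" in part.columns:
            part["slide_id"] = sid
        else:
            part.insert(0, "slide_id", sid)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# encoding kernel


@njit(cache=True)
def _pursuit_kernel(G, AtX, xnorm2, sparsity, tol):  # pragma: no cover - jitted
    """Truncated nonnegative pursuit for a batch of targets.

    G is the (K, K) atom gram matrix, AtX the (K, n) atom/target correlations,
    xnorm2 the squared target norms. For each target: repeatedly add the atom
    with maximal positive correlation to the residual, re-fit the active set
    by nonnegative least squares (inner deletion loop), and stop at the atom
    budget, when no positive correlation remains, or when the residual norm
    improves by less than ``tol``.
    """
    K = G.shape[0]
    n = AtX.shape[1]
    codes = np.zeros((n, K))
    for col in range(n):
        Atx = AtX[:, col]
        coef = np.zeros(K)
        passive = np.zeros(K, dtype=np.bool_)
        n_active = 0
        res_norm = np.sqrt(max(xnorm2[col], 0.0))
        while n_active < sparsity:
            # gradient = correlation of atoms with current residual
            w = Atx - G @ coef
            jbest = -1
            wbest = tol
            for j in range(K):
                if not passive[j] and w[j] > wbest:
                    wbest = w[j]
                    jbest = j
            if jbest < 0:
                break
            coef_prev = coef.copy()
            passive_prev = passive.copy()
            n_active_prev = n_active
            passive[jbest] = True
            n_active += 1
            # nonnegative least squares on the passive set (deletion loop)
            while True:
                idx = np.empty(n_active, dtype=np.int64)
                m = 0
                for j in range(K):
                    if passive[j]:
                        idx[m] = j
                        m += 1
                Gp = np.empty((m, m))
                bp = np.empty(m)
                for a in range(m):
                    bp[a] = Atx[idx[a]]
                    for b in range(m):
                        Gp[a, b] = G[idx[a], idx[b]]
                z = np.linalg.solve(Gp + 1e-12 * np.eye(m), bp)
                if np.all(z >= -1e-12):
                    for j in range(K):
                        coef[j] = 0.0
                    for a in range(m):
                        coef[idx[a]] = max(z[a], 0.0)
                    break
                # drop the most negative coefficient and re-solve
                amin = 0
                zmin = z[0]
                for a in range(1, m):
                    if z[a] < zmin:
                        zmin = z[a]
                        amin = a
                passive[idx[amin]] = False
                n_active -= 1
            # residual norm after refit
            Gc = G @ coef
            q = 0.0
            for a in range(K):
                if coef[a] > 0.0:
                    q += coef[a] * (2.0 * Atx[a] - Gc[a])
            new_norm2 = max(xnorm2[col] - q, 0.0)
            new_norm = np.sqrt(new_norm2)
            if res_norm - new_norm < tol:
                # sub-tolerance improvement: revert the addition and stop
                coef = coef_prev
                passive = passive_prev
                n_active = n_active_prev
                break
            res_norm = new_norm
        codes[col] = coef
    return codes


def encode(
    X: np.ndarray,
    dictionary: CMBDictionary,
    sparsity: int | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Sparse-encode standardized rows against the dictionary.

    Returns an ``(n, n_atoms)`` nonnegative code matrix with at most
    ``sparsity`` nonzeros per row. A zero input row yields an all-zero code.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != dictionary.atoms.shape[1]:
        raise ValueError("input dimension does not match the dictionary")
    s = dictionary.sparsity if sparsity is None else int(sparsity)
    A = dictionary.atoms
    G = A @ A.T
    AtX = A @ X.T
    xnorm2 = np.einsum("ij,ij->i", X, X)
    return _pursuit_kernel(G, AtX, xnorm2, s, tol)


def sparse_encode(
    x: np.ndarray,
    dictionary: CMBDictionary,
    sparsity: int | None = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Sparse code of a single standardized 15-vector (see :func:`encode`)."""
    return encode(np.asarray(x, float)[None, :], dictionary, sparsity, tol)[0]


# ---------------------------------------------------------------------------
# dictionary learning


def learn_dictionary(
    X: np.ndarray,
    n_atoms: int = 256,
    sparsity: int = 30,
    n_iter: int = 30,
    seed: int = 0,
    rel_tol: float = 1e-5,
    feature_means: np.ndarray | None = None,
    feature_sds: np.ndarray | None = None,
) -> CMBDictionary:
    """Learn the biomarker dictionary by alternating minimization.

    Each iteration sparse-encodes every training row against the current
    atoms, then updates each used atom to its least-squares optimum over the
    rows using it (coefficients rescaled to absorb the renormalization). A
    per-row monotone safeguard keeps the previous code whenever fresh pursuit
    would reconstruct worse, so the recorded mean-squared-error trace is
    non-increasing by construction. Atoms unused in an epoch are re-seeded
    from the worst-reconstructed rows.

    Parameters
    ----------
    X:
        Standardized training matrix with at least ``n_atoms`` distinct rows.
    n_iter:
        Maximum alternations; stops early when the relative objective change
        falls below ``rel_tol``.
    feature_means, feature_sds:
        Standardization statistics to store with the model (for re-applying
        to new cohorts).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < n_atoms:
        raise ValueError(f"need at least {n_atoms} rows, got {n}")
    distinct = np.unique(X, axis=0)
    distinct = distinct[np.linalg.norm(distinct, axis=1) > 1e-12]
    if len(distinct) < n_atoms:
        raise ValueError(
            f"need at least {n_atoms} distinct nonzero rows, got {len(distinct)}"
        )

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(len(distinct), size=n_atoms, replace=False)
    atoms = distinct[init_idx]
    atoms = atoms / np.linalg.norm(atoms, axis=1, keepdims=True)

    trace: list[float] = []
    codes = np.zeros((n, n_atoms))
    model = CMBDictionary(atoms=atoms.copy(), sparsity=sparsity)
    for _iteration in range(n_iter):
        model.atoms = atoms
        fresh = encode(X, model, sparsity=sparsity)
        # monotone safeguard: keep whichever code reconstructs each row better
        err_fresh = np.sum((X - fresh @ atoms) ** 2, axis=1)
        err_prev = np.sum((X - codes @ atoms) ** 2, axis=1)
        keep_prev = err_prev < err_fresh
        codes = np.where(keep_prev[:, None], codes, fresh)
        err = np.where(keep_prev, err_prev, err_fresh)
        obj = float(err.mean())
        trace.append(obj)
        if obj < 1e-14:
            break
        if len(trace) > 1 and (trace[-2] - obj) / trace[-2] < rel_tol:
            break

        # per-atom least-squares update
        recon = codes @ atoms
        usage = (codes > 0).sum(axis=0)
        for k in range(n_atoms):
            users = codes[:, k] > 0
            if not users.any():
                continue
            c = codes[users, k]
            E = X[users] - recon[users] + np.outer(c, atoms[k])
            d_ls = E.T @ c / (c @ c)
            scale = np.linalg.norm(d_ls)
            if scale <= 1e-12:
                continue
            new_atom = d_ls / scale
            recon[users] += np.outer(c * scale, new_atom) - np.outer(c, atoms[k])
            atoms[k] = new_atom
            codes[users, k] = c * scale
        # re-seed dead atoms from the worst-reconstructed rows
        dead = np.flatnonzero(usage == 0)
        if len(dead):
            err_now = np.sum((X - recon) ** 2, axis=1)
            worst = np.argsort(err_now)[::-1]
            for k, row in zip(dead, worst):
                v = X[row]
                nv = np.linalg.norm(v)
                if nv > 1e-12:
                    atoms[k] = v / nv

    return CMBDictionary(
        atoms=atoms,
        sparsity=sparsity,
        feature_means=np.asarray(
            feature_means if feature_means is not None else np.zeros(d), float
        ),
        feature_sds=np.asarray(
            feature_sds if feature_sds is not None else np.ones(d), float
        ),
        objective_trace=trace,
        seed=seed,
    )


def train_fast_encoder(
    X: np.ndarray,
    codes: np.ndarray,
    architecture: str = "mlp",
    alpha: float = 1e-3,
    hidden: int = 64,
    seed: int = 0,
) -> FastEncoder:
    """Fit the fast encoder mapping features to pursuit codes.

    ``architecture="mlp"`` (default) fits one hidden layer by least squares
    (L-BFGS); ``"ridge"`` fits a plain affine ridge map. The encoder is an
    optional approximate path for large cohorts; the greedy pursuit remains
    the reference encoder.
    """
    X = np.asarray(X, float)
    codes = np.asarray(codes, float)
    if len(X) != len(codes):
        raise ValueError("X and codes must have aligned rows")
    if architecture == "ridge":
        from sklearn.linear_model import Ridge

        ridge = Ridge(alpha=alpha, fit_intercept=True)
        ridge.fit(X, codes)
        return FastEncoder(
            layers=[(np.asarray(ridge.coef_.T, float), np.asarray(ridge.intercept_, float))]
        )
    if architecture != "mlp":
        raise ValueError(f"unknown architecture {architecture!r}")
    from sklearn.neural_network import MLPRegressor

    mlp = MLPRegressor(
        hidden_layer_sizes=(hidden,), solver="lbfgs", max_iter=500, random_state=seed
    )
    mlp.fit(X, codes)
    return FastEncoder(
        layers=[
            (np.asarray(W, float), np.asarray(b, float))
            for W, b in zip(mlp.coefs_, mlp.intercepts_)
        ],
        activation="relu",
    )


# ---------------------------------------------------------------------------
# pooling


def pool_context(codes_by_sample: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Max-pool per-cell sparse codes into one context vector per sample.

    Each sample's context is the elementwise maximum over its cells' codes —
    the peak abundance of every biomarker in the sample. Returns a DataFrame
    indexed by sample id with ``CMB_1..CMB_K`` columns.
    """
    if not codes_by_sample:
        raise ValueError("no samples supplied")
    rows = {}
    n_atoms = None
    for sid in sorted(codes_by_sample):
        block = np.atleast_2d(np.asarray(codes_by_sample[sid], float))
        if block.size == 0 or block.shape[0] == 0:
            raise ValueError(f"sample {sid!r} has no cellular codes")
        if n_atoms is None:
            n_atoms = block.shape[1]
        elif block.shape[1] != n_atoms:
            raise ValueError("inconsistent code dimensions across samples")
        rows[sid] = block.max(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = [f"CMB_{j}" for j in range(1, n_atoms + 1)]
    out.index.name = "sample_id"
    return out
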