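"""End-to-end orchestration: feature tables -> dictionary -> contexts -> subtypes.

Thin composition of the module-level operations, used by the CLI, the
examples and the end-to-end tests. Each step is also usable on its own.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .morphometry import FEATURE_NAMES, standardize
from .spsd import CMBDictionary, encode, learn_dictionary, pool_context, sample_objects
from .subtyping import ConsensusResult, SubtypeModel, consensus_cluster, finalize_subtypes, select_k


def learn_from_tables(
    features: Mapping[str, pd.DataFrame],
    rate: int = 1000,
    n_atoms: int = 256,
    sparsity: int = 30,
    n_iter: int = 10,
    seed: int = 0,
) -> CMBDictionary:
    """Sample cells per slide, standardize, and learn the biomarker bank.

    Standardization statistics are computed on the sampled training matrix
    and stored with the dictionary for application to new cohorts.
    """
    sampled = sample_objects(features, rate=rate, seed=seed)
    Z, (means, sds) = standardize(sampled[list(FEATURE_NAMES)].to_numpy(float))
    return learn_dictionary(
        Z, n_atoms=n_atoms, sparsity=sparsity, n_iter=n_iter, seed=seed,
        feature_means=means, feature_sds=sds,
    )


def encode_cohort(
    features: Mapping[str, pd.DataFrame],
    dictionary: CMBDictionary,
    use_fast_encoder: bool = False,
) -> pd.DataFrame:
    """Encode every cell with the trained dictionary and max-pool per sample.

    Applies the dictionary's stored standardization to each slide's features,
    sparse-encodes (or uses the fast encoder when requested and available),
    and returns the (samples x biomarkers) context matrix.
    """
    codes_by_sample: dict[str, np.ndarray] = {}
    stats = (dictionary.feature_means, dictionary.feature_sds)
    for sid in sorted(features):
        table = features[sid]
        Z, _ = standardize(table[list(FEATURE_NAMES)].to_numpy(float), stats=stats)
        if use_fast_encoder:
            if dictionary.encoder is None:
                raise ValueError("dictionary has no trained fast encoder")
            codes_by_sample[sid] = dictionary.encoder.predict(Z)
        else:
            codes_by_sample[sid] = encode(Z, dictionary)
    return pool_context(codes_by_sample)


def subtype_cohort(
    contexts: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    k_range: range = range(2, 7),
    n_boot: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
) -> tuple[SubtypeModel, list[ConsensusResult], pd.DataFrame]:
    """Consensus-cluster contexts over a k range and finalize the best model.

    ``survival`` (rows aligned with ``contexts``) both tie-breaks the k
    selection by log-rank separation and anchors subtype numbering so that
    higher indices carry worse outcome.
    """
    results = [
        consensus_cluster(contexts, k, n_boot=n_boot, subsample=subsample, seed=seed + k)
        for k in k_range
    ]
    k, trace = select_k(results, survival=survival)
    chosen = next(r for r in results if r.k == k)
    model = finalize_subtypes(
        contexts, k, chosen.assignments, survival=survival,
        provenance={"seed": seed, "n_boot": n_boot, "k_range": list(k_range)},
    )
    return model, results, trace
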