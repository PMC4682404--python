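"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from depca import core


def zero_reference(item_ids) -> core.ReferenceVector:
    return core.ReferenceVector(r=pd.Series(0.0, index=list(item_ids)),
                                provenance="grand_mean")


def random_centered(rng: np.random.Generator, n_samples: int, n_items: int
                    ) -> core.CenteredMatrix:
    X = pd.DataFrame(
        rng.normal(size=(n_samples, n_items)),
        index=[f"s{k}" for k in range(n_samples)],
        columns=[f"i{l}" for l in range(n_items)],
    )
    return core.CenteredMatrix(X=X)


def per_sample_groups(X: core.CenteredMatrix) -> core.Design:
    """Each sample is its own training group (degenerate configuration T = X)."""
    return core.Design(group_of={s: s for s in X.sample_ids})


def grouped_design(X: core.CenteredMatrix, n_groups: int) -> core.Design:
    """Assign samples round-robin to n_groups groups."""
    samples = X.sample_ids
    return core.Design(
        group_of={s: f"G{k % n_groups}" for k, s in enumerate(samples)})


def fit_from_centered(X: core.CenteredMatrix, design: core.Design | None = None,
                      **kwargs):
    """Convenience: training matrix + axis model from a centered matrix."""
    if design is None:
        design = per_sample_groups(X)
    T = core.build_training(X, design, **kwargs)
    model = core.fit_axes(T, zero_reference(X.item_ids), X.m_f)
    return model, T


def duplicate_items(X: core.CenteredMatrix, k: int) -> core.CenteredMatrix:
    """Tile every item column k times (new unique ids), preserving values."""
    tiled = np.tile(X.X.to_numpy(), (1, k))
    cols = [f"d{c}_{i}" for c in range(k) for i in X.item_ids]
    return core.CenteredMatrix(
        X=pd.DataFrame(tiled, index=X.sample_ids, columns=cols))


def align_columns(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Flip columns of `other` whose correlation with `reference` is negative."""
    signs = np.sign(np.einsum("ij,ij->j", reference, other))
    signs[signs == 0] = 1.0
    return other * signs
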