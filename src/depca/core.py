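"""Designed-experiment principal component analysis.

Standard PCA ties both the rotation center and the axis directions to the
particular matrix being analysed, so scores cannot be compared across
experiments and group bias (unequal replication) distorts the axes.  This
module implements a variant built for designed experiments:

* the data are centered on an experiment-defined **reference** (the mean of
  a control group, or the grand mean), which becomes the origin of the
  component space;
* axes are identified by singular value decomposition of a **training
  matrix** ``T`` whose rows are group representatives (means, trimmed means
  or medians of the centered samples), so every group carries equal weight
  no matter how many replicates it has;
* sample scores ``Y_s = X @ V_T`` are divided by ``sqrt(m_f)`` (the number
  of functional items) and item scores ``Y_i = T.T @ U_T`` by ``sqrt(n_t)``
  (the number of training rows).  Because any score is a sum of ``m_f``
  bounded inner-product terms through unit-norm loadings, unscaled scores
  grow like ``sqrt(m_f)``; the division yields a size unit independent of
  how many items (or training rows) were used, so scores from different
  item sets, and sample and item scores themselves, live on comparable
  scales.

Missing and excluded (e.g. test-negative) items are encoded as exact zeros
in the centered matrix: zero means "no difference from the reference", so
the replacement can only pull scores toward the origin, never away from it
(a fail-safe direction).

The factorization ``(V_T, D_T, U_T)`` plus the reference vector form an
:class:`AxisModel` that can be serialized and shared, letting other
laboratories project their own samples onto pre-arranged axes and classify
unknown material by nearest group representative.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UsageError

logger = logging.getLogger(__name__)

GRAND_MEAN = "grand_mean"
CONTROL_GROUP = "control_group"

#: deterministic replacement for the manual per-axis sign choice: the
#: loading of largest absolute value in each column of V is made positive,
#: ties broken by lowest item index.
SIGN_CONVENTION = "largest-loading-positive"

_DEFAULT_TOL_RANK = 1e-12


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Item-by-sample grid of normalized expression levels.

    ``values`` has item ids as the index and sample ids as columns; ``NaN``
    marks missing cells.  Ids must be unique on both axes.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate item ids: {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dup}")

    @property
    def item_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass(frozen=True)
class Design:
    """Sample-to-group map plus the rule designating the reference.

    ``reference_rule`` is either :data:`GRAND_MEAN` (item-wise mean over all
    samples, the natural choice for a time course with no control) or
    :data:`CONTROL_GROUP` with ``control_label`` naming the control group.
    ``training_groups`` lists the groups that contribute rows to the
    training matrix, in order; by default every group, in first-appearance
    order.
    """

    group_of: Mapping[str, str]
    reference_rule: str = GRAND_MEAN
    control_label: str | None = None
    training_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.reference_rule not in (GRAND_MEAN, CONTROL_GROUP):
            raise UsageError(f"unknown reference rule {self.reference_rule!r}")
        groups = list(dict.fromkeys(self.group_of.values()))
        if self.reference_rule == CONTROL_GROUP:
            if self.control_label is None:
                raise UsageError("control_group rule requires control_label")
            if self.control_label not in groups:
                raise DataError(
                    f"control group {self.control_label!r} has no samples; "
                    f"groups present: {groups}"
                )
        if not self.training_groups:
            object.__setattr__(self, "training_groups", tuple(groups))
        else:
            missing = [g for g in self.training_groups if g not in groups]
            if missing:
                raise DataError(f"training groups without samples: {missing}")

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.group_of.values()))

    def samples_of(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.group_of]
        if missing:
            raise DataError(f"samples without a group assignment: {missing}")


@dataclass(frozen=True)
class ReferenceVector:
    """Per-item reference level ``r``; the origin of the component space.

    ``undefined_items`` lists items whose reference could not be computed
    (all designated cells missing); their reference is 0 and they are
    excluded from the functional item count downstream.
    """

    r: pd.Series
    provenance: str
    undefined_items: frozenset[str] = frozenset()

    @property
    def item_ids(self) -> list[str]:
        return list(self.r.index)


@dataclass(frozen=True)
class CenteredMatrix:
    """Sample-by-item matrix of reference-subtracted values.

    Missing cells and cells of excluded items are exactly 0.  ``m_f`` is a
    property of the matrix: the number of items not excluded.  Per-sample
    missing cells do not change ``m_f``; they are zero-filled.
    """

    X: pd.DataFrame  # samples x items
    excluded_items: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.m_f < 1:
            raise DataError("no functional items remain (m_f < 1)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    @property
    def m_f(self) -> int:
        return self.n_items - len(self.excluded_items)


@dataclass(frozen=True)
class TrainingMatrix:
    """Centered group representatives (rows) over the same items as X.

    Row labels are group labels, or sample ids for groups expanded into
    their individual samples (the group-bias scenario).
    """

    T: pd.DataFrame  # rows x items

    @property
    def row_labels(self) -> list[str]:
        return list(self.T.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.T.columns)

    @property
    def n_t(self) -> int:
        return self.T.shape[0]


@dataclass(frozen=True)
class AxisModel:
    """The shareable factorization ``T = U_T @ diag(D_T) @ V_T.T``.

    ``V`` (items x axes) has orthonormal columns and defines the axis
    directions; ``d`` holds the non-increasing singular values; ``U``
    (training rows x axes) is kept so item components and training scores
    can be reproduced.  ``reference``, ``n_t`` and ``m_f`` travel with the
    model so a receiving laboratory can center and scale identically.
    """

    V: pd.DataFrame                    # items x axes, columns PC1..PCk
    d: np.ndarray                      # singular values, non-increasing
    reference: ReferenceVector
    n_t: int
    m_f: int
    U: pd.DataFrame | None = None      # training rows x axes
    sign_convention: str = SIGN_CONVENTION

    @property
    def item_ids(self) -> list[str]:
        return list(self.V.index)

    @property
    def n_axes(self) -> int:
        return self.V.shape[1]

    @property
    def axis_labels(self) -> list[str]:
        return list(self.V.columns)

    def validate(self, atol: float = 1e-10) -> None:
        """Check orthonormality of V (and of U when present)."""
        V = self.V.to_numpy()
        gram = V.T @ V
        if not np.allclose(gram, np.eye(self.n_axes), atol=atol):
            raise DataError("V columns are not orthonormal")
        if np.any(np.diff(self.d) > 0) or np.any(self.d < 0):
            raise DataError("singular values must be non-negative and non-increasing")
        if self.U is not None:
            U = self.U.to_numpy()
            if not np.allclose(U.T @ U, np.eye(self.n_axes), atol=atol):
                raise DataError("U columns are not orthonormal")


@dataclass(frozen=True)
class ComponentTable:
    """Scores of samples (or items) on the model's axes.

    ``scaled`` records whether the size-unit division has been applied and
    ``scale_divisor`` by what (``sqrt(m_f)`` for samples, ``sqrt(n_t)`` for
    items).  Axis columns are labeled ``PC1..`` unscaled, ``sPC1..`` scaled.
    """

    scores: pd.DataFrame
    row_kind: str  # "samples" | "items"
    scaled: bool = False
    scale_divisor: float | None = None

    def __post_init__(self) -> None:
        if self.row_kind not in ("samples", "items"):
            raise UsageError(f"row_kind must be 'samples' or 'items', got {self.row_kind!r}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def _axis_labels(k: int, scaled: bool) -> list[str]:
    prefix = "sPC" if scaled else "PC"
    return [f"{prefix}{j + 1}" for j in range(k)]


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def compute_reference(matrix: ExpressionMatrix, design: Design) -> ReferenceVector:
    """Item-wise mean over the designated sample set.

    The designated set is every sample under the grand-mean rule, or the
    control group's samples under the control-group rule.  Missing cells are
    ignored; items with no observed cell in the set get reference 0 and are
    flagged for exclusion downstream.
    """
    design.check_covers(matrix)
    if design.reference_rule == GRAND_MEAN:
        samples = matrix.sample_ids
        provenance = GRAND_MEAN
    else:
        samples = [s for s in matrix.sample_ids
                   if design.group_of[s] == design.control_label]
        provenance = f"{CONTROL_GROUP}:{design.control_label}"
    if not samples:
        raise DataError(
            f"reference rule {provenance!r} designates no samples in the matrix"
        )
    sub = matrix.values[samples]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        r = sub.mean(axis=1, skipna=True)
    undefined = frozenset(r.index[r.isna()])
    if undefined:
        logger.warning("%d items have no observed reference cell; excluded",
                       len(undefined))
    return ReferenceVector(r=r.fillna(0.0), provenance=provenance,
                           undefined_items=undefined)


def center(matrix: ExpressionMatrix, reference: ReferenceVector) -> CenteredMatrix:
    """Subtract the reference from every sample; transpose to sample-by-item.

    Observed cells become ``s - r``; missing cells become exactly 0 (no
    difference from the reference).  Items whose reference was undefined are
    excluded from ``m_f``.
    """
    missing = [i for i in matrix.item_ids if i not in reference.r.index]
    if missing:
        raise DataError(f"reference does not cover items: {missing}")
    r = reference.r.reindex(matrix.item_ids)
    X = matrix.values.sub(r, axis=0).T  # samples x items
    X = X.fillna(0.0)
    excluded = frozenset(i for i in reference.undefined_items
                         if i in matrix.values.index)
    if excluded:
        X.loc[:, list(excluded)] = 0.0
    return CenteredMatrix(X=X, excluded_items=excluded)


def zero_out_items(X: CenteredMatrix, items: Iterable[str]) -> CenteredMatrix:
    """Zero-replace the listed items' columns and drop them from ``m_f``.

    Used to remove e.g. test-negative genes.  The shape is unchanged, so
    axis models stay aligned; the zeros pull scores toward the origin only.
    """
    items = set(items)
    unknown = items - set(X.item_ids)
    if unknown:
        raise DataError(f"unknown item ids: {sorted(unknown)}")
    if not items:
        return X
    newX = X.X.copy()
    newX.loc[:, sorted(items)] = 0.0
    return CenteredMatrix(X=newX, excluded_items=X.excluded_items | items)


# ---------------------------------------------------------------------------
# training matrix and axes
# ---------------------------------------------------------------------------

def _representative_row(rows: np.ndarray, representative: str,
                        trim_fraction: float, group: str) -> np.ndarray:
    n_g = rows.shape[0]
    if representative == "mean":
        return rows.mean(axis=0)
    if representative == "median":
        return np.median(rows, axis=0)
    if representative == "trimmed_mean":
        if n_g < 5:
            warnings.warn(
                f"group {group!r} has {n_g} samples; trimmed mean degrades "
                "to the mean below 5 samples", UserWarning, stacklevel=3)
            return rows.mean(axis=0)
        if math.ceil(2 * trim_fraction * n_g) >= n_g:
            raise UsageError(
                f"trim fraction {trim_fraction} removes all {n_g} samples "
                f"of group {group!r}")
        return stats.trim_mean(rows, trim_fraction, axis=0)
    raise UsageError(f"unknown representative {representative!r}")


def build_training(X: CenteredMatrix, design: Design,
                   representative: str = "mean",
                   trim_fraction: float = 0.2,
                   expand_groups: Iterable[str] = ()) -> TrainingMatrix:
    """One row per training group: the group representative of its samples.

    Groups in ``expand_groups`` instead contribute every individual sample
    row — this reproduces group bias on purpose (each extra row pulls the
    axes toward that group), which balanced representatives avoid.
    """
    expand = set(expand_groups)
    unknown = expand - set(design.training_groups)
    if unknown:
        raise DataError(f"expand_groups not in training groups: {sorted(unknown)}")
    sample_index = {s: i for i, s in enumerate(X.sample_ids)}
    rows: list[np.ndarray] = []
    labels: list[str] = []
    Xv = X.X.to_numpy()
    for group in design.training_groups:
        members = [s for s in design.samples_of(group) if s in sample_index]
        if not members:
            raise DataError(f"training group {group!r} has no samples in the matrix")
        sub = Xv[[sample_index[s] for s in members], :]
        if group in expand:
            rows.extend(sub)
            labels.extend(members)
        else:
            rows.append(_representative_row(sub, representative, trim_fraction, group))
            labels.append(group)
    T = pd.DataFrame(np.asarray(rows), index=labels, columns=X.item_ids)
    return TrainingMatrix(T=T)


def fit_axes(T: TrainingMatrix, reference: ReferenceVector, m_f: int,
             tol_rank: float = _DEFAULT_TOL_RANK) -> AxisModel:
    """Identify orthogonal axes by SVD of the training matrix.

    ``T`` is *not* re-centered: the reference already fixed the center of
    rotation, and subtracting T's column means would silently move it back
    to the grand mean.  Axes with singular value below ``tol_rank`` times
    the largest are numerically null and dropped.  Signs are made
    deterministic by :func:`unify_signs`.
    """
    A = T.T.to_numpy(dtype=float)
    if not np.any(A):
        raise DataError("training data identical to reference (all-zero matrix)")
    U, d, Vt = np.linalg.svd(A, full_matrices=False)
    keep = d > tol_rank * d[0]
    U, d, Vt = U[:, keep], d[keep], Vt[keep, :]
    labels = _axis_labels(len(d), scaled=False)
    model = AxisModel(
        V=pd.DataFrame(Vt.T, index=T.item_ids, columns=labels),
        d=d,
        reference=reference,
        n_t=T.n_t,
        m_f=int(m_f),
        U=pd.DataFrame(U, index=T.row_labels, columns=labels),
    )
    return unify_signs(model)


def unify_signs(model: AxisModel) -> AxisModel:
    """Deterministic sign choice per axis.

    SVD fixes each axis only up to sign.  For each column of V, if the
    loading of largest absolute value is negative, negate that column of V
    and of U (ties go to the lowest item index, numpy argmax order).  The
    product ``U @ diag(d) @ V.T`` is unchanged; applying twice is a no-op.
    """
    V = model.V.to_numpy().copy()
    U = model.U.to_numpy().copy() if model.U is not None else None
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            if U is not None:
                U[:, j] = -U[:, j]
    return replace(
        model,
        V=pd.DataFrame(V, index=model.V.index, columns=model.V.columns),
        U=None if U is None else pd.DataFrame(U, index=model.U.index,
                                              columns=model.U.columns),
        sign_convention=SIGN_CONVENTION,
    )


# ---------------------------------------------------------------------------
# projection and scaling
# ---------------------------------------------------------------------------

def _align_items(X: CenteredMatrix, model: AxisModel) -> np.ndarray:
    """Reconcile matrix items with model items by id.

    Model items absent from the matrix contribute 0 (scores move toward the
    origin, never away); matrix items absent from the model are dropped with
    a logged count.
    """
    model_items = model.item_ids
    present = [i for i in model_items if i in X.X.columns]
    if not present:
        raise DataError("no overlap between matrix items and model items")
    dropped = X.n_items - len(present)
    zero_filled = len(model_items) - len(present)
    if dropped:
        logger.info("dropping %d matrix items absent from the axis model", dropped)
    if zero_filled:
        logger.info("zero-filling %d model items absent from the matrix", zero_filled)
    aligned = X.X.reindex(columns=model_items, fill_value=0.0)
    return aligned.to_numpy(dtype=float)


def project_samples(X: CenteredMatrix, model: AxisModel) -> ComponentTable:
    """Unscaled sample scores ``Y_s = X @ V_T`` on the model's axes."""
    Xa = _align_items(X, model)
    Y = Xa @ model.V.to_numpy()
    return ComponentTable(
        scores=pd.DataFrame(Y, index=X.sample_ids,
                            columns=_axis_labels(model.n_axes, scaled=False)),
        row_kind="samples",
    )


def training_scores(model: AxisModel) -> ComponentTable:
    """Unscaled scores of the training rows themselves: ``U_T @ diag(D_T)``.

    Identical to projecting the training matrix, so group representatives
    and experimental samples live on the same axes.
    """
    if model.U is None:
        raise DataError("axis model carries no left vectors (U); "
                        "re-fit or load a model saved with them")
    Y = model.U.to_numpy() * model.d
    return ComponentTable(
        scores=pd.DataFrame(Y, index=model.U.index,
                            columns=_axis_labels(model.n_axes, scaled=False)),
        row_kind="samples",
    )


def item_components(model: AxisModel, T: TrainingMatrix) -> ComponentTable:
    """Unscaled item scores ``Y_i = T.T @ U_T`` (algebraically ``V_T @ diag(D_T)``)."""
    if model.U is None:
        raise DataError("axis model carries no left vectors (U)")
    if T.row_labels != list(model.U.index) or T.item_ids != model.item_ids:
        raise DataError("training matrix does not match the fitted model "
                        "(row labels or item ids differ)")
    Y = T.T.to_numpy().T @ model.U.to_numpy()
    return ComponentTable(
        scores=pd.DataFrame(Y, index=T.item_ids,
                            columns=_axis_labels(model.n_axes, scaled=False)),
        row_kind="items",
    )


def _scale(table: ComponentTable, count: int, what: str) -> ComponentTable:
    if count < 1:
        raise UsageError(f"{what} must be >= 1, got {count}")
    if table.scaled:
        raise UsageError("component table is already scaled")
    divisor = math.sqrt(count)
    scores = table.scores / divisor
    scores.columns = _axis_labels(table.n_axes, scaled=True)
    return ComponentTable(scores=scores, row_kind=table.row_kind,
                          scaled=True, scale_divisor=divisor)


def scale_sample_components(Y_s: ComponentTable, m_f: int) -> ComponentTable:
    """Scaled sample scores ``Z_s = Y_s / sqrt(m_f)``.

    Divides out the sqrt growth of scores with the number of functional
    items, leaving the average per-item contribution — a size unit that is
    stable under adding or removing (uninformative halves of) items.
    """
    if Y_s.row_kind != "samples":
        raise UsageError("scale_sample_components expects a sample table")
    return _scale(Y_s, m_f, "m_f")


def scale_item_components(Y_i: ComponentTable, n_t: int) -> ComponentTable:
    """Scaled item scores ``Z_i = Y_i / sqrt(n_t)`` (n_t = training rows)."""
    if Y_i.row_kind != "items":
        raise UsageError("scale_item_components expects an item table")
    return _scale(Y_i, n_t, "n_t")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify(sample_scores: ComponentTable, training_scores: ComponentTable,
             n_axes_used: int | None = None) -> pd.DataFrame:
    """Nearest-representative classification in component space.

    Euclidean distance over the first ``n_axes_used`` axes (default: all
    shared axes) from each sample to each training representative.  Both
    tables must be on the same scale (both scaled or both unscaled).  Ties
    go to the earlier training row.

    Returns a frame indexed by sample id with columns ``label`` (nearest
    representative), ``distance``, and one ``dist_<label>`` column per
    representative.
    """
    if sample_scores.scaled != training_scores.scaled:
        raise UsageError("sample and training scores must be on the same scale")
    available = min(sample_scores.n_axes, training_scores.n_axes)
    if n_axes_used is None:
        n_axes_used = available
    if n_axes_used > available or n_axes_used < 1:
        raise UsageError(
            f"n_axes_used={n_axes_used} outside 1..{available} available axes")
    S = sample_scores.scores.to_numpy()[:, :n_axes_used]
    R = training_scores.scores.to_numpy()[:, :n_axes_used]
    # (n_samples, n_reps) distance matrix
    D = np.sqrt(((S[:, None, :] - R[None, :, :]) ** 2).sum(axis=2))
    nearest = D.argmin(axis=1)  # argmin takes the first minimum: tie rule
    labels = list(training_scores.scores.index)
    out = pd.DataFrame(
        {
            "label": [labels[i] for i in nearest],
            "distance": D[np.arange(len(nearest)), nearest],
        },
        index=sample_scores.scores.index,
    )
    for j, lab in enumerate(labels):
        out[f"dist_{lab}"] = D[:, j]
    return out
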