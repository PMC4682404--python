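"""Per-gene two-way ANOVA filter for expressional change.

Each gene is measured by several probes across all samples.  The filter
fits the additive fixed-effects model

    value = overall level + probe sensitivity + group effect + error

per gene and tests the group factor with the standard F test.  Genes with
p below the threshold (default 0.01, no multiplicity correction) are
"positive"; negative genes are what :func:`depca.core.zero_out_items`
removes before axes are identified.  An F test is one-sided by
construction; the conventional F p-value is used.

Genes that cannot support the test (fewer than 2 probes, fewer than 2
groups represented, or no residual degree of freedom) are flagged
untestable and are never positive.

The F statistics are computed by projection onto the column spaces of the
full and probe-only design matrices, vectorized across all genes sharing a
probe count; a test cross-checks the result against a conventional
per-gene OLS ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .core import Design
from .errors import DataError, UsageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeLevelData:
    """Normalized probe values for many genes over one sample set.

    ``values`` is indexed by (gene_id, probe_id) with sample columns.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.nlevels != 2:
            raise DataError("probe-level index must be (gene_id, probe_id)")
        if self.values.index.has_duplicates:
            raise DataError("duplicate (gene_id, probe_id) rows")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index.get_level_values(0).unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class FilterResult:
    """Per-gene p-value for the group effect and the positive call.

    ``table`` columns: ``p_value`` (NaN for untestable genes), ``positive``
    (bool), ``untestable`` (bool).  ``positive`` is exactly ``p < alpha``.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def n_positive(self) -> int:
        return int(self.table["positive"].sum())

    @property
    def n_untestable(self) -> int:
        return int(self.table["untestable"].sum())

    @property
    def n_negative(self) -> int:
        return len(self.table) - self.n_positive - self.n_untestable


def _group_f_batch(Y: np.ndarray, n_probes: int, groups: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """F statistic and p for the group factor, all genes at once.

    ``Y``: (n_genes, n_probes * n_samples) with cells ordered probe-major.
    Residual sums of squares come from orthonormal bases (QR) of the full
    (probe + group) and reduced (probe only) design-matrix column spaces.
    """
    n_samples = len(groups)
    n_obs = n_probes * n_samples
    labels = pd.unique(groups)
    n_groups = len(labels)
    probe_idx = np.repeat(np.arange(n_probes), n_samples)
    group_idx = np.tile(
        np.array([np.flatnonzero(labels == g)[0] for g in groups]), n_probes)

    def onehot(idx: np.ndarray, k: int) -> np.ndarray:
        M = np.zeros((n_obs, k))
        M[np.arange(n_obs), idx] = 1.0
        return M

    X_red = onehot(probe_idx, n_probes)           # spans intercept too
    X_full = np.hstack([X_red, onehot(group_idx, n_groups)[:, 1:]])
    df_num = n_groups - 1
    df_den = n_obs - (n_probes + n_groups - 1)
    if df_den < 1:
        raise UsageError("no residual degrees of freedom for the ANOVA")
    Q_red, _ = np.linalg.qr(X_red)
    Q_full, _ = np.linalg.qr(X_full)
    yy = np.einsum("ij,ij->i", Y, Y)
    rss_full = yy - np.einsum("ij,ij->i", Y @ Q_full, Y @ Q_full)
    rss_red = yy - np.einsum("ij,ij->i", Y @ Q_red, Y @ Q_red)
    ss_group = np.maximum(rss_red - rss_full, 0.0)
    rss_full = np.maximum(rss_full, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_group / df_num) / (rss_full / df_den)
    # constant-within-model genes: no evidence of a group effect
    scale = np.maximum(yy, 1.0)
    degenerate = rss_full <= 1e-12 * scale
    F = np.where(degenerate & (ss_group <= 1e-12 * scale), 0.0, F)
    p = stats.f.sf(F, df_num, df_den)
    p = np.where(np.isnan(F), np.nan, p)
    return F, p


def anova_group_test(data: ProbeLevelData, design: Design,
                     alpha: float = 0.01) -> FilterResult:
    """Test every gene's group effect with the additive two-factor ANOVA.

    Requires complete probe data (no missing cells) and >=2 probes, >=2
    groups, and >=1 residual degree of freedom per gene; genes failing
    these are untestable, never positive.
    """
    if not 0 <= alpha <= 1:
        raise UsageError(f"alpha must be in [0, 1], got {alpha}")
    missing = [s for s in data.sample_ids if s not in design.group_of]
    if missing:
        raise DataError(f"samples without a group assignment: {missing}")
    groups = np.array([design.group_of[s] for s in data.sample_ids])
    n_groups = len(pd.unique(groups))
    n_samples = len(data.sample_ids)

    counts = data.values.groupby(level=0, sort=False).size()
    genes = list(counts.index)
    p_out = pd.Series(np.nan, index=genes, dtype=float)
    untestable = pd.Series(False, index=genes)

    vals = data.values
    if vals.isna().any().any():
        bad = vals.index[vals.isna().any(axis=1)].get_level_values(0).unique()
        raise DataError(f"missing probe values for genes: {list(bad)[:5]}...")

    for n_probes, sub_counts in counts.groupby(counts):
        batch_genes = list(sub_counts.index)
        df_den = n_probes * n_samples - (n_probes + n_groups - 1)
        if n_probes < 2 or n_groups < 2 or df_den < 1:
            untestable[batch_genes] = True
            continue
        # probe-major layout: (gene, probe*sample)
        sub = vals.loc[batch_genes]
        Y = sub.to_numpy().reshape(len(batch_genes), n_probes * n_samples)
        _, p = _group_f_batch(Y, n_probes, groups)
        p_out[batch_genes] = p

    positive = (p_out < alpha).fillna(False) & ~untestable
    table = pd.DataFrame({
        "p_value": p_out,
        "positive": positive.astype(bool),
        "untestable": untestable.astype(bool),
    })
    logger.info("ANOVA filter at alpha=%g: %d positive, %d negative, %d untestable",
                alpha, int(table["positive"].sum()),
                int((~table["positive"] & ~table["untestable"]).sum()),
                int(table["untestable"].sum()))
    return FilterResult(table=table, alpha=alpha)


def anova_group_test_gene_level(matrix_values: pd.DataFrame, design: Design,
                                alpha: float = 0.01) -> FilterResult:
    """One-way ANOVA fallback on gene-level values (factor: group).

    An approximation of the probe-level test for when only summarized
    expression values are available; probe sensitivity cannot be modeled.
    """
    groups = np.array([design.group_of[s] for s in matrix_values.columns])
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise UsageError("one-way ANOVA needs >= 2 groups")
    samples_by_group = [np.flatnonzero(groups == g) for g in labels]
    V = matrix_values.to_numpy()
    args = [V[:, idx] for idx in samples_by_group]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*args, axis=1)
    p = pd.Series(res.pvalue, index=matrix_values.index)
    table = pd.DataFrame({
        "p_value": p,
        "positive": (p < alpha).fillna(False),
        "untestable": p.isna(),
    })
    return FilterResult(table=table, alpha=alpha)


def select_items(result: FilterResult) -> tuple[set[str], set[str]]:
    """Partition testable genes into (positive, negative) id sets.

    The negative set is what gets zero-replaced before axis fitting;
    untestable genes belong to neither set.
    """
    t = result.table
    testable = ~t["untestable"]
    positive = set(t.index[t["positive"] & testable])
    negative = set(t.index[~t["positive"] & testable])
    return positive, negative


def benjamini_hochberg(result: FilterResult, alpha: float | None = None
                       ) -> FilterResult:
    """Optional FDR mode: recompute positives at a BH-adjusted threshold.

    Off by default; the plain per-gene threshold is the primary behaviour.
    """
    from statsmodels.stats.multitest import multipletests  # optional dep

    t = result.table.copy()
    alpha = result.alpha if alpha is None else alpha
    testable = ~t["untestable"] & t["p_value"].notna()
    reject, *_ = multipletests(t.loc[testable, "p_value"], alpha=alpha,
                               method="fdr_bh")
    t["positive"] = False
    t.loc[testable, "positive"] = reject
    return FilterResult(table=t, alpha=alpha)
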