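"""Feature filtering and head vs body/tail significance screening.

Columns containing any non-finite sentinel, or constant across all cases,
are removed before testing (a zero-variance column has no defined t
statistic).  Each surviving feature is then compared between the two tumor
location classes with a two-sided Welch (unequal-variance) t-test — the
groups are unbalanced and variance equality is unverifiable — and flagged
significant at p < alpha with no multiplicity correction by default; an
optional Benjamini-Hochberg FDR flag is provided but off by default, since
the screening this mirrors used a plain 5% threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .feature_grid import FeatureTable
from .io_preprocess import ValidationError

__all__ = [
    "ScreeningConfig",
    "ScreeningResult",
    "filter_features",
    "ttest_screen",
    "manhattan_export",
]


@dataclass(frozen=True)
class ScreeningConfig:
    alpha: float = 0.05
    fdr: bool = False  # optional Benjamini-Hochberg correction

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class ScreeningResult:
    """Per-feature Welch statistics plus summary counts.

    ``frame`` is indexed by descriptor string with columns
    ``family, t, p, significant``.
    """

    frame: pd.DataFrame
    alpha: float

    @property
    def n_tested(self) -> int:
        return len(self.frame)

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_tested if self.n_tested else float("nan")

    def significant_columns(self) -> list[str]:
        return list(self.frame.index[self.frame["significant"]])


def filter_features(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Drop unusable columns: any non-finite value, or zero variance.

    Returns the filtered table and the list of dropped descriptors.
    Idempotent; raises if every column is dropped.
    """
    if table.n_cases == 0 or table.n_features == 0:
        raise ValidationError("empty feature table")
    vals = table.values
    finite = np.isfinite(vals).all(axis=0)
    varying = np.zeros(table.n_features, dtype=bool)
    varying[finite] = np.ptp(vals[:, finite], axis=0) > 0
    keep = finite & varying
    dropped = [c for c, k in zip(table.columns, keep) if not k]
    if not keep.any():
        raise ValidationError("all feature columns were unusable")
    kept_cols = [c for c, k in zip(table.columns, keep) if k]
    return table.subset_columns(kept_cols), dropped


def ttest_screen(
    head_rows: FeatureTable,
    bodytail_rows: FeatureTable,
    config: ScreeningConfig = ScreeningConfig(),
) -> ScreeningResult:
    """Two-sided Welch t-test per feature, head vs body/tail.

    The t statistic is signed head-minus-body/tail; swapping the groups
    negates every t and preserves every p.  Requires at least two cases per
    group and identical descriptors in identical order.
    """
    if head_rows.columns != bodytail_rows.columns:
        raise ValidationError("descriptor mismatch between groups")
    if head_rows.n_cases < 2 or bodytail_rows.n_cases < 2:
        raise ValidationError("need at least 2 cases per group")
    a = head_rows.values
    b = bodytail_rows.values
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical columns trigger scipy's precision-loss warning;
        # they resolve to t=0, p=1 below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    # both groups constant at the same value: scipy yields nan (0/0);
    # an identical pair of groups carries no signal, so t=0, p=1
    degenerate = ~np.isfinite(t) & ~np.isfinite(p)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    # infinite separation (zero within-group variance, different means)
    inf_sep = np.isinf(t)
    p[inf_sep] = 0.0
    if config.fdr:
        reject = _benjamini_hochberg(p, config.alpha)
    else:
        reject = p < config.alpha
    families = [d.family for d in head_rows.descriptors]
    frame = pd.DataFrame(
        {"family": families, "t": t, "p": p, "significant": reject},
        index=head_rows.columns,
    )
    return ScreeningResult(frame, config.alpha)


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    passed = np.nonzero(p[order] <= (np.arange(m) + 1) / m * alpha)[0]
    reject = np.zeros(m, dtype=bool)
    if passed.size:
        reject[order[: passed.max() + 1]] = True
    return reject


def manhattan_export(
    result: ScreeningResult,
    csv_path,
    plot_path: Optional[str] = None,
) -> pd.DataFrame:
    """Write per-feature -log10(p), grouped by family, as CSV and optionally
    as a rendered Manhattan plot."""
    frame = result.frame.copy()
    frame = frame.sort_values("family", kind="stable")
    with np.errstate(divide="ignore"):
        frame["neg_log10_p"] = -np.log10(frame["p"])
    frame.to_csv(csv_path, index=True, index_label="descriptor")
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 4))
        x = np.arange(len(frame))
        for fam, grp in frame.groupby("family", sort=False):
            pos = x[frame["family"] == fam]
            ax.scatter(pos, grp["neg_log10_p"], s=4, label=fam)
        ax.axhline(-np.log10(result.alpha), color="red", lw=0.8, ls="--")
        ax.set_xlabel("feature (grouped by family)")
        ax.set_ylabel(r"$-\log_{10} p$")
        ax.legend(fontsize=7, ncol=4)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return frame
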