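"""Effect sizes and object-level differential testing.

Two statistical layers mirror the 2D and 3D halves of the workflow:

* Cohen's d per feature between two pixel groups, used to find cell-type
  marker candidates whose effect is concordant (same sign, strong in
  both) between the within-biculture comparison and the
  between-monoculture comparison.
* A volcano analysis between two groups of 3D objects: two-sided t-test
  (Welch by default) on per-object mean intensities, Benjamini-Hochberg
  adjustment across the feature list, log2 fold change of group means.
  The unit of replication is the 3D object, never the voxel — testing on
  voxels would pseudo-replicate massively.

Default thresholds follow the spheroid workflow (adjusted p < 0.01,
|log2 FC| > 1); the organoid comparison uses p < 0.05 and
|log2 FC| > 1.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cohens_d",
    "marker_concordance",
    "differential_test",
    "volcano_table",
    "volcano_plot",
    "DifferentialResult",
    "EffectSizeResult",
]


# --------------------------------------------------------------------------
# effect sizes
# --------------------------------------------------------------------------

def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Cohen's d per feature: (mean_A − mean_B) / pooled sd.

    Pooled sd uses n−1 sample variances.  Arrays are
    ``(n_units, n_features)`` (units are pixels-in-region for 2D,
    objects for 3D).  Where the pooled sd is zero, d is 0 for equal
    means and ±inf otherwise.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 units")
    diff = a.mean(axis=0) - b.mean(axis=0)
    pooled = np.sqrt(
        ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1))
        / (na + nb - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / pooled
    d[(pooled == 0) & (diff == 0)] = 0.0
    d[(pooled == 0) & (diff > 0)] = np.inf
    d[(pooled == 0) & (diff < 0)] = -np.inf
    return d


@dataclass
class EffectSizeResult:
    """Per-feature effect sizes of two comparisons plus concordance."""

    d_comparison1: np.ndarray
    d_comparison2: np.ndarray
    concordant: np.ndarray
    positive_set: np.ndarray   # feature indices, strong positive in both
    negative_set: np.ndarray   # feature indices, strong negative in both
    d_threshold: float


def marker_concordance(
    effects1: np.ndarray, effects2: np.ndarray, d_threshold: float = 0.8
) -> EffectSizeResult:
    """Features with a strong, same-sign effect in both comparisons.

    With the sign convention d > 0 = higher in the first-named cell type,
    the positive set collects that type's marker candidates and the
    negative set the other type's.
    """
    d1 = np.asarray(effects1, dtype=float)
    d2 = np.asarray(effects2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("effect vectors must share the feature axis")
    strong = (np.abs(d1) >= d_threshold) & (np.abs(d2) >= d_threshold)
    same_sign = np.sign(d1) == np.sign(d2)
    conc = strong & same_sign
    return EffectSizeResult(
        d_comparison1=d1, d_comparison2=d2, concordant=conc,
        positive_set=np.nonzero(conc & (d1 > 0))[0],
        negative_set=np.nonzero(conc & (d1 < 0))[0],
        d_threshold=d_threshold,
    )


# --------------------------------------------------------------------------
# differential testing
# --------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-feature volcano statistics for group A vs group B."""

    mz: np.ndarray
    log2_fc: np.ndarray
    p_value: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    alpha: float
    lfc_threshold: float
    n_a: int
    n_b: int


def _profile_matrix(profiles) -> np.ndarray:
    """Accept an (n_objects, n_features) array or an object_profiles table."""
    if isinstance(profiles, pd.DataFrame):
        cols = [c for c in profiles.columns if c.startswith("f")
                and c[1:].isdigit()]
        cols.sort(key=lambda c: int(c[1:]))
        return profiles[cols].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(profiles, dtype=float))


def differential_test(
    profiles_a,
    profiles_b,
    mz: np.ndarray | None = None,
    alpha: float = 0.01,
    lfc_threshold: float = 1.0,
    test: str = "welch",
    epsilon: float | None = None,
) -> DifferentialResult:
    """Two-sided t-test per feature on per-object mean profiles.

    Welch's unequal-variance test by default (``test="student"`` for the
    pooled-variance variant).  P-values are Benjamini-Hochberg adjusted
    across all tested features.  The log2 fold change is of group means
    (A over B) with an additive offset *epsilon* guarding zeros
    (default: smallest positive group mean × 10⁻³).  A feature is
    significant when ``p_adj < alpha`` and ``|log2_fc| > lfc_threshold``.
    Features with zero variance in both groups get p = 1.
    """
    a = _profile_matrix(profiles_a)
    b = _profile_matrix(profiles_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the feature axis")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 objects")
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    if epsilon is None:
        pos = np.concatenate([mean_a[mean_a > 0], mean_b[mean_b > 0]])
        epsilon = (pos.min() * 1e-3) if pos.size else 1e-9
    log2_fc = np.log2(mean_a + epsilon) - np.log2(mean_b + epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = sps.ttest_ind(a, b, axis=0, equal_var=(test == "student"))
    p = np.asarray(tt.pvalue, dtype=float)
    flat = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    p[flat] = 1.0
    p = np.nan_to_num(p, nan=1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    sig = (p_adj < alpha) & (np.abs(log2_fc) > lfc_threshold)
    if mz is None:
        mz = np.arange(a.shape[1], dtype=float)
    return DifferentialResult(
        mz=np.asarray(mz, dtype=float), log2_fc=log2_fc, p_value=p,
        p_adj=p_adj, significant=sig, alpha=alpha,
        lfc_threshold=lfc_threshold, n_a=len(a), n_b=len(b),
    )


def volcano_table(result: DifferentialResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full volcano table sorted by adjusted p, plus the significant subset.

    Returns ``(table, selected)``; *selected* is the feature list handed
    to 3D rendering.
    """
    table = pd.DataFrame({
        "mz": result.mz,
        "log2_fc": result.log2_fc,
        "p_value": result.p_value,
        "p_adj": result.p_adj,
        "significant": result.significant,
    }).sort_values(["p_adj", "p_value", "mz"], kind="stable").reset_index(drop=True)
    return table, table[table["significant"]].reset_index(drop=True)


def volcano_plot(result: DifferentialResult, path=None):
    """Volcano scatter (log2 FC vs −log10 adjusted p); saves if *path*."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    y = -np.log10(np.maximum(result.p_adj, 1e-300))
    ax.scatter(result.log2_fc, y, s=12,
               c=np.where(result.significant, "crimson", "grey"))
    ax.axhline(-np.log10(result.alpha), ls="--", lw=0.8, c="k")
    for x in (-result.lfc_threshold, result.lfc_threshold):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (A / B)")
    ax.set_ylabel("-log10 adjusted p")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
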