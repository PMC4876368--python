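"""Group-level comparison of full- and partial-correlation networks.

Given per-subject connectivity matrices, each edge gets an effect size: the
Fisher z-transform is applied to the subject values and the mean z is
divided by its standard deviation.  Thresholding the absolute effect size
(rather than p-values, which saturate at large sample sizes) splits edges
into four categories — significant only under partial correlation (A), only
under full correlation (B), under both (C), or neither (D) — with per-
category sign consistency between the two measures.  A module partition of
the nodes additionally yields block-wise Spearman rank correlations between
the two averaged networks, contrasting within-module and between-module
agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectStack",
    "ModulePartition",
    "EdgeEffectSizes",
    "EdgeCategoryTable",
    "edge_effect_size",
    "categorize_edges",
    "modulewise_spearman",
    "shrinkage_comparison",
]

DEFAULT_THRESHOLD_SIG = 0.5
DEFAULT_THRESHOLD_MOD = 0.3

#: effect-size classes used in the sparsity-shrinkage comparison
SHRINKAGE_CLASSES = ("significant_positive", "moderate_positive",
                     "moderate_negative", "significant_negative", "null")


@dataclass
class SubjectStack:
    """Per-subject symmetric connectivity matrices of one kind."""

    matrices: list[np.ndarray]
    kind: str = "full"  # "full" or "partial"

    def __post_init__(self) -> None:
        if len(self.matrices) < 2:
            raise ValueError("need at least 2 subjects")
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        shape = self.matrices[0].shape
        for idx, m in enumerate(self.matrices):
            if m.shape != shape:
                raise ValueError(f"subject {idx} has shape {m.shape}, expected {shape}")

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n_nodes(self) -> int:
        return self.matrices[0].shape[0]


@dataclass
class ModulePartition:
    """Assignment of each node to exactly one functional module."""

    node_labels: list[str]
    module_names: list[str] = field(default=None)

    def __post_init__(self) -> None:
        if self.module_names is None:
            seen: list[str] = []
            for lab in self.node_labels:
                if lab not in seen:
                    seen.append(lab)
            self.module_names = seen
        missing = set(self.node_labels) - set(self.module_names)
        if missing:
            raise ValueError(f"labels without a module entry: {sorted(missing)}")

    @property
    def n_modules(self) -> int:
        return len(self.module_names)


@dataclass
class EdgeEffectSizes:
    """Edgewise effect sizes mean(z)/SD(z) with the mean z retained for
    sign comparisons.  Diagonal and zero-SD edges are NaN."""

    values: np.ndarray
    mean_z: np.ndarray
    threshold_sig: float = DEFAULT_THRESHOLD_SIG
    threshold_mod: float = DEFAULT_THRESHOLD_MOD


@dataclass
class EdgeCategoryTable:
    """Four-way edge classification with per-category sign consistency."""

    category: np.ndarray  # per-edge labels 'A'..'D' ('' on diagonal/missing)
    proportions: dict[str, float]
    sign_consistency: dict[str, float]
    n_classified: int
    n_excluded: int


def edge_effect_size(stack: SubjectStack) -> EdgeEffectSizes:
    """Fisher-z effect size per edge across subjects.

    Each subject value is atanh-transformed; the effect size is the mean of
    the z values divided by their standard deviation (divisor S-1).  Edges
    whose values do not vary across subjects have undefined effect size and
    are reported as NaN with a warning.
    """
    arr = np.stack(stack.matrices)
    off = ~np.eye(stack.n_nodes, dtype=bool)
    if np.any(np.abs(arr[:, off]) >= 1):
        raise ValueError("off-diagonal values at or beyond +/-1; Fisher z "
                         "transform undefined")
    z = np.arctanh(np.where(off, arr, 0.0))
    mean_z = z.mean(axis=0)
    sd_z = z.std(axis=0, ddof=1)
    # SD indistinguishable from zero (identical subject values up to float
    # rounding) -> effect size undefined
    degenerate = sd_z <= 1e-12 * np.maximum(1.0, np.abs(mean_z))
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(degenerate, np.nan, mean_z / sd_z)
    eff[~off] = np.nan
    mean_z = np.where(off, mean_z, np.nan)
    n_degenerate = int(degenerate[np.triu_indices(stack.n_nodes, 1)].sum())
    if n_degenerate:
        warnings.warn(f"{n_degenerate} edge(s) with zero variance across "
                      "subjects; effect size undefined there", stacklevel=2)
    return EdgeEffectSizes(values=eff, mean_z=mean_z)


def categorize_edges(
    es_full: EdgeEffectSizes,
    es_partial: EdgeEffectSizes,
    threshold: float = DEFAULT_THRESHOLD_SIG,
) -> EdgeCategoryTable:
    """Classify upper-triangle edges by significance under each measure.

    An edge is significant where its absolute effect size exceeds
    ``threshold``.  Categories: A significant in partial only, B in full
    only, C in both, D in neither.  Sign consistency within a category is
    the fraction of its edges whose mean-z signs agree between the two
    measures (structurally guaranteed for no category — a C edge can mix
    signs).  Edges with a missing effect size in either map are excluded
    from all denominators.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    F = es_full.values
    P = es_partial.values
    if F.shape != P.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {P.shape}")
    M = F.shape[0]
    iu = np.triu_indices(M, k=1)
    f, p = F[iu], P[iu]
    ok = np.isfinite(f) & np.isfinite(p)
    sig_f = np.abs(f) > threshold
    sig_p = np.abs(p) > threshold
    cat = np.where(sig_p & ~sig_f, "A",
                   np.where(sig_f & ~sig_p, "B",
                            np.where(sig_f & sig_p, "C", "D")))
    cat = np.where(ok, cat, "")
    n_ok = int(ok.sum())
    proportions = {}
    sign_consistency = {}
    same_sign = (np.sign(es_full.mean_z[iu]) == np.sign(es_partial.mean_z[iu]))
    for label in "ABCD":
        in_cat = ok & (cat == label)
        n_cat = int(in_cat.sum())
        proportions[label] = n_cat / n_ok if n_ok else float("nan")
        sign_consistency[label] = (
            float(same_sign[in_cat].mean()) if n_cat else float("nan")
        )
    category = np.full((M, M), "", dtype=object)
    category[iu] = cat
    category[(iu[1], iu[0])] = cat
    return EdgeCategoryTable(category=category, proportions=proportions,
                             sign_consistency=sign_consistency,
                             n_classified=n_ok, n_excluded=int((~ok).sum()))


def _block_edges(M: int, labels: np.ndarray, mod_a: str, mod_b: str):
    """Upper-triangle edge indices belonging to one module-pair block."""
    ia = np.flatnonzero(labels == mod_a)
    ib = np.flatnonzero(labels == mod_b)
    if mod_a == mod_b:
        pairs = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1:]]
    else:
        pairs = [(min(i, j), max(i, j)) for i in ia for j in ib]
    return pairs


def modulewise_spearman(
    avg_full: np.ndarray,
    avg_partial: np.ndarray,
    partition: ModulePartition,
) -> dict:
    """Block-wise Spearman agreement between two averaged networks.

    For each of the K(K+1)/2 module-pair blocks (K within-module diagonal
    blocks plus K(K-1)/2 between-module blocks) the Spearman rank
    correlation between the full and partial edge values is computed; blocks
    with fewer than 3 edges, or whose values are entirely tied, are reported
    missing.  Returns a dict with the per-block table, within/between
    summaries, and a two-sample Wilcoxon rank-sum p-value comparing within-
    vs between-module correlations.
    """
    avg_full = np.asarray(avg_full, dtype=float)
    avg_partial = np.asarray(avg_partial, dtype=float)
    M = avg_full.shape[0]
    if len(partition.node_labels) != M:
        raise ValueError("partition does not cover all nodes")
    labels = np.asarray(partition.node_labels)
    mods = partition.module_names
    rows = []
    for a in range(len(mods)):
        for b in range(a, len(mods)):
            pairs = _block_edges(M, labels, mods[a], mods[b])
            within = mods[a] == mods[b]
            rho = np.nan
            note = ""
            if len(pairs) < 3:
                note = "fewer than 3 edges"
            else:
                x = np.array([avg_full[i, j] for i, j in pairs])
                y = np.array([avg_partial[i, j] for i, j in pairs])
                if np.all(x == x[0]) or np.all(y == y[0]):
                    note = "all values tied"
                    warnings.warn(f"block ({mods[a]}, {mods[b]}) has only "
                                  "tied values; Spearman undefined",
                                  stacklevel=2)
                else:
                    rho = float(stats.spearmanr(x, y).statistic)
            rows.append({"module_a": mods[a], "module_b": mods[b],
                         "within": within, "n_edges": len(pairs),
                         "rho": rho, "note": note})
    table = pd.DataFrame(rows)
    w = table.loc[table["within"], "rho"].dropna()
    b = table.loc[~table["within"], "rho"].dropna()
    if len(w) and len(b):
        pval = float(stats.ranksums(w, b).pvalue)
    else:
        pval = float("nan")
    return {
        "blocks": table,
        "within_mean": float(w.mean()) if len(w) else float("nan"),
        "within_sd": float(w.std(ddof=1)) if len(w) > 1 else float("nan"),
        "between_mean": float(b.mean()) if len(b) else float("nan"),
        "between_sd": float(b.std(ddof=1)) if len(b) > 1 else float("nan"),
        "p_value": pval,
    }


def _shrinkage_class(e: float, sig: float, mod: float) -> str:
    if not np.isfinite(e):
        return "missing"
    if e > sig:
        return "significant_positive"
    if e > mod:
        return "moderate_positive"
    if e < -sig:
        return "significant_negative"
    if e < -mod:
        return "moderate_negative"
    return "null"


def shrinkage_comparison(
    es_loose: EdgeEffectSizes,
    es_tight: EdgeEffectSizes,
    threshold_sig: float = DEFAULT_THRESHOLD_SIG,
    threshold_mod: float = DEFAULT_THRESHOLD_MOD,
) -> dict:
    """How edge effect-size classes survive stronger sparsity control.

    Classifies every upper-triangle edge under both settings into
    significant positive (> ``threshold_sig``), moderate positive
    (``threshold_mod``..``threshold_sig``), moderate negative, significant
    negative, or null, and reports the class-transition counts plus the
    per-class retention proportion (fraction of edges keeping their loose-
    setting class under the tight setting).
    """
    L = es_loose.values
    Ttight = es_tight.values
    if L.shape != Ttight.shape:
        raise ValueError(f"shape mismatch: {L.shape} vs {Ttight.shape}")
    iu = np.triu_indices(L.shape[0], k=1)
    classes_loose = [_shrinkage_class(e, threshold_sig, threshold_mod)
                     for e in L[iu]]
    classes_tight = [_shrinkage_class(e, threshold_sig, threshold_mod)
                     for e in Ttight[iu]]
    transitions = pd.crosstab(
        pd.Series(classes_loose, name="loose"),
        pd.Series(classes_tight, name="tight"),
    ).reindex(index=SHRINKAGE_CLASSES, columns=SHRINKAGE_CLASSES,
              fill_value=0)
    retention = {}
    for cls in SHRINKAGE_CLASSES:
        total = int(transitions.loc[cls].sum())
        retention[cls] = (
            float(transitions.loc[cls, cls] / total) if total else float("nan")
        )
    return {"transitions": transitions, "retention": retention}
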