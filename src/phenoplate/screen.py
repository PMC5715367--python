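"""Statistical layer of the screen.

Two-group color-profile clustering (the survival / germination call),
Fisher's exact and one-way ANOVA line-vs-wild-type tests with
Benjamini-Hochberg FDR control, and the multi-trait morpho-colorimetric
profile clustering with per-line density heatmaps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GREEN_CLASSES_16",
    "two_group_color_clustering",
    "fisher_exact_2x2",
    "bh_adjust",
    "oneway_anova",
    "line_significance",
    "MultiTraitResult",
    "multitrait_profile_heatmap",
]

#: 16-class hue bins whose centers fall in the green band (~90-180 degrees),
#: used to decide which of the two clusters is the alive/germinated one
GREEN_CLASSES_16 = (4, 5, 6, 7)

ALPHA = 0.05


@dataclass
class TwoGroupResult:
    labels: np.ndarray  # 0/1 per record
    alive_group: int  # which label is alive/germinated
    degenerate: bool = False

    @property
    def alive(self) -> np.ndarray:
        """Boolean alive/germinated call per record."""
        return self.labels == self.alive_group


def two_group_color_clustering(
    profiles: np.ndarray,
    green_classes: tuple[int, ...] = GREEN_CLASSES_16,
    linkage: str = "average",
) -> TwoGroupResult:
    """Cut a hierarchical tree of joined color profiles into two groups.

    ``profiles`` is (n, K_joined) with the VIS hue-class fractions first.
    Euclidean distances, agglomerative clustering (average linkage by
    default), tree cut at 2 clusters.  The group with the larger mean mass in
    the green VIS hue classes is labeled alive/germinated.  If all profiles
    are identical the output is a flagged single-group degenerate result.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or len(profiles) < 2:
        raise ValueError("need at least two records with joined color profiles")
    if np.allclose(profiles, profiles[0]):
        logger.warning("all color profiles identical; degenerate single group")
        return TwoGroupResult(
            labels=np.zeros(len(profiles), dtype=int), alive_group=0, degenerate=True
        )
    z = hierarchy.linkage(profiles, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(z, t=2, criterion="maxclust") - 1
    green = profiles[:, list(green_classes)].sum(axis=1)
    mean0 = green[labels == 0].mean() if (labels == 0).any() else -np.inf
    mean1 = green[labels == 1].mean() if (labels == 1).any() else -np.inf
    return TwoGroupResult(labels=labels, alive_group=int(mean1 > mean0))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric outcomes whose probability does not
    exceed that of the observed table.  A zero row or column margin makes the
    table degenerate; p = 1 is returned with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def oneway_anova(group_a, group_b) -> tuple[float, float]:
    """Classical one-way ANOVA between two groups: (F, p).

    Degenerate inputs: two identical constant groups give F = 0, p = 1;
    zero within-group variance with unequal means gives p = 0 (perfect
    separation, flagged with a warning).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    within = a.var(ddof=1) + b.var(ddof=1)
    if within == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero within-group variance with unequal means; p = 0", stacklevel=2
        )
        return float("inf"), 0.0
    with np.errstate(invalid="ignore"):
        f, p = sps.f_oneway(a, b)
    return float(f), float(p)


def line_significance(
    table: pd.DataFrame,
    test: str = "fisher",
    wild_type: str = "Col-0",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-line test against wild type with BH adjustment across lines.

    ``test="fisher"``: ``table`` has one row per line with columns
    ``line, n_group1, n_group2`` (e.g. alive / dead counts).
    ``test="anova"``: long format with columns ``line, value`` (one row per
    plant, e.g. major axis).

    The BH family is all non-wild-type lines in the table (one condition).
    Lines with no detected seedlings are omitted with a warning.  Returns a
    frame with ``line, statistic, p_raw, p_adj, significant``.
    """
    if test not in ("fisher", "anova"):
        raise ValueError(f"unknown test {test!r}")
    rows = []
    if test == "fisher":
        tab = table.set_index("line")
        if wild_type not in tab.index:
            raise ValueError(f"wild-type line {wild_type!r} missing from table")
        wt1 = int(tab.loc[wild_type, "n_group1"])
        wt2 = int(tab.loc[wild_type, "n_group2"])
        for line, row in tab.iterrows():
            if line == wild_type:
                continue
            n1, n2 = int(row["n_group1"]), int(row["n_group2"])
            if n1 + n2 == 0:
                warnings.warn(f"line {line!r} has no detected seedlings; omitted")
                continue
            p = fisher_exact_2x2(n1, wt1, n2, wt2)
            # odds-ratio direction of the line relative to wild type
            with np.errstate(divide="ignore", invalid="ignore"):
                odds = (n1 * wt2) / (n2 * wt1) if n2 * wt1 > 0 else np.inf
            rows.append({"line": line, "statistic": float(odds), "p_raw": p})
    else:
        groups = {k: v["value"].to_numpy(float) for k, v in table.groupby("line")}
        if wild_type not in groups:
            raise ValueError(f"wild-type line {wild_type!r} missing from table")
        wt = groups[wild_type]
        for line, vals in groups.items():
            if line == wild_type:
                continue
            if len(vals) == 0:
                warnings.warn(f"line {line!r} has no detected seedlings; omitted")
                continue
            if len(vals) < 2:
                warnings.warn(f"line {line!r} has a single plant; omitted")
                continue
            f, p = oneway_anova(vals, wt)
            rows.append({"line": line, "statistic": f, "p_raw": p})
    out = pd.DataFrame(rows, columns=["line", "statistic", "p_raw"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


@dataclass
class MultiTraitResult:
    """Five-group (C1-C5) multi-trait clustering of digital plants and the
    per-line density heatmap over those groups."""

    plant_groups: np.ndarray  # group index 0..4 per plant
    density: pd.DataFrame  # lines x C1..C5, rows sum to 1
    plant_linkage: np.ndarray
    line_linkage: np.ndarray | None
    line_order: list[str]
    dropped_features: list[str] = field(default_factory=list)

    @property
    def heatmap(self) -> np.ndarray:
        return self.density.loc[self.line_order].to_numpy()


def multitrait_profile_heatmap(
    records: pd.DataFrame,
    feature_columns: tuple[str, ...],
    line_column: str = "line",
    n_groups: int = 5,
    plant_linkage: str = "ward",
    line_linkage: str = "average",
) -> MultiTraitResult:
    """Cluster plants on z-scored morpho-colorimetric features into C1-C5 and
    lines on their density vectors over the groups.

    Features are z-scored within the condition (the records given); constant
    features are dropped with a warning.  The plant tree is cut at
    ``n_groups`` clusters; groups are relabeled C1..C5 in order of first
    appearance in the input so the labeling is deterministic.
    """
    if len(records) < n_groups:
        raise ValueError(f"need at least {n_groups} plants")
    feats = records.loc[:, list(feature_columns)].to_numpy(float)
    if not np.isfinite(feats).all():
        raise ValueError("all features must be finite")
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(feature_columns, keep) if not k]
    if dropped:
        warnings.warn(f"constant features dropped from z-scoring: {dropped}")
    if not keep.any():
        raise ValueError("all features are constant")
    z = (feats[:, keep] - mean[keep]) / sd[keep]
    zl = hierarchy.linkage(z, method=plant_linkage, metric="euclidean")
    raw = hierarchy.fcluster(zl, t=n_groups, criterion="maxclust")
    # deterministic relabeling: C1 = first cluster encountered, etc.
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel)
    groups = np.array([relabel[r] for r in raw])

    lines = records[line_column].to_numpy()
    line_ids = list(pd.unique(lines))
    dens = np.zeros((len(line_ids), n_groups))
    for i, lid in enumerate(line_ids):
        sel = groups[lines == lid]
        counts = np.bincount(sel, minlength=n_groups).astype(float)
        dens[i] = counts / counts.sum()
    density = pd.DataFrame(
        dens, index=pd.Index(line_ids, name=line_column),
        columns=[f"C{i + 1}" for i in range(n_groups)],
    )
    if len(line_ids) >= 2:
        ll = hierarchy.linkage(dens, method=line_linkage, metric="euclidean")
        order = [line_ids[i] for i in hierarchy.leaves_list(ll)]
    else:
        ll = None
        order = line_ids
    return MultiTraitResult(
        plant_groups=groups,
        density=density,
        plant_linkage=zl,
        line_linkage=ll,
        line_order=order,
        dropped_features=dropped,
    )
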