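"""Nonparametric effect-size machinery.

Group differences are quantified by the measure of effect size (mes)
based on Cohen's U3: the fraction of one sample lying above the other
sample's median.  Δmes = |mes − 0.5| is the distance from
no-difference, maximal at 0.5.  Effect sizes, not p-values, are the
primary statistic; Kruskal-Wallis tests are provided as a complement.
No multiple-testing correction is applied across features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

DEFAULT_STAR_THRESHOLDS = (0.2, 0.3, 0.4)  # *, **, ***


@dataclass(frozen=True)
class MesResult:
    """Cohen's-U3 effect size between two samples."""

    mes: float
    delta: float
    stars: str
    direction: int = 0  # +1 if sample a tends above b's median, −1 below, 0 equal

    def __post_init__(self) -> None:
        if not 0.0 <= self.mes <= 1.0:
            raise ValueError("mes must lie in [0, 1]")


def significance_stars(delta: float, thresholds: tuple[float, float, float] = DEFAULT_STAR_THRESHOLDS) -> str:
    """Significance code for a Δmes: '***' if ≥ 0.4, '**' if ≥ 0.3,
    '*' if ≥ 0.2, else '' (default thresholds)."""
    if not 0.0 <= delta <= 0.5:
        raise ValueError("Δmes must lie in [0, 0.5]")
    t1, t2, t3 = thresholds
    if delta >= t3:
        return "***"
    if delta >= t2:
        return "**"
    if delta >= t1:
        return "*"
    return ""


def cohen_u3_mes(a, b, thresholds: tuple[float, float, float] = DEFAULT_STAR_THRESHOLDS) -> MesResult:
    """Measure of effect size based on Cohen's U3.

    mes is the fraction of sample ``a`` strictly above the median of
    sample ``b``, with values exactly equal to that median counted at
    half weight — so identical samples give mes = 0.5 exactly.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    med = np.median(b)
    mes = (np.count_nonzero(a > med) + 0.5 * np.count_nonzero(a == med)) / a.size
    delta = abs(mes - 0.5)
    direction = 0 if mes == 0.5 else (1 if mes > 0.5 else -1)
    return MesResult(float(mes), float(delta), significance_stars(delta, thresholds), direction)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value
    (df = #groups − 1).  All values identical → (0, 1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


@dataclass
class PairwiseTable:
    """Per-feature Cohen's-U3 results for every unordered group pair.

    ``table`` is long-format: pair, group_a, group_b, feature, mes, delta,
    stars, direction.  ``counts(threshold)`` gives the number of features
    discriminating each pair at Δmes ≥ threshold.
    """

    table: pd.DataFrame
    feature_names: list[str]
    group_pairs: list[tuple[str, str]]
    small_groups: list[str] = field(default_factory=list)

    def counts(self, threshold: float = 0.3) -> pd.Series:
        sig = self.table[self.table["delta"] >= threshold]
        base = pd.Series(0, index=[f"{a}-{b}" for a, b in self.group_pairs])
        got = sig.groupby("pair").size()
        return base.add(got, fill_value=0).astype(int)

    def pair_frame(self, a: str, b: str) -> pd.DataFrame:
        key = f"{a}-{b}" if (self.table["pair"] == f"{a}-{b}").any() else f"{b}-{a}"
        return self.table[self.table["pair"] == key]


def pairwise_discrimination(
    features: pd.DataFrame,
    groups: pd.Series,
    threshold: float = 0.2,
    thresholds: tuple[float, float, float] = DEFAULT_STAR_THRESHOLDS,
) -> PairwiseTable:
    """Cohen's-U3 effect sizes for every feature and unordered group pair.

    ``features`` is a (bees × features) DataFrame and ``groups`` the
    per-bee labels (same index).  Groups with fewer than 2 bees are
    flagged in ``small_groups`` but still compared.
    """
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = {g: features.loc[groups[groups == g].index].to_numpy(float) for g in labels}
    small = [g for g in labels if by_group[g].shape[0] < 2]
    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        xa, xb = by_group[a], by_group[b]
        med_b = np.median(xb, axis=0)
        mes = (
            (xa > med_b).sum(axis=0) + 0.5 * (xa == med_b).sum(axis=0)
        ) / xa.shape[0]
        delta = np.abs(mes - 0.5)
        for fi, fname in enumerate(features.columns):
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "group_a": a,
                    "group_b": b,
                    "feature": fname,
                    "feature_index": fi,
                    "mes": float(mes[fi]),
                    "delta": float(delta[fi]),
                    "stars": significance_stars(float(delta[fi]), thresholds),
                    "direction": 0 if mes[fi] == 0.5 else (1 if mes[fi] > 0.5 else -1),
                }
            )
    return PairwiseTable(pd.DataFrame(rows), list(features.columns), pairs, small)


def top_discriminants(
    table: PairwiseTable,
    k: int = 25,
    edge_of_feature=None,
    max_delta: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """Per group pair: the k best-discriminating features (descending
    Δmes, ties by feature index) and, when ``edge_of_feature`` maps
    feature names to edge ids, per-edge counts and cumulative Δmes scaled
    so that k · max_delta ≙ 100 %.

    Returns {"top": long DataFrame, "per_edge": summary DataFrame}.
    """
    if edge_of_feature is None:
        edge_of_feature = lambda name: name.split("_")[0]  # noqa: E731
    tops = []
    per_edge_rows = []
    for a, b in table.group_pairs:
        sub = table.pair_frame(a, b).sort_values(
            ["delta", "feature_index"], ascending=[False, True], kind="stable"
        )
        top = sub.head(min(k, len(sub))).copy()
        top["rank"] = np.arange(1, len(top) + 1)
        tops.append(top)
        edges = top["feature"].map(edge_of_feature)
        for e in sorted(edges.unique()):
            sel = top[edges == e]
            per_edge_rows.append(
                {
                    "pair": f"{a}-{b}",
                    "edge": e,
                    "count": len(sel),
                    "sum_delta": float(sel["delta"].sum()),
                    "percent_of_max": 100.0 * float(sel["delta"].sum()) / (k * max_delta),
                }
            )
    return {
        "top": pd.concat(tops, ignore_index=True),
        "per_edge": pd.DataFrame(per_edge_rows),
    }
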