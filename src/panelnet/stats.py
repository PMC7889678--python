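"""Inferential statistics for paired panel studies.

Paired t-tests on module eigengenes and single genes, Holm–Šidák and
Benjamini–Hochberg multiplicity corrections, sample-level hierarchical
clustering with two-group cuts and neighbour-pair calls, Pearson
chi-square (no continuity correction) and the exact binomial McNemar
test for paired binary outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import binom, chi2_contingency, ttest_rel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedDesign",
    "ContingencyTable",
    "TestResult",
    "DegenerateDataError",
    "paired_t",
    "holm_sidak",
    "bh_fdr",
    "pearson_chi2",
    "mcnemar_exact",
    "cluster_samples",
    "neighbour_pairs",
    "paired_cluster_contingency",
    "detection_timepoint_table",
]


class DegenerateDataError(ValueError):
    """Raised when a test's input admits no sampling variability."""


@dataclass
class PairedDesign:
    """Patient-matched baseline/progression observations."""

    patient_ids: list[str]
    baseline: dict[str, float]
    progression: dict[str, float]

    def __post_init__(self) -> None:
        missing = [
            p
            for p in self.patient_ids
            if p not in self.baseline or p not in self.progression
        ]
        if missing:
            raise ValueError(f"patients missing a timepoint: {missing}")

    def differences(self) -> np.ndarray:
        """progression - baseline, in patient order."""
        return np.array(
            [self.progression[p] - self.baseline[p] for p in self.patient_ids],
            dtype=float,
        )

    @classmethod
    def from_series(
        cls, values: pd.Series, pairs: list[tuple[str, str]]
    ) -> "PairedDesign":
        """Build from per-sample values and (baseline, progression) sample pairs."""
        patients = [f"pair{i + 1}" for i in range(len(pairs))]
        return cls(
            patient_ids=patients,
            baseline={p: float(values[b]) for p, (b, _) in zip(patients, pairs)},
            progression={p: float(values[r]) for p, (_, r) in zip(patients, pairs)},
        )


@dataclass
class ContingencyTable:
    """r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be > 0")
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"col{j}" for j in range(self.counts.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.row_labels, columns=self.col_labels
        )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    adjusted_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "df": self.df,
            "adjusted_p": self.adjusted_p,
        }


def paired_t(design: PairedDesign) -> TestResult:
    """Two-sided paired t-test on progression - baseline differences."""
    d = design.differences()
    if len(d) < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    if np.ptp(d) == 0:
        raise DegenerateDataError(
            "all paired differences identical; t statistic undefined"
        )
    base = np.array([design.baseline[p] for p in design.patient_ids])
    prog = np.array([design.progression[p] for p in design.patient_ids])
    res = ttest_rel(prog, base)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="paired t-test",
        df=float(len(d) - 1),
    )


def holm_sidak(p_values) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm-sidak")[1]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_chi2(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence (default: no continuity
    correction, the convention for the desk-scale tables here)."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    stat, p, dof, _ = chi2_contingency(counts, correction=yates)
    return TestResult(
        statistic=float(stat),
        p_value=float(p),
        method="Pearson chi-square" + (" (Yates)" if yates else ""),
        df=float(dof),
    )


def mcnemar_exact(b: int, c: int) -> TestResult:
    """Exact McNemar test from the two discordant-pair counts.

    Under marginal homogeneity the smaller discordant count is
    Binomial(b + c, 1/2); the two-sided p is ``min(1, 2 P(X <= min(b, c)))``
    and 1 when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, method="exact McNemar", df=None
        )
    p = min(1.0, 2.0 * float(binom.cdf(min(b, c), n, 0.5)))
    return TestResult(
        statistic=float(min(b, c)), p_value=p, method="exact McNemar", df=None
    )


def mcnemar_chi2(b: int, c: int, continuity: bool = True) -> TestResult:
    """Chi-square approximation to McNemar (available behind a flag)."""
    from scipy.stats import chi2 as chi2_dist

    if b + c == 0:
        return TestResult(0.0, 1.0, method="McNemar chi-square", df=1.0)
    num = (abs(b - c) - 1) ** 2 if continuity else (b - c) ** 2
    stat = num / (b + c)
    return TestResult(
        statistic=float(stat),
        p_value=float(chi2_dist.sf(stat, 1)),
        method="McNemar chi-square",
        df=1.0,
    )


def cluster_samples(expr: pd.DataFrame, k: int = 2):
    """Unsupervised clustering of samples on centred and scaled genes.

    Each gene (row) is z-scored across samples, samples are clustered
    by Euclidean distance with average linkage, and the dendrogram is
    cut into ``k`` groups.  Returns ``(labels, linkage_matrix,
    leaf_order)``; labels are 1..k in scipy's deterministic order.
    """
    n = expr.shape[1]
    if k > n:
        raise ValueError(f"cannot cut {n} samples into {k} groups")
    arr = expr.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    z = np.zeros_like(arr)
    np.divide(arr - mu, sd, out=z, where=sd > 0)
    zmat = linkage(pdist(z.T, metric="euclidean"), method="average")
    labels = pd.Series(
        fcluster(zmat, t=k, criterion="maxclust"), index=expr.columns, name="cluster"
    )
    leaf_order = [expr.columns[i] for i in leaves_list(zmat)]
    return labels, zmat, leaf_order


def _sibling_leaf_pairs(z: np.ndarray, leaf_names: list[str]) -> set[frozenset]:
    """Leaf pairs that merge with each other before anything else."""
    n = len(leaf_names)
    out = set()
    for left, right in z[:, :2].astype(int):
        if left < n and right < n:
            out.add(frozenset((leaf_names[left], leaf_names[right])))
    return out


def neighbour_pairs(
    z: np.ndarray,
    leaf_names: list[str],
    pairs: list[tuple[str, str]],
) -> pd.Series:
    """Which (baseline, progression) pairs form a two-leaf clade.

    A pair clusters "as neighbours" iff its two samples merge with each
    other before either merges with any other sample.
    """
    names = set(leaf_names)
    for b, r in pairs:
        if b not in names or r not in names:
            raise ValueError(f"pair ({b}, {r}) not among the clustered samples")
    siblings = _sibling_leaf_pairs(np.asarray(z), list(leaf_names))
    return pd.Series(
        {f"{b}|{r}": frozenset((b, r)) in siblings for b, r in pairs},
        name="neighbour",
    )


def paired_cluster_contingency(
    labels: pd.Series, pairs: list[tuple[str, str]]
) -> ContingencyTable:
    """Cross-tabulate each pair's (baseline cluster, progression cluster).

    For a two-group cut the off-diagonal cells are the discordant
    counts that feed :func:`mcnemar_exact`.
    """
    groups = sorted(labels.unique())
    idx = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    for b, r in pairs:
        counts[idx[labels[b]], idx[labels[r]]] += 1
    return ContingencyTable(
        counts=counts,
        row_labels=[f"baseline:cluster{g}" for g in groups],
        col_labels=[f"progression:cluster{g}" for g in groups],
    )


def mcnemar_from_square_table(table: ContingencyTable) -> TestResult:
    """Exact McNemar on a 2x2 paired cross-tabulation."""
    if table.counts.shape != (2, 2):
        raise ValueError("McNemar needs a 2x2 paired table")
    return mcnemar_exact(int(table.counts[0, 1]), int(table.counts[1, 0]))


def neighbour_arm_table(
    neighbour: pd.Series, arm_of_pair: list[str]
) -> ContingencyTable:
    """Arm x (neighbour, apart) table for the chi-square comparison of
    how often matched pairs cluster next to each other per arm."""
    if len(neighbour) != len(arm_of_pair):
        raise ValueError("one arm label per pair required")
    arms = sorted(set(arm_of_pair))
    counts = np.zeros((len(arms), 2), dtype=int)
    for called, arm in zip(neighbour.to_numpy(), arm_of_pair):
        counts[arms.index(arm), 0 if called else 1] += 1
    return ContingencyTable(
        counts=counts, row_labels=arms, col_labels=["neighbours", "apart"]
    )


def detection_timepoint_table(
    n_detected_baseline: int,
    n_baseline: int,
    n_detected_progression: int,
    n_progression: int,
    gene: str = "gene",
) -> ContingencyTable:
    """Timepoint x (detected, not detected) table for a single gene."""
    return ContingencyTable(
        counts=np.array(
            [
                [n_detected_baseline, n_baseline - n_detected_baseline],
                [n_detected_progression, n_progression - n_detected_progression],
            ]
        ),
        row_labels=["baseline", "progression"],
        col_labels=[f"{gene}+", f"{gene}-"],
    )
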