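"""Panel normalization: background subtraction, geNorm, scaling, QC.

Mirrors the classical hybridization-counting workflow: per-sample
background threshold from negative-control probes (mean + 2 SD),
subtraction with a floor at 1, geNorm selection of reference genes
from the candidate set, geometric-mean scaling, log2 transform,
detection calls, and removal of samples with too many undetected
probes.

All standard deviations use the n-1 (sample) denominator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ENDOGENOUS, NEGATIVE, NORM_CANDIDATE, POSITIVE

logger = logging.getLogger(__name__)

__all__ = [
    "RawCounts",
    "DetectionMatrix",
    "GeNormResult",
    "NormalizedMatrix",
    "background_threshold",
    "apply_background",
    "detection_calls",
    "genorm_rank",
    "genorm_select",
    "normalize_counts",
    "qc_filter_samples",
    "normalize_dataset",
]

PROBE_CLASSES = frozenset({ENDOGENOUS, NEGATIVE, POSITIVE, NORM_CANDIDATE})


@dataclass
class RawCounts:
    """Probe x sample non-negative count matrix with probe classes."""

    values: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe IDs: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        missing = self.values.index.difference(self.probe_class.index)
        if len(missing):
            raise ValueError(f"probes without a class: {list(missing)}")
        unknown = set(self.probe_class.unique()) - PROBE_CLASSES
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        self.probe_class = self.probe_class.reindex(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.values.loc[self.probe_class == cls]


@dataclass
class DetectionMatrix:
    """Boolean endogenous-probe x sample matrix; True = detected."""

    values: pd.DataFrame

    def undetected_fraction(self) -> pd.Series:
        return 1.0 - self.values.mean(axis=0)


@dataclass
class GeNormResult:
    """geNorm stability ranking of normalization candidates.

    ``stability_M`` holds the gene-stability measure M computed on the
    full candidate set; ``elimination_order`` lists candidates removed
    during stepwise exclusion, least stable first; ``pairwise_variation_V``
    holds V(n, n+1) for n = 2 .. K-1.
    """

    stability_M: dict[str, float]
    elimination_order: list[str]
    pairwise_variation_V: list[float]
    stability_order: list[str]  # most stable first
    selected_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "stability_M": self.stability_M,
                    "elimination_order": self.elimination_order,
                    "pairwise_variation_V": self.pairwise_variation_V,
                    "stability_order": self.stability_order,
                    "selected_genes": self.selected_genes,
                },
                indent=1,
            )
        )


@dataclass
class NormalizedMatrix:
    """Gene x sample log2 expression after scaling, with QC bookkeeping.

    ``normalization_factors`` maps each sample to the geometric mean of
    the selected reference genes in that sample (NF); the multiplicative
    factor applied was ``geomean(NF) / NF_s``.
    """

    values: pd.DataFrame
    kept_samples: list[str]
    normalization_factors: dict[str, float]

    @property
    def kept(self) -> pd.DataFrame:
        return self.values[self.kept_samples]


def background_threshold(neg_counts: pd.DataFrame) -> pd.Series:
    """Per-sample detection threshold: negative-control mean + 2 SD.

    ``neg_counts`` is a negative-control-probe x sample matrix with at
    least two probes (the SD is undefined otherwise).
    """
    if neg_counts.shape[0] < 2:
        raise ValueError(
            f"need >= 2 negative-control probes, got {neg_counts.shape[0]}"
        )
    return neg_counts.mean(axis=0) + 2.0 * neg_counts.std(axis=0, ddof=1)


def apply_background(counts: RawCounts, thresholds: pd.Series) -> pd.DataFrame:
    """Subtract per-sample background; floor corrected values at 1.

    Returns the endogenous and normalization-candidate rows only;
    control probes carry no biological signal past this point.
    """
    keep = counts.probe_class.isin([ENDOGENOUS, NORM_CANDIDATE])
    corrected = counts.values.loc[keep].astype(float).sub(thresholds, axis=1)
    return corrected.clip(lower=1.0)


def detection_calls(counts: RawCounts, thresholds: pd.Series) -> DetectionMatrix:
    """A probe is detected in a sample iff its raw count exceeds the
    sample's background threshold (strict inequality)."""
    endo = counts.of_class(ENDOGENOUS)
    return DetectionMatrix(values=endo.gt(thresholds, axis=1))


def _pairwise_m(log_expr: pd.DataFrame) -> pd.Series:
    """geNorm M for each candidate in ``log_expr`` (candidates x samples,
    log2 scale): mean over other candidates of the SD of the pairwise
    log-ratio across samples."""
    ids = list(log_expr.index)
    arr = log_expr.to_numpy()
    m = np.empty(len(ids))
    for j in range(len(ids)):
        sds = [
            np.std(arr[j] - arr[k], ddof=1) for k in range(len(ids)) if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=ids)


def genorm_rank(candidate_expr: pd.DataFrame) -> GeNormResult:
    """Rank normalization candidates by geNorm stability.

    ``candidate_expr`` is a candidate x sample matrix on linear scale
    with strictly positive entries.  Computes each candidate's M on the
    full set, then iteratively removes the least stable candidate
    (highest M, ties broken by lexicographically first probe ID) until
    two remain, and records the pairwise variation V(n, n+1) of
    normalization factors built from the top n vs top n+1 candidates.
    """
    if candidate_expr.shape[0] < 3:
        raise ValueError("geNorm needs >= 3 candidates")
    if candidate_expr.shape[1] < 2:
        raise ValueError("geNorm needs >= 2 samples")
    if (candidate_expr.to_numpy() <= 0).any():
        raise ValueError("candidate expression must be strictly positive")

    log_expr = np.log2(candidate_expr.astype(float))
    full_m = _pairwise_m(log_expr)

    remaining = log_expr.copy()
    elimination: list[str] = []
    while remaining.shape[0] > 2:
        m = _pairwise_m(remaining)
        worst = m[m == m.max()].index.min()  # lexicographic tie-break
        elimination.append(worst)
        remaining = remaining.drop(index=worst)
    last_two_m = _pairwise_m(log_expr.loc[remaining.index])
    last_two = sorted(remaining.index, key=lambda g: (last_two_m[g], g))
    stability_order = last_two + elimination[::-1]

    # V(n, n+1): SD across samples of the log2 ratio of normalization
    # factors from the n vs n+1 most stable candidates
    v: list[float] = []
    for n in range(2, len(stability_order)):
        nf_n = log_expr.loc[stability_order[:n]].mean(axis=0)
        nf_n1 = log_expr.loc[stability_order[: n + 1]].mean(axis=0)
        v.append(float(np.std(nf_n - nf_n1, ddof=1)))

    return GeNormResult(
        stability_M={g: float(full_m[g]) for g in candidate_expr.index},
        elimination_order=elimination,
        pairwise_variation_V=v,
        stability_order=stability_order,
    )


def genorm_select(result: GeNormResult, v_cutoff: float = 0.15) -> list[str]:
    """Choose how many reference genes to keep.

    Start from the two most stable candidates; while V(n, n+1) is at or
    above ``v_cutoff`` (adding a gene still changes the normalization
    factor appreciably), include the next gene; stop at the first n
    where V drops below the cutoff.
    """
    order = result.stability_order
    selected = list(order[:2])
    for i, v in enumerate(result.pairwise_variation_V):
        if v < v_cutoff:
            break
        selected.append(order[2 + i])
    result.selected_genes = selected
    return selected


def normalize_counts(
    corrected: pd.DataFrame, selected_genes: list[str]
) -> NormalizedMatrix:
    """Scale each sample by its reference-gene geometric mean and log2.

    NF_s is the geometric mean of the selected reference genes in
    sample s; each sample is multiplied by geomean_s(NF)/NF_s so the
    reference genes average out flat, then floored at 1 and log2
    transformed (all output values >= 0).
    """
    missing = [g for g in selected_genes if g not in corrected.index]
    if missing:
        raise ValueError(f"selected genes missing from matrix: {missing}")
    if not selected_genes:
        raise ValueError("need at least one selected reference gene")
    log_nf = np.log2(corrected.loc[selected_genes]).mean(axis=0)
    nf = np.power(2.0, log_nf)
    reference = np.power(2.0, log_nf.mean())
    scaled = corrected.mul(reference / nf, axis=1).clip(lower=1.0)
    return NormalizedMatrix(
        values=np.log2(scaled),
        kept_samples=list(corrected.columns),
        normalization_factors={s: float(nf[s]) for s in corrected.columns},
    )


def qc_filter_samples(
    detection: DetectionMatrix, max_undetected_fraction: float = 0.5
) -> list[str]:
    """Keep samples whose undetected-probe fraction does not exceed the
    cutoff (strictly greater fractions are removed)."""
    frac = detection.undetected_fraction()
    return [s for s in detection.values.columns if frac[s] <= max_undetected_fraction]


@dataclass
class NormalizationOutput:
    """Bundle of all normalization-stage artifacts."""

    normalized: NormalizedMatrix  # endogenous genes only
    detection: DetectionMatrix
    genorm: GeNormResult
    thresholds: pd.Series
    dropped_samples: list[str]
    positive_control_summary: pd.DataFrame


def normalize_dataset(
    raw: RawCounts,
    v_cutoff: float = 0.15,
    max_undetected_fraction: float = 0.5,
    n_ref_genes: int | None = None,
) -> NormalizationOutput:
    """Full normalization of one panel dataset.

    Background thresholds -> subtraction/floor -> geNorm reference-gene
    selection on the corrected candidates -> geometric-mean scaling and
    log2 -> detection calls -> sample QC.  ``n_ref_genes`` overrides the
    V-based stopping rule with a fixed count of top-stability genes.

    Positive controls are summarized (per-probe mean and CV across
    samples) for QC reporting but take no part in normalization.
    """
    thresholds = background_threshold(raw.of_class(NEGATIVE))
    corrected = apply_background(raw, thresholds)
    detection = detection_calls(raw, thresholds)

    cand_ids = raw.probe_class.index[raw.probe_class == NORM_CANDIDATE]
    genorm = genorm_rank(corrected.loc[cand_ids])
    if n_ref_genes is not None:
        if not (2 <= n_ref_genes <= len(genorm.stability_order)):
            raise ValueError("n_ref_genes out of range")
        selected = genorm.stability_order[:n_ref_genes]
        genorm.selected_genes = list(selected)
    else:
        selected = genorm_select(genorm, v_cutoff=v_cutoff)

    normalized_all = normalize_counts(corrected, selected)
    endo_ids = raw.probe_class.index[raw.probe_class == ENDOGENOUS]
    kept = qc_filter_samples(detection, max_undetected_fraction)
    dropped = [s for s in raw.sample_ids if s not in kept]
    if dropped:
        logger.info("QC removed %d sample(s): %s", len(dropped), dropped)

    pos = raw.of_class(POSITIVE).astype(float)
    pos_summary = pd.DataFrame(
        {
            "mean_count": pos.mean(axis=1),
            "cv": pos.std(axis=1, ddof=1) / pos.mean(axis=1).replace(0, np.nan),
        }
    )

    normalized = NormalizedMatrix(
        values=normalized_all.values.loc[endo_ids],
        kept_samples=kept,
        normalization_factors=normalized_all.normalization_factors,
    )
    return NormalizationOutput(
        normalized=normalized,
        detection=detection,
        genorm=genorm,
        thresholds=thresholds,
        dropped_samples=dropped,
        positive_control_summary=pos_summary,
    )
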