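"""Readers and writers for the pipeline's plain-text artifacts.

Count matrices and metadata travel as TSV/CSV (delimiter auto-detected),
gene sets as GMT, dendrograms as Newick, reports and ground truth as
JSON.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree

from .enrichment import GeneSetCollection
from .normalize import PROBE_CLASSES, DetectionMatrix, NormalizedMatrix, RawCounts
from .simulate import SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "read_gmt",
    "write_normalized",
    "write_detection",
    "linkage_to_newick",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text().splitlines()[0]
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_counts(path: str | Path) -> RawCounts:
    """Read a probe x sample count table.

    First column: probe ID; second column: probe class (endogenous,
    negative, positive, norm_candidate); remaining columns: per-sample
    counts.  Raises :class:`ParseError` naming the offending cell for
    negative counts, unknown classes, or duplicate probe IDs.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: need probe ID, probe class and >=1 sample column")
    probe_col, class_col = df.columns[0], df.columns[1]
    probes = df[probe_col].astype(str)
    dup = probes[probes.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate probe ID(s): {sorted(set(dup))}")
    classes = df[class_col].astype(str)
    bad_class = classes[~classes.isin(PROBE_CLASSES)]
    if len(bad_class):
        row = bad_class.index[0]
        raise ParseError(
            f"{path}: row {row + 2} (probe {probes[row]}): unknown probe class "
            f"{bad_class.iloc[0]!r}"
        )
    values = df.drop(columns=[probe_col, class_col])
    values.index = probes
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric count at probe {values.index[r]}, "
            f"sample {values.columns[c]}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = np.argwhere((numeric < 0).to_numpy())[0]
        raise ParseError(
            f"{path}: negative count at probe {numeric.index[r]}, "
            f"sample {numeric.columns[c]}"
        )
    return RawCounts(
        values=numeric, probe_class=pd.Series(classes.values, index=numeric.index)
    )


def write_counts(raw: RawCounts, path: str | Path) -> None:
    out = raw.values.copy()
    out.insert(0, "probe_class", raw.probe_class)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMeta:
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    required = {"sample", "patient", "timepoint", "arm"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata column(s): {sorted(missing)}")
    bad_tp = df.loc[
        ~df["timepoint"].isin([SampleMeta.BASELINE, SampleMeta.PROGRESSION])
    ]
    if len(bad_tp):
        raise ParseError(
            f"{path}: row {bad_tp.index[0] + 2}: timepoint must be "
            f"'{SampleMeta.BASELINE}' or '{SampleMeta.PROGRESSION}'"
        )
    if df["sample"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample IDs")
    return SampleMeta(table=df[sorted(required, key=list(df.columns).index)])


def read_gmt(path: str | Path) -> GeneSetCollection:
    return GeneSetCollection.from_gmt(path)


def write_normalized(norm: NormalizedMatrix, path: str | Path) -> None:
    out = norm.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_detection(detection: DetectionMatrix, path: str | Path) -> None:
    out = detection.values.astype(int)
    out.index.name = "probe"
    out.to_csv(path, sep="\t")


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string.

    Branch lengths are differences of merge heights, so leaf-to-root
    path length equals the root merge height (ultrametric tree).
    """
    tree = to_tree(np.asarray(z), rd=False)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
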