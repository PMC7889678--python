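"""Over-representation analysis against a fixed panel background.

Module gene lists are tested for enrichment in user-supplied gene sets
(GMT format) with the exact hypergeometric upper-tail test, using the
full panel as the background universe so only terms the panel can see
are ever called enriched.  No multiple-testing correction is applied by
default, matching the raw p < 0.01 convention; an optional BH column is
available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "hypergeometric_test",
    "module_ora",
]


@dataclass
class GeneSetCollection:
    """Term -> gene-list mapping with optional descriptions."""

    sets: dict[str, list[str]]
    term_descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for term, genes in self.sets.items():
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.info(
                    "term %s: dropped %d duplicate gene(s)",
                    term,
                    len(genes) - len(unique),
                )
            if not unique:
                raise ValueError(f"term {term} has an empty gene list")
            cleaned[term] = unique
        self.sets = cleaned

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        descriptions: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT needs term, description, >=1 gene"
                )
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate term {term}")
            sets[term] = genes
            descriptions[term] = desc
        return cls(sets=sets, term_descriptions=descriptions)

    def to_gmt(self, path: str | Path) -> None:
        lines = [
            "\t".join([term, self.term_descriptions.get(term, "")] + genes)
            for term, genes in self.sets.items()
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric p-value P(X >= k).

    A draw of ``n`` module genes from a background of ``N`` genes of
    which ``K`` carry the annotation; ``k`` is the observed overlap.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"need n, K <= N; got n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # P(X >= k) = sf(k - 1)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def module_ora(
    assignment,
    sets: GeneSetCollection,
    background: list[str],
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every (module, term) pair.

    Terms are intersected with the background before testing; terms
    with empty intersection are skipped with a warning.  Rows are
    sorted by ascending p (ties by term ID) within each module.
    """
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    n_bg = len(bg)
    rows = []
    term_in_bg = {}
    for term, genes in sets.sets.items():
        inter = [g for g in genes if g in bg_set]
        if not inter:
            logger.warning("term %s has no genes in the background; skipped", term)
            continue
        term_in_bg[term] = set(inter)
    for label in assignment.labels:
        members = [g for g in assignment.members(label) if g in bg_set]
        outside = set(assignment.members(label)) - bg_set
        if outside:
            raise ValueError(
                f"module {label} genes outside the background: {sorted(outside)}"
            )
        for term, annotated in term_in_bg.items():
            k = len(annotated.intersection(members))
            p = hypergeometric_test(k, len(members), len(annotated), n_bg)
            rows.append(
                {
                    "module": label,
                    "term": term,
                    "description": sets.term_descriptions.get(term, ""),
                    "k_overlap": k,
                    "n_module": len(members),
                    "K_term_in_background": len(annotated),
                    "N_background": n_bg,
                    "p_value": p,
                    "significant": bool(p < p_cutoff),
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "module",
            "term",
            "description",
            "k_overlap",
            "n_module",
            "K_term_in_background",
            "N_background",
            "p_value",
            "significant",
        ],
    )
    if len(result):
        result = result.sort_values(
            ["module", "p_value", "term"], kind="mergesort"
        ).reset_index(drop=True)
    return result
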