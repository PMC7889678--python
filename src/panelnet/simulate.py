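"""Synthetic paired pre/post expression-panel datasets.

Emulates a targeted hybridization-counting panel (endogenous probes,
housekeeping normalization candidates, spiked positive controls, orphan
negative controls) measured on patient-matched baseline/progression
biopsy pairs.  Planted co-expression modules are driven by per-module
latent factors; the first ("immune") module's factor is shifted downward
at progression by ``delta`` factor-SD units, and one low-abundance
member gene near the detection threshold serves as an IFN-γ analogue
whose detectability tracks the module.

Counts are Poisson around ``2**log2_expression``, the simplest count
noise consistent with digital hybridization counting.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SampleMeta",
    "generate_dataset",
    "generate_annotation",
]

# probe-class vocabulary shared with panelnet.normalize
ENDOGENOUS = "endogenous"
NEGATIVE = "negative"
POSITIVE = "positive"
NORM_CANDIDATE = "norm_candidate"

#: spiked positive-control input levels: a fixed 4-fold geometric ladder
#: of expected counts (highest first), truncated/extended to n_pos_controls.
POSITIVE_LADDER_TOP = 32768.0
POSITIVE_LADDER_RATIO = 4.0


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent SimulationConfig."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic paired-panel generator.

    Defaults reproduce the geometry of the emulated study panel:
    201 endogenous genes, 6 normalization candidates, 29 patient pairs,
    and four planted modules of sizes 47/30/25/20.
    """

    n_endogenous: int = 201
    n_norm_candidates: int = 6
    n_neg_controls: int = 8
    n_pos_controls: int = 6
    n_pairs: int = 29
    module_sizes: tuple[int, ...] = (47, 30, 25, 20)
    loading_range: tuple[float, float] = (0.5, 0.9)
    delta: float = 0.8
    noise_sd: float = 0.15
    neg_control_rate: float = 8.0
    unstable_candidates: int = 2
    sample_scale_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_endogenous": self.n_endogenous,
            "n_norm_candidates": self.n_norm_candidates,
            "n_neg_controls": self.n_neg_controls,
            "n_pos_controls": self.n_pos_controls,
            "n_pairs": self.n_pairs,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if any(m <= 0 for m in self.module_sizes):
            raise ConfigurationError("module_sizes must be positive")
        if sum(self.module_sizes) > self.n_endogenous:
            raise ConfigurationError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds "
                f"n_endogenous={self.n_endogenous}"
            )
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("loading_range must satisfy 0 < lo <= hi <= 1")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.neg_control_rate <= 0:
            raise ConfigurationError("neg_control_rate must be > 0")
        if not (0 <= self.unstable_candidates <= self.n_norm_candidates):
            raise ConfigurationError(
                "unstable_candidates must be between 0 and n_norm_candidates"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_sizes"] = list(self.module_sizes)
        d["loading_range"] = list(self.loading_range)
        return d


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, for recovery oracles.

    ``module_of_gene`` maps every endogenous gene to a planted module
    label (1-based) or 0 for background genes.  ``factor_values`` holds
    the realized latent factors, one row per planted module.
    """

    module_of_gene: dict[str, int]
    stable_reference_genes: list[str]
    delta: float
    factor_values: pd.DataFrame  # modules x samples
    ifng_gene: str
    unstable_reference_genes: list[str] = field(default_factory=list)

    def module_labels(self) -> pd.Series:
        return pd.Series(self.module_of_gene, name="module")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of_gene": self.module_of_gene,
            "stable_reference_genes": self.stable_reference_genes,
            "unstable_reference_genes": self.unstable_reference_genes,
            "delta": self.delta,
            "ifng_gene": self.ifng_gene,
            "factor_values": {
                "index": [str(i) for i in self.factor_values.index],
                "columns": list(self.factor_values.columns),
                "values": self.factor_values.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SampleMeta:
    """Per-sample annotation: patient, timepoint, treatment arm."""

    table: pd.DataFrame  # columns: sample, patient, timepoint, arm

    BASELINE = "baseline"
    PROGRESSION = "progression"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample"])

    def pairs(self) -> list[tuple[str, str]]:
        """(baseline sample, progression sample) per patient, patient order."""
        out = []
        for patient, grp in self.table.groupby("patient", sort=True):
            base = grp.loc[grp["timepoint"] == self.BASELINE, "sample"]
            prog = grp.loc[grp["timepoint"] == self.PROGRESSION, "sample"]
            if len(base) == 1 and len(prog) == 1:
                out.append((base.iloc[0], prog.iloc[0]))
        return out

    def arm_of_patient(self) -> dict[str, str]:
        return dict(
            self.table.drop_duplicates("patient")[["patient", "arm"]].itertuples(
                index=False, name=None
            )
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _gene_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(config: SimulationConfig):
    """Simulate one paired dataset.

    Returns ``(raw_counts, sample_meta, ground_truth)`` where
    ``raw_counts`` is a :class:`panelnet.normalize.RawCounts`.

    Endogenous log2 expression for gene g in sample s is
    ``mu_g + lambda_g * f_{m(g),s} + scale_s + eps`` with
    ``f ~ N(0,1)`` per module and sample (module-1 progression samples
    shifted by ``-delta``), gene baselines ``mu_g`` uniform on [4, 12]
    log2 counts, and ``eps ~ N(0, noise_sd)``.  Counts are Poisson
    around ``2**expression``.
    """
    from .normalize import RawCounts  # local import to avoid a cycle

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = 2 * cfg.n_pairs

    patients = [f"P{i + 1:03d}" for i in range(cfg.n_pairs)]
    samples, timepoints, patient_of_sample = [], [], []
    for p in patients:
        for tp, suffix in ((SampleMeta.BASELINE, "B"), (SampleMeta.PROGRESSION, "R")):
            samples.append(f"{p}_{suffix}")
            timepoints.append(tp)
            patient_of_sample.append(p)
    # arm split mirrors the emulated trial's ~18:11 pair ratio
    n_bev = int(round(cfg.n_pairs * 18 / 29))
    arm_of = {
        p: ("CIS+PEM+BEV" if i < n_bev else "CIS+PEM") for i, p in enumerate(patients)
    }
    meta = SampleMeta(
        pd.DataFrame(
            {
                "sample": samples,
                "patient": patient_of_sample,
                "timepoint": timepoints,
                "arm": [arm_of[p] for p in patient_of_sample],
            }
        )
    )
    is_progression = np.array([t == SampleMeta.PROGRESSION for t in timepoints])

    genes = _gene_ids(cfg.n_endogenous)
    n_modules = len(cfg.module_sizes)

    # scatter module membership over the panel
    order = rng.permutation(cfg.n_endogenous)
    module_of = np.zeros(cfg.n_endogenous, dtype=int)
    pos = 0
    for m, size in enumerate(cfg.module_sizes, start=1):
        module_of[order[pos : pos + size]] = m
        pos += size

    mu = rng.uniform(4.0, 12.0, size=cfg.n_endogenous)
    lam = np.zeros(cfg.n_endogenous)
    in_module = module_of > 0
    lam[in_module] = rng.uniform(*cfg.loading_range, size=int(in_module.sum()))

    # latent factors: one row per module, one column per sample
    factors = rng.standard_normal((n_modules, n_samples))
    if n_modules >= 1:
        factors[0, is_progression] -= cfg.delta

    # IFN-γ analogue: a module-1 gene parked just above the expected
    # detection threshold, with a strong loading so detectability tracks
    # the immune factor
    ifng_gene = ""
    if n_modules >= 1:
        module1_idx = np.flatnonzero(module_of == 1)
        gi = int(rng.choice(module1_idx))
        thr = cfg.neg_control_rate + 2.0 * np.sqrt(cfg.neg_control_rate)
        mu[gi] = np.log2(thr) + 0.6
        lam[gi] = cfg.loading_range[1]
        ifng_gene = genes[gi]

    scale = rng.normal(0.0, cfg.sample_scale_sd, size=n_samples)
    eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_endogenous, n_samples))
    factor_of_gene = np.zeros((cfg.n_endogenous, n_samples))
    for m in range(1, n_modules + 1):
        factor_of_gene[module_of == m] = factors[m - 1]
    log2_expr = mu[:, None] + lam[:, None] * factor_of_gene + scale[None, :] + eps
    endo_counts = rng.poisson(np.power(2.0, log2_expr))

    # normalization candidates: abundant, no module loading; the first
    # `unstable_candidates` get 3x residual noise
    cand_ids = [f"HK{i + 1:02d}" for i in range(cfg.n_norm_candidates)]
    cand_mu = rng.uniform(9.0, 12.0, size=cfg.n_norm_candidates)
    cand_sd = np.full(cfg.n_norm_candidates, cfg.noise_sd)
    cand_sd[: cfg.unstable_candidates] = 3.0 * cfg.noise_sd
    cand_eps = rng.normal(0.0, 1.0, size=(cfg.n_norm_candidates, n_samples))
    cand_expr = cand_mu[:, None] + cand_sd[:, None] * cand_eps + scale[None, :]
    cand_counts = rng.poisson(np.power(2.0, cand_expr))

    neg_ids = [f"NEG{i + 1:02d}" for i in range(cfg.n_neg_controls)]
    neg_counts = rng.poisson(
        cfg.neg_control_rate, size=(cfg.n_neg_controls, n_samples)
    )

    pos_ids = [f"POS{i + 1:02d}" for i in range(cfg.n_pos_controls)]
    ladder = POSITIVE_LADDER_TOP / POSITIVE_LADDER_RATIO ** np.arange(
        cfg.n_pos_controls
    )
    pos_counts = rng.poisson(np.broadcast_to(ladder[:, None], (cfg.n_pos_controls, n_samples)))

    values = pd.DataFrame(
        np.vstack([endo_counts, cand_counts, neg_counts, pos_counts]),
        index=genes + cand_ids + neg_ids + pos_ids,
        columns=samples,
        dtype=np.int64,
    )
    probe_class = pd.Series(
        [ENDOGENOUS] * cfg.n_endogenous
        + [NORM_CANDIDATE] * cfg.n_norm_candidates
        + [NEGATIVE] * cfg.n_neg_controls
        + [POSITIVE] * cfg.n_pos_controls,
        index=values.index,
        name="probe_class",
    )
    raw = RawCounts(values=values, probe_class=probe_class)

    truth = GroundTruth(
        module_of_gene={g: int(m) for g, m in zip(genes, module_of)},
        stable_reference_genes=cand_ids[cfg.unstable_candidates :],
        unstable_reference_genes=cand_ids[: cfg.unstable_candidates],
        delta=cfg.delta,
        factor_values=pd.DataFrame(
            factors,
            index=[f"module_{m + 1}" for m in range(n_modules)],
            columns=samples,
        ),
        ifng_gene=ifng_gene,
    )
    return raw, meta, truth


def generate_annotation(ground_truth: GroundTruth, n_terms: int, seed: int):
    """Synthetic gene-set collection for exercising over-representation.

    The first ``min(n_terms, n_modules)`` terms are planted: each draws
    80% of its genes from one planted module and the rest uniformly
    from the panel, so the term is strongly enriched in that module.
    Remaining terms are decoys drawn uniformly from the panel.
    """
    from .enrichment import GeneSetCollection

    if n_terms < 0:
        raise ConfigurationError("n_terms must be >= 0")
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(ground_truth.module_of_gene))
    labels = pd.Series(ground_truth.module_of_gene)
    modules = sorted(set(labels) - {0})

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for i, m in enumerate(modules):
        if i >= n_terms:
            break
        members = np.array(sorted(labels.index[labels == m]))
        n_from_module = max(1, int(round(0.8 * len(members))))
        picked = list(rng.choice(members, size=n_from_module, replace=False))
        background = np.setdiff1d(genes, members)
        n_noise = max(0, int(round(len(members) * 0.2)))
        if n_noise:
            picked += list(rng.choice(background, size=n_noise, replace=False))
        term = f"PLANTED_M{m}"
        sets[term] = sorted(set(picked))
        descriptions[term] = f"planted term enriched in module {m}"
    for j in range(len(sets), n_terms):
        size = int(rng.integers(10, 41))
        term = f"DECOY_{j + 1:03d}"
        sets[term] = sorted(set(rng.choice(genes, size=size, replace=False)))
        descriptions[term] = "decoy term drawn uniformly from the panel"
    return GeneSetCollection(sets=sets, term_descriptions=descriptions)
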