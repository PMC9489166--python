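"""Synthetic paired tumor/normal cohorts with planted prognostic structure.

The generator emulates the structure the analysis assumes: ~19,500 genes
measured in tumor and normal bronchial tissue of 123 resected NSCLC
patients, split into six histology-by-treatment groups (24 AC and 32 SCC
and 6 LCC surgery-only; 33 AC, 18 SCC and 10 LCC with adjuvant
chemotherapy), disease-free survival between 3 and 92 months, a planted
per-group gene signature whose summed DDPP weight is an affine function of
DFS, and bimodal normal-tissue expression of the immune-checkpoint genes
CTLA-4, PD-L1 and ICOS with a planted immune-tolerant subgroup.

Ground truth (planted genes, link coefficients, immune membership) is
returned alongside the data so parameter-recovery tests can check the
analysis end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model_io import GROUP_ORDER, PairedExpression, group_label, validate_clinical

_LOG2_OF_1P1 = np.log2(1.1)

DEFAULT_GROUP_SIZES = {
    ("AC", False): 24,
    ("AC", True): 33,
    ("SCC", False): 32,
    ("SCC", True): 18,
    ("LCC", False): 6,
    ("LCC", True): 10,
}

#: per-group planted signature sizes (gene counts of the six printed predictors)
DEFAULT_SIGNATURE_SIZES = {
    ("AC", False): 10,
    ("AC", True): 10,
    ("SCC", False): 15,
    ("SCC", True): 7,
    ("LCC", False): 5,
    ("LCC", True): 10,
}

# months of DFS per unit of summed signature weight, and months at zero weight
DEFAULT_LINK_SLOPES = {
    ("AC", False): 2.0,
    ("AC", True): 1.6,
    ("SCC", False): 2.5,
    ("SCC", True): 1.8,
    ("LCC", False): 2.2,
    ("LCC", True): 1.4,
}
DEFAULT_LINK_INTERCEPTS = {key: 47.5 for key in DEFAULT_GROUP_SIZES}

# TNM stage marginal counts among patients with full clinical data (stages 1..4)
DEFAULT_STAGE_COUNTS = (56, 27, 32, 5)

IMMUNE_GENES = ("CTLA4", "PDL1", "ICOS")

# log2-scale two-component mixture for checkpoint genes in normal tissue;
# the components sit 12 SDs apart so k=2 calls are unambiguous
IMMUNE_LOW_MEAN = 6.0
IMMUNE_HIGH_MEAN = 12.0
IMMUNE_SD = 0.5


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the design constants of the emulated study: gene
    and patient counts, the six group sizes, signature sizes, the DFS
    range in months, 3 patients without TNM staging, and 28
    immune-tolerant patients among the 120 with full clinical data.
    """

    n_genes: int = 19_500
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    signature_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SIGNATURE_SIZES))
    link_slopes: dict = field(default_factory=lambda: dict(DEFAULT_LINK_SLOPES))
    link_intercepts: dict = field(default_factory=lambda: dict(DEFAULT_LINK_INTERCEPTS))
    dfs_range_months: tuple[float, float] = (3.0, 92.0)
    noise_sd: float = 0.05
    intensity_log2_range: tuple[float, float] = (4.0, 14.0)
    immune_genes: tuple[str, ...] = IMMUNE_GENES
    immune_high_fraction: dict = field(
        default_factory=lambda: {"CTLA4": 0.5, "PDL1": 0.65, "ICOS": 0.6}
    )
    immune_tolerant_count: int = 28
    immune_competent_count: int = 30
    missing_stage_count: int = 3
    stage_counts: tuple[int, ...] = DEFAULT_STAGE_COUNTS
    censor_fraction: float = 0.0
    seed: int = 0

    @property
    def n_patients(self) -> int:
        return sum(self.group_sizes.values())

    def validate(self) -> None:
        lo, hi = self.dfs_range_months
        if lo <= 0 or lo >= hi:
            raise ValueError("dfs_range_months must satisfy 0 < min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        unknown = set(self.signature_sizes) - set(self.group_sizes)
        if unknown:
            labels = sorted(group_label(k) for k in unknown)
            raise ValueError(f"signature_sizes reference unknown groups: {labels}")
        if self.intensity_log2_range[0] <= 0:
            raise ValueError("intensity_log2_range must be positive (intensities > 1)")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth planted in a generated cohort."""

    planted_genes: dict  # group label -> list of gene ids
    link_slope: dict  # group label -> months per summed weight unit
    link_intercept: dict
    immune_membership: dict  # patient -> tolerant / competent / other

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _gene_universe(config: SynthConfig, with_signatures: bool) -> tuple[list[str], bool]:
    """Gene id list; immune genes are included as named ids when they fit."""
    needed = sum(config.signature_sizes.values()) if with_signatures else 0
    include_immune = config.n_genes >= len(config.immune_genes) + needed
    immune = list(config.immune_genes) if include_immune else []
    n_anon = config.n_genes - len(immune)
    genes = immune + [f"G{i:05d}" for i in range(1, n_anon + 1)]
    return genes, include_immune


def _clinical_table(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    order = [k for k in GROUP_ORDER if k in config.group_sizes]
    order += [k for k in config.group_sizes if k not in order]
    rows = []
    pid = 0
    for key in order:
        histology, chemo = key
        for _ in range(config.group_sizes[key]):
            pid += 1
            rows.append({"patient_id": f"P{pid:03d}", "histology": histology, "chemo": chemo})
    table = pd.DataFrame(rows).set_index("patient_id")
    n = len(table)

    lo, hi = config.dfs_range_months
    table["dfs_months"] = rng.uniform(lo, hi, size=n)
    table["event"] = True
    if config.censor_fraction > 0:
        censored = rng.random(n) < config.censor_fraction
        table.loc[censored, "event"] = False

    # stage: 3 patients undetermined; the rest follow the printed marginal
    # counts, assigned by noisy DFS rank so advanced stage tracks shorter DFS
    missing = rng.choice(table.index, size=min(config.missing_stage_count, n), replace=False)
    staged = table.index.difference(missing)
    counts = np.array(config.stage_counts, dtype=float)
    quota = np.floor(counts / counts.sum() * len(staged)).astype(int)
    quota[0] += len(staged) - quota.sum()
    noisy = table.loc[staged, "dfs_months"] + rng.normal(0, 15.0, size=len(staged))
    by_risk = noisy.sort_values().index  # shortest DFS first
    stage = pd.Series(pd.NA, index=table.index, dtype="Int64")
    start = 0
    for s, q in zip((4, 3, 2, 1), quota[::-1]):
        stage[by_risk[start:start + q]] = s
        start += q
    table["stage"] = stage
    return validate_clinical(table.reset_index().set_index("patient_id"))


def _plant_signatures(config, rng, genes, clinical, log2_t, log2_n, groups):
    """Overwrite normal-tissue log2 intensities of the planted genes so that
    summed tumor-source weight = (DFS - intercept) / slope + noise.

    Each planted gene carries a distinct share of the summed weight
    (multipliers spread between 0.8/s and 1.2/s) so that every gene is
    individually correlated with DFS but no aggregate of the planted set
    stays perfectly linear once a non-planted gene is mixed in.
    """
    pool = [g for g in genes if g not in config.immune_genes]
    rng_pool = list(rng.permutation(pool))
    planted: dict[str, list[str]] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    pat_pos = {p: i for i, p in enumerate(clinical.index)}

    for key in config.signature_sizes:
        size = config.signature_sizes[key]
        members = groups.get(key, [])
        if size == 0 or not members:
            planted[group_label(key)] = []
            continue
        sig = [rng_pool.pop() for _ in range(size)]
        planted[group_label(key)] = sorted(sig)
        slope = config.link_slopes[key]
        intercept = config.link_intercepts[key]
        dfs = clinical.loc[members, "dfs_months"].to_numpy()
        target = (dfs - intercept) / slope  # summed weight per patient
        g_idx = np.array([gene_pos[g] for g in sig])
        p_idx = np.array([pat_pos[p] for p in members])
        share = np.linspace(0.8, 1.2, size)
        share /= share.sum()
        w = share[:, None] * target[None, :] + rng.normal(
            0.0, config.noise_sd, size=(size, len(members))
        )
        t2 = log2_t[np.ix_(g_idx, p_idx)]
        log1p1_i = t2 / _LOG2_OF_1P1  # log base-1.1 of the tumor intensity
        fold = w / log1p1_i  # log2 fold-change that yields weight w
        log2_n[np.ix_(g_idx, p_idx)] = t2 - fold
    return planted


def _plant_immune(config, rng, genes, clinical, log2_n):
    """Draw checkpoint-gene normal-tissue expression from a planted mixture.

    Tolerant patients (all three genes high) are the `immune_tolerant_count`
    shortest-DFS patients with full clinical data, and competent patients
    (CTLA-4 low, PD-L1/ICOS high) the longest-DFS ones, emulating the
    adverse prognosis of the tolerant profile.  Remaining patients draw
    per-gene calls from `immune_high_fraction`, excluding the two special
    patterns so the planted tolerant count is exact.
    """
    membership: dict[str, str] = {}
    high = {g: {} for g in config.immune_genes}
    full = clinical.index[clinical["stage"].notna()]
    by_dfs = clinical.loc[full, "dfs_months"].sort_values().index
    tolerant = set(by_dfs[: config.immune_tolerant_count])
    competent = set(by_dfs[len(by_dfs) - config.immune_competent_count:]) - tolerant

    ctla4, pdl1, icos = config.immune_genes
    for p in clinical.index:
        if p in tolerant:
            calls = {ctla4: True, pdl1: True, icos: True}
            status = "tolerant"
        elif p in competent:
            calls = {ctla4: False, pdl1: True, icos: True}
            status = "competent"
        else:
            for _ in range(100):
                calls = {g: bool(rng.random() < config.immune_high_fraction.get(g, 0.5))
                         for g in config.immune_genes}
                if not all(calls.values()) and not (
                    not calls[ctla4] and calls[pdl1] and calls[icos]
                ):
                    break
            else:
                calls[icos] = False
            status = "other"
        if p in full:
            membership[p] = status
        for g in config.immune_genes:
            high[g][p] = calls[g]

    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in config.immune_genes:
        means = np.where([high[g][p] for p in clinical.index], IMMUNE_HIGH_MEAN, IMMUNE_LOW_MEAN)
        log2_n[gene_pos[g], :] = rng.normal(means, IMMUNE_SD)
    return membership


def _base_matrices(config: SynthConfig, rng, n_genes, n_patients):
    lo, hi = config.intensity_log2_range
    log2_t = rng.uniform(lo, hi, size=(n_genes, n_patients))
    log2_n = rng.uniform(lo, hi, size=(n_genes, n_patients))
    return log2_t, log2_n


def generate_cohort(config: SynthConfig) -> tuple[PairedExpression, pd.DataFrame, TruthRecord]:
    """Generate a full cohort with planted signatures and immune structure.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, include_immune = _gene_universe(config, with_signatures=True)
    clinical = _clinical_table(config, rng)
    log2_t, log2_n = _base_matrices(config, rng, len(genes), len(clinical))

    groups = {
        key: clinical.index[
            (clinical["histology"] == key[0]) & (clinical["chemo"] == key[1])
        ].tolist()
        for key in config.group_sizes
    }
    planted = _plant_signatures(config, rng, genes, clinical, log2_t, log2_n, groups)
    membership = _plant_immune(config, rng, genes, clinical, log2_n) if include_immune else {}

    expr = PairedExpression(
        tumor=pd.DataFrame(np.exp2(log2_t), index=genes, columns=clinical.index),
        normal=pd.DataFrame(np.exp2(log2_n), index=genes, columns=clinical.index),
    )
    truth = TruthRecord(
        planted_genes=planted,
        link_slope={group_label(k): config.link_slopes[k] for k in config.signature_sizes},
        link_intercept={group_label(k): config.link_intercepts[k] for k in config.signature_sizes},
        immune_membership=membership,
    )
    return expr, clinical, truth


def generate_null_cohort(config: SynthConfig) -> tuple[PairedExpression, pd.DataFrame]:
    """Cohort with no planted structure: every gene weight independent of DFS.

    Tumor and normal log2 intensities are drawn independently and uniformly
    for all genes (checkpoint genes included), giving an exchangeable null
    for specificity experiments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, _ = _gene_universe(config, with_signatures=False)
    clinical = _clinical_table(config, rng)
    log2_t, log2_n = _base_matrices(config, rng, len(genes), len(clinical))
    expr = PairedExpression(
        tumor=pd.DataFrame(np.exp2(log2_t), index=genes, columns=clinical.index),
        normal=pd.DataFrame(np.exp2(log2_n), index=genes, columns=clinical.index),
    )
    return expr, clinical
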