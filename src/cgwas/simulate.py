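"""Synthetic case-control cohorts with latent phenotypic subgroups.

The generator emulates the structure of a large autism case-control resource:
a pool of affected probands that decomposes into latent subgroups, a shared
pool of unaffected controls, independent biallelic autosomal variants in
Hardy-Weinberg proportions, and questionnaire-style phenotype blocks
(motor coordination / social communication / repetitive behavior item
scores), age, and categorical background variables.

Disease model: each subgroup may carry subgroup-specific risk variants with
a per-allele odds ratio. Case genotypes are produced by rejection sampling
with acceptance probability proportional to the logistic odds,
``prod_v OR_v ** dosage_v`` (an exponential tilt of the Hardy-Weinberg
distribution). Under that tilt the case genotype distribution at a causal
variant is exactly Hardy-Weinberg at the shifted frequency
``f' = f * OR / (1 - f + f * OR)``, so the planted allelic odds ratio of a
case-vs-control comparison equals the configured OR without further
calibration (a prevalence-anchored acceptance would attenuate it through
sigmoid saturation).

Phenotype model: each numeric item is standard normal noise; members of
subgroup g have a designated subset of items (round-robin assignment) shifted
by ``subgroup_item_shift`` standard deviations. Categorical variables are
uniform multinomial draws. Missingness is MCAR at ``missing_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, VARIANT_COLUMNS, write_vcf

_N_AUTOSOMES = 22
_VARIANT_SPACING = 10_000  # bp between consecutive simulated variants


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the shape of the emulated study at desk scale:
    2,000 cases / 875 controls / 20,000 variants, questionnaire blocks of
    15, 40 and 43 items plus age, and the usual background categoricals.
    """

    n_cases: int = 2000
    n_controls: int = 875
    n_subgroups: int = 4
    subgroup_weights: tuple = None
    n_variants: int = 20000
    maf_range: tuple = (0.05, 0.5)
    causal_spec: list = field(default_factory=list)  # (variant_idx, subgroup, OR)
    n_numeric_items: tuple = (15, 40, 43)
    categorical_spec: dict = field(
        default_factory=lambda: {
            "ethnicity": 4,
            "dominant_hand": 3,
            "medication": 2,
            "biomedical": 2,
            "intensive_behavioral": 2,
        }
    )
    subgroup_item_shift: float = 2.0
    missing_rate: float = 0.05
    #: exact ALT frequencies for specific variants, e.g. {0: 0.05}; other
    #: variants keep their uniform maf_range draw
    maf_override: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.subgroup_weights is None:
            self.subgroup_weights = tuple([1.0 / self.n_subgroups] * self.n_subgroups)
        self.subgroup_weights = tuple(float(w) for w in self.subgroup_weights)
        if len(self.subgroup_weights) != self.n_subgroups:
            raise ValueError("subgroup_weights length != n_subgroups")
        if abs(sum(self.subgroup_weights) - 1.0) > 1e-9:
            raise ValueError("subgroup_weights must sum to 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for v, g, orr in self.causal_spec:
            if orr <= 0:
                raise ValueError(f"odds ratio for variant {v} must be > 0")
            if not (0 <= g < self.n_subgroups):
                raise ValueError(f"causal subgroup {g} out of range")
            if not (0 <= v < self.n_variants):
                raise ValueError(f"causal variant index {v} out of range")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    case_ids: list
    control_ids: list
    subgroup_labels: np.ndarray  # per case, in [0, n_subgroups)
    causal_spec: list  # realized (variant_idx, subgroup, OR)


def _variant_table(n_variants: int) -> pd.DataFrame:
    """Deterministic variant metadata: variants spread over autosomes 1..22."""
    idx = np.arange(n_variants)
    chrom = (idx % _N_AUTOSOMES) + 1
    pos = (idx // _N_AUTOSOMES + 1) * _VARIANT_SPACING
    return pd.DataFrame(
        {
            "chrom": chrom.astype(str),
            "pos": pos,
            "id": [f"var{i:06d}" for i in idx],
            "ref": "A",
            "alt": "G",
        },
        columns=VARIANT_COLUMNS,
    )


def _draw_mafs(n_variants, maf_range, rng) -> np.ndarray:
    lo, hi = maf_range
    return rng.uniform(lo, hi, size=n_variants)


def simulate_genotypes(
    n_samples: int, n_variants: int, maf_range=(0.05, 0.5), seed: int = 0
) -> GenotypeMatrix:
    """Independent biallelic variants in Hardy-Weinberg proportions.

    Each variant's ALT frequency is drawn uniformly in ``maf_range`` and
    genotypes are Binomial(2, f) hard calls.
    """
    if n_samples < 1 or n_variants < 1:
        raise ValueError("n_samples and n_variants must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range {maf_range} not within (0, 0.5]")
    rng = np.random.default_rng(seed)
    f = _draw_mafs(n_variants, maf_range, rng)
    dos = rng.binomial(2, f, size=(n_samples, n_variants)).astype(np.float32)
    ids = [f"s{i:05d}" for i in range(n_samples)]
    return GenotypeMatrix(ids, _variant_table(n_variants), dos)


def simulate_phenotypes(
    subgroup_labels, config: SimConfig, rng=None, sample_ids=None
) -> pd.DataFrame:
    """Phenotype table for the given per-case subgroup labels.

    Numeric questionnaire items are N(0,1) plus a ``subgroup_item_shift``
    mean shift on the item subset assigned (round-robin) to each subgroup;
    age is N(100, 30) months, unshifted. Cells go missing independently at
    ``missing_rate`` (MCAR).
    """
    labels = np.asarray(subgroup_labels)
    if labels.size and (labels.min() < 0 or labels.max() >= config.n_subgroups):
        raise ValueError("subgroup labels out of range for config")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(labels)
    block_names = (
        ["dcdq", "scq", "rbsr"]
        if len(config.n_numeric_items) == 3
        else [f"block{i}" for i in range(len(config.n_numeric_items))]
    )
    cols = {}
    item_names = []
    for bname, n_items in zip(block_names, config.n_numeric_items):
        item_names += [f"{bname}_{i + 1:02d}" for i in range(n_items)]
    n_items_total = len(item_names)
    X = rng.standard_normal((n, n_items_total))
    # item j is shifted for subgroup (j mod n_subgroups)
    owner = np.arange(n_items_total) % config.n_subgroups
    shift = (labels[:, None] == owner[None, :]) * config.subgroup_item_shift
    X = X + shift
    for j, name in enumerate(item_names):
        cols[name] = X[:, j]
    cols["age_months"] = rng.normal(100.0, 30.0, size=n)
    df = pd.DataFrame(cols)
    for cname, n_levels in config.categorical_spec.items():
        lv = rng.integers(0, n_levels, size=n)
        df[cname] = pd.array([f"level{v}" for v in lv], dtype="string")
    if config.missing_rate > 0:
        mask = rng.random(df.shape) < config.missing_rate
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    if sample_ids is None:
        sample_ids = [f"case{i:05d}" for i in range(n)]
    df.insert(0, "sample_id", list(sample_ids))
    return df


def _subgroup_counts(config: SimConfig) -> np.ndarray:
    """Exact subgroup case counts by largest-remainder apportionment."""
    w = np.asarray(config.subgroup_weights)
    raw = w * config.n_cases
    counts = np.floor(raw).astype(int)
    rem = config.n_cases - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _sample_cases_for_subgroup(
    n_needed, causal_idx, causal_logor, mafs, rng, attempt_cap=2_000_000
):
    """Rejection-sample causal-variant genotypes of accepted cases.

    Acceptance probability is proportional to the logistic odds
    ``exp(sum_v log(OR_v) * g_v)`` (normalized by its maximum over
    genotypes), so accepted genotypes follow the exponentially tilted
    Hardy-Weinberg distribution and the planted allelic OR is exact. Only
    causal columns influence acceptance, so non-causal columns are filled
    in afterwards from the base distribution.
    """
    if len(causal_idx) == 0:
        return np.empty((n_needed, 0), dtype=np.int64)
    out = []
    got = attempts = 0
    batch = max(1024, 4 * n_needed)
    f = mafs[causal_idx]
    log_max = np.maximum(0.0, 2.0 * causal_logor).sum()
    while got < n_needed:
        g = rng.binomial(2, f, size=(batch, len(causal_idx)))
        logp = g @ causal_logor - log_max
        accept = rng.random(batch) < np.exp(logp)
        acc = g[accept]
        out.append(acc[: n_needed - got])
        got += min(len(acc), n_needed - got)
        attempts += batch
        if attempts > attempt_cap and got == 0:
            raise RuntimeError(
                "rejection sampling stalled for causal variants "
                f"{sorted(set(causal_idx.tolist()))}: odds ratios too extreme"
            )
    return np.concatenate(out, axis=0)


def simulate_cohort(config: SimConfig):
    """Full cohort: (GenotypeMatrix, phenotype table for cases, SimTruth).

    Controls are drawn from the base genotype distribution; cases of
    subgroup g are rejection-sampled under the logistic disease model with
    that subgroup's causal variants. Sample order is cases then controls.
    """
    master = np.random.default_rng(config.seed)
    s_maf, s_ctrl, s_case, s_pheno = master.integers(2**31, size=4)
    rng_maf = np.random.default_rng(s_maf)
    mafs = _draw_mafs(config.n_variants, config.maf_range, rng_maf)
    for v, f in config.maf_override.items():
        mafs[int(v)] = float(f)

    rng_ctrl = np.random.default_rng(s_ctrl)
    ctrl = rng_ctrl.binomial(2, mafs, size=(config.n_controls, config.n_variants))

    counts = _subgroup_counts(config)
    rng_case = np.random.default_rng(s_case)
    case_blocks = []
    labels = []
    for g, n_g in enumerate(counts):
        spec_g = [(v, orr) for v, sg, orr in config.causal_spec if sg == g]
        cidx = np.array([v for v, _ in spec_g], dtype=int)
        clogor = np.array([np.log(orr) for _, orr in spec_g])
        block = rng_case.binomial(2, mafs, size=(n_g, config.n_variants))
        if len(cidx):
            block[:, cidx] = _sample_cases_for_subgroup(
                n_g, cidx, clogor, mafs, rng_case
            )
        case_blocks.append(block)
        labels += [g] * n_g
    cases = (
        np.concatenate(case_blocks, axis=0)
        if case_blocks
        else np.empty((0, config.n_variants), int)
    )
    labels = np.array(labels, dtype=int)

    case_ids = [f"case{i:05d}" for i in range(config.n_cases)]
    control_ids = [f"ctrl{i:05d}" for i in range(config.n_controls)]
    dosages = np.concatenate([cases, ctrl], axis=0).astype(np.float32)
    gm = GenotypeMatrix(case_ids + control_ids, _variant_table(config.n_variants), dosages)

    rng_pheno = np.random.default_rng(s_pheno)
    pheno = simulate_phenotypes(labels, config, rng=rng_pheno, sample_ids=case_ids)
    truth = SimTruth(case_ids, control_ids, labels, list(config.causal_spec))
    return gm, pheno, truth


def write_cohort(gm: GenotypeMatrix, pheno: pd.DataFrame, truth: SimTruth, directory):
    """Write genotypes.vcf, phenotypes.csv, truth.tsv and causal_spec.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_vcf(gm, directory / "genotypes.vcf")
    pheno.to_csv(directory / "phenotypes.csv", index=False)
    pd.DataFrame(
        {"sample_id": truth.case_ids, "subgroup": truth.subgroup_labels}
    ).to_csv(directory / "truth.tsv", sep="\t", index=False)
    with open(directory / "causal_spec.json", "w") as fh:
        json.dump(
            [
                {"variant_index": int(v), "subgroup": int(g), "odds_ratio": float(o)}
                for v, g, o in truth.causal_spec
            ],
            fh,
            indent=1,
        )
    return {
        "vcf": directory / "genotypes.vcf",
        "phenotypes": directory / "phenotypes.csv",
        "truth": directory / "truth.tsv",
        "causal_spec": directory / "causal_spec.json",
    }
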