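"""Variant-level QC and PCA-based sample exclusion.

Filters follow standard array-GWAS practice: drop variants with minor allele
frequency < 0.01, call rate < 0.95, or an exact Hardy-Weinberg test
p < 1e-6. Samples whose projections on principal components 1 or 2 of the
standardized genotype matrix exceed 6 standard deviations are flagged as
ancestry outliers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genotypes import GenotypeMatrix, read_genotypes  # noqa: F401  (re-export)


@dataclass
class FilterReport:
    n_input: int
    n_removed: dict  # rule -> count, attribution in precedence order
    n_retained: int
    thresholds: dict

    def __post_init__(self):
        if sum(self.n_removed.values()) != self.n_input - self.n_retained:
            raise ValueError("removal counts do not sum to n_input - n_retained")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.n_removed.items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["stage", "n"])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


@lru_cache(maxsize=100_000)
def _hwe_het_probs(n: int, n_a: int) -> tuple:
    """P(het count) for all feasible het counts given n genotypes and n_a
    copies of the minor allele, conditional on the allele counts.

    Uses the standard recurrence on heterozygote counts; returns
    (het_counts, probabilities).
    """
    h0 = n_a % 2
    hets = list(range(h0, n_a + 1, 2))
    # unnormalized probabilities via the ratio recurrence:
    # P(h+2)/P(h) = h_a(h) * h_b(h) ... derived from the multinomial form
    logp = [0.0]
    for h in hets[:-1]:
        n_aa = (n_a - h) // 2
        n_bb = n - n_aa - h
        # ratio P(h+2)/P(h) = 4 * n_aa * n_bb / ((h+2)(h+1))
        logp.append(logp[-1] + np.log(4.0 * n_aa * n_bb) - np.log((h + 2) * (h + 1)))
    p = np.exp(np.array(logp) - max(logp))
    p /= p.sum()
    return tuple(hets), tuple(p)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    p = sum of the conditional probabilities of all heterozygote counts no
    more likely than the observed one, given the allele counts. Monomorphic
    input returns 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or (n_AA + n_Aa + n_aa) < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = n_AA + n_Aa + n_aa
    n_a = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele copies
    if n_a == 0:
        return 1.0
    hets, probs = _hwe_het_probs(n, n_a)
    probs = np.asarray(probs)
    obs = hets.index(n_Aa)
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def hwe_chisq_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square Hardy-Weinberg test (available as an alternative)."""
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if np.any(exp == 0):
        return 1.0
    stat = (((np.array([n_AA, n_Aa, n_aa]) - exp) ** 2) / exp).sum()
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Per-variant statistics and filtering


def variant_stats(gm: GenotypeMatrix, hwe_method: str = "exact") -> pd.DataFrame:
    """alt_freq, maf, call_rate and HWE p per variant.

    Frequencies use raw dosages over called samples; the HWE test uses
    hard-call counts (fractional dosages rounded for HWE only). All-missing
    variants get NaN frequencies, call_rate 0 and hwe_p NaN.
    """
    dos = gm.dosages.astype(float)
    called = ~np.isnan(dos)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(dos, axis=0) / (2 * n_called)
    alt_freq = np.where(n_called > 0, alt_freq, np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    call_rate = n_called / gm.n_samples
    hard = np.round(dos)
    test = hwe_exact_p if hwe_method == "exact" else hwe_chisq_p
    hwe_p = np.full(gm.n_variants, np.nan)
    for j in range(gm.n_variants):
        if n_called[j] == 0:
            continue
        col = hard[called[:, j], j]
        n_aa = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_AA = int(len(col) - n_aa - n_het)
        hwe_p[j] = test(n_AA, n_het, n_aa)
    return pd.DataFrame(
        {"alt_freq": alt_freq, "maf": maf, "call_rate": call_rate, "hwe_p": hwe_p}
    )


def apply_variant_filters(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
    hwe_method: str = "exact",
):
    """Keep variants with maf >= maf_min AND call_rate >= callrate_min AND
    hwe_p >= hwe_p_min. Returns (filtered GenotypeMatrix, FilterReport).

    The retained set is an AND of predicates (order-independent); the
    report attributes each removal to the first failing rule in the
    precedence maf -> call_rate -> hwe.
    """
    stats = variant_stats(gm, hwe_method=hwe_method)
    fail_maf = ~(stats["maf"] >= maf_min)  # NaN maf fails
    fail_cr = stats["call_rate"] < callrate_min
    fail_hwe = ~(stats["hwe_p"] >= hwe_p_min)
    keep = ~(fail_maf | fail_cr | fail_hwe)
    removed = {
        "maf": int(fail_maf.sum()),
        "call_rate": int((fail_cr & ~fail_maf).sum()),
        "hwe": int((fail_hwe & ~fail_maf & ~fail_cr).sum()),
    }
    report = FilterReport(
        n_input=gm.n_variants,
        n_removed=removed,
        n_retained=int(keep.sum()),
        thresholds={"maf_min": maf_min, "callrate_min": callrate_min, "hwe_p_min": hwe_p_min},
    )
    return gm.subset_variants(keep.to_numpy()), report


# ---------------------------------------------------------------------------
# PCA ancestry outliers


def pca_outliers(
    gm: GenotypeMatrix,
    n_components: int = 10,
    sd_threshold: float = 6.0,
    test_components=(1, 2),
) -> list:
    """Sample ids whose PC scores exceed ``sd_threshold`` SD on the tested
    components (1-based indices, default PCs 1 and 2).

    Variants are mean-centered and scaled to unit variance with missing
    entries set to 0 (the mean) before the decomposition. Component signs
    are canonicalized (largest-magnitude loading positive), which leaves
    the symmetric SD rule unaffected in any case.
    """
    from sklearn.decomposition import PCA

    if gm.n_samples < 3:
        raise ValueError("need at least 3 samples for PCA outlier detection")
    dos = gm.dosages.astype(float)
    mean = np.nanmean(dos, axis=0)
    sd = np.nanstd(dos, axis=0)
    sd[sd == 0] = 1.0
    X = (dos - mean) / sd
    X[np.isnan(X)] = 0.0
    n_comp = min(n_components, gm.n_samples - 1, gm.n_variants)
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(X)
    # canonical sign: largest-|loading| positive
    for c in range(n_comp):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    out = np.zeros(gm.n_samples, dtype=bool)
    for comp in test_components:
        c = comp - 1
        if c >= n_comp:
            continue
        s = scores[:, c]
        lim = sd_threshold * s.std(ddof=0)
        out |= np.abs(s) > lim
    return [sid for sid, o in zip(gm.sample_ids, out) if o]
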