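"""Case-control association scans with additive-dosage logistic regression.

Per variant, the model is ``logit P(case) = b0 + beta * dosage`` with no
covariates; significance is a two-sided Wald test on beta. The fit is a
Newton-Raphson iteration vectorized across variants (the model has two
parameters, so the per-variant Hessian solves in closed form), which is what
makes genome-wide per-cluster scans cheap.

Each scan is scored with the genomic inflation factor
``lambda = median(chi2_quantile(1 - p, df=1)) / 0.4549``; a well-calibrated
null scan has lambda near 1, and lambda < 1.05 is used downstream as the
cluster-validity rule. Non-converged / separated variants are flagged and
excluded from lambda and from significance lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dec import ClusterAssignment
from .genotypes import GenotypeMatrix

#: median of the 1-df chi-square distribution
CHI2_MEDIAN_1DF = float(chi2.ppf(0.5, df=1))

_MAX_ABS_BETA = 12.0  # |log-OR| beyond this is treated as separation

RECORD_COLUMNS = [
    "chrom", "pos", "id", "ref", "alt", "n_case", "n_control",
    "alt_freq", "beta", "se", "or_", "l95", "u95", "p", "converged",
]


@dataclass
class AssociationRecord:
    """Single-variant logistic result (log-odds per ALT allele)."""

    beta: float
    se: float
    p: float
    converged: bool
    n_case: int
    n_control: int
    alt_freq: float

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple:
        return (
            float(np.exp(self.beta - 1.96 * self.se)),
            float(np.exp(self.beta + 1.96 * self.se)),
        )


@dataclass
class ScanResult:
    """One association scan (pooled or one cluster) over all tested variants."""

    label: str
    records: pd.DataFrame  # RECORD_COLUMNS
    lambda_: float
    n_case: int
    n_control: int
    n_skipped_monomorphic: int = 0

    def to_tsv(self, path):
        df = self.records.rename(
            columns={
                "chrom": "CHR", "pos": "POS", "ref": "REF", "alt": "ALT",
                "alt_freq": "ALT_FREQ", "or_": "OR", "l95": "L95", "u95": "U95",
                "p": "P", "n_case": "N_CASE", "n_control": "N_CTRL",
                "converged": "CONVERGED",
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class CgwasResult:
    """Per-cluster scans sharing one control pool."""

    scans: list  # list[ScanResult]
    mean_lambda: float
    significant: pd.DataFrame  # records with p < alpha, plus 'cluster' column
    min_cases: int
    alpha: float
    skipped_clusters: dict = field(default_factory=dict)  # label -> n_case


# ---------------------------------------------------------------------------
# Vectorized Newton fits


def _newton_logistic(D, y, max_iter=25, tol=1e-10):
    """Fit intercept+slope logistic per column of D (NaN = missing).

    Returns (beta, se, converged) arrays. The Newton step solves the 2x2
    system exactly; separation shows up as diverging |beta| or a singular
    Hessian and is flagged rather than raised.
    """
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = D.shape
    M = ~np.isnan(D)
    Dz = np.where(M, D, 0.0)
    yc = y[:, None]

    b0 = np.full(m, 0.0)
    ybar = (yc * M).sum(axis=0) / np.maximum(M.sum(axis=0), 1)
    ybar = np.clip(ybar, 1e-9, 1 - 1e-9)
    b0 = np.log(ybar / (1 - ybar))
    b1 = np.zeros(m)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    singular = np.zeros(m, dtype=bool)
    S0 = S1 = S2 = None
    for _ in range(max_iter):
        eta = b0[None, :] + Dz * b1[None, :]
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.where(M, mu * (1 - mu), 0.0)
        g0 = np.where(M, yc - mu, 0.0).sum(axis=0)
        g1 = (Dz * np.where(M, yc - mu, 0.0)).sum(axis=0)
        S0 = w.sum(axis=0)
        S1 = (w * Dz).sum(axis=0)
        S2 = (w * Dz * Dz).sum(axis=0)
        det = S0 * S2 - S1 * S1
        bad = det <= 1e-12
        singular |= bad & active
        det_safe = np.where(bad, 1.0, det)
        d0 = (S2 * g0 - S1 * g1) / det_safe
        d1 = (S0 * g1 - S1 * g0) / det_safe
        d0 = np.where(active & ~bad, d0, 0.0)
        d1 = np.where(active & ~bad, d1, 0.0)
        # damp huge steps (early iterations near separation)
        step = np.maximum(np.abs(d0), np.abs(d1))
        scale = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-300), 1.0)
        b0 += d0 * scale
        b1 += d1 * scale
        newly = active & (step < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break
    det = S0 * S2 - S1 * S1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, S0 / det, np.nan))
    ok = converged & (np.abs(b1) < _MAX_ABS_BETA) & ~singular & np.isfinite(se)
    return b1, se, ok


def _newton_logistic_counts(R, S, max_iter=25, tol=1e-10):
    """Newton fits from genotype-by-status counts (hard-call fast path).

    ``R[g, j]`` / ``S[g, j]`` = number of cases / controls with dosage g at
    variant j. With dosages in {0,1,2} these six counts are sufficient
    statistics, so each Newton iteration is O(variants) rather than
    O(samples x variants). Same flagging as :func:`_newton_logistic`.
    """
    R = np.asarray(R, dtype=float)
    S = np.asarray(S, dtype=float)
    m = R.shape[1]
    N = R + S  # (3, m) totals per dosage level
    g = np.array([0.0, 1.0, 2.0])[:, None]
    n_called = N.sum(axis=0)
    ybar = np.clip(R.sum(axis=0) / np.maximum(n_called, 1), 1e-9, 1 - 1e-9)
    b0 = np.log(ybar / (1 - ybar))
    b1 = np.zeros(m)
    active = np.ones(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    singular = np.zeros(m, dtype=bool)
    S0 = S1 = S2 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0[None, :] + g * b1[None, :]  # (3, m)
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = N * mu * (1 - mu)
        g0 = (R - N * mu).sum(axis=0)
        g1 = (g * (R - N * mu)).sum(axis=0)
        S0 = w.sum(axis=0)
        S1 = (g * w).sum(axis=0)
        S2 = (g * g * w).sum(axis=0)
        det = S0 * S2 - S1 * S1
        bad = det <= 1e-12
        singular |= bad & active
        det_safe = np.where(bad, 1.0, det)
        d0 = np.where(active & ~bad, (S2 * g0 - S1 * g1) / det_safe, 0.0)
        d1 = np.where(active & ~bad, (S0 * g1 - S1 * g0) / det_safe, 0.0)
        step = np.maximum(np.abs(d0), np.abs(d1))
        scale = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-300), 1.0)
        b0 += d0 * scale
        b1 += d1 * scale
        newly = active & (step < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break
    det = S0 * S2 - S1 * S1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, S0 / det, np.nan))
    ok = converged & (np.abs(b1) < _MAX_ABS_BETA) & ~singular & np.isfinite(se)
    return b1, se, ok


def logistic_additive(dosage, status) -> AssociationRecord:
    """Additive-dosage logistic fit for a single variant.

    ``status`` is 0/1 (control/case). Raises when only one status level is
    present; flags ``converged=False`` (p = NaN) on separation or
    non-convergence instead of raising.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=float)
    if len(np.unique(status)) < 2:
        raise ValueError("both cases and controls are required")
    called = ~np.isnan(dosage)
    if np.nanstd(dosage) == 0:
        raise ValueError("variant is monomorphic in this sample")
    beta, se, ok = _newton_logistic(dosage[:, None], status)
    b, s, good = float(beta[0]), float(se[0]), bool(ok[0])
    z2 = (b / s) ** 2 if good else np.nan
    p = float(chi2.sf(z2, df=1)) if good else np.nan
    return AssociationRecord(
        beta=b,
        se=s,
        p=p,
        converged=good,
        n_case=int(status[called].sum()),
        n_control=int((1 - status[called]).sum()),
        alt_freq=float(np.nanmean(dosage) / 2),
    )


# ---------------------------------------------------------------------------
# Scans


def inflation_factor(pvalues) -> float:
    """Genomic inflation factor from two-sided p-values.

    Converts each p to its 1-df chi-square quantile and divides the median
    by the null median 0.4549. NaN p-values are ignored; an empty input is
    an error.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_MEDIAN_1DF)


def run_scan(
    gm: GenotypeMatrix, case_ids, control_ids, label: str = "pooled", chunk: int = 4096
) -> ScanResult:
    """Logistic scan of all variants polymorphic within the scan sample.

    Variants monomorphic among the scan's called genotypes are skipped (and
    counted); lambda is computed from the converged records' p-values.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise ValueError("case and control id sets must be non-empty")
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control id sets overlap")
    rows = gm.sample_rows(case_ids + control_ids)
    y = np.r_[np.ones(len(case_ids)), np.zeros(len(control_ids))]
    D = gm.dosages[rows].astype(float)
    called = ~np.isnan(D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        colsd = np.nanstd(D, axis=0)
        poly = (called.sum(axis=0) > 0) & (colsd > 0)
    idx = np.flatnonzero(poly)
    n_skipped = int((~poly).sum())

    hard = bool(np.all(D[called] == np.round(D[called])))
    betas = np.empty(idx.size)
    ses = np.empty(idx.size)
    oks = np.empty(idx.size, dtype=bool)
    is_case = (y == 1)[:, None]
    for start in range(0, idx.size, chunk):
        sl = idx[start : start + chunk]
        if hard:
            Dc, Mc = D[:, sl], called[:, sl]
            R = np.stack([((Dc == g) & Mc & is_case).sum(axis=0) for g in (0, 1, 2)])
            Sc = np.stack([((Dc == g) & Mc & ~is_case).sum(axis=0) for g in (0, 1, 2)])
            b, s, ok = _newton_logistic_counts(R, Sc)
        else:
            b, s, ok = _newton_logistic(D[:, sl], y)
        betas[start : start + chunk] = b
        ses[start : start + chunk] = s
        oks[start : start + chunk] = ok

    with np.errstate(invalid="ignore", divide="ignore"):
        z2 = (betas / ses) ** 2
        p = np.where(oks, chi2.sf(z2, df=1), np.nan)
    # 0-underflow guard: smallest positive double keeps p in (0,1]
    p = np.where(oks & (p == 0), 5e-324, p)
    ncall_case = called[: len(case_ids)][:, idx].sum(axis=0)
    ncall_ctrl = called[len(case_ids) :][:, idx].sum(axis=0)
    alt_freq = np.nanmean(D[:, idx], axis=0) / 2
    v = gm.variants.iloc[idx].reset_index(drop=True)
    with np.errstate(over="ignore"):
        or_ = np.exp(betas)
        l95 = np.exp(betas - 1.96 * ses)
        u95 = np.exp(betas + 1.96 * ses)
    records = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "pos": v["pos"],
            "id": v["id"],
            "ref": v["ref"],
            "alt": v["alt"],
            "n_case": ncall_case,
            "n_control": ncall_ctrl,
            "alt_freq": alt_freq,
            "beta": betas,
            "se": ses,
            "or_": or_,
            "l95": l95,
            "u95": u95,
            "p": p,
            "converged": oks,
        },
        columns=RECORD_COLUMNS,
    )
    lam = inflation_factor(p[oks]) if oks.any() else np.nan
    return ScanResult(
        label=label,
        records=records,
        lambda_=lam,
        n_case=len(case_ids),
        n_control=len(control_ids),
        n_skipped_monomorphic=n_skipped,
    )


def run_cgwas(
    gm: GenotypeMatrix,
    assignment: ClusterAssignment,
    control_ids,
    min_cases: int = 10,
    alpha: float = 5e-8,
) -> CgwasResult:
    """One scan per non-empty cluster with at least ``min_cases`` cases,
    all against the shared control pool.

    ``min_cases`` defaults to 10, i.e. the "more than nine cases" reporting
    rule applied as an eligibility rule. Significant records across scans
    are pooled with their cluster labels.
    """
    members = assignment.members()
    scans, skipped = [], {}
    for lab in sorted(members):
        ids = members[lab]
        if len(ids) < min_cases:
            skipped[str(lab)] = len(ids)
            continue
        scans.append(run_scan(gm, ids, control_ids, label=f"cluster{lab}"))
    if not scans:
        warnings.warn("no cluster reached the minimum case count; empty cGWAS result")
        sig = pd.DataFrame(columns=["cluster"] + RECORD_COLUMNS)
        return CgwasResult([], np.nan, sig, min_cases, alpha, skipped)
    lambdas = [s.lambda_ for s in scans if np.isfinite(s.lambda_)]
    mean_lambda = float(np.mean(lambdas)) if lambdas else np.nan
    sig_parts = []
    for s in scans:
        hit = s.records[(s.records["p"] < alpha) & s.records["converged"]].copy()
        if len(hit):
            hit.insert(0, "cluster", s.label)
            sig_parts.append(hit)
    sig = (
        pd.concat(sig_parts, ignore_index=True)
        if sig_parts
        else pd.DataFrame(columns=["cluster"] + RECORD_COLUMNS)
    )
    return CgwasResult(scans, mean_lambda, sig, min_cases, alpha, skipped)
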