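"""Post-processing of association scans: LD clumping, gene annotation,
cluster phenotype profiles, and Manhattan/QQ reports.

Clumping is the PLINK-style greedy procedure: the unassigned significant
record with the smallest p becomes an index SNP and absorbs the remaining
significant records on the same chromosome within a physical window whose
dosage correlation with the index reaches the r^2 bound. Annotation is a
containment / nearest-flank lookup against a user-supplied BED gene model
(half-open 0-based on disk, 1-based closed internally).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import CgwasResult, ScanResult, inflation_factor
from .features import ID_COLUMN
from .genotypes import GenotypeMatrix

INTERGENIC_SENTINEL = "NA"


# ---------------------------------------------------------------------------
# LD


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Computed over jointly-called samples; monomorphic input returns NaN.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class ClumpedLocus:
    """A clumped locus: the lowest-p index record plus absorbed members."""

    index_record: pd.Series
    member_keys: list  # variant keys incl. the index
    cluster_label: str


def clump(
    scan: ScanResult,
    gm: GenotypeMatrix,
    p1: float = 5e-8,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> list:
    """Greedy LD clumping of a scan's significant records.

    Candidates are converged records with p < p1. Repeatedly take the
    smallest-p unassigned candidate as an index (ties broken by (chrom,
    pos)) and absorb unassigned candidates on the same chromosome within
    ``window_kb`` of it whose r^2 with the index is >= ``r2_threshold``.
    Every candidate ends up in exactly one locus.
    """
    rec = scan.records
    cand = rec[(rec["p"] < p1) & rec["converged"]].copy()
    if cand.empty:
        return []
    key_to_col = {k: j for j, k in enumerate(gm.variant_keys())}
    cand["key"] = (
        cand["chrom"].astype(str) + ":" + cand["pos"].astype(str) + ":" + cand["alt"]
    )
    missing = [k for k in cand["key"] if k not in key_to_col]
    if missing:
        raise KeyError(f"scan records not present in genotype matrix: {missing[:3]}")
    cand = cand.sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    unassigned = np.ones(len(cand), dtype=bool)
    loci = []
    window = window_kb * 1000.0
    for i in range(len(cand)):
        if not unassigned[i]:
            continue
        idx_row = cand.iloc[i]
        unassigned[i] = False
        members = [idx_row["key"]]
        a = gm.dosages[:, key_to_col[idx_row["key"]]]
        for j in range(len(cand)):
            if not unassigned[j]:
                continue
            row = cand.iloc[j]
            if row["chrom"] != idx_row["chrom"]:
                continue
            if abs(row["pos"] - idx_row["pos"]) > window:
                continue
            r2 = ld_r2(a, gm.dosages[:, key_to_col[row["key"]]])
            if np.isfinite(r2) and r2 >= r2_threshold:
                unassigned[j] = False
                members.append(row["key"])
        loci.append(ClumpedLocus(idx_row, members, scan.label))
    return loci


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass
class GeneAnnotation:
    function: str  # interval class, or "intergenic"
    gene_symbol: str  # containing gene, or "left, right" flanks


def read_gene_model(path) -> dict:
    """BED (0-based half-open) -> per-chromosome sorted interval table.

    Columns: chrom, start, end, symbol, and optionally a class label
    (e.g. intronic / ncRNA_intronic) in the fifth column; absent classes
    default to "intronic". Internally intervals become 1-based closed.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("gene model BED needs at least 4 columns (chrom start end symbol)")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "symbol"})
    df["klass"] = df[4] if df.shape[1] > 4 else "intronic"
    df["start1"] = df["start"].astype(int) + 1  # to 1-based closed
    df["end1"] = df["end"].astype(int)
    out = {}
    for chrom, grp in df.groupby(df["chrom"].astype(str)):
        g = grp.sort_values(["start1", "end1"]).reset_index(drop=True)
        out[chrom] = g[["start1", "end1", "symbol", "klass"]]
    return out


def annotate(chrom, pos, gene_model: dict) -> GeneAnnotation:
    """Containment / nearest-flank annotation of one position."""
    chrom = str(chrom)
    pos = int(pos)
    tab = gene_model.get(chrom)
    if tab is None or tab.empty:
        return GeneAnnotation("intergenic", INTERGENIC_SENTINEL)
    inside = tab[(tab["start1"] <= pos) & (pos <= tab["end1"])]
    if len(inside):
        hit = inside.iloc[0]
        return GeneAnnotation(str(hit["klass"]), str(hit["symbol"]))
    left = tab[tab["end1"] < pos]
    right = tab[tab["start1"] > pos]
    lsym = (
        str(left.loc[left["end1"].idxmax(), "symbol"]) if len(left) else INTERGENIC_SENTINEL
    )
    rsym = (
        str(right.loc[right["start1"].idxmin(), "symbol"])
        if len(right)
        else INTERGENIC_SENTINEL
    )
    return GeneAnnotation("intergenic", f"{lsym}, {rsym}")


# ---------------------------------------------------------------------------
# Cluster profile (per-cluster phenotype summary)


def cluster_profile(assignment, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster n, numeric means and categorical level percentages.

    ``assignment`` may be a ClusterAssignment (with sample ids) or a mapping
    sample_id -> label. Rows are non-empty clusters; columns are ``n``,
    ``<numeric> mean``, and ``<categorical>=<level> %``.
    """
    if hasattr(assignment, "members"):
        label_of = {
            sid: lab for lab, ids in assignment.members().items() for sid in ids
        }
    else:
        label_of = dict(assignment)
    missing = [s for s in phenotypes[ID_COLUMN] if s not in label_of]
    if missing:
        raise KeyError(f"no cluster label for sample(s) {missing[:3]}")
    df = phenotypes.copy()
    df["_cluster"] = [label_of[s] for s in df[ID_COLUMN]]
    from .features import split_columns

    num_cols, cat_cols = split_columns(phenotypes)
    rows = []
    for lab, grp in df.groupby("_cluster"):
        row = {"cluster": lab, "n": len(grp)}
        for c in num_cols:
            row[f"{c} mean"] = grp[c].mean()
        for c in cat_cols:
            obs = grp[c].dropna()
            for lv in sorted(map(str, df[c].dropna().unique())):
                row[f"{c}={lv} %"] = (
                    100.0 * (obs.astype(str) == lv).mean() if len(obs) else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Reports


def _manhattan(ax, records: pd.DataFrame, title: str):
    colors = ["#30508c", "#92a8d1"]
    offset = 0
    ticks, labels = [], []
    logp = -np.log10(records["p"].astype(float))
    for i, chrom in enumerate(sorted(records["chrom"].unique(), key=lambda c: (len(c), c))):
        sel = records["chrom"] == chrom
        x = records.loc[sel, "pos"].astype(float) + offset
        ax.scatter(x, logp[sel], s=4, color=colors[i % 2], rasterized=True)
        ticks.append(x.mean())
        labels.append(chrom)
        offset = x.max() + 1
    ax.axhline(-np.log10(5e-8), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)


def _qq(ax, pvals, title: str):
    p = np.sort(np.asarray(pvals, dtype=float))
    p = p[~np.isnan(p)]
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    obs = -np.log10(p)
    ax.scatter(exp, obs, s=4, color="#30508c", rasterized=True)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    lam = inflation_factor(p)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.set_title(f"{title}  $\\lambda$ = {lam:.3f}")
    return lam


def render_reports(
    cgwas_result: CgwasResult,
    pooled: ScanResult,
    outdir,
    gm: GenotypeMatrix = None,
    gene_model: dict = None,
    phenotypes: pd.DataFrame = None,
    assignment=None,
    clump_kwargs: dict = None,
) -> dict:
    """Write Manhattan/QQ plots per scan, the significant-locus table and
    the cluster phenotype profile under ``outdir``. Returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    scans = ([pooled] if pooled is not None else []) + list(cgwas_result.scans)
    for scan in scans:
        rec = scan.records[scan.records["converged"]]
        if rec.empty:
            continue
        fig, axes = plt.subplots(1, 2, figsize=(11, 3.2))
        _manhattan(axes[0], rec, scan.label)
        _qq(axes[1], rec["p"], scan.label)
        fig.tight_layout()
        path = outdir / f"scan_{scan.label}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written[f"plot_{scan.label}"] = path

    # significant loci table (clumped when genotypes are available)
    sig_rows = []
    if gm is not None:
        for scan in cgwas_result.scans:
            for locus in clump(scan, gm, p1=cgwas_result.alpha, **(clump_kwargs or {})):
                row = locus.index_record.drop(labels=["key"], errors="ignore").to_dict()
                row["cluster"] = locus.cluster_label
                row["n_members"] = len(locus.member_keys)
                if gene_model is not None:
                    ann = annotate(row["chrom"], row["pos"], gene_model)
                    row["function"] = ann.function
                    row["gene_symbol"] = ann.gene_symbol
                sig_rows.append(row)
    else:
        sig_rows = cgwas_result.significant.to_dict("records")
    cols = ["cluster", "chrom", "pos", "ref", "alt", "alt_freq", "or_", "l95", "u95", "p"]
    if gene_model is not None:
        cols += ["function", "gene_symbol"]
    sig = pd.DataFrame(sig_rows)
    sig = sig.reindex(columns=[c for c in cols if sig.empty or c in sig.columns] or cols)
    if sig.empty:
        sig = pd.DataFrame(columns=cols)
    sig_path = outdir / "significant_loci.tsv"
    sig.to_csv(sig_path, sep="\t", index=False)
    written["significant_loci"] = sig_path

    if phenotypes is not None and assignment is not None:
        prof = cluster_profile(assignment, phenotypes)
        prof_path = outdir / "cluster_profile.tsv"
        prof.to_csv(prof_path, sep="\t")
        written["cluster_profile"] = prof_path
        fig, ax = plt.subplots(
            figsize=(max(4, 0.25 * len(prof)), max(3, 0.18 * len(prof.columns)))
        )
        num = prof.drop(columns=["n"]).astype(float)
        z = (num - num.mean()) / num.std(ddof=0).replace(0, 1)
        im = ax.imshow(z.T, aspect="auto", cmap="coolwarm", vmin=-2.5, vmax=2.5)
        ax.set_xticks(range(len(prof)), prof.index, fontsize=5)
        ax.set_yticks(range(len(num.columns)), num.columns, fontsize=4)
        fig.colorbar(im, ax=ax, label="z (across clusters)")
        fig.tight_layout()
        heat_path = outdir / "cluster_profile_heatmap.png"
        fig.savefig(heat_path, dpi=120)
        plt.close(fig)
        written["cluster_profile_heatmap"] = heat_path
    return written
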