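"""Genotype container and file I/O (VCF v4.2 and PLINK text).

Dosages are expected ALT-allele counts per individual, stored as float32 in
[0, 2] with NaN marking missing calls. Coordinates are 1-based (VCF
convention) on autosomes. Multi-allelic VCF records are skipped with a
warning: the downstream association model is defined for biallelic sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.nan

#: columns of the per-variant metadata table
VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with variant metadata.

    Attributes
    ----------
    sample_ids : list[str]
        Row labels, unique.
    variants : pandas.DataFrame
        One row per variant with columns ``chrom`` (str, "1".."22"),
        ``pos`` (int, 1-based), ``id``, ``ref``, ``alt``.
    dosages : numpy.ndarray
        float32 array of shape (n_samples, n_variants); NaN = missing.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    _sample_index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_rows(self, ids) -> np.ndarray:
        """Row indices for the given sample ids; unknown ids raise KeyError."""
        try:
            return np.array([self._sample_index[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def subset_samples(self, ids) -> "GenotypeMatrix":
        rows = self.sample_rows(ids)
        return GenotypeMatrix(list(ids), self.variants.copy(), self.dosages[rows])

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def variant_keys(self) -> pd.Index:
        v = self.variants
        return pd.Index(
            v["chrom"].astype(str) + ":" + v["pos"].astype(str) + ":" + v["alt"]
        )


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a VCF v4.2 file.

    Integral dosages are written as GT hard calls; if any dosage is
    fractional the FORMAT becomes GT:DS with DS rounded to 3 decimals
    (GT is the nearest hard call).
    """
    dos = gm.dosages
    called = ~np.isnan(dos)
    fractional = bool(np.any(dos[called] != np.round(dos[called])))
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if fractional:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,'
                'Description="Estimated ALT allele dosage">\n'
            )
        for chrom in dict.fromkeys(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        fmt = "GT:DS" if fractional else "GT"
        for j, var in gm.variants.iterrows():
            col = dos[:, j]
            fields = []
            for d in col:
                if np.isnan(d):
                    fields.append("./.:." if fractional else "./.")
                elif fractional:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:.3f}")
                else:
                    fields.append(gt_codes[int(d)])
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t{var['id']}\t{var['ref']}\t"
                f"{var['alt']}\t.\t.\t.\t{fmt}\t" + "\t".join(fields) + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    has_ds = "DS" in vcf.raw_header
    meta, cols = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ds = var.format("DS") if has_ds else None
        if ds is not None:
            col = np.asarray(ds, dtype=np.float32).reshape(-1)
            col = col.copy()
            col[col < 0] = MISSING  # cyvcf2 missing sentinel is negative
        else:
            col = np.empty(len(samples), dtype=np.float32)
            for i, g in enumerate(var.genotypes):
                alleles = g[:-1]
                col[i] = MISSING if -1 in alleles else float(sum(alleles))
        meta.append(
            (str(var.CHROM), int(var.POS), var.ID or ".", var.REF, var.ALT[0])
        )
        cols.append(col)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic VCF record(s)")
    variants = pd.DataFrame(meta, columns=VARIANT_COLUMNS)
    dosages = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), np.float32)
    )
    return GenotypeMatrix(samples, variants, dosages)


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map) — no reader for this format ships with the
# environment's libraries, so it is parsed directly.


def _read_plink_text(prefix) -> GenotypeMatrix:
    prefix = str(prefix)
    if prefix.endswith(".ped"):
        prefix = prefix[:-4]
    map_path, ped_path = Path(prefix + ".map"), Path(prefix + ".ped")
    meta = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, vid, _cm, pos = parts[:4]
            meta.append((chrom, int(pos), vid))
    n_var = len(meta)
    sample_ids, rows = [], []
    alleles_seen: list[dict] = [dict() for _ in range(n_var)]
    with open(ped_path) as fh:
        ped_lines = []
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_var} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            ped_lines.append(parts[6:])
            for j in range(n_var):
                for a in parts[6 + 2 * j : 8 + 2 * j]:
                    if a != "0":
                        alleles_seen[j][a] = alleles_seen[j].get(a, 0) + 1
    # REF = major allele, ALT = minor; dosage counts ALT alleles
    refs, alts = [], []
    for j in range(n_var):
        order = sorted(alleles_seen[j], key=lambda a: (-alleles_seen[j][a], a))
        refs.append(order[0] if order else "0")
        alts.append(order[1] if len(order) > 1 else ".")
    dosages = np.empty((len(sample_ids), n_var), dtype=np.float32)
    for i, geno in enumerate(ped_lines):
        for j in range(n_var):
            a1, a2 = geno[2 * j], geno[2 * j + 1]
            if a1 == "0" or a2 == "0":
                dosages[i, j] = MISSING
            else:
                dosages[i, j] = (a1 == alts[j]) + (a2 == alts[j])
    variants = pd.DataFrame(
        {
            "chrom": [m[0] for m in meta],
            "pos": [m[1] for m in meta],
            "id": [m[2] for m in meta],
            "ref": refs,
            "alt": alts,
        }
    )
    return GenotypeMatrix(sample_ids, variants, dosages)


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from ``vcf`` or ``plink-text`` (.ped/.map prefix)."""
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink-text":
        return _read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")
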