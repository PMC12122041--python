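"""Postprocessing: LD r^2, clumping vs a brute-force oracle, annotation,
cluster profiles and report files."""

import numpy as np
import pandas as pd
import pytest

from cgwas.assoc import RECORD_COLUMNS, CgwasResult, ScanResult, run_scan
from cgwas.genotypes import GenotypeMatrix
from cgwas.postprocess import (
    annotate,
    clump,
    cluster_profile,
    ld_r2,
    read_gene_model,
    render_reports,
)
from cgwas.simulate import SimConfig, _variant_table, simulate_cohort, simulate_genotypes


class TestLdR2:
    def test_identical_vectors(self):
        a = np.array([0, 1, 2, 1, 0], float)
        assert ld_r2(a, a) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.3, 5000).astype(float)
        b = rng.binomial(2, 0.3, 5000).astype(float)
        assert ld_r2(a, b) <= 0.01

    def test_symmetry(self, rng):
        a = rng.binomial(2, 0.2, 100).astype(float)
        b = rng.binomial(2, 0.4, 100).astype(float)
        assert ld_r2(a, b) == ld_r2(b, a)

    def test_monomorphic_undefined(self):
        assert np.isnan(ld_r2([0, 0, 0], [0, 1, 2]))


def _scan_from(gm, pvals, label="cluster0"):
    v = gm.variants
    n = len(pvals)
    rec = pd.DataFrame(
        {
            "chrom": v["chrom"][:n].to_numpy(),
            "pos": v["pos"][:n].to_numpy(),
            "id": v["id"][:n].to_numpy(),
            "ref": "A",
            "alt": "G",
            "n_case": 10,
            "n_control": 10,
            "alt_freq": 0.2,
            "beta": 0.0,
            "se": 1.0,
            "or_": 1.0,
            "l95": 0.5,
            "u95": 2.0,
            "p": pvals,
            "converged": True,
        },
        columns=RECORD_COLUMNS,
    )
    return ScanResult(label, rec, 1.0, 10, 10)


def clump_oracle(records, r2_fn, p1, r2_thr, window):
    """Brute-force greedy clumping over explicit candidate lists."""
    cand = [r for r in records if r["p"] < p1]
    cand.sort(key=lambda r: (r["p"], r["chrom"], r["pos"]))
    taken = set()
    loci = []
    for i, idx in enumerate(cand):
        if i in taken:
            continue
        taken.add(i)
        members = [idx["id"]]
        for j, other in enumerate(cand):
            if j in taken:
                continue
            if other["chrom"] != idx["chrom"]:
                continue
            if abs(other["pos"] - idx["pos"]) > window:
                continue
            if r2_fn(idx["id"], other["id"]) >= r2_thr:
                taken.add(j)
                members.append(other["id"])
        loci.append((idx["id"], sorted(members)))
    return loci


class TestClump:
    def _correlated_gm(self, seed=0, n=400, m=12):
        """Variants with planted LD blocks: pairs (2i, 2i+1) are copies with
        a little noise; blocks are independent."""
        rng = np.random.default_rng(seed)
        base = rng.binomial(2, 0.3, size=(n, m // 2)).astype(np.float32)
        cols = []
        for j in range(m // 2):
            cols.append(base[:, j])
            noisy = base[:, j].copy()
            flip = rng.random(n) < 0.05
            noisy[flip] = rng.binomial(2, 0.3, flip.sum())
            cols.append(noisy)
        dos = np.column_stack(cols)
        variants = _variant_table(m)
        # put everything on one chromosome with tight spacing
        variants["chrom"] = "1"
        variants["pos"] = np.arange(1, m + 1) * 10_000
        return GenotypeMatrix([f"s{i}" for i in range(n)], variants, dos)

    def test_linked_pair_forms_single_locus(self):
        gm = self._correlated_gm()
        pvals = np.full(12, 0.5)
        pvals[0], pvals[1] = 1e-10, 1e-9  # linked pair
        pvals[4] = 1e-4  # not below p1
        scan = _scan_from(gm, pvals)
        loci = clump(scan, gm, p1=5e-8, r2_threshold=0.1, window_kb=250)
        assert len(loci) == 1
        assert loci[0].index_record["id"] == "var000000"
        assert sorted(loci[0].member_keys) == ["1:10000:G", "1:20000:G"]

    def test_no_significant_records_empty(self):
        gm = self._correlated_gm()
        scan = _scan_from(gm, np.full(12, 0.5))
        assert clump(scan, gm) == []

    def test_single_significant_is_singleton_locus(self):
        gm = self._correlated_gm()
        pvals = np.full(12, 0.5)
        pvals[6] = 1e-12
        loci = clump(_scan_from(gm, pvals), gm)
        assert len(loci) == 1
        assert loci[0].member_keys == ["1:70000:G"]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        gm = self._correlated_gm(seed=seed, m=12)
        rng = np.random.default_rng(seed + 100)
        pvals = 10.0 ** (-rng.uniform(2, 14, size=12))
        scan = _scan_from(gm, pvals)
        loci = clump(scan, gm, p1=1e-6, r2_threshold=0.1, window_kb=30)
        id_of = {k: i for i, k in enumerate(gm.variant_keys())}

        def r2_fn(id_a, id_b):
            ja = gm.variants.index[gm.variants["id"] == id_a][0]
            jb = gm.variants.index[gm.variants["id"] == id_b][0]
            return ld_r2(gm.dosages[:, ja], gm.dosages[:, jb])

        records = scan.records.to_dict("records")
        expected = clump_oracle(records, r2_fn, 1e-6, 0.1, 30_000)
        got = [
            (l.index_record["id"],
             sorted(gm.variants.loc[[id_of[k] for k in l.member_keys], "id"]))
            for l in loci
        ]
        assert got == expected

    def test_partition_property(self):
        gm = self._correlated_gm(seed=5)
        rng = np.random.default_rng(9)
        pvals = 10.0 ** (-rng.uniform(6, 14, size=12))
        loci = clump(_scan_from(gm, pvals), gm, p1=1e-5)
        all_members = [k for l in loci for k in l.member_keys]
        assert len(all_members) == len(set(all_members)) == 12


class TestAnnotate:
    @pytest.fixture()
    def model(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text(
            "1\t100\t200\tGENE_A\tintronic\n"
            "1\t500\t800\tGENE_B\tncRNA_intronic\n"
            "2\t10\t50\tGENE_C\tintronic\n"
        )
        return read_gene_model(bed)

    def test_containment(self, model):
        ann = annotate("1", 150, model)
        assert (ann.function, ann.gene_symbol) == ("intronic", "GENE_A")

    def test_class_passthrough(self, model):
        assert annotate("1", 600, model).function == "ncRNA_intronic"

    def test_intergenic_flanks(self, model):
        ann = annotate("1", 300, model)
        assert ann.function == "intergenic"
        assert ann.gene_symbol == "GENE_A, GENE_B"

    def test_chromosome_without_genes(self, model):
        ann = annotate("7", 100, model)
        assert ann.function == "intergenic"
        assert ann.gene_symbol == "NA"

    def test_bed_halfopen_convention(self, model):
        # BED 100..200 covers 1-based positions 101..200
        assert annotate("1", 100, model).function == "intergenic"
        assert annotate("1", 101, model).function == "intronic"
        assert annotate("1", 200, model).function == "intronic"
        assert annotate("1", 201, model).function == "intergenic"


class TestClusterProfile:
    def test_hand_computed_means_and_percentages(self):
        pheno = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "score": [7.0, 7.0, 7.0, 1.0, 2.0, 3.0],
                "hand": ["L", "L", "R", "R", "R", None],
            }
        )
        labels = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        prof = cluster_profile(labels, pheno)
        assert prof.loc[0, "n"] == 3
        assert prof.loc[0, "score mean"] == pytest.approx(7.0)
        assert prof.loc[1, "score mean"] == pytest.approx(2.0)
        assert prof.loc[0, "hand=L %"] == pytest.approx(100 * 2 / 3)
        assert prof.loc[1, "hand=R %"] == pytest.approx(100.0)

    def test_n_column_partitions_cases(self, small_cohort):
        _cfg, _gm, pheno, truth = small_cohort
        labels = dict(zip(truth.case_ids, truth.subgroup_labels))
        prof = cluster_profile(labels, pheno)
        assert prof["n"].sum() == len(pheno)


class TestRenderReports:
    def test_report_files_and_empty_significant_tsv(self, small_cohort, tmp_path):
        _cfg, gm, pheno, truth = small_cohort
        pooled = run_scan(gm, truth.case_ids, truth.control_ids)
        cg = CgwasResult(
            scans=[run_scan(gm, truth.case_ids[:50], truth.control_ids, label="cluster0")],
            mean_lambda=1.0,
            significant=pd.DataFrame(columns=["cluster"] + RECORD_COLUMNS),
            min_cases=10,
            alpha=5e-8,
        )
        labels = {s: 0 for s in truth.case_ids[:50]}
        labels.update({s: 1 for s in truth.case_ids[50:]})
        written = render_reports(
            cg, pooled, tmp_path, gm=gm, phenotypes=pheno, assignment=labels
        )
        assert written["significant_loci"].exists()
        sig = pd.read_csv(written["significant_loci"], sep="\t")
        assert len(sig) == 0 and len(sig.columns) > 0
        assert (tmp_path / "scan_pooled.png").exists()
        assert (tmp_path / "scan_cluster0.png").exists()
        assert (tmp_path / "cluster_profile.tsv").exists()
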