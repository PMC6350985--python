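"""DEG calling, gene neighborhoods, binding-region assignment, the 7-group
and conserved-set classifications, and ddCt fold changes."""

import numpy as np
import pandas as pd
import pytest

from glibind import (
    assign_regions,
    bin_deg_by_binding,
    bin_deg_by_conservation,
    build_neighborhoods,
    call_deg,
    ddct_fold_change,
)
from glibind.expression import BINDING_GROUP_LETTERS, Gene, GeneRecord
from glibind.regions import Region
from glibind.simulate import simulate_expression


def genes_on_chrom(n, chrom="c", pitch=1_000, body=400):
    out = []
    for i in range(n):
        start = i * pitch + (pitch - body) // 2
        out.append(Gene(f"g{i}", chrom, start, start + body))
    return out


def record(gene, status="up", log2fc=1.0):
    return GeneRecord(gene.gene_id, gene.chrom, gene.start, gene.end, gene.strand,
                      log2fc, 0.001, status)


class TestCallDeg:
    def test_planted_twofold_effect_called_up(self):
        genes = [Gene("bmp2_like", "c", 0, 100)]
        table = simulate_expression(genes, {"bmp2_like": np.log2(2.2)}, 4, 0.05, seed=1)
        (rec,) = call_deg(table, 1.5, 0.05)
        assert rec.deg_status == "up"
        assert rec.log2fc == pytest.approx(np.log2(2.2), abs=0.1)

    def test_null_gene_not_flagged(self):
        genes = [Gene("flat", "c", 0, 100)]
        table = simulate_expression(genes, {}, 4, 0.25, seed=2)
        (rec,) = call_deg(table)
        assert rec.deg_status == "none"

    def test_cross_implementation_agreement(self, rng):
        """Flags match an independent Welch-test implementation."""
        from statsmodels.stats.weightstats import ttest_ind

        genes = genes_on_chrom(50)
        truth = {f"g{i}": float(rng.normal(0, 1.2)) for i in range(50)}
        table = simulate_expression(genes, truth, 4, 0.4, seed=3)
        records = call_deg(table, 1.5, 0.05)
        for rec, row in zip(records, table.itertuples(index=False)):
            trt = [getattr(row, f"treated_{i}") for i in range(1, 5)]
            ctrl = [getattr(row, f"control_{i}") for i in range(1, 5)]
            _, p, _ = ttest_ind(trt, ctrl, usevar="unequal")
            lfc = np.mean(trt) - np.mean(ctrl)
            if p < 0.05 and lfc >= np.log2(1.5):
                expected = "up"
            elif p < 0.05 and lfc <= -np.log2(1.5):
                expected = "down"
            else:
                expected = "none"
            assert rec.deg_status == expected
            assert rec.p_value == pytest.approx(p, abs=1e-9)

    def test_degenerate_thresholds_label_every_gene(self):
        genes = genes_on_chrom(30)
        table = simulate_expression(genes, {}, 3, 0.3, seed=4)
        records = call_deg(table, fc_threshold=1.0, alpha=1.0)
        assert all(r.deg_status in ("up", "down") for r in records)

    def test_single_replicate_rejected(self):
        table = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["c"], "start": [0], "end": [10],
             "strand": ["+"], "control_1": [8.0], "treated_1": [9.0]}
        )
        with pytest.raises(ValueError):
            call_deg(table)


class TestNeighborhoods:
    def test_three_gene_construction(self):
        genes = [Gene("A", "c", 100, 200), Gene("B", "c", 500, 600), Gene("C", "c", 900, 1_000)]
        spans = {n.gene_id: (n.start, n.end) for n in build_neighborhoods(genes, {"c": 5_000})}
        assert spans["B"] == (200, 900)
        assert spans["A"] == (0, 500)
        assert spans["C"] == (600, 5_000)

    def test_single_gene_spans_whole_chromosome(self):
        (nb,) = build_neighborhoods([Gene("solo", "c", 2_000, 2_400)], {"c": 5_000})
        assert (nb.start, nb.end) == (0, 5_000)

    def test_two_neighbors_per_side(self):
        genes = [Gene(x, "c", i * 1_000, i * 1_000 + 100) for i, x in enumerate("ABCDE")]
        spans = {n.gene_id: (n.start, n.end) for n in
                 build_neighborhoods(genes, {"c": 10_000}, neighbors_per_side=2)}
        assert spans["C"] == (100, 4_000)

    def test_spans_contain_body_even_for_overlapping_genes(self):
        genes = [Gene("A", "c", 100, 900), Gene("B", "c", 500, 1_500)]
        for nb, gene in zip(build_neighborhoods(genes, {"c": 5_000}), genes):
            match = next(g for g in genes if g.gene_id == nb.gene_id)
            assert nb.start <= match.start and nb.end >= match.end

    def test_no_orphaned_intergenic_gaps(self):
        genes = genes_on_chrom(10)
        nbs = build_neighborhoods(genes, {"c": 10_000})
        covered = np.zeros(10_000, dtype=bool)
        for nb in nbs:
            covered[nb.start : nb.end] = True
        first = min(g.start for g in genes)
        last = max(g.end for g in genes)
        assert covered[first:last].all()


class TestAssignRegions:
    def test_region_in_gene_body_labels_that_gene(self):
        genes = genes_on_chrom(3)
        nbs = build_neighborhoods(genes, {"c": 3_000})
        labels = assign_regions({"G1": [Region("c", 1_400, 1_500)]}, nbs)
        assert labels == {"g1": {"G1"}}

    def test_intergenic_region_labels_both_flanking_genes(self):
        genes = genes_on_chrom(3)
        nbs = build_neighborhoods(genes, {"c": 3_000})
        # gap between gene 0 body ([300,700)) and gene 1 body ([1300,1700))
        labels = assign_regions({"G2": [Region("c", 900, 1_000)]}, nbs)
        assert labels == {"g0": {"G2"}, "g1": {"G2"}}

    def test_matches_brute_force_all_pairs(self, rng):
        genes = genes_on_chrom(30)
        nbs = build_neighborhoods(genes, {"c": 30_000})
        classes = {
            label: [Region("c", int(s), int(s) + 200)
                    for s in rng.integers(0, 29_800, size=25)]
            for label in ("G1", "G2", "GIS")
        }
        labels = assign_regions(classes, nbs)
        expected = {}
        for label, regions in classes.items():
            for nb in nbs:
                if any(r.start < nb.end and r.end > nb.start for r in regions):
                    expected.setdefault(nb.gene_id, set()).add(label)
        assert labels == expected


class TestBindingGroups:
    def test_singleton_and_full_vectors(self):
        genes = genes_on_chrom(2)
        records = [record(genes[0]), record(genes[1])]
        labels = {"g0": {"G1"}, "g1": {"G1", "G2", "GIS"}}
        groups = bin_deg_by_binding(records, labels)
        assert [r.gene_id for r in groups["a"]] == ["g0"]
        assert [r.gene_id for r in groups["g"]] == ["g1"]

    def test_letter_map_covers_all_seven_subsets(self):
        assert sorted(BINDING_GROUP_LETTERS.values()) == list("abcdefg")

    def test_count_conservation(self, rng):
        genes = genes_on_chrom(40)
        statuses = ["up", "down", "none"]
        records = [record(g, status=statuses[i % 3]) for i, g in enumerate(genes)]
        labels = {}
        for g in genes[:30]:
            k = int(rng.integers(1, 8))
            subset = [s for s, bit in zip(("G1", "G2", "GIS"), f"{k:03b}") if bit == "1"]
            labels[g.gene_id] = set(subset)
        groups = bin_deg_by_binding(records, labels)
        expected = sum(
            1 for r in records if r.deg_status != "none" and labels.get(r.gene_id)
        )
        assert sum(len(v) for v in groups.values()) == expected


class TestConservationSets:
    def test_mouse_gli1_only_gene(self):
        g = Gene("m1only", "c", 0, 100)
        sets = bin_deg_by_conservation(
            [record(g)], {"m1only": {"hG1": False, "hG2": False, "mG1": True, "mG3": False}}
        )
        assert [r.gene_id for r in sets["b'"]] == ["m1only"]

    def test_smad7_like_pattern_is_common_target(self):
        g = Gene("smad7_like", "c", 0, 100)
        sets = bin_deg_by_conservation(
            [record(g)], {"smad7_like": {"hG1": True, "hG2": True, "mG1": False, "mG3": True}}
        )
        assert [r.gene_id for r in sets["d'"]] == ["smad7_like"]

    def test_count_conservation(self, rng):
        genes = genes_on_chrom(30)
        records = [record(g) for g in genes]
        flags = {}
        for g in genes:
            vec = {k: bool(rng.integers(0, 2)) for k in ("hG1", "hG2", "mG1", "mG3")}
            flags[g.gene_id] = vec
        sets = bin_deg_by_conservation(records, flags)
        expected = sum(1 for g in genes if any(flags[g.gene_id].values()))
        assert sum(len(v) for v in sets.values()) == expected


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])

    def test_identical_conditions_give_fold_one(self):
        rows = []
        for sample, cond in (("s1", "carrier"), ("s2", "treated")):
            rows += [(sample, cond, "TGT", 24.0), (sample, cond, "ACTB", 18.0),
                     (sample, cond, "GAPDH", 20.0)]
        folds = ddct_fold_change(self._table(rows), "TGT", ["ACTB", "GAPDH"])
        assert folds["s2"] == pytest.approx(1.0)

    def test_minus_one_ddct_doubles(self):
        rows = [("s1", "carrier", "TGT", 24.0), ("s1", "carrier", "ACTB", 18.0),
                ("s2", "treated", "TGT", 23.0), ("s2", "treated", "ACTB", 18.0)]
        folds = ddct_fold_change(self._table(rows), "TGT", ["ACTB"])
        assert folds["s2"] == pytest.approx(2.0)

    def test_matches_spreadsheet_recomputation(self, rng):
        samples = [("c1", "carrier"), ("c2", "carrier"), ("t1", "treated"), ("t2", "treated")]
        genes = ["TGT", "ACTB", "GAPDH"]
        rows = [(s, cond, g, float(rng.uniform(15, 30))) for s, cond in samples for g in genes]
        table = self._table(rows)
        folds = ddct_fold_change(table, "TGT", ["ACTB", "GAPDH"])
        wide = table.pivot(index="sample", columns="gene", values="ct")
        dct = wide["TGT"] - wide[["ACTB", "GAPDH"]].mean(axis=1)
        ref = dct[["c1", "c2"]].mean()
        for s in ("t1", "t2"):
            assert folds[s] == pytest.approx(2 ** -(dct[s] - ref))

    def test_missing_control_rejected(self):
        rows = [("s1", "carrier", "TGT", 24.0)]
        with pytest.raises(ValueError):
            ddct_fold_change(self._table(rows), "TGT", ["ACTB"])
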