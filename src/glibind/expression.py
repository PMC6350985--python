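"""Differential expression and cistrome-transcriptome integration.

Differentially expressed genes (DEGs) are called per gene with a Welch
two-sample t-test on log2 expression (treated vs control replicates); a gene
is "up" when its mean log2 fold change is at least log2(fc_threshold) and the
two-sided p-value is below alpha, symmetrically "down". No multiple-testing
correction is applied by default; Benjamini-Hochberg is available.

Binding regions are mapped to genes through regulatory neighborhoods: the
span from the body end of the nearest upstream gene to the body start of the
nearest downstream gene (whole intergenic regions plus the gene body;
chromosome ends where no neighbor exists). Intergenic regions may therefore
credit both flanking genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import overlaps_any

CONTROL_PREFIX = "control_"
TREATED_PREFIX = "treated_"

#: Fixed group-letter order for the 7 nonempty subsets of {G1, G2, GIS}:
#: by label count, then lexicographic. Letters are identifiers only.
BINDING_GROUP_LETTERS: dict[frozenset, str] = {
    frozenset({"G1"}): "a",
    frozenset({"G2"}): "b",
    frozenset({"GIS"}): "c",
    frozenset({"G1", "G2"}): "d",
    frozenset({"G1", "GIS"}): "e",
    frozenset({"G2", "GIS"}): "f",
    frozenset({"G1", "G2", "GIS"}): "g",
}


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its differential-expression call."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    log2fc: float
    p_value: float
    deg_status: str  # up / down / none


@dataclass(frozen=True)
class Neighborhood:
    """Regulatory span of a gene: nearest upstream body end to nearest
    downstream body start, clipped to the chromosome; contains the body."""

    gene_id: str
    chrom: str
    start: int
    end: int


def _replicate_columns(table: pd.DataFrame, prefix: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(prefix)]
    if len(cols) < 2:
        raise ValueError(f"need >= 2 replicate columns with prefix {prefix!r}")
    return cols


def call_deg(
    table: pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    correct: bool = False,
) -> list[GeneRecord]:
    """Call DEGs from an expression table (log2 scale).

    ``table`` columns: gene_id, chrom, start, end, strand, then replicate
    columns ``control_*`` and ``treated_*``. With ``correct=True`` the p-values
    are Benjamini-Hochberg adjusted before thresholding.
    """
    ctrl_cols = _replicate_columns(table, CONTROL_PREFIX)
    trt_cols = _replicate_columns(table, TREATED_PREFIX)
    ctrl = table[ctrl_cols].to_numpy(float)
    trt = table[trt_cols].to_numpy(float)
    log2fc = trt.mean(axis=1) - ctrl.mean(axis=1)
    pvals = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False).pvalue
    pvals = np.nan_to_num(pvals, nan=1.0)
    if correct:
        pvals = _benjamini_hochberg(pvals)
    min_lfc = np.log2(fc_threshold)
    records = []
    for row, lfc, p in zip(table.itertuples(index=False), log2fc, pvals):
        if p < alpha and lfc >= min_lfc:
            status = "up"
        elif p < alpha and lfc <= -min_lfc:
            status = "down"
        else:
            status = "none"
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                log2fc=float(lfc),
                p_value=float(p),
                deg_status=status,
            )
        )
    return records


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def build_neighborhoods(
    genes: Sequence[Gene],
    chrom_lengths: Mapping[str, int],
    neighbors_per_side: int = 1,
) -> list[Neighborhood]:
    """Per gene, the span from the nearest upstream neighbor's body end to the
    nearest downstream neighbor's body start (``neighbors_per_side=2`` extends
    one more gene each way). Chromosome ends substitute for missing neighbors;
    overlapping genes are allowed and spans always contain the gene body."""
    if neighbors_per_side < 1:
        raise ValueError("neighbors_per_side must be >= 1")
    by_chrom: dict[str, list[Gene]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    neighborhoods = []
    for chrom, members in by_chrom.items():
        members.sort(key=lambda g: (g.start, g.end))
        length = chrom_lengths[chrom]
        for i, gene in enumerate(members):
            up = i - neighbors_per_side
            down = i + neighbors_per_side
            start = members[up].end if up >= 0 else 0
            end = members[down].start if down < len(members) else length
            neighborhoods.append(
                Neighborhood(
                    gene_id=gene.gene_id,
                    chrom=chrom,
                    start=min(start, gene.start),
                    end=max(end, gene.end),
                )
            )
    neighborhoods.sort(key=lambda n: (n.chrom, n.start, n.gene_id))
    return neighborhoods


def assign_regions(
    classes: Mapping[str, Sequence],
    neighborhoods: Sequence[Neighborhood],
) -> dict[str, set[str]]:
    """Map gene -> set of binding-class labels.

    A gene carries label L when at least one region of class L intersects its
    neighborhood by >= 1 bp; a region in a shared intergenic gap labels both
    flanking genes. Genes with no label are omitted from the result.
    """
    labels: dict[str, set[str]] = {}
    neighborhoods = list(neighborhoods)
    for label, regions in classes.items():
        regions = list(regions)
        if not regions:
            continue
        flags = overlaps_any(neighborhoods, regions)
        for nb, flag in zip(neighborhoods, flags):
            if flag:
                labels.setdefault(nb.gene_id, set()).add(label)
    return labels


def bin_deg_by_binding(
    deg: Sequence[GeneRecord],
    labels: Mapping[str, set[str]],
) -> dict[str, list[GeneRecord]]:
    """Partition DEGs carrying >= 1 binding label into the 7 groups a-g
    defined by the nonempty subsets of {G1, G2, GIS}."""
    groups: dict[str, list[GeneRecord]] = {}
    for record in deg:
        if record.deg_status == "none":
            continue
        gene_labels = frozenset(labels.get(record.gene_id, ()))
        if not gene_labels:
            continue
        letter = BINDING_GROUP_LETTERS[gene_labels]
        groups.setdefault(letter, []).append(record)
    return groups


#: Conserved-set letters over the (hG1, hG2, mG1, mG3) gene membership vector.
#: Mouse-only: b' (mG1), c' (mG3), f' (both mouse). Human+mouse common
#: targets: a' (mG1+human), d' (mG3+human), g' (both mouse+human). Human-only
#: within conserved regions: e'.
def _conservation_set_letter(hg1: bool, hg2: bool, mg1: bool, mg3: bool) -> str:
    human = hg1 or hg2
    if mg1 and mg3:
        return "g'" if human else "f'"
    if mg1:
        return "a'" if human else "b'"
    if mg3:
        return "d'" if human else "c'"
    return "e'"


def bin_deg_by_conservation(
    deg: Sequence[GeneRecord],
    flags: Mapping[str, Mapping[str, bool]],
) -> dict[str, list[GeneRecord]]:
    """Partition DEGs by their conserved-region binding membership vector.

    ``flags`` maps gene_id -> {hG1, hG2, mG1, mG3} booleans (genes absent from
    the mapping, or with an all-false vector, are outside the conserved-region
    universe and are skipped). Sets are disjoint and exhaustive over the
    remaining DEGs.
    """
    sets: dict[str, list[GeneRecord]] = {}
    for record in deg:
        if record.deg_status == "none":
            continue
        vec = flags.get(record.gene_id)
        if not vec or not any(vec.values()):
            continue
        letter = _conservation_set_letter(
            bool(vec.get("hG1")), bool(vec.get("hG2")), bool(vec.get("mG1")), bool(vec.get("mG3"))
        )
        sets.setdefault(letter, []).append(record)
    return sets


def ddct_fold_change(
    table: pd.DataFrame,
    target: str,
    controls: Sequence[str],
    treated_label: str = "treated",
    carrier_label: str = "carrier",
) -> pd.Series:
    """Comparative-threshold-cycle (ddCt) fold changes, per treated sample.

    ``table`` columns: sample, condition, gene, ct. Per sample,
    dCt = Ct(target) - mean Ct(endogenous controls); ddCt subtracts the mean
    dCt of the carrier samples; fold change = 2**(-ddCt). Returns a Series
    indexed by sample for the treated condition.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("at least one endogenous control gene is required")
    required = {"sample", "condition", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive and finite")
    dct: dict[str, float] = {}
    condition: dict[str, str] = {}
    for sample, rows in table.groupby("sample"):
        by_gene = rows.set_index("gene")["ct"]
        missing = [g for g in [target, *controls] if g not in by_gene.index]
        if missing:
            raise ValueError(f"sample {sample!r} missing Ct for {missing}")
        dct[sample] = float(by_gene[target] - by_gene[controls].mean())
        condition[sample] = rows["condition"].iloc[0]
    carrier = [v for s, v in dct.items() if condition[s] == carrier_label]
    if not carrier:
        raise ValueError(f"no samples with condition {carrier_label!r}")
    reference = float(np.mean(carrier))
    treated = {s: 2.0 ** -(v - reference) for s, v in dct.items() if condition[s] == treated_label}
    return pd.Series(treated, name="fold_change").sort_index()
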