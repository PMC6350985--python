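"""Readers and writers for the text formats the pipeline exchanges.

FASTA via Bio.SeqIO; bedGraph and BED6 as 0-based half-open tab-separated
text; expression and gene tables as TSV via pandas; truth sets as JSON.
All writers are deterministic (sorted chromosomes, fixed float formatting)
so identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageTrack
from .regions import Region


def write_fasta(sequence: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequence.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length encode a dense track; zero-valued runs are omitted, matching
    bedGraph convention. Values use repr formatting so floats round-trip."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            values = track.values[chrom]
            boundaries = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [len(values)]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{float(v)!r}\n")


def read_bedgraph(
    path, chrom_lengths: Mapping[str, int], library_size: int, normalized: bool = False
) -> CoverageTrack:
    values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            values[chrom][int(start) : int(end)] = float(value)
    return CoverageTrack(values=values, library_size=library_size, normalized=normalized)


def write_bed(regions: Iterable, path, extra_columns=None) -> None:
    """Write BED6 (chrom start end name score strand); the score column
    carries the intensity as a float-formatted string, '.' when absent.
    ``extra_columns`` maps column name -> callable(region) for BED6+ output."""
    extra_columns = extra_columns or {}
    with open(path, "w") as fh:
        for i, region in enumerate(regions):
            name = getattr(region, "name", "") or getattr(region, "fraction", "") or str(i)
            score = getattr(region, "score", None)
            if score is None:
                score = getattr(region, "intensity", None)
            score_str = "." if score is None else f"{float(score)!r}"
            strand = getattr(region, "strand", ".") or "."
            fields = [region.chrom, str(region.start), str(region.end), name, score_str, strand]
            fields.extend(str(fn(region)) for fn in extra_columns.values())
            fh.write("\t".join(fields) + "\n")


def read_bed(path) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            score = None
            if len(fields) > 4 and fields[4] != ".":
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            regions.append(
                Region(chrom=chrom, start=start, end=end, name=name, score=score, strand=strand)
            )
    return regions


def write_peaks_bed(peaks: Sequence, path) -> None:
    """Peaks as BED6+2: name = fraction, score = intensity, then summit and a
    comma-joined selection-reasons string."""
    write_bed(
        peaks,
        path,
        extra_columns={
            "summit": lambda p: p.summit,
            "reasons": lambda p: ",".join(getattr(p, "reasons", ())) or ".",
        },
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genes(genes: Sequence, path) -> None:
    rows = [
        {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end, "strand": g.strand}
        for g in genes
    ]
    write_table(pd.DataFrame(rows), path)


def read_genes(path) -> list:
    from .expression import Gene

    df = read_table(path)
    return [
        Gene(gene_id=r.gene_id, chrom=r.chrom, start=int(r.start), end=int(r.end), strand=r.strand)
        for r in df.itertuples(index=False)
    ]
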