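"""Plain-text format I/O: FASTA, BED(+UMI), methylome TSV, bedGraph.

All writers end files with a newline; readers transparently accept
gzip-compressed input (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caller import FragmentRecord
from .genome import Genome, Methylome


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> Genome:
    with open_text(path) as handle:
        return Genome({rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")})


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome[chrom]), id=chrom, description="")
        for chrom in genome
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def write_fragments_bed(fragments: Iterable[FragmentRecord], path) -> None:
    """BED6 plus a 7th UMI column and an optional 8th allele column."""
    with open(path, "w") as handle:
        for f in fragments:
            fields = [f.chrom, str(f.start), str(f.end), f.name or ".", ".", ".", f.umi or "."]
            if f.allele is not None:
                fields.append(f.allele)
            handle.write("\t".join(fields) + "\n")


def read_fragments_bed(path) -> list[FragmentRecord]:
    fragments = []
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(
                    f"{path}, line {lineno}: expected >= 7 columns (BED6 + UMI), "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-integer interval") from exc
            allele = fields[7] if len(fields) > 7 and fields[7] != "." else None
            umi = fields[6] if fields[6] != "." else ""
            fragments.append(
                FragmentRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    umi=umi,
                    name=fields[3] if fields[3] != "." else "",
                    allele=allele,
                )
            )
    return fragments


_METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "prob", "r_base"]


def write_methylome_tsv(methylome: Methylome, path) -> None:
    methylome.to_frame().to_csv(path, sep="\t", index=False)


def read_methylome_tsv(path) -> Methylome:
    frame = pd.read_csv(open_text(path), sep="\t", dtype={"chrom": str, "r_base": str})
    missing = set(_METHYLOME_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"methylome TSV missing columns {sorted(missing)}")
    return Methylome.from_frame(frame)


def write_bedgraph(entries: Iterable[tuple[str, int, int, float]], path) -> None:
    with open(path, "w") as handle:
        for chrom, start, end, value in entries:
            handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def methylome_bedgraph_entries(
    methylome: Methylome, strand: str
) -> list[tuple[str, int, int, float]]:
    """Single-base bedGraph entries for one strand's methylation track."""
    want_watson = strand == "+"
    entries = []
    for chrom, sites in methylome.chroms.items():
        for pos, is_w, prob in zip(sites.pos, sites.is_watson, sites.prob):
            if bool(is_w) == want_watson:
                entries.append((chrom, int(pos), int(pos) + 1, float(prob)))
    return entries


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(open_text(path), sep="\t")


def read_regions_bed(path) -> list:
    """BED6 regions; column 6 is the motif orientation (+/-). Returns
    :class:`~hemidyad.analysis.RegionSpec` objects without offsets (attach
    designated dyad offsets from a sidecar table if needed)."""
    from .analysis import RegionSpec

    regions = []
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}, line {lineno}: expected BED6 with strand, got "
                    f"{len(fields)} columns"
                )
            regions.append(
                RegionSpec(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    orientation=fields[5],
                )
            )
    return regions
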