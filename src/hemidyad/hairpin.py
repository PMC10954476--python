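"""Hairpin-bisulfite readout of synthetic molecules.

Hairpin bisulfite sequencing reads both strands of a single duplex after
hairpin ligation, resolving dyad methylation directly: an unconverted C
on a strand means that strand's cytosine was methylated. This module
simulates that readout over genomic windows (no FASTQ round-trip and no
aligner — the reads are emitted as per-strand base strings indexed by
Watson coordinates) and recovers per-dyad statuses independently of the
fragment-geometry caller, serving as its cross-validation oracle.

Each simulated read carries a copy of the hairpin linker whose cytosines
are unmethylated by construction; the realized conversion rate of a
library is estimated from those linker cytosines alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import STATUSES, predominant_status
from .genome import (
    CRICK,
    WATSON,
    DyadSite,
    Genome,
    Methylome,
    MoleculeMethylation,
    reverse_complement,
)

#: Hairpin linker reference sequence; all of its cytosines are unmethylated,
#: so their conversion behaviour measures the bisulfite conversion rate.
DEFAULT_LINKER = "TGCAGGATCCAGCTTACGCT"


@dataclass(frozen=True)
class ConversionParams:
    """Bisulfite chemistry: an unmethylated C reads as T with probability
    ``conversion_rate``; a methylated C erroneously reads as T with
    probability ``failure_rate``."""

    conversion_rate: float = 0.99
    failure_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.conversion_rate <= 1 or not 0 <= self.failure_rate <= 1:
            raise ValueError("conversion and failure rates must lie in [0, 1]")


@dataclass
class HairpinRead:
    """Post-bisulfite readout of both strands of one molecule over a window.

    ``watson_seq`` and ``crick_seq`` are indexed by Watson coordinates
    (``crick_seq[i]`` is the Crick-strand base paired with Watson position
    ``start + i``), so a dyad's two cytosines are looked up at
    ``watson_c`` and ``crick_c`` directly.
    """

    molecule_id: int
    chrom: str
    start: int
    end: int
    watson_seq: str
    crick_seq: str
    linker_seq: str


def _convert(
    bases: list[str],
    c_positions: np.ndarray,
    methylated: set[int],
    params: ConversionParams,
    rng: np.random.Generator,
) -> None:
    for off in c_positions:
        rate = params.failure_rate if off in methylated else params.conversion_rate
        if rng.random() < rate:
            bases[off] = "T"


def simulate_hairpin_reads(
    genome: Genome,
    methylome: Methylome,
    molecules: Sequence[MoleculeMethylation],
    windows: Sequence[tuple[str, int, int]],
    params: ConversionParams = ConversionParams(),
    linker: str = DEFAULT_LINKER,
    rng: np.random.Generator | None = None,
) -> list[HairpinRead]:
    """One read per (molecule, window) with conversion applied per strand."""
    if rng is None:
        rng = np.random.default_rng(params.seed)

    # Methylated-site lookup per chrom: Watson-coordinate -> site index, by strand.
    site_index: dict[str, tuple[dict[int, int], dict[int, int]]] = {}
    for chrom, sites in methylome.chroms.items():
        watson = {int(p): i for i, p in enumerate(sites.pos) if sites.is_watson[i]}
        crick = {int(p): i for i, p in enumerate(sites.pos) if not sites.is_watson[i]}
        site_index[chrom] = (watson, crick)

    linker_cs = np.array([i for i, b in enumerate(linker) if b == "C"], dtype=np.int64)

    reads: list[HairpinRead] = []
    for chrom, start, end in windows:
        window_seq = genome.fetch(chrom, start, end)
        codes = np.frombuffer(window_seq.encode("ascii"), dtype=np.uint8)
        watson_cs = np.nonzero(codes == ord("C"))[0]
        crick_cs = np.nonzero(codes == ord("G"))[0]  # Crick C pairs with Watson G
        w_idx, c_idx = site_index.get(chrom, ({}, {}))
        for mol in molecules:
            states = mol.states.get(chrom)
            meth_w = {
                off
                for off in watson_cs
                if (i := w_idx.get(start + int(off))) is not None and states is not None and states[i]
            }
            meth_c = {
                off
                for off in crick_cs
                if (i := c_idx.get(start + int(off))) is not None and states is not None and states[i]
            }
            wbases = list(window_seq)
            _convert(wbases, watson_cs, meth_w, params, rng)
            cbases = [b.translate(_COMP) for b in window_seq]
            _convert(cbases, crick_cs, meth_c, params, rng)
            lbases = list(linker)
            _convert(lbases, linker_cs, set(), params, rng)
            reads.append(
                HairpinRead(
                    molecule_id=mol.molecule_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    watson_seq="".join(wbases),
                    crick_seq="".join(cbases),
                    linker_seq="".join(lbases),
                )
            )
    return reads


_COMP = str.maketrans("ACGTN", "TGCAN")


def estimate_conversion_rate(
    reads: Sequence[HairpinRead], linker: str = DEFAULT_LINKER
) -> float:
    """Converted fraction of the linker's (unmethylated) cytosines."""
    c_positions = [i for i, b in enumerate(linker) if b == "C"]
    total = converted = 0
    for read in reads:
        for i in c_positions:
            total += 1
            if read.linker_seq[i] == "T":
                converted += 1
    if total == 0:
        raise ValueError("no linker cytosines observed")
    return converted / total


def extract_dyad_status(read: HairpinRead, dyad: DyadSite) -> str:
    """Dyad status from one read: a retained C on a strand means that
    strand was methylated on this molecule."""
    if dyad.chrom != read.chrom or not (
        read.start <= dyad.watson_c and dyad.crick_c < read.end
    ):
        raise ValueError("dyad lies outside the read window")
    watson_me = read.watson_seq[dyad.watson_c - read.start] == "C"
    crick_me = read.crick_seq[dyad.crick_c - read.start] == "C"
    if watson_me and crick_me:
        return "me"
    if watson_me:
        return "hemiW"
    if crick_me:
        return "hemiC"
    return "unme"


def aggregate_predominant(counts: Mapping[str, int], min_count: int = 3) -> str | None:
    """Unique most frequent of the four statuses among >= ``min_count``
    observations; ``None`` (excluded) below the count floor or on ties."""
    return predominant_status(dict(counts), min_count=min_count)


def call_dyads_from_reads(
    reads: Sequence[HairpinRead],
    dyads: Sequence[DyadSite],
    min_count: int = 3,
) -> pd.DataFrame:
    """Per-dyad status counts and predominant call across all covering reads."""
    # Reads sharing a window are grouped so each dyad only visits the few
    # windows that contain it.
    by_window: dict[tuple[str, int, int], list[HairpinRead]] = {}
    for read in reads:
        by_window.setdefault((read.chrom, read.start, read.end), []).append(read)
    windows_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in by_window:
        windows_by_chrom.setdefault(chrom, []).append((start, end))
    rows = []
    for dyad in dyads:
        counts = {s: 0 for s in STATUSES}
        for start, end in windows_by_chrom.get(dyad.chrom, ()):
            if start <= dyad.watson_c and dyad.crick_c < end:
                for read in by_window[(dyad.chrom, start, end)]:
                    counts[extract_dyad_status(read, dyad)] += 1
        status = aggregate_predominant(counts, min_count=min_count)
        rows.append(
            {
                "chrom": dyad.chrom,
                "watson_c": dyad.watson_c,
                "crick_c": dyad.crick_c,
                "kind": dyad.kind,
                **counts,
                "status": status if status is not None else "excluded",
            }
        )
    return pd.DataFrame(rows)
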