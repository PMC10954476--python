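"""MspJI cut model, molecule digestion and library simulation.

MspJI cleaves 9/13 nt downstream of a methylated CNNR motif, leaving a
4 nt 5' overhang. After end repair both strands of a fragment extend to
the far (13 nt) cut, so the model places a single breakpoint per
successful recognition event:

* Watson-strand mC at ``p`` (motif ``p..p+3``): breakpoint at ``p + 17``
  (half-open offset = motif end ``p+4`` plus 13);
* Crick-strand mC at Watson coordinate ``q`` (motif spanning ``q-3..q``):
  breakpoint at ``q - 16``.

A fully methylated CpG dyad in YNCGNR context therefore yields a 32 bp
fragment with the 6-mer context at its center; a fully methylated CWG
dyad yields 31 bp. The 9 nt near cut and the overhang are bookkeeping
only (exposed for geometry checks); overhang ligation chemistry is not
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import FragmentRecord
from .genome import Genome, Methylome, MoleculeMethylation

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CutModel:
    near_offset: int = 9  # cut on the methylated strand, nt downstream of motif end
    far_offset: int = 13  # cut on the opposite strand; defines the fragment edge

    @property
    def overhang(self) -> int:
        """Length of the 5' overhang between the two nicks (4 nt)."""
        return self.far_offset - self.near_offset

    def watson_breakpoint(self, c: int) -> int:
        """Half-open breakpoint for a methylated Watson C at ``c``."""
        return c + 4 + self.far_offset

    def crick_breakpoint(self, c: int) -> int:
        """Half-open breakpoint for a methylated Crick C at Watson coordinate ``c``."""
        return c - 3 - self.far_offset


CUT_MODEL = CutModel()


@dataclass(frozen=True)
class DigestionParams:
    """Per-site cutting probabilities.

    ``efficiency_by_r`` maps the motif's downstream R base to the cut
    probability; the defaults are the measured near-complete digestion of
    mCGNG-class sites (~97%) and the insufficient digestion of mCGNA-class
    sites (~80%). ``star_activity`` is the probability of cutting an
    *unmethylated* CNNR site (off-target activity), 0 by default since the
    unmethylated template is barely digested.
    """

    efficiency_by_r: Mapping[str, float] = field(
        default_factory=lambda: {"G": 0.97, "A": 0.80}
    )
    star_activity: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        probs = list(self.efficiency_by_r.values()) + [self.star_activity]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all cut probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class LibraryParams:
    """Library construction knobs: size selection, 32-mer purification
    efficiency, UMIs, and PCR duplication."""

    n_molecules: int = 100
    size_min: int = 32
    size_max: int = 1000
    e_pu: float = 1.0  # capture probability of 32 bp fragments relative to longer ones
    umi_length: int = 8
    duplicate_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.e_pu <= 1:
            raise ValueError("e_pu must lie in [0, 1]")
        if self.size_min > 32:
            raise ValueError("size_min must be <= 32 to retain doubly-cut CpG fragments")
        if not 0 <= self.duplicate_rate <= 1:
            raise ValueError("duplicate_rate must lie in [0, 1]")


def _cut_probabilities(
    sites, params: DigestionParams, require_context: bool = True
) -> np.ndarray:
    eff = np.zeros(sites.n, dtype=float)
    for base, p in params.efficiency_by_r.items():
        eff[sites.r_base == base] = p
    if require_context:
        invalid = (sites.prob > 0) & ~np.isin(sites.r_base, list(params.efficiency_by_r))
        if np.any(invalid):
            pos = sites.pos[invalid][0]
            raise ValueError(
                f"methylatable site at {pos} lies outside a CNNR context; "
                "the cut model is undefined there"
            )
    return eff


def breakpoints_for_molecule(
    genome: Genome,
    methylome: Methylome,
    molecule: MoleculeMethylation,
    params: DigestionParams = DigestionParams(),
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Sorted, deduplicated breakpoints per contig for one duplex copy.

    Each methylated site cuts independently with the efficiency of its R
    class; unmethylated CNNR sites cut with ``star_activity``. Breakpoints
    falling outside ``(0, contig_length)`` are clipped away.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out: dict[str, np.ndarray] = {}
    for chrom, sites in methylome.chroms.items():
        states = molecule.states[chrom]
        eff = _cut_probabilities(sites, params)
        cut = states & (rng.random(sites.n) < eff)
        if params.star_activity > 0:
            star_ok = np.isin(sites.r_base, list(params.efficiency_by_r))
            cut |= ~states & star_ok & (rng.random(sites.n) < params.star_activity)
        bps = np.where(sites.is_watson, sites.pos + 17, sites.pos - 16)[cut]
        n = genome.length(chrom)
        bps = np.unique(bps[(bps > 0) & (bps < n)])
        out[chrom] = bps
    return out


def digest_molecule(chrom_length: int, breakpoints: Sequence[int]) -> list[tuple[int, int]]:
    """Partition ``[0, chrom_length)`` at the given sorted breakpoints.

    ``k`` breakpoints yield ``k + 1`` fragments whose lengths sum to the
    molecule length.
    """
    edges = np.concatenate(([0], np.asarray(breakpoints, dtype=np.int64), [chrom_length]))
    if np.any(np.diff(edges) <= 0):
        raise ValueError("breakpoints must be strictly increasing within (0, length)")
    return [(int(s), int(e)) for s, e in zip(edges[:-1], edges[1:])]


def simulate_library(
    genome: Genome,
    methylome: Methylome,
    digestion_params: DigestionParams = DigestionParams(),
    library_params: LibraryParams = LibraryParams(),
) -> list[FragmentRecord]:
    """End-to-end library emitter: sample duplex copies from the methylome,
    digest each, size-select, thin 32-mers by ``e_pu``, attach random UMIs
    and optionally emit PCR-duplicate copies.

    All randomness flows from ``library_params.seed``, so a fixed seed
    reproduces the library exactly.
    """
    rng = np.random.default_rng(library_params.seed)
    n = library_params.n_molecules
    lp = library_params

    fragments: list[tuple[str, int, int, int]] = []  # chrom, start, end, molecule
    for chrom, sites in methylome.chroms.items():
        chrom_len = genome.length(chrom)
        eff = _cut_probabilities(sites, digestion_params)
        meth = rng.random((n, sites.n)) < sites.prob
        cut = meth & (rng.random((n, sites.n)) < eff)
        if digestion_params.star_activity > 0:
            star_ok = np.isin(sites.r_base, list(digestion_params.efficiency_by_r))
            cut |= ~meth & star_ok & (
                rng.random((n, sites.n)) < digestion_params.star_activity
            )
        bp_all = np.where(sites.is_watson, sites.pos + 17, sites.pos - 16)
        for mol in range(n):
            bps = bp_all[cut[mol]]
            bps = np.unique(bps[(bps > 0) & (bps < chrom_len)])
            edges = np.concatenate(([0], bps, [chrom_len]))
            for s, e in zip(edges[:-1], edges[1:]):
                length = e - s
                if length < lp.size_min or length > lp.size_max:
                    continue
                if length == 32 and lp.e_pu < 1 and rng.random() >= lp.e_pu:
                    continue
                fragments.append((chrom, int(s), int(e), mol))

    umis = [
        "".join(row) for row in _BASES[rng.integers(0, 4, size=(len(fragments), lp.umi_length))]
    ]
    records: list[FragmentRecord] = []
    dup_draws = rng.random(len(fragments)) < lp.duplicate_rate
    for i, ((chrom, s, e, mol), umi) in enumerate(zip(fragments, umis)):
        rec = FragmentRecord(chrom, s, e, umi=umi, name=f"m{mol}:f{i}")
        records.append(rec)
        if dup_draws[i]:
            records.append(FragmentRecord(chrom, s, e, umi=umi, name=f"m{mol}:f{i}:dup"))
    return records


def insilico_digest_lengths(
    positions: Sequence[int],
    probabilities: Sequence[float],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Whole-genome in-silico digest: each cut site is independently set to
    1 (cut) with its probability and the distance between neighboring
    1-sites is a fragment length. Returns the length histogram as a
    Series indexed by length.
    """
    positions = np.asarray(positions, dtype=np.int64)
    probabilities = np.asarray(probabilities, dtype=float)
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("cut probabilities must lie in [0, 1]")
    if np.any(np.diff(positions) < 0):
        raise ValueError("cut sites must be ordered by coordinate")
    if rng is None:
        rng = np.random.default_rng(seed)
    cut = rng.random(positions.size) < probabilities
    lengths = np.diff(positions[cut])
    values, counts = np.unique(lengths, return_counts=True)
    return pd.Series(counts, index=values, name="count")


def cut_edge_motif_fraction(genome: Genome, fragments: Sequence[FragmentRecord]) -> float:
    """Fraction of internal fragment boundaries explainable by the cut model.

    A boundary ``b`` (any fragment start > 0 or end < contig length) is
    explainable when a CNNR motif ends exactly 13 bp inside one of the two
    abutting fragments: a Watson motif at ``b - 17`` (C with R at
    ``b - 14``) or a Crick motif at ``b + 16`` (G with a pyrimidine at
    ``b + 13``). In an idealized simulation every boundary is a cut and
    the fraction is 1.0; chromosome ends are never counted.
    """
    boundaries: dict[str, set[int]] = {}
    for f in fragments:
        b = boundaries.setdefault(f.chrom, set())
        if f.start > 0:
            b.add(f.start)
        if f.end < genome.length(f.chrom):
            b.add(f.end)
    total = ok = 0
    for chrom, bs in boundaries.items():
        seq = genome[chrom]
        n = len(seq)
        for b in bs:
            total += 1
            watson = b >= 17 and seq[b - 17] == "C" and seq[b - 14] in "AG"
            crick = b + 16 < n and seq[b + 16] == "G" and seq[b + 13] in "CT"
            if watson or crick:
                ok += 1
    if total == 0:
        raise ValueError("no internal fragment boundaries to assess")
    return ok / total
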