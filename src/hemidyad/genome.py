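"""Genome and methylome containers plus MspJI motif scanning.

Coordinate conventions used across the whole package:

* coordinates are 0-based, intervals half-open ``[start, end)``;
* Crick-strand sites are indexed by the Watson coordinate of the paired
  base (never by reverse-complement coordinates), so a single coordinate
  system covers both strands;
* ``N`` bases never match any motif class (not Y, not R, not C/G).

MspJI recognizes a methylated CNNR motif (R = A/G) and the two cytosines
of a CpG dyad are *both* recognizable exactly when the dyad sits in the
palindromic YNCGNR context (Y = C/T); the analogous context for CHG dyads
is YCWGR (W = A/T).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

WATSON = "+"
CRICK = "-"

PURINES = "AG"  # R
PYRIMIDINES = "CT"  # Y

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_A, _C, _G, _T = (ord(b) for b in "ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codes(seq: str) -> np.ndarray:
    """Sequence as a uint8 array of ASCII codes (zero-copy view of the bytes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class Genome:
    """A set of named contigs holding uppercase A/C/G/T/N strings."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not set(seq) <= _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"contig {name!r} contains invalid characters {bad}")
            self.sequences[name] = seq

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Half-open slice with strict bounds checking."""
        n = self.length(chrom)
        if not (0 <= start <= end <= n):
            raise IndexError(f"[{start}, {end}) outside [0, {n}) on {chrom}")
        return self.sequences[chrom][start:end]


@dataclass(frozen=True)
class DyadSite:
    """A CpG or CWG dyad anchored at the Watson-strand cytosine.

    ``crick_c`` is the Watson coordinate of the base paired with the
    Crick-strand cytosine (``watson_c + 1`` for CpG, ``watson_c + 2`` for
    CWG). ``resolvable`` is true iff the full palindromic context holds so
    that *both* strands' cytosines sit in a CNNR motif. ``r_watson`` /
    ``r_crick`` are the downstream R bases of each strand's motif (they
    drive the strand-specific cutting efficiency); ``None`` when the
    context is incomplete.
    """

    chrom: str
    watson_c: int
    crick_c: int
    kind: str  # "CpG" | "CWG"
    resolvable: bool
    r_watson: str | None
    r_crick: str | None

    @property
    def left_cut(self) -> int:
        """Breakpoint produced by a methylated Crick-strand cytosine."""
        return self.crick_c - 16

    @property
    def right_cut(self) -> int:
        """Breakpoint produced by a methylated Watson-strand cytosine."""
        return self.watson_c + 17


def scan_cnnr_sites(genome: Genome) -> list[tuple[str, int, str]]:
    """All strand-level CNNR cytosines, as ``(chrom, position, strand)``.

    A Watson site sits at ``p`` iff ``genome[p] == C`` and
    ``genome[p+3]`` is a purine; a Crick site is reported at the Watson
    coordinate ``q`` of the paired base iff ``genome[q] == G`` and
    ``genome[q-3]`` is a pyrimidine. Sites whose motif would run off a
    contig end are omitted.
    """
    out: list[tuple[str, int, str]] = []
    for chrom in genome:
        wpos, cpos = scan_cnnr_arrays(genome, chrom)
        out.extend((chrom, int(p), WATSON) for p in wpos)
        out.extend((chrom, int(q), CRICK) for q in cpos)
    return out


def scan_cnnr_arrays(genome: Genome, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-contig CNNR scan; returns (watson_positions, crick_positions)."""
    codes = _codes(genome[chrom])
    if codes.size < 4:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    head, tail = codes[:-3], codes[3:]
    watson = np.nonzero((head == _C) & ((tail == _A) | (tail == _G)))[0]
    crick = np.nonzero((tail == _G) & ((head == _C) | (head == _T)))[0] + 3
    return watson.astype(np.int64), crick.astype(np.int64)


def _r_bases(codes: np.ndarray, watson_c: np.ndarray, gap: int) -> tuple[list, list]:
    """Downstream R base of each strand's motif for dyads with Crick C at
    ``watson_c + gap``; ``None`` where the context (or the contig) ends."""
    n = codes.size
    r_w: list[str | None] = []
    r_c: list[str | None] = []
    for p in watson_c:
        down = p + 3
        r_w.append(chr(codes[down]) if down < n and codes[down] in (_A, _G) else None)
        up = p + gap - 3  # Crick motif's R pairs with the Watson base 3 upstream of crick_c
        if up >= 0 and codes[up] in (_C, _T):
            r_c.append("G" if codes[up] == _C else "A")
        else:
            r_c.append(None)
    return r_w, r_c


def scan_dyads(genome: Genome, kind: str = "CpG") -> list[DyadSite]:
    """Every Watson-strand CpG (or C-W-G) dyad in the genome.

    The ``resolvable`` flag marks dyads in the full YNCGNR (CpG) or
    YCWGR-with-flanks (CWG) context, i.e. those whose methylation status
    can be resolved on both strands.
    """
    if kind not in ("CpG", "CWG"):
        raise ValueError(f"kind must be 'CpG' or 'CWG', got {kind!r}")
    gap = 1 if kind == "CpG" else 2
    dyads: list[DyadSite] = []
    for chrom in genome:
        codes = _codes(genome[chrom])
        if codes.size < gap + 1:
            continue
        if kind == "CpG":
            hits = np.nonzero((codes[:-1] == _C) & (codes[1:] == _G))[0]
        else:
            mid = codes[1:-1]
            hits = np.nonzero(
                (codes[:-2] == _C) & ((mid == _A) | (mid == _T)) & (codes[2:] == _G)
            )[0]
        r_w, r_c = _r_bases(codes, hits, gap)
        for p, rw, rc in zip(hits, r_w, r_c):
            dyads.append(
                DyadSite(
                    chrom=chrom,
                    watson_c=int(p),
                    crick_c=int(p) + gap,
                    kind=kind,
                    resolvable=rw is not None and rc is not None,
                    r_watson=rw,
                    r_crick=rc,
                )
            )
    return dyads


# ---------------------------------------------------------------------------
# Methylome


@dataclass
class MethylomeSites:
    """Per-contig site table as parallel arrays sorted by position.

    ``pos`` is the Watson coordinate of the site's base; ``is_watson``
    distinguishes the strand; ``prob`` is the per-molecule methylation
    probability; ``r_base`` is the downstream R base of the site's CNNR
    motif ('A'/'G', or 'N' when the site is not in a CNNR context and
    therefore can never be cut).
    """

    pos: np.ndarray
    is_watson: np.ndarray
    prob: np.ndarray
    context: np.ndarray
    r_base: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("methylation probabilities must lie in [0, 1]")
        order = np.lexsort((~self.is_watson, self.pos))
        for name in ("pos", "is_watson", "prob", "context", "r_base"):
            setattr(self, name, np.asarray(getattr(self, name))[order])

    @property
    def n(self) -> int:
        return int(self.pos.size)


class Methylome:
    """Per-site, per-strand methylation probabilities over a genome."""

    def __init__(self, chroms: Mapping[str, MethylomeSites]):
        self.chroms: dict[str, MethylomeSites] = dict(chroms)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str, float, str, str]]
    ) -> "Methylome":
        """Build from ``(chrom, pos, strand, prob, context, r_base)`` rows."""
        by_chrom: dict[str, list] = {}
        for chrom, pos, strand, prob, context, r_base in records:
            by_chrom.setdefault(chrom, []).append(
                (pos, strand == WATSON, prob, context, r_base)
            )
        chroms = {}
        for chrom, rows in by_chrom.items():
            pos, is_w, prob, ctx, r = zip(*rows)
            chroms[chrom] = MethylomeSites(
                pos=np.array(pos, dtype=np.int64),
                is_watson=np.array(is_w, dtype=bool),
                prob=np.array(prob, dtype=float),
                context=np.array(ctx, dtype=object),
                r_base=np.array(r, dtype=object),
            )
        return cls(chroms)

    def n_sites(self) -> int:
        return sum(s.n for s in self.chroms.values())

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom, s in self.chroms.items():
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": s.pos,
                        "strand": np.where(s.is_watson, WATSON, CRICK),
                        "context": s.context,
                        "prob": s.prob,
                        "r_base": s.r_base,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(
                columns=["chrom", "pos", "strand", "context", "prob", "r_base"]
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Methylome":
        return cls.from_records(
            (r.chrom, int(r.pos), r.strand, float(r.prob), r.context, r.r_base)
            for r in frame.itertuples()
        )


@dataclass
class MoleculeMethylation:
    """Binary methylation state of one DNA duplex copy.

    ``states[chrom]`` is a boolean array parallel to the methylome's site
    arrays for that contig.
    """

    molecule_id: int
    states: dict[str, np.ndarray]


def sample_molecules(
    methylome: Methylome, n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> list[MoleculeMethylation]:
    """Realize per-site probabilities as ``n`` independent duplex copies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    per_chrom = {
        chrom: rng.random((n, s.n)) < s.prob for chrom, s in methylome.chroms.items()
    }
    return [
        MoleculeMethylation(i, {chrom: mat[i] for chrom, mat in per_chrom.items()})
        for i in range(n)
    ]
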