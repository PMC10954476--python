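"""Dyad and strand-level methylation calling from fragment records.

The caller inverts the MspJI cut geometry: a fragment edge sitting exactly
13 bp downstream of a CNNR motif is evidence that the motif's cytosine was
methylated on that molecule, while a fragment spanning the would-be
breakpoint with no matching edge is evidence it was not. For a resolvable
dyad the two strand-wise observations combine into one of four statuses
(unme / hemiW / hemiC / me) per molecule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import CRICK, WATSON, DyadSite

# Per-molecule classification outcomes.
UNME = "unme"
HEMI_W = "hemiW"
HEMI_C = "hemiC"
ME = "me"
STRAND_ONLY_W = "strand_only_W"
STRAND_ONLY_C = "strand_only_C"
NO_CALL = "no_call"

STATUSES = (UNME, HEMI_W, HEMI_C, ME)
_COUNT_COLUMNS = (UNME, HEMI_W, HEMI_C, ME, STRAND_ONLY_W, STRAND_ONLY_C)
_COL_INDEX = {name: i for i, name in enumerate(_COUNT_COLUMNS)}

# Dyad cut intervals are at most 32 bp wide (CpG: 32, CWG: 31).
_MAX_DYAD_SPAN = 32


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment: 0-based half-open interval plus UMI."""

    chrom: str
    start: int
    end: int
    umi: str = ""
    name: str = ""
    allele: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DyadCallCounts:
    """Per-dyad tallies of the four statuses plus edge-only evidence.

    ``strand_only`` counts record fragments whose single matching edge
    proves one strand's methylation but whose extent cannot witness the
    partner strand (the partner cut site lies outside the fragment); they
    feed strand-level calls but never the four-status coverage.
    """

    dyad: DyadSite
    unme: int = 0
    hemiW: int = 0
    hemiC: int = 0
    me: int = 0
    strand_only_W: int = 0
    strand_only_C: int = 0

    @property
    def coverage(self) -> int:
        return self.unme + self.hemiW + self.hemiC + self.me


@dataclass(frozen=True)
class CallerConfig:
    min_dyad_coverage: int = 5  # "more than four reads"
    dedup: bool = True
    kinds: tuple[str, ...] = ("CpG",)

    def __post_init__(self) -> None:
        if self.min_dyad_coverage < 1:
            raise ValueError("min_dyad_coverage must be >= 1")


def dedup_fragments(fragments: Iterable[FragmentRecord]) -> list[FragmentRecord]:
    """One record per (chrom, start, end, UMI) key.

    Records are stably sorted by the key first, so retention (first
    occurrence within each key group) is deterministic regardless of
    input order.
    """
    key = lambda f: (f.chrom, f.start, f.end, f.umi)
    out = []
    for _, group in itertools.groupby(sorted(fragments, key=key), key=key):
        out.append(next(group))
    return out


def _classify(start: int, end: int, left_cut: int, right_cut: int) -> str:
    if end == right_cut:
        if start == left_cut:
            return ME
        return HEMI_W if start < left_cut else STRAND_ONLY_W
    if start == left_cut:
        return HEMI_C if end > right_cut else STRAND_ONLY_C
    if start < left_cut and end > right_cut:
        return UNME
    return NO_CALL


def classify_fragment_vs_dyad(fragment: FragmentRecord, dyad: DyadSite) -> str:
    """Per-molecule status of ``dyad`` as witnessed by one fragment.

    Edge matching is exact integer equality: ``me`` iff the fragment is
    precisely the doubly-cut interval, ``hemiW``/``hemiC`` iff exactly one
    edge matches and the fragment extends past the partner cut, ``unme``
    iff the fragment strictly spans both cut sites with neither edge
    matching. Raises for non-resolvable dyads, which must be filtered out
    upstream.
    """
    if not dyad.resolvable:
        raise ValueError(f"dyad at {dyad.chrom}:{dyad.watson_c} is not resolvable")
    if fragment.chrom != dyad.chrom:
        return NO_CALL
    return _classify(fragment.start, fragment.end, dyad.left_cut, dyad.right_cut)


def count_dyad_statuses(
    fragments: Sequence[FragmentRecord],
    dyads: Sequence[DyadSite],
    config: CallerConfig = CallerConfig(),
) -> pd.DataFrame:
    """Tally per-molecule statuses for every resolvable dyad.

    Returns one row per resolvable dyad with the four status counts, the
    separate strand-only tallies, coverage (four statuses only) and an
    ``excluded`` flag for dyads below ``min_dyad_coverage``.
    """
    if config.dedup:
        fragments = dedup_fragments(fragments)

    resolvable = [d for d in dyads if d.resolvable]
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for idx, d in enumerate(resolvable):
        per_chrom.setdefault(d.chrom, ([], [], []))
        per_chrom[d.chrom][0].append(d.left_cut)
        per_chrom[d.chrom][1].append(d.right_cut)
        per_chrom[d.chrom][2].append(idx)
    indexed = {}
    for chrom, (ls, rs, idxs) in per_chrom.items():
        order = np.argsort(ls, kind="stable")
        indexed[chrom] = (
            np.asarray(ls)[order],
            np.asarray(rs)[order],
            np.asarray(idxs)[order],
        )

    counts = np.zeros((len(resolvable), len(_COUNT_COLUMNS)), dtype=np.int64)
    for frag in fragments:
        entry = indexed.get(frag.chrom)
        if entry is None:
            continue
        lefts, rights, idxs = entry
        lo = np.searchsorted(lefts, frag.start - _MAX_DYAD_SPAN, side="right")
        hi = np.searchsorted(lefts, frag.end, side="left")
        for i in range(lo, hi):
            if rights[i] <= frag.start:
                continue
            status = _classify(frag.start, frag.end, int(lefts[i]), int(rights[i]))
            if status != NO_CALL:
                counts[idxs[i], _COL_INDEX[status]] += 1

    frame = pd.DataFrame(
        {
            "chrom": [d.chrom for d in resolvable],
            "watson_c": [d.watson_c for d in resolvable],
            "crick_c": [d.crick_c for d in resolvable],
            "kind": [d.kind for d in resolvable],
            "r_watson": [d.r_watson for d in resolvable],
            "r_crick": [d.r_crick for d in resolvable],
        }
    )
    for name in _COUNT_COLUMNS:
        frame[name] = counts[:, _COL_INDEX[name]]
    frame["coverage"] = frame[list(STATUSES)].sum(axis=1)
    frame["excluded"] = frame["coverage"] < config.min_dyad_coverage
    return frame


def call_cytosine_levels(
    fragments: Sequence[FragmentRecord],
    cnnr_sites: Sequence[tuple[str, int, str]],
    config: CallerConfig = CallerConfig(),
) -> pd.DataFrame:
    """Strand-level methylation level at every CNNR cytosine.

    Methylated evidence for a site is a fragment edge at the site's
    breakpoint (Watson: ``end == pos + 17``; Crick: ``start == pos - 16``);
    unmethylated evidence is a fragment strictly spanning the breakpoint.
    ``level = meth / (meth + unmeth)``; NaN when uncovered.
    """
    if config.dedup:
        fragments = dedup_fragments(fragments)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, group in itertools.groupby(
        sorted(fragments, key=lambda f: f.chrom), key=lambda f: f.chrom
    ):
        group = list(group)
        by_chrom[chrom] = (
            np.sort(np.array([f.start for f in group], dtype=np.int64)),
            np.sort(np.array([f.end for f in group], dtype=np.int64)),
        )

    rows = []
    empty = np.empty(0, dtype=np.int64)
    for chrom, pos, strand in cnnr_sites:
        starts, ends = by_chrom.get(chrom, (empty, empty))
        bp = pos + 17 if strand == WATSON else pos - 16
        if strand == WATSON:
            meth = int(
                np.searchsorted(ends, bp, side="right")
                - np.searchsorted(ends, bp, side="left")
            )
        else:
            meth = int(
                np.searchsorted(starts, bp, side="right")
                - np.searchsorted(starts, bp, side="left")
            )
        spanning = int(
            np.searchsorted(starts, bp, side="left")
            - np.searchsorted(ends, bp, side="right")
        )
        total = meth + spanning
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "meth": meth,
                "unmeth": spanning,
                "level": meth / total if total else np.nan,
                "excluded": total < config.min_dyad_coverage,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "meth", "unmeth", "level", "excluded"],
    )


def dyad_levels(counts) -> dict[str, float]:
    """Four-status fractions (and per-strand hemi levels) for one dyad.

    Accepts a :class:`DyadCallCounts`, a mapping, or a DataFrame row with
    the four status fields. Errors on zero coverage; strand-only evidence
    never enters the denominators.
    """
    get = (
        counts.get
        if isinstance(counts, dict)
        else lambda k: getattr(counts, k)
    )
    vals = {s: int(get(s)) for s in STATUSES}
    coverage = sum(vals.values())
    if coverage == 0:
        raise ValueError("dyad has zero four-status coverage")
    fractions = {s: vals[s] / coverage for s in STATUSES}
    fractions["hemi_watson_level"] = fractions[HEMI_W]
    fractions["hemi_crick_level"] = fractions[HEMI_C]
    return fractions


def predominant_status(counts, min_count: int = 3) -> str | None:
    """Unique most frequent of the four statuses, or None when coverage is
    below ``min_count`` or the maximum is tied."""
    get = counts.get if isinstance(counts, dict) else lambda k: getattr(counts, k)
    vals = {s: int(get(s) or 0) for s in STATUSES}
    total = sum(vals.values())
    if total < min_count:
        return None
    best = max(vals.values())
    winners = [s for s, v in vals.items() if v == best]
    return winners[0] if len(winners) == 1 else None
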