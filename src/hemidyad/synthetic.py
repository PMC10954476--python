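"""Seeded generators for genomes, designed methylomes, the worked-example
construct, and allele models.

Everything here is synthetic by design: the generators emit truth tables
alongside the data so that every pipeline stage can be scored without any
external download. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import (
    DyadSite,
    Genome,
    Methylome,
    scan_cnnr_sites,
    scan_dyads,
)

_STATUSES = ("unme", "hemiW", "hemiC", "me")

#: Minimum Watson-C spacing between dyads that receive designed statuses.
#: Cut offsets of a dyad span watson_c - 15 .. watson_c + 17; 34 bp is the
#: smallest spacing at which no foreign cut can coincide with a dyad's own
#: cut offsets, which is what makes exact-geometry round-trip calling
#: possible on designed methylomes.
MIN_DESIGN_SEPARATION = 34


@dataclass(frozen=True)
class MethylomeDesign:
    """Target composition of a designed methylome.

    ``status_probs`` is the per-dyad status distribution sampled
    independently for each designed dyad; per-molecule methylation
    probabilities are then deterministic 0/1 per strand, so every molecule
    of a dyad shares the dyad's true state. ``cph_rate`` is the fraction
    of strand-level CNNR cytosines outside dyads that are methylated.
    """

    status_probs: Mapping[str, float] = field(
        default_factory=lambda: {"unme": 0.25, "hemiW": 0.25, "hemiC": 0.25, "me": 0.25}
    )
    cph_rate: float = 0.0
    dyad_kind: str = "CpG"
    min_separation: int = MIN_DESIGN_SEPARATION

    def __post_init__(self) -> None:
        total = sum(self.status_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"status probabilities must sum to 1, got {total}")
        if set(self.status_probs) - set(_STATUSES):
            raise ValueError(f"unknown statuses in {set(self.status_probs)}")
        if not 0 <= self.cph_rate <= 1:
            raise ValueError("cph_rate must lie in [0, 1]")


def make_genome(
    length: int, n_chroms: int = 1, gc: float = 0.5, seed: int | None = 0
) -> Genome:
    """i.i.d. random genome with the stated GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc < 1:
        raise ValueError("gc must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    return Genome(
        {
            f"chr{i + 1}": "".join(bases[rng.choice(4, size=length, p=probs)])
            for i in range(n_chroms)
        }
    )


CONSTRUCT_LENGTH = 146
CONSTRUCT_DYAD_POS = 72


def plant_construct(seed: int = 0) -> tuple[Genome, DyadSite]:
    """The 146 bp worked-example duplex: exactly one resolvable CpG dyad
    with the Watson C at 0-based 72 and no other CNNR site on either strand.

    The background is restricted to A/T (no C or G means no stray CNNR
    context anywhere) and the six bases 70..75 spell T A C G A A — a
    YNCGNR context of the CGNA class on both strands. The downstream R of
    the Watson motif must be A: a G three bases after the dyad C would
    itself complete a second, Crick-strand CNNR motif.
    """
    rng = np.random.default_rng(seed)
    bases = np.where(rng.random(CONSTRUCT_LENGTH) < 0.5, "A", "T")
    bases[70:76] = list("TACGAA")
    genome = Genome({"construct": "".join(bases)})

    sites = scan_cnnr_sites(genome)
    dyads = [d for d in scan_dyads(genome, "CpG") if d.resolvable]
    if len(dyads) != 1 or dyads[0].watson_c != CONSTRUCT_DYAD_POS or len(sites) != 2:
        raise RuntimeError("construct generation violated its own constraints")
    return genome, dyads[0]


def make_construct_methylome(
    genome: Genome,
    dyad: DyadSite,
    watson_methylated: bool = True,
    crick_methylated: bool = True,
) -> Methylome:
    """Methylome for the worked-example construct with the dyad's two
    strands methylated as requested (deterministic 0/1 probabilities)."""
    return Methylome.from_records(
        [
            (
                dyad.chrom,
                dyad.watson_c,
                "+",
                1.0 if watson_methylated else 0.0,
                dyad.kind,
                dyad.r_watson,
            ),
            (
                dyad.chrom,
                dyad.crick_c,
                "-",
                1.0 if crick_methylated else 0.0,
                dyad.kind,
                dyad.r_crick,
            ),
        ]
    )


def make_methylome(
    genome: Genome,
    design: MethylomeDesign = MethylomeDesign(),
    seed: int | None = 0,
) -> tuple[Methylome, pd.DataFrame]:
    """Designed methylome plus its per-dyad truth table.

    Statuses are assigned to resolvable dyads whose cut offsets fall
    inside the contig and that are at least ``design.min_separation``
    apart (greedy left-to-right selection); all other dyads stay
    unmethylated and out of the truth table. CpH (strand-level CNNR)
    methylation, when enabled, is likewise kept clear of designed dyads so
    that foreign cuts cannot fall on a designed dyad's cut offsets.
    """
    rng = np.random.default_rng(seed)
    statuses = list(design.status_probs)
    probs = [design.status_probs[s] for s in statuses]

    all_dyads = scan_dyads(genome, design.dyad_kind)
    dyads_by_chrom: dict[str, list[DyadSite]] = {}
    for dyad in all_dyads:
        dyads_by_chrom.setdefault(dyad.chrom, []).append(dyad)

    records: list[tuple[str, int, str, float, str, str]] = []
    truth_rows = []
    selected_by_chrom: dict[str, list[int]] = {}
    for chrom in genome:
        n = genome.length(chrom)
        selected: list[DyadSite] = []
        last = None
        for dyad in dyads_by_chrom.get(chrom, []):
            if not dyad.resolvable:
                continue
            if dyad.left_cut < 1 or dyad.right_cut > n - 1:
                continue  # a cut at the contig boundary is unobservable
            if last is not None and dyad.watson_c - last < design.min_separation:
                continue
            selected.append(dyad)
            last = dyad.watson_c
        selected_by_chrom[chrom] = [d.watson_c for d in selected]
        for dyad in selected:
            status = statuses[rng.choice(len(statuses), p=probs)]
            watson_p = 1.0 if status in ("me", "hemiW") else 0.0
            crick_p = 1.0 if status in ("me", "hemiC") else 0.0
            records.append(
                (chrom, dyad.watson_c, "+", watson_p, design.dyad_kind, dyad.r_watson)
            )
            records.append(
                (chrom, dyad.crick_c, "-", crick_p, design.dyad_kind, dyad.r_crick)
            )
            truth_rows.append(
                {
                    "chrom": chrom,
                    "watson_c": dyad.watson_c,
                    "crick_c": dyad.crick_c,
                    "kind": dyad.kind,
                    "status": status,
                    "r_watson": dyad.r_watson,
                    "r_crick": dyad.r_crick,
                }
            )

    if design.cph_rate > 0:
        all_dyad_positions = {
            (d.chrom, p) for d in all_dyads for p in (d.watson_c, d.crick_c)
        }
        for chrom, pos, strand in scan_cnnr_sites(genome):
            if (chrom, pos) in all_dyad_positions:
                continue
            anchors = np.asarray(selected_by_chrom.get(chrom, []), dtype=np.int64)
            if anchors.size:
                i = np.searchsorted(anchors, pos)
                near = min(
                    abs(pos - int(anchors[j]))
                    for j in (max(i - 1, 0), min(i, anchors.size - 1))
                )
                if near < design.min_separation:
                    continue
            if rng.random() < design.cph_rate:
                seq = genome[chrom]
                r = seq[pos + 3] if strand == "+" else {"C": "G", "T": "A"}[seq[pos - 3]]
                records.append((chrom, pos, strand, 1.0, "CpH", r))

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "watson_c", "crick_c", "kind", "status", "r_watson", "r_crick"],
    )
    return Methylome.from_records(records), truth


def make_allele_model(
    n_snps: int,
    imprint_fraction: float,
    coverage: int,
    seed: int | None = 0,
    imprint_proportion: float = 0.95,
    spacing: int = 1000,
) -> pd.DataFrame:
    """Per-SNP allele count table with truth flags.

    Imprinted SNPs draw maternal counts at ``imprint_proportion`` (0.95 by
    default), balanced SNPs at 0.5; the ``imprinted`` column records the
    truth for power/type-I scoring.
    """
    if not 0 <= imprint_fraction <= 1:
        raise ValueError("imprint_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    imprinted = rng.random(n_snps) < imprint_fraction
    p = np.where(imprinted, imprint_proportion, 0.5)
    maternal = rng.binomial(coverage, p)
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(n_snps)],
            "chrom": "chr1",
            "pos": np.arange(n_snps) * spacing + spacing // 2,
            "maternal": maternal,
            "paternal": coverage - maternal,
            "imprinted": imprinted,
        }
    )
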