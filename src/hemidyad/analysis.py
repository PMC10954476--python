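"""Downstream statistics on dyad calls.

Covers the orientation-aware analyses around TF motifs (cluster
classification by the predominant status of a designated dyad,
motif-strand-relative hemi-methylation profiles, mean signal annotation
over motif-centered windows) and allele-specific methylation/binding
testing (per-SNP binomial test against a balanced 0.5 proportion with
Benjamini-Hochberg FDR control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .caller import FragmentRecord, predominant_status

#: Cluster semantics: 1 = unmethylated, 2 = hemi-methylated on the motif
#: strand, 3 = hemi-methylated on the opposite strand, 4 = fully methylated.
CLUSTER_OF_STATUS_FORWARD = {"unme": 1, "hemiW": 2, "hemiC": 3, "me": 4}
CLUSTER_OF_STATUS_REVERSE = {"unme": 1, "hemiW": 3, "hemiC": 2, "me": 4}


@dataclass(frozen=True)
class RegionSpec:
    """An oriented region (e.g. a 19 bp TF motif occurrence).

    ``orientation`` is the motif strand: '+' when the motif reads on
    Watson, '-' when on Crick. ``offsets`` are designated dyad positions
    counted along the motif strand from the motif's first base.
    """

    chrom: str
    start: int
    end: int
    orientation: str = "+"
    offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        if any(not 0 <= o < self.end - self.start for o in self.offsets):
            raise ValueError("offsets must fall inside the region")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def genomic_offset_position(self, offset: int) -> int:
        """Watson coordinate of motif-strand position ``offset``."""
        if self.orientation == "+":
            return self.start + offset
        return self.end - 1 - offset


@dataclass
class ClusterAssignment:
    region: RegionSpec
    offset: int
    cluster: int | None
    status: str | None
    reason: str | None = None  # why excluded, when cluster is None


@dataclass(frozen=True)
class AlleleCounts:
    snp_id: str
    chrom: str
    pos: int
    maternal: int
    paternal: int

    @property
    def coverage(self) -> int:
        return self.maternal + self.paternal


@dataclass
class BiasCall:
    snp_id: str
    p_value: float
    q_value: float
    biased: bool


def assign_region_cluster(
    region: RegionSpec,
    dyad_calls: pd.DataFrame,
    offset: int,
    min_count: int = 3,
) -> ClusterAssignment:
    """Cluster 1-4 assignment from the predominant status of the dyad at a
    designated motif offset; hemi clusters are motif-strand-relative, so a
    '-' region swaps the roles of hemiW and hemiC."""
    pos = region.genomic_offset_position(offset)
    hit = dyad_calls[
        (dyad_calls["chrom"] == region.chrom)
        & ((dyad_calls["watson_c"] == pos) | (dyad_calls["crick_c"] == pos))
    ]
    if hit.empty:
        return ClusterAssignment(region, offset, None, None, reason="no_dyad")
    row = hit.iloc[0]
    status = predominant_status(
        {s: int(row[s]) for s in ("unme", "hemiW", "hemiC", "me")},
        min_count=min_count,
    )
    if status is None:
        return ClusterAssignment(region, offset, None, None, reason="indeterminate")
    mapping = (
        CLUSTER_OF_STATUS_FORWARD
        if region.orientation == "+"
        else CLUSTER_OF_STATUS_REVERSE
    )
    return ClusterAssignment(region, offset, mapping[status], status)


def oriented_hemi_profile(
    dyad_calls: pd.DataFrame,
    regions: Sequence[RegionSpec],
    flank: int,
) -> pd.DataFrame:
    """Mean motif-strand (``same``) and opposite-strand (``oppo``)
    hemi-methylation levels binned by signed offset from region centers.

    Offsets are measured on the motif strand: for a '-' region the sign
    flips and hemiW/hemiC swap roles, so the profile is comparable across
    orientations. Dyads below coverage (coverage == 0 or excluded) are
    skipped. Returns a frame indexed by offset with ``same``, ``oppo`` and
    the number of contributing (region, dyad) pairs.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    covered = dyad_calls[dyad_calls["coverage"] > 0]
    same_sum: dict[int, float] = {}
    oppo_sum: dict[int, float] = {}
    n_obs: dict[int, int] = {}
    for region in regions:
        center = region.center
        window = covered[
            (covered["chrom"] == region.chrom)
            & (covered["watson_c"] >= center - flank)
            & (covered["watson_c"] <= center + flank)
        ]
        for row in window.itertuples():
            cov = row.coverage
            hemi_w = row.hemiW / cov
            hemi_c = row.hemiC / cov
            if region.orientation == "+":
                offset, same, oppo = row.watson_c - center, hemi_w, hemi_c
            else:
                offset, same, oppo = center - row.watson_c, hemi_c, hemi_w
            same_sum[offset] = same_sum.get(offset, 0.0) + same
            oppo_sum[offset] = oppo_sum.get(offset, 0.0) + oppo
            n_obs[offset] = n_obs.get(offset, 0) + 1
    offsets = sorted(n_obs)
    return pd.DataFrame(
        {
            "offset": offsets,
            "same": [same_sum[o] / n_obs[o] for o in offsets],
            "oppo": [oppo_sum[o] / n_obs[o] for o in offsets],
            "n": [n_obs[o] for o in offsets],
        }
    ).set_index("offset")


def signal_over_regions(
    track: Mapping[str, np.ndarray],
    regions: Sequence[RegionSpec],
    half_window: int,
) -> pd.Series:
    """Mean per-base signal over the ``2 * half_window + 1`` bases centered
    on each region (e.g. mean RPM in a 100 bp window around a motif
    center). Errors when a window leaves the track."""
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    means = []
    for region in regions:
        values = track[region.chrom]
        lo = region.center - half_window
        hi = region.center + half_window + 1
        if lo < 0 or hi > len(values):
            raise IndexError(
                f"window [{lo}, {hi}) outside track for {region.chrom}"
            )
        means.append(float(np.mean(values[lo:hi])))
    return pd.Series(means, dtype=float)


def count_alleles(
    fragments: Sequence[FragmentRecord],
    snps: pd.DataFrame,
) -> pd.DataFrame:
    """Per-SNP maternal/paternal fragment counts from allele-tagged
    fragments overlapping each SNP position.

    ``snps`` needs columns ``snp_id``, ``chrom``, ``pos``. Fragments with
    no allele tag (or an unknown tag) are ignored.
    """
    rows = []
    for snp in snps.itertuples():
        maternal = paternal = 0
        for f in fragments:
            if f.chrom == snp.chrom and f.start <= snp.pos < f.end:
                if f.allele == "maternal":
                    maternal += 1
                elif f.allele == "paternal":
                    paternal += 1
        rows.append(
            {
                "snp_id": snp.snp_id,
                "chrom": snp.chrom,
                "pos": snp.pos,
                "maternal": maternal,
                "paternal": paternal,
            }
        )
    return pd.DataFrame(rows)


def binomial_bias_test(
    allele_counts: pd.DataFrame,
    min_coverage: int = 11,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Two-sided binomial test of allelic balance per SNP.

    SNPs with coverage >= ``min_coverage`` (i.e. strictly larger than 10
    at the default) are tested against a 0.5 proportion; p-values are
    adjusted across tested SNPs (Benjamini-Hochberg by default) and a SNP
    is flagged biased iff its adjusted q-value is below ``alpha``.
    """
    out = allele_counts.copy()
    out["coverage"] = out["maternal"] + out["paternal"]
    out["tested"] = out["coverage"] >= min_coverage
    pvals = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples()):
        if row.tested:
            pvals[i] = stats.binomtest(
                int(row.maternal), int(row.coverage), 0.5, alternative="two-sided"
            ).pvalue
    out["p"] = pvals
    out["q"] = np.nan
    out["biased"] = False
    tested = out["tested"].to_numpy()
    if tested.any():
        _, qvals, _, _ = multipletests(pvals[tested], alpha=alpha, method=method)
        out.loc[tested, "q"] = qvals
        # bias-SNP rule is a strict inequality on the adjusted FDR
        out.loc[tested, "biased"] = qvals < alpha
    return out


def flag_allele_specific_regions(
    regions: Sequence[RegionSpec],
    bias_calls: pd.DataFrame,
) -> list[bool]:
    """A region is allele-specific iff it contains at least one bias-SNP."""
    biased = bias_calls[bias_calls["biased"]]
    flags = []
    for region in regions:
        hit = biased[
            (biased["chrom"] == region.chrom)
            & (biased["pos"] >= region.start)
            & (biased["pos"] < region.end)
        ]
        flags.append(not hit.empty)
    return flags
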