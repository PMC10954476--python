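"""Efficiency correction of observed dyad status counts.

Incomplete digestion makes a fully methylated dyad masquerade as hemi- or
unmethylated: with per-strand cut efficiencies E_W and E_C and a 32-mer
purification efficiency E_pu, the expected (observed) counts given true
counts (M, W, C, U) are

    M_exp = M * E_W * E_C * E_pu
    W_exp = W + M * E_W * (1 - E_C)
    C_exp = C + M * (1 - E_W) * E_C
    U_exp = U + M * (1 - E_W) * (1 - E_C)

and the correction inverts this map. The printed form above carries no
single-cut efficiency on the true hemi counts; an ``extended`` variant
that additionally scales W and C by their single-cut efficiency is
available but off by default (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import DyadSite

_TOL = 1e-12


@dataclass(frozen=True)
class EfficiencyParams:
    e_watson: float
    e_crick: float
    e_pu: float = 1.0

    def __post_init__(self) -> None:
        for name in ("e_watson", "e_crick", "e_pu"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class DyadCountVector:
    """Counts (me, hemiW, hemiC, unme) for one dyad; floats are allowed so
    that expected and corrected values round-trip exactly."""

    m: float
    w: float
    c: float
    u: float

    @property
    def total(self) -> float:
        return self.m + self.w + self.c + self.u

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.m, self.w, self.c, self.u)


def forward_expected(
    real: DyadCountVector, params: EfficiencyParams, extended: bool = False
) -> DyadCountVector:
    """Expected observed counts given true counts and efficiencies."""
    if min(real.as_tuple()) < 0:
        raise ValueError("true counts must be non-negative")
    ew, ec, epu = params.e_watson, params.e_crick, params.e_pu
    m = real.m * ew * ec * epu
    leak_w = real.m * ew * (1 - ec)
    leak_c = real.m * (1 - ew) * ec
    leak_u = real.m * (1 - ew) * (1 - ec)
    if extended:
        w = real.w * ew + leak_w
        c = real.c * ec + leak_c
        u = real.u + real.w * (1 - ew) + real.c * (1 - ec) + leak_u
    else:
        w = real.w + leak_w
        c = real.c + leak_c
        u = real.u + leak_u
    return DyadCountVector(m=m, w=w, c=c, u=u)


def invert_observed(
    observed: DyadCountVector,
    params: EfficiencyParams,
    extended: bool = False,
    clamp: bool = True,
) -> tuple[DyadCountVector, bool]:
    """Estimate true counts from observed counts (algebraic inversion).

    Negative estimates — possible at small counts — are clamped to 0 and
    flagged via the returned boolean. Requires a positive combined
    efficiency for the fully methylated class.
    """
    ew, ec, epu = params.e_watson, params.e_crick, params.e_pu
    denom = ew * ec * epu
    if denom <= 0:
        raise ZeroDivisionError("e_watson * e_crick * e_pu must be positive to invert")
    m_hat = observed.m / denom
    if extended:
        if ew <= 0 or ec <= 0:
            raise ZeroDivisionError("extended inversion needs positive e_watson and e_crick")
        w_hat = (observed.w - m_hat * ew * (1 - ec)) / ew
        c_hat = (observed.c - m_hat * (1 - ew) * ec) / ec
        u_hat = (
            observed.u
            - w_hat * (1 - ew)
            - c_hat * (1 - ec)
            - m_hat * (1 - ew) * (1 - ec)
        )
    else:
        w_hat = observed.w - m_hat * ew * (1 - ec)
        c_hat = observed.c - m_hat * (1 - ew) * ec
        u_hat = observed.u - m_hat * (1 - ew) * (1 - ec)
    est = DyadCountVector(m=m_hat, w=w_hat, c=c_hat, u=u_hat)
    clamped = any(v < -_TOL for v in est.as_tuple())
    if clamp:
        est = DyadCountVector(*(max(v, 0.0) for v in est.as_tuple()))
    return est, clamped


def assign_efficiencies(
    dyad: DyadSite,
    efficiency_by_r: Mapping[str, float] | None = None,
    e_pu: float = 1.0,
) -> EfficiencyParams:
    """Per-dyad efficiencies from each strand's downstream R base.

    CGNG-class strands cut at ~97%, CGNA-class at ~80% by default.
    """
    if efficiency_by_r is None:
        efficiency_by_r = {"G": 0.97, "A": 0.80}
    if not dyad.resolvable:
        raise ValueError("efficiencies are defined only for resolvable dyads")
    try:
        ew = efficiency_by_r[dyad.r_watson]
        ec = efficiency_by_r[dyad.r_crick]
    except KeyError as exc:
        raise ValueError(f"no efficiency for R base {exc}") from exc
    return EfficiencyParams(e_watson=ew, e_crick=ec, e_pu=e_pu)


def normalize_table(
    calls: pd.DataFrame,
    efficiency_by_r: Mapping[str, float] | None = None,
    e_pu: float = 1.0,
    extended: bool = False,
) -> pd.DataFrame:
    """Add corrected-count columns to a dyad call table.

    Normalization is per dyad, using that dyad's R bases (columns
    ``r_watson`` / ``r_crick``); adds ``me_corr``, ``hemiW_corr``,
    ``hemiC_corr``, ``unme_corr`` and a ``norm_clamped`` flag.
    """
    if efficiency_by_r is None:
        efficiency_by_r = {"G": 0.97, "A": 0.80}
    out = calls.copy()
    corr = np.full((len(out), 4), np.nan)
    flags = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples()):
        params = EfficiencyParams(
            e_watson=efficiency_by_r[row.r_watson],
            e_crick=efficiency_by_r[row.r_crick],
            e_pu=e_pu,
        )
        observed = DyadCountVector(
            m=row.me, w=row.hemiW, c=row.hemiC, u=row.unme
        )
        est, clamped = invert_observed(observed, params, extended=extended)
        corr[i] = est.as_tuple()
        flags[i] = clamped
    out["me_corr"], out["hemiW_corr"], out["hemiC_corr"], out["unme_corr"] = corr.T
    out["norm_clamped"] = flags
    return out
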