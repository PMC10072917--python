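"""Fractionalization index of cause-of-death distributions.

F = 1 - sum_i p_i^2 is the probability that two randomly chosen deaths are
attributable to different causes: 0 when a single cause accounts for all
deaths, and (k-1)/k when deaths are spread uniformly over k causes (20/21
~ 0.952 for the 21-cause level-2 scheme).  The age-structure-corrected
variant takes the cause shares from life-table deaths rather than observed
death counts, so populations with different age pyramids are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .gbd_io import CauseScheme
from .lifetable import CauseDeathMatrix

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class CauseProportions:
    """Probability shares over an ordered cause list."""

    p: np.ndarray
    scheme: CauseScheme | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if self.scheme is not None and len(p) != self.scheme.k:
            raise ValueError("length of p must equal scheme.k")


@dataclass(frozen=True)
class DiversityResult:
    F: float
    variant: str  # "lifetable_adjusted" | "observed"
    location: str = ""
    sex: str = ""
    year: int = 0


def _check_proportions(p: np.ndarray, renormalize: bool) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError("proportions must be finite and non-negative")
    s = p.sum()
    if renormalize:
        if s <= 0:
            raise ValueError("cannot renormalize an all-zero vector")
        return p / s
    if abs(s - 1.0) > _SUM_TOL:
        raise ValueError(f"proportions sum to {s!r}, not 1")
    return p


def fractionalization(p, *, renormalize: bool = False) -> float:
    """F = 1 - sum p_i^2 for a probability vector of cause shares."""
    if isinstance(p, CauseProportions):
        p = p.p
    p = _check_proportions(p, renormalize)
    return float(1.0 - np.dot(p, p))


def fractionalization_observed(death_counts) -> float:
    """F on observed death counts (no age-structure correction)."""
    c = np.asarray(death_counts, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("counts must be finite and non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts are all zero")
    return fractionalization(c / total)


def cause_proportions_from_lifetable(
    cdm: CauseDeathMatrix, scheme: CauseScheme | None = None
) -> CauseProportions:
    """Cause shares of life-table deaths: p_c = sum_x d(x,c) / sum d."""
    total = cdm.total
    if total <= 0:
        raise ValueError("cause-death matrix is all zero")
    return CauseProportions(p=cdm.d_xc.sum(axis=0) / total, scheme=scheme)


def regroup(
    p: CauseProportions,
    mapping: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Aggregate cause shares to a coarser grouping.

    ``mapping`` sends every cause of ``p.scheme`` to a coarser label; when
    omitted, the scheme's level-1 grouping is used.  Returns the merged
    share vector and the group labels (in first-appearance order).  Merging
    can only decrease F.
    """
    if p.scheme is None:
        raise ValueError("regroup requires CauseProportions with a scheme")
    mapping = dict(mapping) if mapping is not None else dict(p.scheme.level1_of)
    missing = [c for c in p.scheme.causes if c not in mapping]
    if missing:
        raise ValueError(f"mapping missing causes: {missing[:5]}")
    groups: dict[str, float] = {}
    for share, cause in zip(p.p, p.scheme.causes):
        groups[mapping[cause]] = groups.get(mapping[cause], 0.0) + float(share)
    return np.array(list(groups.values())), tuple(groups)


def sex_gap(F_male: float, F_female: float) -> float:
    """Signed male-female difference in the fractionalization index."""
    return float(F_male) - float(F_female)
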