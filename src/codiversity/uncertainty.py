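"""Monte-Carlo propagation of GBD-style uncertainty intervals.

Each rate cell carries a point estimate with asymmetric 95% bounds.
Draws are sampled per cell from a two-piece normal centred at the point
estimate — sd_low = (val - lower)/1.96 below it, sd_high = (upper - val)/1.96
above it — truncated at zero, independently across cells (cross-cell
correlation of the underlying GBD posterior is not recoverable from the
intervals alone, and is explicitly not modelled).  Envelopes are the
empirical 2.5th/97.5th percentiles of the statistic over draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .gbd_io import PanelSlice

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class UncertaintyEnvelope:
    """Point estimate with an empirical 95% Monte-Carlo interval."""

    point: float
    lower: float
    upper: float
    n_draws: int
    seed: int

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _panel_key(s: PanelSlice) -> int:
    """Stable integer key of a slice's data, for order-invariant seeding."""
    h = hashlib.blake2b(digest_size=8)
    h.update(np.ascontiguousarray(s.rates).tobytes())
    h.update(np.ascontiguousarray(s.lower).tobytes())
    h.update(np.ascontiguousarray(s.upper).tobytes())
    return int.from_bytes(h.digest(), "little")


def _draw_cells(
    rng: np.random.Generator,
    val: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    n_draws: int,
    distribution: str,
) -> np.ndarray:
    """(n_draws, *val.shape) perturbed values, truncated at 0."""
    z = rng.standard_normal(size=(n_draws,) + val.shape)
    if distribution == "two_piece_normal":
        sd = np.where(z < 0, (val - lower) / Z95, (upper - val) / Z95)
    elif distribution == "symmetric_normal":
        sd = (upper - lower) / (2.0 * Z95)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return np.clip(val + z * sd, 0.0, None)


def sample_rates(
    panel: PanelSlice,
    n_draws: int,
    seed: int,
    *,
    distribution: str = "two_piece_normal",
) -> Iterator[PanelSlice]:
    """Yield ``n_draws`` independently perturbed copies of a panel slice.

    Deterministic given (seed, n_draws); degenerate cells (lower = val =
    upper) are reproduced exactly.
    """
    rng = np.random.default_rng(seed)
    draws = _draw_cells(rng, panel.rates, panel.lower, panel.upper, n_draws, distribution)
    for k in range(n_draws):
        yield PanelSlice(
            rates=draws[k], lower=panel.lower, upper=panel.upper,
            population=panel.population, location=panel.location,
            region=panel.region, sex=panel.sex, year=panel.year,
        )


def _statistic_draws(
    statistic_fn: Callable[[np.ndarray], float],
    panel: PanelSlice,
    n_draws: int,
    seed,
    distribution: str,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    draws = _draw_cells(rng, panel.rates, panel.lower, panel.upper, n_draws, distribution)
    out = np.empty(n_draws)
    for k in range(n_draws):
        try:
            out[k] = statistic_fn(draws[k])
        except Exception as exc:  # noqa: BLE001 - report the failing draw
            raise RuntimeError(f"statistic failed on draw {k}") from exc
    return out


def envelope(
    statistic_fn: Callable[[np.ndarray], float],
    panel: PanelSlice,
    n_draws: int = 1000,
    seed: int = 0,
    *,
    distribution: str = "two_piece_normal",
) -> UncertaintyEnvelope:
    """95% Monte-Carlo envelope of a statistic of the rate grid.

    ``statistic_fn`` maps a perturbed (n_ages, k) rate array to a scalar;
    the point estimate is the statistic on the unperturbed rates.
    """
    point = float(statistic_fn(panel.rates))
    values = _statistic_draws(statistic_fn, panel, n_draws, seed, distribution)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return UncertaintyEnvelope(point=point, lower=float(lo), upper=float(hi),
                               n_draws=n_draws, seed=seed)


def significant_difference(
    statistic_fn: Callable[[np.ndarray], float],
    panel_a: PanelSlice,
    panel_b: PanelSlice,
    n_draws: int = 1000,
    seed: int = 0,
    level: float = 0.05,
    *,
    distribution: str = "two_piece_normal",
) -> tuple[bool, UncertaintyEnvelope]:
    """Flag whether statistic(b) - statistic(a) differs from 0.

    Draw-wise differences are formed from independent draw streams (one
    per panel, seeded from ``seed`` and a content hash of the panel, so
    the result is invariant under swapping the arguments); the difference
    is significant iff its central (1 - level) percentile interval
    excludes 0.
    """
    diffs = None
    for sign, p in ((1.0, panel_b), (-1.0, panel_a)):
        child = np.random.SeedSequence([int(seed), _panel_key(p)])
        vals = _statistic_draws(statistic_fn, p, n_draws, child, distribution)
        diffs = sign * vals if diffs is None else diffs + sign * vals
    lo, hi = np.percentile(diffs, [100 * level / 2, 100 * (1 - level / 2)])
    point = float(statistic_fn(panel_b.rates) - statistic_fn(panel_a.rates))
    env = UncertaintyEnvelope(point=point, lower=float(lo), upper=float(hi),
                              n_draws=n_draws, seed=seed)
    significant = bool(lo > 0 or hi < 0)
    return significant, env
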