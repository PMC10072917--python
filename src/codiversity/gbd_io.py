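"""Reading, writing and validating GBD-results-style mortality extracts.

The canonical in-memory object is :class:`MortalityPanel`: a long-format
table of cause- and age-specific mortality rates (deaths per person-year)
with 95% uncertainty bounds and population counts, covering a full
``age group x cause`` grid for every ``(location, sex, year)`` slice.

The default cause scheme is the GBD level-2 list: 21 mutually exclusive
causes nested in the three level-1 groups (communicable/maternal/neonatal/
nutritional diseases; non-communicable diseases; injuries).  The default
age scheme is the GBD grouping ``<1, 1-4, 5-9, ..., 90-94, 95+``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("codiversity")
if not logger.handlers:  # structured logging to stderr, configured once
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

CMNN = "Communicable, maternal, neonatal, and nutritional diseases"
NCD = "Non-communicable diseases"
INJ = "Injuries"

#: GBD level-2 causes and their level-1 group (21 causes, 3 groups).
DEFAULT_LEVEL2: tuple[tuple[str, str], ...] = (
    ("Cardiovascular diseases", NCD),
    ("Neoplasms", NCD),
    ("Diabetes and kidney diseases", NCD),
    ("Chronic respiratory diseases", NCD),
    ("Mental disorders", NCD),
    ("Neurological disorders", NCD),
    ("Substance use disorders", NCD),
    ("Digestive diseases", NCD),
    ("Musculoskeletal disorders", NCD),
    ("Skin and subcutaneous diseases", NCD),
    ("Other non-communicable diseases", NCD),
    ("Neglected tropical diseases and malaria", CMNN),
    ("HIV/AIDS and sexually transmitted infections", CMNN),
    ("Respiratory infections and tuberculosis", CMNN),
    ("Enteric infections", CMNN),
    ("Other infectious diseases", CMNN),
    ("Maternal and neonatal disorders", CMNN),
    ("Nutritional deficiencies", CMNN),
    ("Transport injuries", INJ),
    ("Self-harm and interpersonal violence", INJ),
    ("Unintentional injuries", INJ),
)

#: The seven GBD super-regions used for regional aggregation.
DEFAULT_REGIONS: tuple[str, ...] = ("SEO", "CEC", "HI", "LAC", "MENA", "SA", "SSA")


class PanelValidationError(ValueError):
    """Raised when a panel violates the grid or bound invariants."""


@dataclass(frozen=True)
class CauseScheme:
    """An ordered list of mutually exclusive causes with a level-1 grouping."""

    causes: tuple[str, ...]
    level1_of: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("cause labels must be unique")
        missing = [c for c in self.causes if c not in self.level1_of]
        if missing:
            raise ValueError(f"causes without a level-1 group: {missing}")

    @property
    def k(self) -> int:
        return len(self.causes)

    @property
    def level1_groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.causes:
            seen.setdefault(self.level1_of[c], None)
        return tuple(seen)

    def index_of(self, cause: str) -> int:
        return self.causes.index(cause)

    @classmethod
    def default(cls) -> "CauseScheme":
        return cls(
            causes=tuple(c for c, _ in DEFAULT_LEVEL2),
            level1_of={c: g for c, g in DEFAULT_LEVEL2},
        )


@dataclass(frozen=True)
class AgeScheme:
    """Ascending age-group lower bounds; the terminal interval is open."""

    lower_bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        lb = np.asarray(self.lower_bounds, dtype=float)
        if lb.size < 2:
            raise ValueError("need at least two age groups")
        if not np.all(np.diff(lb) > 0):
            raise ValueError("lower bounds must be strictly ascending")

    @property
    def n(self) -> int:
        return len(self.lower_bounds)

    @property
    def widths(self) -> np.ndarray:
        """Interval widths in years; the open terminal interval is inf."""
        lb = np.asarray(self.lower_bounds, dtype=float)
        return np.append(np.diff(lb), np.inf)

    def labels(self) -> list[str]:
        out = []
        lb = self.lower_bounds
        for i, lo in enumerate(lb[:-1]):
            hi = lb[i + 1]
            if lo == 0 and hi == 1:
                out.append("<1")
            else:
                out.append(f"{lo:g} to {hi - 1:g}")
        out.append(f"{lb[-1]:g} plus")
        return out

    @classmethod
    def gbd_default(cls) -> "AgeScheme":
        return cls(lower_bounds=(0.0, 1.0) + tuple(float(a) for a in range(5, 100, 5)))


_AGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:(?:to|-|–)\s*(\d+(?:\.\d+)?))?\s*(?:(plus|\+))?\s*$")


def normalize_age_label(label: str) -> float:
    """Map a GBD age-group label to its lower bound in years.

    Accepts both the GBD-results dialect ("<1", "1 to 4", "95 plus") and
    the compact shorthand ("0-1", "1-5", "95+").
    """
    s = str(label).strip().lower().replace("years", "").strip()
    if s in ("<1", "< 1", "under 1", "0"):
        return 0.0
    m = _AGE_RE.match(s)
    if not m:
        raise ValueError(f"unrecognized age-group label: {label!r}")
    return float(m.group(1))


@dataclass(frozen=True)
class PanelSlice:
    """One (location, sex, year) slice on the age x cause grid (arrays)."""

    rates: np.ndarray  # (n_ages, k) deaths per person-year
    lower: np.ndarray  # (n_ages, k)
    upper: np.ndarray  # (n_ages, k)
    population: np.ndarray  # (n_ages,) persons
    location: str = ""
    region: str = ""
    sex: str = ""
    year: int = 0


@dataclass
class MortalityPanel:
    """Long-format mortality rates with uncertainty bounds and population.

    ``data`` columns: location, region, sex, year, age_index, cause, rate,
    lower, upper, population.  Every (location, sex, year) slice covers the
    full age x cause grid of the attached schemes.
    """

    data: pd.DataFrame
    cause_scheme: CauseScheme
    age_scheme: AgeScheme

    COLUMNS = ("location", "region", "sex", "year", "age_index", "cause",
               "rate", "lower", "upper", "population")

    def validate(self) -> None:
        df = self.data
        for col in self.COLUMNS:
            if col not in df.columns:
                raise PanelValidationError(f"missing column {col!r}")
        bad = df["cause"][~df["cause"].isin(self.cause_scheme.causes)].unique()
        if len(bad):
            raise PanelValidationError(f"unknown causes: {list(bad)[:5]}")
        if df["age_index"].min() < 0 or df["age_index"].max() >= self.age_scheme.n:
            raise PanelValidationError("age_index out of range for the age scheme")
        neg = df[(df[["rate", "lower", "upper", "population"]] < 0).any(axis=1)]
        if len(neg):
            raise PanelValidationError(f"negative values in {len(neg)} records")
        viol = df[(df["lower"] > df["rate"] + 1e-12) | (df["rate"] > df["upper"] + 1e-12)]
        if len(viol):
            first = viol.iloc[0]
            raise PanelValidationError(
                f"{len(viol)} records violate lower <= rate <= upper; first at "
                f"({first['location']}, {first['sex']}, {first['year']}, "
                f"age_index {first['age_index']}, {first['cause']})"
            )
        self._validate_grid(df)

    def _validate_grid(self, df: pd.DataFrame) -> None:
        n_cells = self.age_scheme.n * self.cause_scheme.k
        full = pd.MultiIndex.from_product(
            [range(self.age_scheme.n), self.cause_scheme.causes],
            names=["age_index", "cause"],
        )
        gaps: list[tuple] = []
        for key, grp in df.groupby(["location", "sex", "year"], sort=False):
            if len(grp) == n_cells:
                idx = pd.MultiIndex.from_frame(grp[["age_index", "cause"]])
                if not idx.has_duplicates:
                    continue
            present = pd.MultiIndex.from_frame(grp[["age_index", "cause"]])
            for age_idx, cause in full.difference(present)[:5]:
                gaps.append((*key, self.age_scheme.labels()[age_idx], cause))
            dup = present[present.duplicated()]
            if len(dup):
                raise PanelValidationError(f"duplicate cells in slice {key}: {list(dup[:5])}")
        if gaps:
            raise PanelValidationError(
                f"{len(gaps)}+ missing grid cells; first: {gaps[:5]}"
            )

    def slice_keys(self) -> list[tuple[str, str, int]]:
        return list(
            self.data[["location", "sex", "year"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )

    def _indexed(self) -> pd.DataFrame:
        # lazy (location, sex, year) index: slice lookups are frequent
        cached = getattr(self, "_ix", None)
        if cached is None or len(cached) != len(self.data):
            cached = self.data.set_index(["location", "sex", "year"]).sort_index()
            object.__setattr__(self, "_ix", cached)
        return cached

    def get_slice(self, location: str, sex: str, year: int) -> PanelSlice:
        try:
            grp = self._indexed().loc[(location, sex, year)]
        except KeyError:
            raise KeyError((location, sex, year)) from None
        grp = grp.copy()
        grp["location"], grp["sex"], grp["year"] = location, sex, int(year)
        return self._slice_from_group(grp)

    def iter_slices(self) -> Iterator[PanelSlice]:
        for _, grp in self.data.groupby(["location", "sex", "year"], sort=False):
            yield self._slice_from_group(grp)

    def _slice_from_group(self, grp: pd.DataFrame) -> PanelSlice:
        A, k = self.age_scheme.n, self.cause_scheme.k
        cause_idx = grp["cause"].map({c: j for j, c in enumerate(self.cause_scheme.causes)})
        rates = np.zeros((A, k))
        lower = np.zeros((A, k))
        upper = np.zeros((A, k))
        pop = np.zeros(A)
        ai = grp["age_index"].to_numpy()
        ci = cause_idx.to_numpy()
        rates[ai, ci] = grp["rate"].to_numpy()
        lower[ai, ci] = grp["lower"].to_numpy()
        upper[ai, ci] = grp["upper"].to_numpy()
        pop[ai] = grp["population"].to_numpy()
        first = grp.iloc[0]
        return PanelSlice(rates=rates, lower=lower, upper=upper, population=pop,
                          location=str(first["location"]), region=str(first.get("region", "")),
                          sex=str(first["sex"]), year=int(first["year"]))


def read_panel(
    path: str | Path,
    cause_scheme: CauseScheme | None = None,
    age_scheme: AgeScheme | None = None,
    *,
    region_of: Mapping[str, str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> MortalityPanel:
    """Read a GBD-results-style CSV into a validated :class:`MortalityPanel`.

    The CSV needs columns for location, sex, year, age-group label, cause
    label, point estimate ``val`` with ``lower``/``upper`` bounds, and
    ``population``.  A ``metric`` column of ``Deaths`` (counts) is converted
    to rates on read by dividing by population; the canonical internal unit
    is deaths per person-year.  ``column_map`` renames non-standard headers.
    """
    cause_scheme = cause_scheme or CauseScheme.default()
    age_scheme = age_scheme or AgeScheme.gbd_default()
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["location", "sex", "year", "age", "cause", "val", "lower", "upper", "population"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelValidationError(f"CSV missing columns: {missing}")

    lowers = {normalize_age_label(lbl): lbl for lbl in df["age"].unique()}
    bound_to_index = {lb: i for i, lb in enumerate(age_scheme.lower_bounds)}
    unknown = [lbl for lb, lbl in lowers.items() if lb not in bound_to_index]
    if unknown:
        raise PanelValidationError(f"age labels not in scheme: {unknown}")
    df["age_index"] = df["age"].map(lambda s: bound_to_index[normalize_age_label(s)])

    unknown_causes = set(df["cause"].unique()) - set(cause_scheme.causes)
    if unknown_causes:
        raise PanelValidationError(f"unknown causes: {sorted(unknown_causes)[:5]}")

    if "metric" in df.columns and (df["metric"].str.lower() == "deaths").any():
        is_count = df["metric"].str.lower() == "deaths"
        pop = df.loc[is_count, "population"]
        if (pop <= 0).any():
            raise PanelValidationError("death counts require positive population")
        for col in ("val", "lower", "upper"):
            df.loc[is_count, col] = df.loc[is_count, col] / pop

    if "region" not in df.columns:
        if region_of is not None:
            df["region"] = df["location"].map(dict(region_of))
            if df["region"].isna().any():
                lost = df.loc[df["region"].isna(), "location"].unique()
                raise PanelValidationError(f"locations without region: {list(lost)[:5]}")
        else:
            df["region"] = df["location"]

    out = df.rename(columns={"val": "rate"})[list(MortalityPanel.COLUMNS)].copy()
    out["year"] = out["year"].astype(int)
    panel = MortalityPanel(out, cause_scheme, age_scheme)
    panel.validate()
    logger.info("read panel: %d records, %d slices", len(out), len(panel.slice_keys()))
    return panel


def write_panel(panel: MortalityPanel, path: str | Path) -> None:
    """Write a panel back to the CSV dialect accepted by :func:`read_panel`."""
    df = panel.data.copy()
    labels = panel.age_scheme.labels()
    df["age"] = df["age_index"].map(lambda i: labels[i])
    df = df.rename(columns={"rate": "val"})
    cols = ["location", "region", "sex", "year", "age", "cause", "val", "lower", "upper", "population"]
    df[cols].to_csv(path, index=False)


def write_results_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write pipeline outputs (levels / decomposition / LOESS / trajectories) as CSVs.

    ``results`` maps a table name to a DataFrame; empty frames produce
    header-only files.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in results.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
        logger.info("wrote %s (%d rows)", p, len(df))
    return written
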