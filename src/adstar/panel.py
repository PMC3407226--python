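"""District-day analysis panels and fixed-effect design matrices.

The panel joins daily visit counts per district and age group with a citywide
temperature series, per-district population denominators, the district
adjacency graph and a lag assignment.  The fixed-effect design holds the
day-of-week (DOW) indicator block (Monday..Saturday, Sunday reference), the
dust-storm-lag-index (DSLI) indicator block (lag0..lag7, all other days
reference) and the log-population offset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .calendar_ads import LAG_CLASSES, N_LAGS, REFERENCE_CLASS, LagAssignment

__all__ = ["PanelDataset", "DesignMatrices", "build_panel", "build_design",
           "lag_stratified_means"]

logger = logging.getLogger(__name__)

DOW_NAMES = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday")
DSLI_NAMES = tuple(f"lag{k}" for k in range(N_LAGS + 1))


class PanelValidationError(ValueError):
    """The panel inputs are incomplete or inconsistent."""


@dataclass
class PanelDataset:
    """One age group's district-day records plus spatial/denominator context.

    ``records`` has one row per (date, district) with columns
    ``date, district, visits, temperature``; rows are sorted by
    (date, district).  ``populations`` maps district -> positive integer,
    ``graph`` is the undirected district adjacency graph, ``lag`` the study
    window's lag assignment, ``age_group`` a label.
    """

    records: pd.DataFrame = field(repr=False)
    populations: dict[str, int]
    graph: nx.Graph = field(repr=False)
    lag: LagAssignment = field(repr=False)
    age_group: str = "all"

    @property
    def n_obs(self) -> int:
        return len(self.records)

    @property
    def districts(self) -> list[str]:
        return sorted(self.populations)

    def counts(self) -> np.ndarray:
        return self.records["visits"].to_numpy(dtype=float)


@dataclass(frozen=True)
class DesignMatrices:
    """Fixed-effect blocks and covariate vectors aligned with the panel rows."""

    dow: sp.csr_matrix = field(repr=False)          # n x 6, Sunday reference
    dsli: sp.csr_matrix = field(repr=False)         # n x 8, "other days" reference
    offset: np.ndarray = field(repr=False)          # log population
    time_index: np.ndarray = field(repr=False)      # days since study_start
    temperature: np.ndarray = field(repr=False)
    district: np.ndarray = field(repr=False)        # district label per row
    dow_names: tuple = DOW_NAMES
    dsli_names: tuple = DSLI_NAMES


def build_panel(
    counts: pd.DataFrame,
    temps: pd.Series,
    populations: pd.DataFrame | Mapping[str, int],
    adjacency: Sequence[tuple],
    lag: LagAssignment,
    age_group: str = "all",
) -> PanelDataset:
    """Join counts, temperature, populations and adjacency into a panel.

    ``counts`` needs columns ``date, district, visits`` (an optional
    ``age_group`` column is filtered to ``age_group``); ``temps`` is a daily
    series indexed by date; ``populations`` either a mapping or a frame with
    ``district, population`` (optionally per ``age_group``).  Missing
    temperature days are filled by linear interpolation (logged); missing
    (date, district) count combinations are an error.
    """
    df = counts.copy()
    if "age_group" in df.columns:
        df = df[df["age_group"] == age_group].drop(columns="age_group")
    required = {"date", "district", "visits"}
    if not required <= set(df.columns):
        raise PanelValidationError(f"counts must have columns {sorted(required)}")
    df["date"] = pd.to_datetime(df["date"])
    if (df["visits"] < 0).any():
        raise PanelValidationError("negative visit counts")

    index = lag.classes.index
    districts = sorted(df["district"].unique())
    # completeness: every (date, district) combination exactly once
    full = pd.MultiIndex.from_product([index, districts], names=["date", "district"])
    have = pd.MultiIndex.from_frame(df[["date", "district"]])
    if have.has_duplicates:
        dup = df[have.duplicated()].head()
        raise PanelValidationError(f"duplicate (date, district) rows, e.g.\n{dup}")
    missing = full.difference(have)
    if len(missing):
        examples = ", ".join(f"({d.date()}, {s})" for d, s in missing[:5])
        raise PanelValidationError(
            f"{len(missing)} missing (date, district) combinations, e.g. {examples}"
        )

    t = pd.Series(temps).copy()
    t.index = pd.to_datetime(t.index)
    t = t.reindex(index)
    n_gap = int(t.isna().sum())
    if n_gap:
        if t.notna().sum() < 2:
            raise PanelValidationError("temperature series has <2 observed days")
        logger.info("interpolating %d missing temperature days", n_gap)
        t = t.interpolate(method="linear", limit_direction="both")

    if isinstance(populations, Mapping):
        pops = dict(populations)
    else:
        p = populations
        if "age_group" in p.columns:
            p = p[p["age_group"] == age_group]
        pops = dict(zip(p["district"], p["population"]))
    missing_pop = set(districts) - set(pops)
    if missing_pop:
        raise PanelValidationError(f"populations missing districts {sorted(missing_pop)}")
    if any(v <= 0 for v in pops.values()):
        raise PanelValidationError("non-positive population")
    pops = {d: int(pops[d]) for d in districts}

    G = nx.Graph()
    G.add_nodes_from(districts)
    for a, b in adjacency:
        if a in districts and b in districts:
            G.add_edge(a, b)
    if len(districts) > 1:
        isolated = [d for d in districts if G.degree(d) == 0]
        if isolated:
            raise PanelValidationError(
                f"adjacency omits district(s) {isolated}; "
                "graph must cover all districts"
            )
        if not nx.is_connected(G):
            raise PanelValidationError("district adjacency graph is disconnected")

    df = df.set_index(["date", "district"]).reindex(full).reset_index()
    df["temperature"] = t.loc[df["date"]].to_numpy()
    df = df.sort_values(["date", "district"], kind="stable").reset_index(drop=True)
    df["visits"] = df["visits"].astype(np.int64)
    return PanelDataset(
        records=df, populations=pops, graph=G, lag=lag, age_group=age_group
    )


def build_design(panel: PanelDataset) -> DesignMatrices:
    """Indicator blocks, offset and covariates for the panel rows.

    Pure function of the panel: repeated calls return identical arrays.
    """
    rec = panel.records
    n = len(rec)
    dates = pd.DatetimeIndex(rec["date"])

    dow_idx = dates.dayofweek.to_numpy()  # Monday=0 .. Sunday=6
    rows = np.flatnonzero(dow_idx < 6)
    dow = sp.csr_matrix(
        (np.ones(len(rows)), (rows, dow_idx[rows])), shape=(n, 6)
    )

    lag_class = panel.lag.classes.loc[dates].to_numpy()
    col_of = {f"lag{k}": k for k in range(N_LAGS + 1)}
    rows, cols = [], []
    for i, c in enumerate(lag_class):
        if c != REFERENCE_CLASS:
            rows.append(i)
            cols.append(col_of[c])
    dsli = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, N_LAGS + 1)
    )

    district = rec["district"].to_numpy()
    offset = np.log([panel.populations[d] for d in district])
    start = panel.lag.classes.index[0]
    time_index = (dates - start).days.to_numpy(dtype=float)
    return DesignMatrices(
        dow=dow,
        dsli=dsli,
        offset=np.asarray(offset, dtype=float),
        time_index=time_index,
        temperature=rec["temperature"].to_numpy(dtype=float),
        district=district,
    )


def lag_stratified_means(panel: PanelDataset) -> pd.DataFrame:
    """Per-district mean and sample SD of counts within each lag class 0..7.

    Mirrors the descriptive table of daily average visits by district and lag
    day; empty strata yield missing values, not zeros.
    """
    rec = panel.records
    lag_class = panel.lag.classes.loc[pd.DatetimeIndex(rec["date"])].to_numpy()
    df = rec.assign(lag_class=lag_class)
    df = df[df["lag_class"] != REFERENCE_CLASS]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 1-obs strata -> NaN sd
        out = (
            df.groupby(["district", "lag_class"], observed=True)["visits"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=1))
            .reset_index()
        )
    # ensure every (district, lag class) cell appears, missing where empty
    full = pd.MultiIndex.from_product(
        [panel.districts, list(DSLI_NAMES)], names=["district", "lag_class"]
    )
    out = (
        out.set_index(["district", "lag_class"])
        .reindex(full)
        .reset_index()
    )
    return out
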