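"""Land-use transition (Markov) matrices and loss/gain balance accounting.

A transition matrix cross-tabulates area (ha) by land-use category at
two dates. Following the bookkeeping convention used for the printed
case-study tables, **columns index the earlier date and rows the later
date**: reading down a column gives where that category's area went
(losses), reading along a row gives where a category's area came from
(gains), and the diagonal is unchanged area. Per-category balances are

    losses = column total − diagonal
    gains  = row total − diagonal
    net    = gains − losses = total_t2 − total_t1
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = [
    "TransitionMatrix",
    "cross_tabulate",
    "cross_tabulate_polygons",
    "balance",
    "net_transfer",
    "percent_change",
    "read_matrix_csv",
    "load_reference_table",
    "REFERENCE_TABLES",
]


@dataclass
class TransitionMatrix:
    """Square area cross-tabulation; rows = later date, columns = earlier.

    ``cells`` is a category×category DataFrame of hectares with
    identical row and column index order.
    """

    cells: pd.DataFrame
    date1: str = "t1"
    date2: str = "t2"

    def __post_init__(self) -> None:
        if list(self.cells.index) != list(self.cells.columns):
            raise ValueError("row and column categories must match and be ordered alike")
        if (self.cells.to_numpy() < 0).any():
            raise ValueError("negative transition area")

    @property
    def categories(self) -> list[str]:
        return list(self.cells.index)

    @property
    def row_totals(self) -> pd.Series:
        """Per-category area at the later date ('Total t2')."""
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        """Per-category area at the earlier date ('Total t1')."""
        return self.cells.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.cells.to_numpy().sum())

    def transpose(self) -> "TransitionMatrix":
        """Swap to the rows-=-earlier-date convention."""
        return TransitionMatrix(self.cells.T.copy(), date1=self.date2, date2=self.date1)

    def to_frame(self) -> pd.DataFrame:
        """Printable layout with marginal totals appended."""
        out = self.cells.copy()
        out[f"Total {self.date2}"] = self.row_totals
        bottom = self.col_totals.copy()
        bottom[f"Total {self.date2}"] = self.grand_total
        out.loc[f"Total {self.date1}"] = bottom
        return out

    def write_csv(self, path) -> None:
        self.to_frame().round(1).to_csv(path, index_label="category")


def cross_tabulate(
    map_t1: Grid,
    map_t2: Grid,
    legend: dict[int, str],
    date1: str = "t1",
    date2: str = "t2",
) -> TransitionMatrix:
    """Cross-tabulate two co-registered categorical rasters into hectares.

    Cell (r, c) is the area that was category c at the earlier date and
    category r at the later date. Pixels that are nodata on either date
    are excluded from the tabulation.
    """
    map_t1.require_same_geometry(map_t2, "land-use maps")
    if map_t1.crs_units != "m":
        raise ValueError("transition areas require a projected grid in metres")
    valid = map_t1.mask & map_t2.mask
    c1 = map_t1.values[valid].astype(int)
    c2 = map_t2.values[valid].astype(int)
    present = set(np.unique(c1)) | set(np.unique(c2))
    unknown = present - set(legend)
    if unknown:
        raise ValueError(f"category codes {sorted(unknown)} missing from legend")
    codes = sorted(legend)
    k = len(codes)
    flat = np.searchsorted(codes, c2) * k + np.searchsorted(codes, c1)
    counts = np.bincount(flat, minlength=k * k).reshape(k, k)
    px_ha = map_t1.pixel_size**2 / 1e4
    names = [legend[c] for c in codes]
    cells = pd.DataFrame(counts * px_ha, index=names, columns=names)
    return TransitionMatrix(cells, date1=date1, date2=date2)


def cross_tabulate_polygons(
    features_t1: list[tuple[str, object]],
    features_t2: list[tuple[str, object]],
    categories: list[str] | None = None,
    date1: str = "t1",
    date2: str = "t2",
) -> TransitionMatrix:
    """Cross-tabulate two (category, polygon) layers by intersection.

    Features are (category label, shapely geometry in a projected
    metric CRS) pairs; cell areas come from the geometric intersection
    of every t1/t2 feature pair, converted m² → ha. Both layers should
    cover the same support for the conservation identities to hold.
    """
    if categories is None:
        categories = sorted({c for c, _ in features_t1} | {c for c, _ in features_t2})
    unknown = ({c for c, _ in features_t1} | {c for c, _ in features_t2}) - set(categories)
    if unknown:
        raise ValueError(f"categories {sorted(unknown)} missing from legend")
    cells = pd.DataFrame(0.0, index=categories, columns=categories)
    for c1, g1 in features_t1:
        for c2, g2 in features_t2:
            inter = g1.intersection(g2)
            if not inter.is_empty:
                cells.at[c2, c1] += inter.area / 1e4
    return TransitionMatrix(cells, date1=date1, date2=date2)


def balance(matrix: TransitionMatrix) -> pd.DataFrame:
    """Per-category losses, gains, net balance and percent change.

    net = gains − losses = total_t2 − total_t1 identically; percent
    change is relative to the earlier date (NaN where that total is 0).
    """
    diag = pd.Series(np.diag(matrix.cells.to_numpy()), index=matrix.categories)
    t1 = matrix.col_totals
    t2 = matrix.row_totals
    losses = t1 - diag
    gains = t2 - diag
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(t1 > 0, 100.0 * (t2 - t1) / t1, np.nan)
    return pd.DataFrame(
        {
            "total_t1": t1,
            "total_t2": t2,
            "unchanged": diag,
            "losses": losses,
            "gains": gains,
            "net": gains - losses,
            "pct_change": pct,
        }
    )


def net_transfer(matrix: TransitionMatrix, category_a: str, category_b: str) -> float:
    """Net area flow (ha) from category a to category b.

    (area a→b) − (area b→a); positive means a lost area to b on balance.
    With columns = earlier date, a→b is the cell at row b, column a.
    """
    for cat in (category_a, category_b):
        if cat not in matrix.categories:
            raise KeyError(f"category {cat!r} not in matrix")
    a_to_b = float(matrix.cells.at[category_b, category_a])
    b_to_a = float(matrix.cells.at[category_a, category_b])
    return a_to_b - b_to_a


def percent_change(total_t1: float, total_t2: float, ndigits: int | None = 1) -> float:
    """100·(t2 − t1)/t1, rounded to one decimal for reporting by default."""
    if total_t1 <= 0:
        raise ValueError("earlier-date total must be positive")
    pct = 100.0 * (total_t2 - total_t1) / total_t1
    return round(pct, ndigits) if ndigits is not None else pct


def read_matrix_csv(path, date1: str = "t1", date2: str = "t2") -> TransitionMatrix:
    """Read a transition matrix from CSV in the printed-table layout.

    The first column holds row categories; a trailing 'Total ...' column
    and row, if present, are dropped (they are recomputed); '-' cells
    parse as 0 ha.
    """
    raw = pd.read_csv(path, index_col=0)
    raw = raw.replace("-", 0.0).astype(float)
    total_cols = [c for c in raw.columns if str(c).lower().startswith("total")]
    total_rows = [r for r in raw.index if str(r).lower().startswith("total")]
    cells = raw.drop(columns=total_cols).drop(index=total_rows)
    cells = cells.loc[:, cells.index]  # enforce identical ordering
    return TransitionMatrix(cells, date1=date1, date2=date2)


#: Published 1981–2008 land-use cross-tabulations for the two
#: case-study areas on the southern Oltenia sands, re-entered from the
#: printed tables (hectares; '-' = 0).
REFERENCE_TABLES = {
    "ciupercenii": "ciupercenii_1981_2008.csv",
    "jiana": "jiana_1981_2008.csv",
}


def load_reference_table(name: str, with_printed_totals: bool = False):
    """Load a bundled case-study transition table.

    With ``with_printed_totals`` the printed marginal totals are
    returned alongside for consistency checking; otherwise only the
    :class:`TransitionMatrix` (totals recomputed from cells).
    """
    if name not in REFERENCE_TABLES:
        raise KeyError(f"unknown reference table {name!r}; have {sorted(REFERENCE_TABLES)}")
    resource = importlib.resources.files("aridforest.data") / REFERENCE_TABLES[name]
    with importlib.resources.as_file(resource) as path:
        raw = pd.read_csv(path, index_col=0).replace("-", 0.0).astype(float)
    matrix = TransitionMatrix(
        raw.drop(columns=["Total 2008"]).drop(index=["Total 1981"]),
        date1="1981",
        date2="2008",
    )
    if not with_printed_totals:
        return matrix
    printed = {
        "row_totals": raw.loc[raw.index != "Total 1981", "Total 2008"],
        "col_totals": raw.loc["Total 1981"].drop("Total 2008"),
        "grand_total": float(raw.at["Total 1981", "Total 2008"]),
    }
    return matrix, printed
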