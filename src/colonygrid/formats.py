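"""Tab-delimited log/key/statistics file I/O and the core tabular types.

The file dialect is fixed and documented here so every stage of the pipeline
round-trips through it:

* **log file** — TSV, UTF-8, one header row with columns
  ``plate  condition  row  col  value`` (``mode`` optional).  One record per
  grid position; rows/columns are 1-based with A1 = (1, 1) at the image
  top-left.
* **key file** — TSV with columns ``plate  row  col  strain  orf``
  (``control`` optional; truthy values ``1/true/yes`` flag designated
  controls).
* **stats files** — three TSVs (all strains / positive hits / suppressors)
  with a shared column set, written with an ISO-8601 date prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path

import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

LOG_COLUMNS = ["plate", "condition", "row", "col", "value"]
KEY_COLUMNS = ["plate", "row", "col", "strain", "orf"]
STATS_COLUMNS = [
    "strain", "orf", "plate", "condition", "positions",
    "control_mean", "experimental_mean", "growth_ratio", "log_ratio",
    "z_score", "p_value", "p_adjusted",
    "n_control", "n_experimental", "excluded_count",
]

#: growth on the experimental plate at or below half the control value
HIT_RATIO = 0.5
#: growth on the experimental plate at or above twice the control value
SUPPRESSOR_RATIO = 2.0


@dataclass(frozen=True)
class GridFormat:
    """Colony array format: 384 (16x24) or 1536 (32x48) positions.

    ``replicate_layout="quad_2x2"`` marks plates where each strain occupies a
    2x2 block of four replicate colonies (e.g. 384 strains on a 1536 plate).
    """

    n_colonies: int
    rows: int
    cols: int
    replicate_layout: str = "none"

    def __post_init__(self) -> None:
        if self.rows * self.cols != self.n_colonies:
            raise ValueError(
                f"rows*cols = {self.rows * self.cols} != n_colonies = {self.n_colonies}"
            )
        if self.replicate_layout not in ("none", "quad_2x2"):
            raise ValueError(f"unknown replicate layout {self.replicate_layout!r}")
        if self.replicate_layout == "quad_2x2" and (self.rows % 2 or self.cols % 2):
            raise ValueError("quad_2x2 layout requires even row and column counts")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)


FORMAT_384 = GridFormat(384, 16, 24)
FORMAT_1536 = GridFormat(1536, 32, 48)
FORMAT_1536_QUAD = GridFormat(1536, 32, 48, replicate_layout="quad_2x2")

GRID_FORMATS = {384: FORMAT_384, 1536: FORMAT_1536}


def grid_format(n: int, quad: bool = False) -> GridFormat:
    """Look up the standard 384/1536 format, optionally with quad replicates."""
    if n not in GRID_FORMATS:
        raise ValueError(f"unsupported colony format {n}; expected 384 or 1536")
    fmt = GRID_FORMATS[n]
    if quad:
        return GridFormat(fmt.n_colonies, fmt.rows, fmt.cols, "quad_2x2")
    return fmt


@dataclass
class MeasurementTable:
    """Per-position colony growth values for one or more plates.

    Wraps a DataFrame with columns ``plate, condition, row, col, value``
    (plus ``mode`` and, after :func:`join_key`, ``strain/orf/control``).
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=LOG_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"measurement table missing columns: {missing}")
        df = self.data
        if len(df):
            if (df["value"] < 0).any():
                bad = df.loc[df["value"] < 0].iloc[0]
                raise IntegrityError(
                    f"negative value at plate {bad['plate']} ({bad['row']},{bad['col']})"
                )
            dup = df.duplicated(subset=["plate", "condition", "row", "col"])
            if dup.any():
                bad = df.loc[dup].iloc[0]
                raise IntegrityError(
                    "duplicate position: plate "
                    f"{bad['plate']!r} condition {bad['condition']!r} "
                    f"row {bad['row']} col {bad['col']}"
                )

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self.data[LOG_COLUMNS].reset_index(drop=True)
        b = other.data[LOG_COLUMNS].reset_index(drop=True)
        return a.equals(b)

    def plates(self) -> pd.DataFrame:
        """Unique (plate, condition) pairs in stable order."""
        return self.data[["plate", "condition"]].drop_duplicates().reset_index(drop=True)


@dataclass
class PlateKey:
    """Position -> strain mapping with designated-control flags."""

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=KEY_COLUMNS + ["control"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"key missing columns: {missing}")
        if "control" not in self.data.columns:
            self.data = self.data.assign(control=False)
        self.data["control"] = self.data["control"].astype(bool)
        dup = self.data.duplicated(subset=["plate", "row", "col"])
        if dup.any():
            bad = self.data.loc[dup].iloc[0]
            raise IntegrityError(
                f"duplicate key position: plate {bad['plate']!r} "
                f"row {bad['row']} col {bad['col']}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_controls(self) -> int:
        return int(self.data["control"].sum())


_TRUTHY = {"1", "true", "yes", "y", "t"}


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (header row required)") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_log_file(path: str | Path) -> MeasurementTable:
    """Read a measurement log file.

    Unparseable rows are reported (with 1-based line numbers, counting the
    header as line 1) and skipped; duplicate positions raise
    :class:`IntegrityError`.
    """
    df = _read_tsv(path, LOG_COLUMNS)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        try:
            rec = {
                "plate": str(getattr(row, "plate")),
                "condition": str(getattr(row, "condition")),
                "row": int(getattr(row, "row")),
                "col": int(getattr(row, "col")),
                "value": float(getattr(row, "value")),
            }
            if hasattr(row, "mode"):
                rec["mode"] = str(getattr(row, "mode"))
        except (TypeError, ValueError):
            logger.warning("%s: line %d unparseable, skipped", path, line_no)
            continue
        records.append(rec)
    cols = LOG_COLUMNS + (["mode"] if "mode" in df.columns else [])
    out = pd.DataFrame(records, columns=cols)
    return MeasurementTable(out)


def write_log_file(table: MeasurementTable, path: str | Path, append: bool = False) -> None:
    """Write a measurement log; records are grouped by plate in input order."""
    path = Path(path)
    cols = [c for c in LOG_COLUMNS + ["mode"] if c in table.data.columns]
    df = table.data[cols]
    # stable grouping by plate, preserving first-appearance order
    order = {p: i for i, p in enumerate(df["plate"].drop_duplicates())}
    df = df.sort_values(by="plate", key=lambda s: s.map(order), kind="stable")
    mode = "a" if append and path.exists() else "w"
    df.to_csv(path, sep="\t", index=False, mode=mode, header=(mode == "w"),
              float_format="%.6g", lineterminator="\n")


def read_key_file(path: str | Path, fmt: GridFormat | None = None) -> PlateKey:
    """Read a key file. The ``control`` column is optional (defaults false).

    If ``fmt`` is given, positions outside the grid bounds raise
    :class:`FormatError`.
    """
    df = _read_tsv(path, KEY_COLUMNS)
    out = pd.DataFrame({
        "plate": df["plate"].astype(str),
        "row": df["row"].astype(int),
        "col": df["col"].astype(int),
        "strain": df["strain"].astype(str),
        "orf": df["orf"].astype(str),
    })
    if "control" in df.columns:
        out["control"] = df["control"].str.strip().str.lower().isin(_TRUTHY)
    else:
        out["control"] = False
    if fmt is not None:
        bad = out[(out["row"] < 1) | (out["row"] > fmt.rows)
                  | (out["col"] < 1) | (out["col"] > fmt.cols)]
        if len(bad):
            b = bad.iloc[0]
            raise FormatError(
                f"{path}: position ({b['row']},{b['col']}) outside "
                f"{fmt.rows}x{fmt.cols} grid"
            )
    return PlateKey(out)


def write_key_file(key: PlateKey, path: str | Path) -> None:
    df = key.data.copy()
    df["control"] = df["control"].astype(int)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def join_key(table: MeasurementTable, key: PlateKey) -> MeasurementTable:
    """Annotate each measurement with strain/orf/control from the key.

    Positions absent from the key get placeholder ids ``UNKNOWN_<row>_<col>``
    and a logged warning instead of failing, so partial keys stay usable.
    Record count is conserved.
    """
    merged = table.data.merge(
        key.data, on=["plate", "row", "col"], how="left", validate="many_to_one"
    )
    unmapped = merged["strain"].isna()
    if unmapped.any():
        n = int(unmapped.sum())
        logger.warning("join_key: %d position(s) missing from key; placeholders used", n)
        merged.loc[unmapped, "strain"] = [
            f"UNKNOWN_{r}_{c}"
            for r, c in zip(merged.loc[unmapped, "row"], merged.loc[unmapped, "col"])
        ]
        merged.loc[unmapped, "orf"] = merged.loc[unmapped, "strain"]
        merged.loc[unmapped, "control"] = False
    merged["control"] = merged["control"].astype(bool)
    return MeasurementTable(merged)


def write_stats_files(
    stats: pd.DataFrame,
    out_dir: str | Path,
    date: str | None = None,
    basename: str = "screen-stats",
) -> tuple[Path, Path, Path]:
    """Write the three classification files and return their paths.

    * ``<date>-<basename>-all.txt`` — every tested strain;
    * ``...-positive-hits.txt`` — experimental/control growth ratio <= 0.5;
    * ``...-suppressors.txt`` — growth ratio >= 2.0.

    Both boundaries are inclusive, so a strain at exactly 0.5 (or 2.0)
    appears in the all-file and its classification file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if date is None:
        date = _date.today().isoformat()
    cols = [c for c in STATS_COLUMNS if c in stats.columns]
    df = stats[cols]
    ratio = pd.to_numeric(stats["growth_ratio"], errors="coerce")
    paths = (
        out_dir / f"{date}-{basename}-all.txt",
        out_dir / f"{date}-{basename}-positive-hits.txt",
        out_dir / f"{date}-{basename}-suppressors.txt",
    )
    subsets = (df, df[ratio <= HIT_RATIO], df[ratio >= SUPPRESSOR_RATIO])
    for p, sub in zip(paths, subsets):
        sub.to_csv(p, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
    return paths
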