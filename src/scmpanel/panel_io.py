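"""Read, validate, filter, and write multi-brand weekly sales panels.

The canonical in-memory representation is :class:`SalesPanel`: a dense
``brand x week`` matrix of equivalized unit sales plus per-brand metadata.
Input is a tidy long-format delimited table (one row per brand-week); the
column names are supplied through a small schema mapping so arbitrary
extracts can be ingested without renaming on disk.

Brands with missing weeks are retained at read time (cells are NaN and the
brand is flagged incomplete in the metadata); :func:`filter_brands` drops
them.  Missing weeks are never imputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

#: default long-format column names
DEFAULT_SCHEMA = {"brand": "brand", "week": "week", "sales": "sales"}

#: brand_meta columns guaranteed to exist after validation
META_COLUMNS = ("major_brand", "product_type", "treated_family", "complete")


@dataclass(frozen=True)
class StudyWindows:
    """Partition of the analysis weeks into pre / intervention / post.

    The three blocks must be disjoint, contiguous, ordered and jointly
    cover ``1..T``.  The pre window needs at least two weeks because the
    standardization scale is a dispersion estimate.
    """

    pre: tuple[int, ...]
    intervention: tuple[int, ...]
    post: tuple[int, ...]

    def __post_init__(self) -> None:
        pre, mid, post = map(np.asarray, (self.pre, self.intervention, self.post))
        if len(pre) < 2:
            raise ConfigurationError("pre window must contain at least 2 weeks")
        if len(mid) == 0 or len(post) == 0:
            raise ConfigurationError("intervention and post windows must be non-empty")
        full = np.concatenate([pre, mid, post])
        if not np.array_equal(full, np.arange(full[0], full[0] + len(full))):
            raise ConfigurationError(
                "windows must be contiguous, ordered, and jointly cover the study weeks"
            )

    @classmethod
    def default(cls, n_weeks: int = 52) -> "StudyWindows":
        """Weeks 1-19 pre, 20-30 intervention, 31..n_weeks post."""
        if n_weeks < 31:
            raise ConfigurationError("default windows require at least 31 weeks")
        return cls(
            pre=tuple(range(1, 20)),
            intervention=tuple(range(20, 31)),
            post=tuple(range(31, n_weeks + 1)),
        )

    @classmethod
    def from_bounds(cls, pre_end: int, intervention_end: int, n_weeks: int) -> "StudyWindows":
        return cls(
            pre=tuple(range(1, pre_end + 1)),
            intervention=tuple(range(pre_end + 1, intervention_end + 1)),
            post=tuple(range(intervention_end + 1, n_weeks + 1)),
        )

    @property
    def all_weeks(self) -> tuple[int, ...]:
        return tuple(self.pre) + tuple(self.intervention) + tuple(self.post)

    @property
    def n_weeks(self) -> int:
        return len(self.all_weeks)


@dataclass
class SalesPanel:
    """A dense brands x weeks sales matrix with brand metadata.

    Parameters
    ----------
    brand_ids
        Ordered unique brand identifiers, one per matrix row.
    week_index
        Strictly increasing integer week labels with unit step (1..T).
    sales
        ``(n_brands, n_weeks)`` array of equivalized unit sales.  NaN marks
        a missing brand-week; such brands are flagged incomplete and must be
        removed by :func:`filter_brands` before analysis.
    treated_id
        Identifier of the intervention brand; must be present in
        ``brand_ids``.
    brand_meta
        Per-brand attribute frame indexed by brand id with at least the
        columns in :data:`META_COLUMNS`.
    week_end_dates
        Optional calendar dates aligned with ``week_index``; metadata only.
    """

    brand_ids: list[str]
    week_index: np.ndarray
    sales: np.ndarray
    treated_id: str
    brand_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    week_end_dates: list | None = None

    def __post_init__(self) -> None:
        self.brand_ids = [str(b) for b in self.brand_ids]
        self.week_index = np.asarray(self.week_index, dtype=int)
        self.sales = np.asarray(self.sales, dtype=float)
        if self.brand_meta is None:
            self.brand_meta = _default_meta(self.brand_ids, self.treated_id)
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        n, t = self.sales.shape
        if len(self.brand_ids) != n:
            raise IntegrityError("brand_ids length does not match sales rows")
        if len(set(self.brand_ids)) != n:
            raise IntegrityError("brand_ids must be unique")
        if len(self.week_index) != t:
            raise IntegrityError("week_index length does not match sales columns")
        steps = np.diff(self.week_index)
        if t > 1 and not np.all(steps == 1):
            raise IntegrityError("week_index must be strictly increasing with unit step")
        if str(self.treated_id) not in self.brand_ids:
            raise ConfigurationError(f"treated brand {self.treated_id!r} not in panel")
        with np.errstate(invalid="ignore"):
            if np.any(self.sales < 0):
                raise IntegrityError("sales must be non-negative")
        missing = set(self.brand_meta.index.astype(str)) ^ set(self.brand_ids)
        if missing:
            raise IntegrityError(f"brand_meta does not cover panel brands: {sorted(missing)}")
        # refresh the completeness flag from the matrix itself
        self.brand_meta = self.brand_meta.loc[self.brand_ids]
        self.brand_meta["complete"] = ~np.isnan(self.sales).any(axis=1)

    # -- convenience -------------------------------------------------------

    @property
    def n_brands(self) -> int:
        return len(self.brand_ids)

    @property
    def n_weeks(self) -> int:
        return len(self.week_index)

    def brand_row(self, brand_id: str) -> np.ndarray:
        return self.sales[self.brand_ids.index(str(brand_id))]

    def week_positions(self, weeks: Iterable[int]) -> np.ndarray:
        """Map week labels to column positions."""
        pos = np.searchsorted(self.week_index, np.asarray(list(weeks), dtype=int))
        pos = np.clip(pos, 0, self.n_weeks - 1)
        if not np.array_equal(self.week_index[pos], np.asarray(list(weeks), dtype=int)):
            raise ConfigurationError("requested weeks are not all present in the panel")
        return pos

    def incomplete_brands(self) -> list[str]:
        return [b for b, ok in zip(self.brand_ids, self.brand_meta["complete"]) if not ok]

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format view (brand, week, sales), NaN rows dropped."""
        frame = pd.DataFrame(self.sales, index=self.brand_ids, columns=self.week_index)
        long = frame.stack().rename("sales").rename_axis(["brand", "week"]).reset_index()
        return long


def _default_meta(brand_ids: Sequence[str], treated_id: str) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "major_brand": list(brand_ids),
            "product_type": "e-cigarette",
            "treated_family": [b == str(treated_id) for b in brand_ids],
            "complete": True,
        },
        index=pd.Index([str(b) for b in brand_ids], name="brand"),
    )
    return meta


# ---------------------------------------------------------------------------
# reading


def read_panel(
    path: str | Path,
    treated_id: str,
    schema: Mapping[str, str] | None = None,
    meta_path: str | Path | None = None,
    week_labels: Sequence[int] | None = None,
    sep: str = ",",
) -> SalesPanel:
    """Read a long-format delimited sales table into a :class:`SalesPanel`.

    Parameters
    ----------
    path
        Delimited text file with one row per brand-week.
    treated_id
        Brand identifier of the intervention unit.
    schema
        Mapping from the roles ``brand``/``week``/``sales`` to the actual
        column names in the file.  Defaults to identity naming.
    meta_path
        Optional brand metadata CSV (columns: brand, major_brand,
        product_type, treated_family).
    week_labels
        Expected full set of week labels.  Defaults to the union observed in
        the file; brands missing any label get NaN cells and are flagged
        incomplete.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    table = pd.read_csv(path, sep=sep)
    missing_cols = [schema[r] for r in ("brand", "week", "sales") if schema[r] not in table.columns]
    if missing_cols:
        raise SchemaError(f"input table is missing columns: {missing_cols}")

    table = table.rename(
        columns={schema["brand"]: "brand", schema["week"]: "week", schema["sales"]: "sales"}
    )
    table["brand"] = table["brand"].astype(str)

    # week may be an integer index or a week-ending calendar date; dates are
    # mapped to 1..T and kept as metadata (all computation uses indices)
    week_dates = None
    week_numeric = pd.to_numeric(table["week"], errors="coerce")
    if week_numeric.isna().any():
        parsed = pd.to_datetime(table["week"], errors="coerce")
        if parsed.isna().any():
            raise SchemaError("week column is neither integer index nor parseable dates")
        ordered = sorted(parsed.unique())
        date_to_idx = {d: i + 1 for i, d in enumerate(ordered)}
        table["week"] = parsed.map(date_to_idx)
        week_dates = [pd.Timestamp(d).date() for d in ordered]
    else:
        table["week"] = week_numeric.astype(int)

    dup = table.duplicated(subset=["brand", "week"])
    if dup.any():
        pairs = table.loc[dup, ["brand", "week"]].head(5).to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (brand, week) rows, e.g. {pairs}")

    sales = pd.to_numeric(table["sales"], errors="coerce")
    if sales.isna().any() and table["sales"].notna().any():
        bad = table.loc[sales.isna() & table["sales"].notna(), "sales"].head(3).tolist()
        raise IntegrityError(f"non-numeric sales values, e.g. {bad}")
    if (sales < 0).any():
        raise IntegrityError("negative sales values in input")
    table["sales"] = sales

    wide = table.pivot(index="brand", columns="week", values="sales")
    if week_labels is not None:
        wide = wide.reindex(columns=list(week_labels))
    wide = wide.sort_index(axis=1)

    brand_ids = list(wide.index)
    meta = None
    if meta_path is not None:
        meta = read_brand_meta(meta_path, brand_ids, treated_id)
    panel = SalesPanel(
        brand_ids=brand_ids,
        week_index=np.asarray(wide.columns, dtype=int),
        sales=wide.to_numpy(dtype=float),
        treated_id=str(treated_id),
        brand_meta=meta,
        week_end_dates=week_dates,
    )
    return panel


def read_brand_meta(
    path: str | Path, brand_ids: Sequence[str], treated_id: str
) -> pd.DataFrame:
    """Read a brand metadata CSV, filling defaults for absent columns."""
    raw = pd.read_csv(path)
    if "brand" not in raw.columns:
        raise SchemaError("brand metadata must have a 'brand' column")
    raw["brand"] = raw["brand"].astype(str)
    raw = raw.set_index("brand")
    meta = _default_meta(brand_ids, treated_id)
    for col in ("major_brand", "product_type", "treated_family"):
        if col in raw.columns:
            common = meta.index.intersection(raw.index)
            meta.loc[common, col] = raw.loc[common, col]
    meta["treated_family"] = meta["treated_family"].astype(bool)
    return meta


def write_panel(panel: SalesPanel, path: str | Path, sep: str = ",") -> None:
    """Write the panel in tidy long format (round-trips with read_panel)."""
    panel.to_long().to_csv(path, sep=sep, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# transformations


def aggregate_subbrands(panel: SalesPanel, mapping: Mapping[str, str]) -> SalesPanel:
    """Sum sub-brand sales into major brands.

    Brands absent from ``mapping`` map to themselves.  The treated id is
    remapped when it is a constituent of an aggregated major brand.  If a
    brand that is *not* flagged as part of the treated family would be merged
    into the treated major brand, the treated unit would be contaminated and
    a :class:`ConfigurationError` is raised.
    """
    mapping = {str(k): str(v) for k, v in mapping.items()}
    target = {b: mapping.get(b, b) for b in panel.brand_ids}
    treated_major = target[str(panel.treated_id)]

    family = dict(zip(panel.brand_ids, panel.brand_meta["treated_family"].astype(bool)))
    intruders = [
        b for b in panel.brand_ids if target[b] == treated_major and not family[b] and b != panel.treated_id
    ]
    if intruders:
        raise ConfigurationError(
            f"donor brands {intruders} would merge into the treated major brand {treated_major!r}"
        )

    majors = list(dict.fromkeys(target[b] for b in panel.brand_ids))
    n_major, t = len(majors), panel.n_weeks
    sales = np.zeros((n_major, t))
    for i, b in enumerate(panel.brand_ids):
        sales[majors.index(target[b])] += panel.sales[i]  # NaN propagates by design

    meta_rows = []
    for major in majors:
        members = [b for b in panel.brand_ids if target[b] == major]
        sub = panel.brand_meta.loc[members]
        meta_rows.append(
            {
                "major_brand": major,
                "product_type": sub["product_type"].iloc[0],
                "treated_family": bool(sub["treated_family"].any()),
                "complete": True,  # recomputed in validate()
            }
        )
    meta = pd.DataFrame(meta_rows, index=pd.Index(majors, name="brand"))

    return SalesPanel(
        brand_ids=majors,
        week_index=panel.week_index.copy(),
        sales=sales,
        treated_id=treated_major,
        brand_meta=meta,
        week_end_dates=panel.week_end_dates,
    )


def filter_brands(
    panel: SalesPanel,
    windows: StudyWindows | None = None,
    exclusions: Sequence[str] = (),
) -> SalesPanel:
    """Drop incomplete brands and excluded product types.

    Removal counts and the removed share of total sales are logged.  The
    operation is idempotent.  Removing the treated brand is fatal.
    """
    exclusions = {str(e).lower() for e in exclusions}
    drop: list[str] = []
    for b in panel.brand_ids:
        incomplete = not bool(panel.brand_meta.loc[b, "complete"])
        excluded = str(panel.brand_meta.loc[b, "product_type"]).lower() in exclusions
        if incomplete or excluded:
            drop.append(b)

    if str(panel.treated_id) in drop:
        raise ConfigurationError(
            f"treated brand {panel.treated_id!r} was removed by filtering"
        )
    if not drop:
        return panel

    keep_idx = [i for i, b in enumerate(panel.brand_ids) if b not in drop]
    total = np.nansum(panel.sales)
    removed = np.nansum(panel.sales[[panel.brand_ids.index(b) for b in drop]])
    share = 100.0 * removed / total if total > 0 else 0.0
    logger.info(
        "filter_brands: removed %d of %d brands carrying %s%% of total sales",
        len(drop),
        panel.n_brands,
        f"<0.1" if 0 < share < 0.1 else f"{share:.2f}",
    )

    return SalesPanel(
        brand_ids=[panel.brand_ids[i] for i in keep_idx],
        week_index=panel.week_index.copy(),
        sales=panel.sales[keep_idx],
        treated_id=panel.treated_id,
        brand_meta=panel.brand_meta.iloc[keep_idx].copy(),
        week_end_dates=panel.week_end_dates,
    )


# ---------------------------------------------------------------------------
# results output


def write_results(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    manifest: Mapping | None = None,
) -> list[Path]:
    """Write result tables as CSV plus a JSON run manifest.

    Refuses to write when ``tables`` is empty.  Floats are formatted with a
    fixed precision so identical results are byte-identical on disk.
    """
    if not tables:
        raise ValueError("no result tables to write")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, frame in tables.items():
        if not isinstance(frame, pd.DataFrame):
            frame = pd.DataFrame(frame)
        dest = out / f"{name}.csv"
        frame.to_csv(dest, index=False, float_format="%.12g")
        written.append(dest)
    manifest_path = out / "manifest.json"
    payload = dict(manifest or {})
    payload.setdefault("tables", sorted(tables))
    manifest_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    written.append(manifest_path)
    return written


# ---------------------------------------------------------------------------
# config


def load_run_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration (windows, treated id, mapping...)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError("run config must be a mapping")
    return cfg


def windows_from_config(cfg: Mapping, n_weeks: int = 52) -> StudyWindows:
    """Build StudyWindows from config keys pre_end / intervention_end."""
    pre_end = int(cfg.get("pre_end", 19))
    intervention_end = int(cfg.get("intervention_end", 30))
    return StudyWindows.from_bounds(pre_end, intervention_end, int(cfg.get("n_weeks", n_weeks)))
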