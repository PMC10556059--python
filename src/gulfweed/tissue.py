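"""Reading, validating and summarizing Sargassum tissue-composition tables.

The canonical table is a CSV with one row per replicate:

    sample_id,cruise,station_id,latitude,longitude,date,species,replicate,
    pct_C,pct_N,pct_P,d15N,as_ug_g,era

%C/%N/%P are percent of dry weight, d15N is permil vs atmospheric N2,
arsenic is ug per g dry weight, dates ISO-8601, species one of
``S_fluitans_III`` / ``S_natans_I`` and era one of ``y2021`` /
``y1983_1987`` / ``y2015_2018``.  Missing chemistry is carried as NaN —
never imputed, always distinguishable from zero — and every downstream fit
or summary reports its effective n.

Longitudes are normalized to [-180, 180) on read.  Rows with unparseable or
out-of-range coordinates, or with every chemistry field missing, are
rejected with a logged reason; accepted/rejected counts travel with the
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "ATOMIC_MASS",
    "REQUIRED_COLUMNS",
    "TissueTable",
    "RatioSet",
    "read_tissue_table",
    "elemental_ratios",
    "add_ratio_columns",
    "summarize_by_group",
    "compare_groups",
]

ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974, "As": 74.922}

REQUIRED_COLUMNS = (
    "sample_id", "cruise", "station_id", "latitude", "longitude", "date",
    "species", "replicate", "pct_C", "pct_N", "pct_P", "d15N", "as_ug_g", "era",
)

_CHEMISTRY = ("pct_C", "pct_N", "pct_P", "d15N", "as_ug_g")

SPECIES = ("S_fluitans_III", "S_natans_I")
ERAS = ("y2021", "y1983_1987", "y2015_2018")


def normalize_longitude(lon):
    """Map longitudes onto the half-open interval [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class TissueTable:
    """A validated tissue table plus its acceptance bookkeeping."""

    frame: pd.DataFrame
    n_accepted: int
    n_rejected: int
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self):
        return len(self.frame)


def read_tissue_table(path, schema: dict[str, str] | None = None) -> TissueTable:
    """Read and validate a tissue CSV.

    ``schema`` optionally maps canonical column names to the file's column
    names.  Raises :class:`SchemaError` naming any missing required column
    and :class:`EmptyInputError` for a file with no data rows.
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file has no header or rows")
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    rejections: list[tuple[int, str]] = []
    records = []
    for idx, row in raw.iterrows():
        lat = pd.to_numeric(row["latitude"], errors="coerce")
        lon = pd.to_numeric(row["longitude"], errors="coerce")
        if not np.isfinite(lat) or not np.isfinite(lon):
            rejections.append((idx, "unparseable coordinates"))
            continue
        if not -90.0 <= lat <= 90.0:
            rejections.append((idx, f"latitude {lat} outside [-90, 90]"))
            continue
        chem = {c: pd.to_numeric(row[c], errors="coerce") for c in _CHEMISTRY}
        if all(pd.isna(v) for v in chem.values()):
            rejections.append((idx, "all chemistry fields missing"))
            continue
        rec = {
            "sample_id": row["sample_id"],
            "cruise": row["cruise"],
            "station_id": row["station_id"],
            "latitude": float(lat),
            "longitude": float(normalize_longitude(lon)),
            "date": pd.to_datetime(row["date"], errors="coerce"),
            "species": row["species"],
            "replicate": pd.to_numeric(row["replicate"], errors="coerce"),
            "era": row["era"],
            **{k: float(v) if np.isfinite(v) else np.nan for k, v in chem.items()},
        }
        records.append(rec)
    for idx, reason in rejections:
        logger.warning("rejected row %d: %s", idx, reason)
    if not records:
        raise EmptyInputError(f"{path}: every row was rejected")
    frame = pd.DataFrame.from_records(records)
    return TissueTable(
        frame=frame,
        n_accepted=len(frame),
        n_rejected=len(rejections),
        rejections=rejections,
    )


@dataclass(frozen=True)
class RatioSet:
    """Elemental ratios for one sample, on a weight or molar basis.

    Undefined ratios (zero or missing denominator) are NaN and listed in
    ``undefined`` rather than raising — a missing %P must not take down a
    whole table's worth of C:N values.
    """

    c_to_n: float
    c_to_p: float
    n_to_p: float
    as_to_p: float
    basis: str
    undefined: tuple[str, ...] = ()


def _ratio(num, den):
    if num is None or den is None or not np.isfinite(num) or not np.isfinite(den) or den == 0:
        return np.nan
    return num / den


def elemental_ratios(
    pct_C: float, pct_N: float, pct_P: float, as_ug_g: float, basis: str = "weight"
) -> RatioSet:
    """Compute C:N, C:P, N:P and As:P for one sample.

    Weight basis divides dry-weight percentages directly, with arsenic
    converted from ug/g to percent (/1e4).  Molar basis divides each percent
    by the element's atomic mass first; the two bases interconvert exactly
    through mass ratios.
    """
    if basis not in ("weight", "molar"):
        raise ValueError("basis must be 'weight' or 'molar'")
    pct_As = as_ug_g / 1e4 if as_ug_g is not None and np.isfinite(as_ug_g) else np.nan
    vals = {"C": pct_C, "N": pct_N, "P": pct_P, "As": pct_As}
    if basis == "molar":
        vals = {
            el: (v / ATOMIC_MASS[el] if v is not None and np.isfinite(v) else np.nan)
            for el, v in vals.items()
        }
    else:
        vals = {
            el: (v if v is not None and np.isfinite(v) else np.nan)
            for el, v in vals.items()
        }
    out = {
        "c_to_n": _ratio(vals["C"], vals["N"]),
        "c_to_p": _ratio(vals["C"], vals["P"]),
        "n_to_p": _ratio(vals["N"], vals["P"]),
        "as_to_p": _ratio(vals["As"], vals["P"]),
    }
    undefined = tuple(k for k, v in out.items() if not np.isfinite(v))
    return RatioSet(basis=basis, undefined=undefined, **out)


def add_ratio_columns(frame: pd.DataFrame, basis: str = "weight") -> pd.DataFrame:
    """Vector version of :func:`elemental_ratios`; appends ratio columns."""
    frame = frame.copy()
    ratios = [
        elemental_ratios(r.pct_C, r.pct_N, r.pct_P, r.as_ug_g, basis=basis)
        for r in frame.itertuples()
    ]
    for col in ("c_to_n", "c_to_p", "n_to_p", "as_to_p"):
        frame[col] = [getattr(r, col) for r in ratios]
    return frame


def summarize_by_group(
    frame: pd.DataFrame,
    group_keys: Sequence[str] = ("region",),
    variables: Sequence[str] = ("pct_C", "pct_N", "pct_P", "d15N", "as_ug_g"),
) -> pd.DataFrame:
    """Tidy per-group summary (n, mean, SD, median, IQR) for each variable.

    Missing values are excluded pairwise (each variable's n counts only its
    own non-missing values).  Empty groups are omitted with a warning.
    """
    group_keys = list(group_keys)
    rows = []
    for keys, sub in frame.groupby(group_keys, observed=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        if len(sub) == 0:
            logger.warning("empty group %s omitted", keys)
            continue
        for var in variables:
            vals = sub[var].dropna().to_numpy(dtype=float)
            row = dict(zip(group_keys, keys))
            row["variable"] = var
            row["n"] = int(vals.size)
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row.update(
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    median=float(med),
                    iqr=float(q3 - q1),
                )
            else:
                row.update(mean=np.nan, sd=np.nan, median=np.nan, iqr=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Result of an across-group comparison of one tissue variable.

    ``method`` labels exactly what was run (Welch one-way ANOVA; pairwise
    Welch t-tests with Holm correction), since the appropriate test is a
    modelling choice, not a fact of the data.
    """

    variable: str
    grouping: str
    testable: bool
    method: str
    statistic: float = np.nan
    p_value: float = np.nan
    pairwise: pd.DataFrame | None = None
    reason: str = ""


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    diff = a.mean() - b.mean()
    if diff == 0:
        return 0.0
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float(diff / pooled) if pooled > 0 else float(np.inf) * np.sign(diff)


def compare_groups(
    frame: pd.DataFrame, variable: str, grouping: str = "region"
) -> GroupComparison:
    """Welch one-way comparison of ``variable`` across levels of ``grouping``,
    with pairwise Welch t-tests under Holm correction.

    Unequal variances are assumed throughout (regional scatter differs).
    Groups need >= 3 non-missing values; with fewer than two such groups the
    result is explicitly "not testable" rather than an exception.
    """
    from scipy import stats as sps
    from statsmodels.stats.multitest import multipletests

    method = "Welch one-way ANOVA; pairwise Welch t-tests, Holm-adjusted; Cohen's d"
    data = frame[[grouping, variable]].dropna()
    groups = {
        k: g[variable].to_numpy(dtype=float)
        for k, g in data.groupby(grouping, observed=True)
        if len(g) >= 3
    }
    if len(groups) < 2:
        return GroupComparison(
            variable=variable, grouping=grouping, testable=False, method=method,
            reason=f"need >= 2 groups with >= 3 non-missing values; have {len(groups)}",
        )

    import pingouin as pg

    long = pd.concat(
        [pd.DataFrame({grouping: k, variable: v}) for k, v in groups.items()],
        ignore_index=True,
    )
    try:
        aov = pg.welch_anova(data=long, dv=variable, between=grouping)
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        stat, p = float(aov["F"].iloc[0]), float(aov[p_col].iloc[0])
    except Exception:  # zero-variance degenerate groups
        stat, p = np.nan, np.nan

    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = groups[a], groups[b]
            if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0:
                t, pr = (np.nan, 1.0) if va.mean() == vb.mean() else (np.inf, 0.0)
            else:
                t, pr = sps.ttest_ind(va, vb, equal_var=False)
            rows.append(
                dict(group_a=a, group_b=b, n_a=va.size, n_b=vb.size,
                     t=float(t), p_raw=float(pr), cohens_d=_cohens_d(va, vb))
            )
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = multipletests(pairwise["p_raw"], method="holm")[1]
    return GroupComparison(
        variable=variable, grouping=grouping, testable=True, method=method,
        statistic=stat, p_value=p, pairwise=pairwise,
    )
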