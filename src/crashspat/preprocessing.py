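"""From raw crash tables to the analysis-ready binary-outcome dataset.

The modelled response is binary: 0 for property-damage-only (PDO) crashes,
1 for crashes with injury or fatality (fatalities are merged into injuries;
they are ~0.5% of the sample and too rare to model separately).  Older
drivers are those aged 65 or more, with the threshold inclusive.

The collinearity screen mirrors the usual Pearson pre-check before probit
fitting: pairs of predictors with |r| at or above a threshold (default 0.7,
a conventional cutoff) are flagged and the later-listed member of each pair
is dropped, deterministically, until no violation remains.

Row order — and therefore the alignment between the design matrix and the
coordinate list feeding the spatial weight matrix — is preserved by every
operation here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: severity_raw values mapped to the binary outcome
_SEVERITY_MAP = {"pdo": 0, "injury": 1, "fatality": 1, "0": 0, "1": 1, 0: 0, 1: 1}
#: markers treated as missing severity (dropped with a logged count)
_UNKNOWN_MARKERS = {"unknown", "nan", ""}


@dataclass
class DesignMatrix:
    """Response vector, predictor matrix with intercept, and metadata."""

    y: np.ndarray                 # binary response, shape (n,)
    X: np.ndarray                 # shape (n, k), first column all ones
    names: list[str]              # column names, names[0] == "intercept"
    coords: np.ndarray | None = None   # (n, 2) planar coords, row-aligned

    def __post_init__(self):
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y row counts differ")
        if not set(np.unique(self.y)).issubset({0, 1}):
            raise ValueError("response must be binary 0/1")
        if self.coords is not None and len(self.coords) != len(self.y):
            raise ValueError("coords and y row counts differ")

    @property
    def n(self) -> int:
        return len(self.y)

    def drop(self, name: str) -> "DesignMatrix":
        """New design without the named column (intercept cannot be dropped)."""
        if name == "intercept":
            raise ValueError("the intercept cannot be removed")
        j = self.names.index(name)
        return DesignMatrix(self.y, np.delete(self.X, j, axis=1),
                            self.names[:j] + self.names[j + 1:], self.coords)


def filter_older_drivers(table: pd.DataFrame, age_threshold: float = 65,
                         age_col: str = "age") -> pd.DataFrame:
    """Keep records with driver age >= threshold (inclusive: '65 and more')."""
    if age_col not in table.columns:
        raise KeyError(f"crash table has no {age_col!r} column")
    out = table[table[age_col] >= age_threshold].copy()
    logger.info("filter_older_drivers: kept %d of %d records (age >= %g)",
                len(out), len(table), age_threshold)
    return out


def binarize_severity(table: pd.DataFrame, severity_col: str = "severity"
                      ) -> pd.DataFrame:
    """Map severity to 0 (PDO) / 1 (injury or fatality).

    Already-binary input passes through unchanged.  Records whose severity
    is a designated unknown marker (NaN, "unknown") are dropped with a
    logged count; any other unrecognized code raises, listing the ids.
    """
    if severity_col not in table.columns:
        raise KeyError(f"crash table has no {severity_col!r} column")
    raw = table[severity_col]

    def norm(v):
        if isinstance(v, str):
            return v.strip().lower()
        if pd.isna(v):
            return "nan"
        if isinstance(v, float) and v.is_integer():
            return int(v)
        return v

    keys = raw.map(norm)
    unknown_mask = keys.isin(_UNKNOWN_MARKERS)
    bad = keys[~unknown_mask & ~keys.isin(_SEVERITY_MAP)]
    if len(bad):
        ids = (table.loc[bad.index, "id"].tolist()
               if "id" in table.columns else bad.index.tolist())
        raise ValueError(f"unrecognized severity code(s) {sorted(set(bad))} "
                         f"in records {ids}")
    if unknown_mask.any():
        logger.warning("binarize_severity: dropped %d record(s) with unknown "
                       "severity", int(unknown_mask.sum()))
    out = table[~unknown_mask].copy()
    out[severity_col] = keys[~unknown_mask].map(_SEVERITY_MAP).astype(int)
    return out


def collinearity_screen(table: pd.DataFrame, predictors: list[str],
                        r_threshold: float = 0.7
                        ) -> tuple[list[str], pd.DataFrame]:
    """Greedy Pearson screen.

    Constant columns are dropped first (flagged, never silent).  Then, while
    any retained pair has |r| >= threshold, the pair with the largest |r| is
    taken and its later-listed member dropped.  Returns the retained names
    and a report of every action (pair, r, column dropped).
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors to screen")
    report_rows = []
    retained = list(predictors)
    for name in list(retained):
        if table[name].nunique() <= 1:
            logger.warning("collinearity_screen: %r is constant; dropped", name)
            report_rows.append({"col_a": name, "col_b": "", "r": np.nan,
                                "dropped": name, "reason": "constant"})
            retained.remove(name)
    while len(retained) >= 2:
        corr = table[retained].astype(float).corr().to_numpy()
        viol = []
        for (i, a), (j, b) in combinations(enumerate(retained), 2):
            if abs(corr[i, j]) >= r_threshold:
                viol.append((abs(corr[i, j]), a, b, corr[i, j]))
        if not viol:
            break
        _, a, b, r = max(viol, key=lambda t: t[0])
        # drop the later-listed column of the worst pair
        report_rows.append({"col_a": a, "col_b": b, "r": r, "dropped": b,
                            "reason": f"|r| >= {r_threshold}"})
        retained.remove(b)
    report = pd.DataFrame(report_rows,
                          columns=["col_a", "col_b", "r", "dropped", "reason"])
    return retained, report


def build_design(table: pd.DataFrame, predictors: list[str],
                 encoding: str = "ordinal",
                 response_col: str = "severity") -> DesignMatrix:
    """Assemble the design matrix with a leading intercept column.

    ``ordinal`` passes the integer codes through as-is (one column per
    covariate — the convention the published tables imply); ``dummy``
    expands each categorical to k-1 indicators against the code-0
    ("Unknown") base level.
    """
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise KeyError(f"predictors not in table: {missing}")
    y = table[response_col].to_numpy()
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("response must be binarized before building the design")
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for p in predictors:
        vals = table[p].to_numpy()
        if encoding == "ordinal":
            cols.append(vals.astype(float))
            names.append(p)
        elif encoding == "dummy":
            levels = np.unique(vals)
            if len(levels) < 2:
                raise ValueError(f"predictor {p!r} has a single observed "
                                 f"level; cannot dummy-encode")
            base = levels[0]   # code 0 / lowest observed level
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{p}={lev}")
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
    coords = None
    if "x" in table.columns and "y" in table.columns:
        coords = np.column_stack([table["x"].to_numpy(float),
                                  table["y"].to_numpy(float)])
    return DesignMatrix(y.astype(int), np.column_stack(cols), names, coords)
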