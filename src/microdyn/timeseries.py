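"""Longitudinal abundance/metabolite tables and their on-disk representation.

The central container is :class:`TimeSeries`: a strictly increasing time grid
plus a (timepoints x variables) value matrix.  Each column carries a name and
a *kind* tag — ``"taxon"`` for microbial abundances or ``"metabolite"`` for
chemical concentrations — so that mixed species/metabolite panels (the input
to MVAR inference) travel as one object.  A boolean mask marks which entries
were actually observed; missing entries are the business of the imputation
module, and inference refuses to run on them.

On disk a TimeSeries is a tidy CSV (first column ``time``, one column per
variable, empty cells for missing values) with a sidecar JSON recording the
column kinds and any provenance metadata.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TAXON = "taxon"
METABOLITE = "metabolite"
_KINDS = frozenset({TAXON, METABOLITE})


class TimeSeriesError(ValueError):
    """Structural problem with a time series (shapes, time grid, kinds)."""


class NormalizationError(TimeSeriesError):
    """Raised when relative-abundance conversion is impossible for a row."""


@dataclass
class TimeSeries:
    """A time grid plus an observation matrix, one column per variable.

    Parameters
    ----------
    times : array of shape (T,)
        Strictly increasing sampling times (arbitrary units).
    values : array of shape (T, V)
        One row per timepoint, one column per variable.  Entries whose mask
        is False are present numerically (often NaN) but considered missing.
    mask : bool array of shape (T, V), optional
        True where the entry was observed.  Defaults to everything observed
        except NaN cells.
    names : sequence of str, optional
        Per-column identifiers; default ``x0..x{V-1}``.
    kinds : sequence of str, optional
        Per-column tag, ``"taxon"`` or ``"metabolite"``; default all taxon.
    meta : dict
        Free-form provenance (transforms applied, imputation records, units).
    """

    times: np.ndarray
    values: np.ndarray
    mask: np.ndarray | None = None
    names: Sequence[str] | None = None
    kinds: Sequence[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.times.ndim != 1:
            raise TimeSeriesError("times must be one-dimensional")
        if self.values.shape[0] != self.times.shape[0]:
            raise TimeSeriesError(
                f"values has {self.values.shape[0]} rows but times has "
                f"{self.times.shape[0]} entries"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise TimeSeriesError("times must be strictly increasing")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise TimeSeriesError("mask shape must match values shape")
        if self.names is None:
            self.names = [f"x{i}" for i in range(self.n_vars)]
        else:
            self.names = [str(n) for n in self.names]
            if len(self.names) != self.n_vars:
                raise TimeSeriesError("one name per column required")
            if len(set(self.names)) != len(self.names):
                raise TimeSeriesError("duplicate variable names")
        if self.kinds is None:
            self.kinds = [TAXON] * self.n_vars
        else:
            self.kinds = [str(k) for k in self.kinds]
            if len(self.kinds) != self.n_vars:
                raise TimeSeriesError("one kind per column required")
            bad = set(self.kinds) - _KINDS
            if bad:
                raise TimeSeriesError(f"unknown variable kinds: {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def n_timepoints(self) -> int:
        return self.times.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    @property
    def taxon_indices(self) -> np.ndarray:
        return np.flatnonzero([k == TAXON for k in self.kinds])

    @property
    def metabolite_indices(self) -> np.ndarray:
        return np.flatnonzero([k == METABOLITE for k in self.kinds])

    @property
    def has_missing(self) -> bool:
        return not bool(self.mask.all())

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            times=self.times.copy(),
            values=self.values.copy(),
            mask=self.mask.copy(),
            names=list(self.names),
            kinds=list(self.kinds),
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: ``time`` column first, masked entries as NaN."""
        vals = self.values.astype(float).copy()
        vals[~self.mask] = np.nan
        df = pd.DataFrame(vals, columns=list(self.names))
        df.insert(0, "time", self.times)
        return df

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nt = sum(k == TAXON for k in self.kinds)
        nm = self.n_vars - nt
        return (
            f"TimeSeries({self.n_timepoints} timepoints, {nt} taxa, "
            f"{nm} metabolites, missing={int((~self.mask).sum())})"
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write-then-rename so interrupted runs never leave truncated files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_timeseries(
    data: TimeSeries, path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Write a tidy CSV plus a sidecar JSON with column kinds and metadata.

    Missing (masked) entries serialize as empty fields.  The sidecar path
    defaults to ``<path>.meta.json``.
    """
    path = Path(path)
    df = data.to_dataframe()
    atomic_write_text(path, df.to_csv(index=False, na_rep=""))
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(
        path.suffix + ".meta.json"
    )
    payload = {"kinds": dict(zip(data.names, data.kinds)), "meta": data.meta}
    atomic_write_text(sidecar, json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def read_timeseries(
    path: str | Path, kinds_sidecar: str | Path | None = None
) -> TimeSeries:
    """Parse a tidy CSV (``time`` column required) into a TimeSeries.

    Empty cells become masked entries.  Column kinds come from the sidecar
    JSON when present (explicit path, else ``<path>.meta.json``); otherwise
    every column is tagged taxon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    if "time" not in df.columns:
        raise TimeSeriesError(f"{path}: no 'time' column")
    names = [c for c in df.columns if c != "time"]
    if len(set(names)) != len(names):
        raise TimeSeriesError(f"{path}: duplicate variable names")
    times = df["time"].to_numpy(dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise TimeSeriesError(f"{path}: time column is not strictly increasing")
    values = df[names].to_numpy(dtype=float)
    mask = np.isfinite(values)

    kinds = None
    meta: dict = {}
    sidecar = (
        Path(kinds_sidecar)
        if kinds_sidecar is not None
        else path.with_suffix(path.suffix + ".meta.json")
    )
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        kind_map = payload.get("kinds", {})
        kinds = [kind_map.get(n, TAXON) for n in names]
        meta = payload.get("meta", {})
    return TimeSeries(times=times, values=values, mask=mask, names=names,
                      kinds=kinds, meta=meta)


# ----------------------------------------------------------------------
# Compositional transform
# ----------------------------------------------------------------------

def to_relative_abundance(data: TimeSeries) -> TimeSeries:
    """Convert taxon columns to per-timepoint proportions.

    Each row's taxon entries are divided by that row's taxon total;
    metabolite columns are untouched.  Relative abundances sacrifice
    absolute-scale identifiability, so the transform is stamped into
    ``meta`` for downstream consumers.  Idempotent.
    """
    out = data.copy()
    tix = out.taxon_indices
    if tix.size == 0:
        raise NormalizationError("no taxon columns to normalize")
    taxa = out.values[:, tix]
    if np.any(taxa[out.mask[:, tix]] < 0):
        raise NormalizationError("taxon abundances must be nonnegative")
    with np.errstate(invalid="ignore"):
        totals = np.nansum(np.where(out.mask[:, tix], taxa, np.nan), axis=1)
    zero_rows = np.flatnonzero(~(totals > 0))
    if zero_rows.size:
        t = data.times[zero_rows[0]]
        raise NormalizationError(
            f"all-zero taxon row at timepoint {t!r} (row {zero_rows[0]})"
        )
    out.values[:, tix] = taxa / totals[:, None]
    out.meta["normalization"] = "relative_abundance"
    out.meta["normalization_caveat"] = (
        "compositional data: absolute interaction scales are not identifiable"
    )
    return out
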