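"""Dissolution-dataset container, CSV I/O, preprocessing, and splitting.

A dataset is a table of (formulation_id, d_mm, L_mm, t_min, Q_pct) records:
one cumulative-release observation of one cylindrical extrudate formulation
(diameter d, length L) at one sampling time.  The preprocessing transforms
mirror the study design: multiplicative noise augmentation, output-balance
duplication, linear scaling into an activation-function range, and
surrogate-model ("enhanced") design-space augmentation.  Splitting is
leave-one-formulation-out: each fold's test set is every record of exactly
one formulation, simulating prediction for an unseen geometry.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COLUMNS = ("formulation_id", "d_mm", "L_mm", "t_min", "Q_pct")
NUMERIC_COLUMNS = ("d_mm", "L_mm", "t_min", "Q_pct")

#: upper tolerance on cumulative release (%): small supersaturation /
#: assay overshoot above 100% is accepted.
Q_MAX = 110.0

__all__ = [
    "COLUMNS",
    "Q_MAX",
    "DissolutionRecord",
    "FormulationSpec",
    "Dataset",
    "VariableScale",
    "ScalingSpec",
    "FoldPair",
    "FormatError",
    "ValidationError",
    "DegenerateRangeError",
    "SplitError",
    "read_dissolution_csv",
    "write_dissolution_csv",
    "scale_linear",
    "unscale_linear",
    "add_noise",
    "balance_by_output",
    "split_leave_one_formulation_out",
    "build_enhanced_dataset",
]


class FormatError(ValueError):
    """CSV file structurally unusable (missing columns, empty, unreadable)."""


class ValidationError(ValueError):
    """Record values violate the dataset invariants."""


class DegenerateRangeError(ValueError):
    """A linear scaling was requested over a zero-width source range."""


class SplitError(ValueError):
    """Dataset cannot be split as requested."""


@dataclass(frozen=True)
class DissolutionRecord:
    """One (formulation, time, release) observation."""

    formulation_id: str
    d: float  # extrudate diameter, mm
    L: float  # extrudate length, mm
    t: float  # sampling time, min
    Q: float  # cumulative drug released, % of dose

    def __post_init__(self):
        if self.d <= 0 or self.L <= 0:
            raise ValidationError(f"nonpositive geometry d={self.d}, L={self.L}")
        if self.t < 0:
            raise ValidationError(f"negative time t={self.t}")
        if not (0.0 <= self.Q <= Q_MAX):
            raise ValidationError(f"Q={self.Q} outside [0, {Q_MAX}]")


@dataclass(frozen=True)
class FormulationSpec:
    """Geometry of one extrudate formulation."""

    formulation_id: str
    d: float  # mm
    L: float  # mm


@dataclass
class Dataset:
    """A table of dissolution records with provenance tracking.

    Wraps a pandas DataFrame with columns ``formulation_id, d_mm, L_mm,
    t_min, Q_pct``.  ``provenance`` tags how the data were produced;
    ``scaling`` records the linear map currently applied (None = raw units).
    """

    df: pd.DataFrame
    provenance: str = "original"
    scaling: "ScalingSpec | None" = None

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"dataset missing columns {missing}")
        if len(self.df) == 0:
            raise FormatError("dataset is empty")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def formulations(self) -> list[str]:
        """Formulation ids in first-appearance order."""
        return list(dict.fromkeys(self.df["formulation_id"]))

    def formulation_specs(self) -> list[FormulationSpec]:
        out = []
        for fid, grp in self.df.groupby("formulation_id", sort=False):
            d_vals, L_vals = grp["d_mm"].unique(), grp["L_mm"].unique()
            if len(d_vals) > 1 or len(L_vals) > 1:
                raise ValidationError(
                    f"formulation {fid!r} has inconsistent geometry"
                )
            out.append(FormulationSpec(str(fid), float(d_vals[0]), float(L_vals[0])))
        return out

    def records(self) -> list[DissolutionRecord]:
        return [
            DissolutionRecord(str(r.formulation_id), float(r.d_mm), float(r.L_mm),
                              float(r.t_min), float(r.Q_pct))
            for r in self.df.itertuples(index=False)
        ]

    def profile(self, formulation_id: str) -> pd.DataFrame:
        """Time-sorted (t_min, Q_pct) curve of one formulation."""
        sub = self.df[self.df["formulation_id"] == formulation_id]
        if len(sub) == 0:
            raise KeyError(formulation_id)
        return sub.sort_values("t_min").reset_index(drop=True)

    def replace(self, df: pd.DataFrame, provenance: str | None = None,
                scaling: "ScalingSpec | None | str" = "keep") -> "Dataset":
        return Dataset(
            df,
            provenance=self.provenance if provenance is None else provenance,
            scaling=self.scaling if scaling == "keep" else scaling,  # type: ignore[arg-type]
        )


@dataclass(frozen=True)
class VariableScale:
    """Endpoints of one variable's linear map source -> target."""

    source_min: float
    source_max: float
    target_min: float
    target_max: float

    def __post_init__(self):
        if not self.source_max > self.source_min:
            raise DegenerateRangeError(
                f"source range [{self.source_min}, {self.source_max}] is degenerate"
            )

    def apply(self, v):
        span = (self.target_max - self.target_min) / (self.source_max - self.source_min)
        return self.target_min + (np.asarray(v, dtype=float) - self.source_min) * span

    def invert(self, v):
        span = (self.source_max - self.source_min) / (self.target_max - self.target_min)
        return self.source_min + (np.asarray(v, dtype=float) - self.target_min) * span


@dataclass(frozen=True)
class ScalingSpec:
    """Per-variable linear-map endpoints, e.g. Q: [0, 100] -> <-0.8, 0.8>.

    The two study target ranges are <0.2, 0.8> (logistic activation) and
    <-0.8, 0.8> (hyperbolic tangent); any user range is accepted.
    """

    variables: Mapping[str, VariableScale]

    @classmethod
    def from_dataset(cls, ds: Dataset,
                     target: tuple[float, float] = (-0.8, 0.8),
                     columns: Sequence[str] = NUMERIC_COLUMNS) -> "ScalingSpec":
        """Build a spec from the dataset's own min/max per column."""
        lo, hi = target
        out = {}
        for c in columns:
            v = ds.df[c].to_numpy(dtype=float)
            out[c] = VariableScale(float(v.min()), float(v.max()), lo, hi)
        return cls(dict(out))

    def to_json(self) -> str:
        return json.dumps(
            {k: dataclasses.asdict(v) for k, v in self.variables.items()},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalingSpec":
        raw = json.loads(text)
        return cls({k: VariableScale(**v) for k, v in raw.items()})


@dataclass
class FoldPair:
    """One leave-one-formulation-out train/test split."""

    train: Dataset
    test: Dataset
    held_out_formulation: str

    def __post_init__(self):
        overlap = set(self.train.formulations) & set(self.test.formulations)
        if overlap:
            raise SplitError(f"formulations {sorted(overlap)} in both members")
        if self.test.formulations != [self.held_out_formulation]:
            raise SplitError("test fold must contain exactly the held-out formulation")


# ---------------------------------------------------------------------------
# I/O

def read_dissolution_csv(path) -> Dataset:
    """Read a dissolution dataset from CSV.

    Expected header: ``formulation_id,d_mm,L_mm,t_min,Q_pct`` (RFC 4180,
    UTF-8).  Raises FormatError on a missing column or empty file,
    ValidationError naming the first offending row on a non-numeric cell or
    an out-of-range value.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    for col in NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"{path}: non-numeric {col!r} at data row {row}")
        df[col] = parsed.astype(float)
    _validate_ranges(df, str(path))
    df["formulation_id"] = df["formulation_id"].astype(str)
    return Dataset(df, provenance="original")


def _validate_ranges(df: pd.DataFrame, origin: str) -> None:
    checks = [
        ("d_mm", df["d_mm"] <= 0, "nonpositive diameter"),
        ("L_mm", df["L_mm"] <= 0, "nonpositive length"),
        ("t_min", df["t_min"] < 0, "negative time"),
        ("Q_pct", (df["Q_pct"] < 0) | (df["Q_pct"] > Q_MAX),
         f"Q outside [0, {Q_MAX}]"),
    ]
    for col, bad, msg in checks:
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"{origin}: {msg} in {col!r} at data row {row}")


def write_dissolution_csv(ds: Dataset, path) -> None:
    ds.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing transforms

def scale_linear(ds: Dataset, spec: ScalingSpec) -> Dataset:
    """Apply per-variable linear maps; the spec is remembered on the result."""
    if ds.scaling is not None:
        raise ValidationError("dataset is already scaled; unscale first")
    df = ds.df.copy()
    for col, vs in spec.variables.items():
        if col not in df.columns:
            raise ValidationError(f"scaling names unknown column {col!r}")
        df[col] = vs.apply(df[col].to_numpy(dtype=float))
    return Dataset(df, provenance="scaled", scaling=spec)


def unscale_linear(ds: Dataset, spec: ScalingSpec | None = None) -> Dataset:
    """Invert ``scale_linear``; exact round-trip to ~1e-12 relative."""
    spec = spec if spec is not None else ds.scaling
    if spec is None:
        raise ValidationError("dataset carries no scaling spec")
    df = ds.df.copy()
    for col, vs in spec.variables.items():
        df[col] = vs.invert(df[col].to_numpy(dtype=float))
    return Dataset(df, provenance="original", scaling=None)


def add_noise(ds: Dataset, amplitude: float = 0.05, seed: int = 0) -> Dataset:
    """Append one jittered copy of every record (multiplicative noise).

    Each numeric field of the copy is drawn uniformly from
    ``[v*(1-amplitude), v*(1+amplitude)]`` — the study's +/-5% continuous
    jitter, applied to every variable.  Originals are kept (augmentation,
    not substitution).  Deterministic for a fixed seed.
    """
    if amplitude < 0:
        raise ValueError(f"negative noise amplitude {amplitude}")
    rng = np.random.default_rng(seed)
    noisy = ds.df.copy()
    for col in NUMERIC_COLUMNS:
        v = noisy[col].to_numpy(dtype=float)
        noisy[col] = v * rng.uniform(1.0 - amplitude, 1.0 + amplitude, size=len(v))
    noisy["Q_pct"] = noisy["Q_pct"].clip(0.0, Q_MAX)
    out = pd.concat([ds.df, noisy], ignore_index=True)
    return Dataset(out, provenance="noised", scaling=ds.scaling)


def balance_by_output(ds: Dataset, n_bins: int = 10) -> Dataset:
    """Duplicate records in under-populated release-level bins.

    Q is binned into ``n_bins`` equal-width bins; records of any nonempty
    bin with fewer than half the largest bin's count are duplicated
    (cyclically) until the bin reaches that level.  No record is removed and
    no new Q value is invented, so the transform only re-weights the
    low-release region that a raw sustained-release dataset under-samples.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    q = ds.df["Q_pct"].to_numpy(dtype=float)
    lo, hi = q.min(), q.max()
    if hi == lo:
        logger.warning("balance_by_output: all records share one Q value; unchanged")
        return ds.replace(ds.df.copy(), provenance="balanced")
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_idx = np.clip(np.digitize(q, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins)
    occupied = np.flatnonzero(counts)
    if len(occupied) == 1:
        logger.warning("balance_by_output: all records in one bin; unchanged")
        return ds.replace(ds.df.copy(), provenance="balanced")
    target = int(np.ceil(counts.max() / 2))
    pieces = [ds.df]
    for b in occupied:
        need = target - counts[b]
        if need <= 0:
            continue
        members = np.flatnonzero(bin_idx == b)
        reps = members[np.arange(need) % len(members)]
        pieces.append(ds.df.iloc[reps])
    out = pd.concat(pieces, ignore_index=True)
    return Dataset(out, provenance="balanced", scaling=ds.scaling)


def split_leave_one_formulation_out(ds: Dataset) -> list[FoldPair]:
    """One train/test pair per formulation; tests partition the dataset."""
    fids = ds.formulations
    if len(fids) < 2:
        raise SplitError("need at least two formulations to split")
    folds = []
    for fid in fids:
        mask = ds.df["formulation_id"] == fid
        test = Dataset(ds.df[mask].copy(), provenance=ds.provenance,
                       scaling=ds.scaling)
        train = Dataset(ds.df[~mask].copy(), provenance=ds.provenance,
                        scaling=ds.scaling)
        folds.append(FoldPair(train=train, test=test, held_out_formulation=fid))
    return folds


def grid_1d(vmin: float, vmax: float, step_frac: float, extend: float) -> np.ndarray:
    """Regular grid from vmin to extend*vmax with step step_frac*(vmax-vmin).

    The upper boundary extend*vmax is always included (the sampled design
    space runs between the minimum and 110% of the maximum), so the last
    interval may be shorter than the step.  Interior node count is the
    closed form floor((extend*vmax - vmin)/step) + 1.
    """
    step = step_frac * (vmax - vmin)
    if step <= 0:
        raise DegenerateRangeError(f"degenerate grid range [{vmin}, {vmax}]")
    top = extend * vmax
    n = int(np.floor((top - vmin) / step + 1e-9)) + 1
    grid = vmin + step * np.arange(n)
    if top - grid[-1] > 1e-9 * step:
        grid = np.append(grid, top)
    return grid


def build_enhanced_dataset(train: Dataset,
                           predictor: Callable[[np.ndarray, np.ndarray], np.ndarray],
                           test: Dataset,
                           step_frac: float = 0.0333,
                           extend: float = 1.10,
                           d_tol: float = 1e-9) -> Dataset:
    """Augment a training set with surrogate-model predictions on a grid.

    A regular (d, t) grid spans each input from its training minimum to
    ``extend`` times its maximum with step ``step_frac`` of the min-max
    range — interpolation plus limited extrapolation of the design space.
    ``predictor(d, t) -> Q`` (typically a trained neural net wrapped with
    its scaling) synthesizes the release value at every node.  Nodes whose
    diameter coincides (within ``d_tol``) with the held-out test
    formulation's diameter are discarded so the augmented set leaks nothing
    about the test geometry.  The result is train plus the artificial
    records; artificial records carry per-diameter ids ``aug###`` and the
    training-set mean length (length does not enter the predictor).
    """
    d = train.df["d_mm"].to_numpy(dtype=float)
    t = train.df["t_min"].to_numpy(dtype=float)
    d_grid = grid_1d(d.min(), d.max(), step_frac, extend)
    t_grid = grid_1d(t.min(), t.max(), step_frac, extend)
    held_d = np.unique(test.df["d_mm"].to_numpy(dtype=float))
    keep = ~np.any(np.abs(d_grid[:, None] - held_d[None, :]) <= d_tol, axis=1)
    d_grid = d_grid[keep]
    L_fill = float(train.df["L_mm"].mean())
    rows = []
    for i, dv in enumerate(d_grid):
        try:
            q = np.asarray(predictor(np.full_like(t_grid, dv), t_grid), dtype=float)
        except Exception:  # surrogate failure at a node group: skip, keep going
            logger.warning("enhanced grid: predictor failed at d=%.4f; skipped", dv)
            continue
        q = np.clip(q, 0.0, Q_MAX)
        rows.append(pd.DataFrame({
            "formulation_id": f"aug{i:03d}",
            "d_mm": dv, "L_mm": L_fill, "t_min": t_grid, "Q_pct": q,
        }))
    out = pd.concat([train.df] + rows, ignore_index=True)
    return Dataset(out, provenance="enhanced", scaling=train.scaling)
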