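"""Baseline prediction grid, per-substitution linear models, transcribed
reference equations, and the web-app data export.

The grid tabulates the trained network over all 3 × 11 × 14 = 462
combinations of secondary-structure code (−1/0/+1), RSA (0.0–1.0 in 0.1
steps) and mean B-factor (10–140 Å² in steps of 10) for each ordered amino
acid substitution — 380 × 462 = 175,560 rows for the full grid.  Enumeration
order is fixed (substitution, then ss ascending, rsa ascending, b ascending)
so exports are diffable.

Per-substitution models are ordinary least squares of ΔTm on (RSA, avg
B-factor, ss code) with intercept.  Two published Val→Ala reference
equations are shipped as transcribed, evaluable fixtures:

* ``val_ala_linear``:   ΔTm = 12.63·RSA − 0.089·B + 1.95·SS − 5.81
* ``val_ala_symbolic``: ΔTm = SS − SS/(8.58·RSA − 0.89) + 13.56·RSA − 7.35
  (a pole at RSA = 0.89/8.58 ≈ 0.1037; evaluation within 1e−9 of the pole
  returns NaN, flagged undefined, rather than ±infinity).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    AA_ALPHABET,
    MutationDataset,
    classify_stability,
)
from .features import N_FEATURES, PropertyTable
from .network import TrainedBaseline, predict_vectors

__all__ = [
    "GridSpec",
    "all_substitutions",
    "generate_grid",
    "SubstitutionLinearModel",
    "fit_substitution_regression",
    "ReferenceEquation",
    "REFERENCE_EQUATIONS",
    "eval_reference_equation",
    "export_webapp_json",
    "validate_webapp_doc",
]


@dataclass
class GridSpec:
    """The structural-feature grid: 3 ss × 11 rsa × 14 b = 462 points."""

    ss_values: tuple[int, ...] = (-1, 0, 1)
    rsa_values: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    b_values: tuple[float, ...] = tuple(float(b) for b in range(10, 150, 10))

    def __post_init__(self):
        if len(self.ss_values) != 3 or len(self.rsa_values) != 11 or len(self.b_values) != 14:
            raise ValueError("grid must be 3 ss x 11 rsa x 14 b values")

    @property
    def size(self) -> int:
        return len(self.ss_values) * len(self.rsa_values) * len(self.b_values)  # 462

    def points(self):
        """Deterministic enumeration: ss asc, rsa asc, b asc."""
        return itertools.product(
            sorted(self.ss_values), sorted(self.rsa_values), sorted(self.b_values)
        )


def all_substitutions() -> list[tuple[str, str]]:
    """All 380 ordered off-diagonal amino-acid pairs, in alphabet order."""
    return [(a, b) for a in AA_ALPHABET for b in AA_ALPHABET if a != b]


def generate_grid(
    model: TrainedBaseline,
    spec: GridSpec | None = None,
    substitutions: list[tuple[str, str]] | None = None,
    table: PropertyTable | None = None,
) -> pd.DataFrame:
    """Tabulate network predictions over the structural grid.

    Returns a DataFrame with columns (wt_aa, mut_aa, ss, rsa, b, pred_dtm),
    462 rows per substitution in the documented enumeration order.
    """
    spec = spec or GridSpec()
    table = table or PropertyTable.default()
    subs = substitutions if substitutions is not None else all_substitutions()
    points = list(spec.points())
    n_pts = len(points)
    struct_block = np.array(points, dtype=float)[:, [1, 2, 0]] if n_pts else np.empty((0, 3))

    frames = []
    X = np.empty((n_pts, N_FEATURES), dtype=float)
    for wt, mut in subs:
        # vectorized layout identical to encode_mutation: wt scales, deltas,
        # then rsa / avg_b / ss
        wt_row, mut_row = table.row(wt), table.row(mut)
        X[:, 0:8] = wt_row
        X[:, 8:16] = mut_row - wt_row
        X[:, 16:19] = struct_block
        preds = predict_vectors(model, X)
        frames.append(
            pd.DataFrame(
                {
                    "wt_aa": wt,
                    "mut_aa": mut,
                    "ss": [p[0] for p in points],
                    "rsa": [p[1] for p in points],
                    "b": [p[2] for p in points],
                    "pred_dtm": preds,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["wt_aa", "mut_aa", "ss", "rsa", "b", "pred_dtm"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class SubstitutionLinearModel:
    """OLS fit of ΔTm on (rsa, avg_b, ss) with intercept for one substitution."""

    wt_aa: str
    mut_aa: str
    coef_rsa: float
    coef_b: float
    coef_ss: float
    intercept: float
    n_entries: int
    rmse: float
    pearson_r: float | None

    def predict(self, rsa, b, ss):
        return (
            self.coef_rsa * np.asarray(rsa)
            + self.coef_b * np.asarray(b)
            + self.coef_ss * np.asarray(ss)
            + self.intercept
        )


def fit_substitution_regression(
    ds: MutationDataset,
    wt_aa: str,
    mut_aa: str,
    min_entries: int = 10,
) -> SubstitutionLinearModel:
    """Least-squares ΔTm ~ rsa + avg_b + ss_code + 1 on the annotated entries
    of one ordered substitution."""
    rows = [
        e
        for e in ds
        if e.wt_aa == wt_aa and e.mut_aa == mut_aa and e.is_annotated
    ]
    if len(rows) < min_entries:
        raise ValueError(
            f"{wt_aa}->{mut_aa}: {len(rows)} annotated entries, need >= {min_entries}"
        )
    X = np.array([[e.rsa, e.avg_b, float(e.ss_code), 1.0] for e in rows])
    y = np.array([e.d_tm for e in rows])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError(f"{wt_aa}->{mut_aa}: rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = fitted - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    r = None
    if np.std(fitted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(fitted, y)[0, 1])
    return SubstitutionLinearModel(
        wt_aa=wt_aa,
        mut_aa=mut_aa,
        coef_rsa=float(beta[0]),
        coef_b=float(beta[1]),
        coef_ss=float(beta[2]),
        intercept=float(beta[3]),
        n_entries=len(rows),
        rmse=rmse,
        pearson_r=r,
    )


@dataclass(frozen=True)
class ReferenceEquation:
    """A published closed-form ΔTm model, transcribed with fixed parameters."""

    name: str
    parameters: tuple[float, ...]
    description: str

    def __call__(self, rsa: float, b: float, ss: float) -> float:
        if self.name == "val_ala_linear":
            c_rsa, c_b, c_ss, c0 = self.parameters
            return c_rsa * rsa + c_b * b + c_ss * ss + c0
        if self.name == "val_ala_symbolic":
            a, c, d, e = self.parameters
            denom = a * rsa - c
            if abs(denom) < 1e-9:
                return math.nan  # flagged undefined at the pole
            return ss - ss / denom + d * rsa + e
        raise KeyError(self.name)

    @property
    def pole_rsa(self) -> float | None:
        if self.name == "val_ala_symbolic":
            a, c, *_ = self.parameters
            return c / a
        return None


REFERENCE_EQUATIONS: dict[str, ReferenceEquation] = {
    "val_ala_linear": ReferenceEquation(
        name="val_ala_linear",
        parameters=(12.63, -0.089, 1.95, -5.81),
        description="Val->Ala multiple linear regression: "
        "dTm = 12.63 RSA - 0.089 B + 1.95 SS - 5.81 (transcribed fixture)",
    ),
    "val_ala_symbolic": ReferenceEquation(
        name="val_ala_symbolic",
        parameters=(8.58, 0.89, 13.56, -7.35),
        description="Val->Ala symbolic-regression result: "
        "dTm = SS - SS/(8.58 RSA - 0.89) + 13.56 RSA - 7.35 (transcribed fixture)",
    ),
}


def eval_reference_equation(name: str, rsa: float, b: float = 0.0, ss: float = 0.0) -> float:
    """Evaluate a shipped reference equation; NaN marks the symbolic pole."""
    if name not in REFERENCE_EQUATIONS:
        raise KeyError(f"unknown reference equation: {name!r}")
    for v in (rsa, b, ss):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    return REFERENCE_EQUATIONS[name](rsa, b, ss)


_WEBAPP_SCHEMA_VERSION = 1


def export_webapp_json(
    ds: MutationDataset,
    grid: pd.DataFrame,
    out_dir,
    threshold: float = 2.0,
) -> list[Path]:
    """Write one JSON document per ordered substitution with experimental
    entries (colored by stability category) and grid predictions, plus an
    index file.  Returns the written paths (index last)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    colors = {"destabilizing": "red", "neutral": "blue", "stabilizing": "green"}

    by_sub: dict[tuple[str, str], list] = {}
    for e in ds:
        by_sub.setdefault((e.wt_aa, e.mut_aa), []).append(e)

    grid_by_sub = dict(tuple(grid.groupby(["wt_aa", "mut_aa"], sort=False))) if len(grid) else {}

    written: list[Path] = []
    index = {"schema_version": _WEBAPP_SCHEMA_VERSION, "substitutions": []}
    for (wt, mut), entries in sorted(by_sub.items()):
        doc = {
            "schema_version": _WEBAPP_SCHEMA_VERSION,
            "wt_aa": wt,
            "mut_aa": mut,
            "entries": [
                {
                    "protein_id": e.protein_id,
                    "chain": e.chain,
                    "residue_number": e.residue_number,
                    "d_tm": e.d_tm,
                    "rsa": e.rsa,
                    "avg_b": e.avg_b,
                    "ss_code": e.ss_code,
                    "category": classify_stability(e.d_tm, threshold),
                    "color": colors[classify_stability(e.d_tm, threshold)],
                }
                for e in entries
            ],
            "grid": (
                grid_by_sub[(wt, mut)][["ss", "rsa", "b", "pred_dtm"]].to_dict("records")
                if (wt, mut) in grid_by_sub
                else []
            ),
        }
        path = out_dir / f"{wt}{mut}.json"
        path.write_text(json.dumps(doc))
        written.append(path)
        index["substitutions"].append(
            {"wt_aa": wt, "mut_aa": mut, "file": path.name, "n_entries": len(entries)}
        )
    index_path = out_dir / "index.json"
    index_path.write_text(json.dumps(index, indent=2))
    written.append(index_path)
    return written


def validate_webapp_doc(doc: dict) -> None:
    """Raise ValueError if a per-substitution export document is malformed."""
    for key in ("schema_version", "wt_aa", "mut_aa", "entries", "grid"):
        if key not in doc:
            raise ValueError(f"missing key: {key}")
    for e in doc["entries"]:
        for key in ("protein_id", "d_tm", "category", "color"):
            if key not in e:
                raise ValueError(f"entry missing key: {key}")
        if e["category"] not in ("destabilizing", "neutral", "stabilizing"):
            raise ValueError(f"bad category: {e['category']}")
    for g in doc["grid"]:
        for key in ("ss", "rsa", "b", "pred_dtm"):
            if key not in g:
                raise ValueError(f"grid row missing key: {key}")
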