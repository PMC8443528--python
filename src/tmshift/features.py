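"""Mutation featurization: the 19-number network input and its normalization.

The input vector for one mutation is laid out as

* slots 0–7   — the 8 physicochemical descriptor values of the wild-type
  amino acid (hydrophobicity, side-chain volume, polarity, formal charge at
  neutral pH, H-bond donor+acceptor count, flexibility, helix propensity,
  sheet propensity);
* slots 8–15  — the descriptor changes, mutant − wild type, same scale order;
* slot 16     — RSA of the wild-type residue (fraction);
* slot 17     — mean C/N/O B-factor (Å²);
* slot 18     — ternary secondary-structure code (−1/0/+1).

The 16 physicochemical numbers follow the "wild-type values plus wild-type→
mutant changes" reading of an 8-scale property table; the table is a
delimited-text config, so any alternative 8-scale set can be swapped in
without code change.  Default scales: Kyte–Doolittle hydrophobicity
(kcal/mol-ish, unitless), Zamyatnin side-chain volume (Å³), Grantham polarity
(unitless), formal charge at neutral pH (−1/0/+1; Asp/Glu −1, Lys/Arg +1,
His 0), side-chain H-bond donor+acceptor count (this package's convention),
Vihinen normalized flexibility (unitless), Pace–Scholtz helix propensity
(kcal/mol), Chou–Fasman sheet propensity (unitless).

Normalization is z-scoring fitted on a training set and reused verbatim
elsewhere; the secondary-structure slot and the two charge-valued slots
(wild-type charge, charge delta) are passed through untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .dataset import AA_ALPHABET, AA_SET
from .structure import StructuralFeatures

SCALE_NAMES = (
    "hydrophobicity",
    "volume",
    "polarity",
    "charge",
    "hbond",
    "flexibility",
    "helix_propensity",
    "sheet_propensity",
)
N_SCALES = len(SCALE_NAMES)
N_FEATURES = 19

# fixed slot indices
WT_SLOTS = tuple(range(0, 8))
DELTA_SLOTS = tuple(range(8, 16))
RSA_SLOT = 16
B_SLOT = 17
SS_SLOT = 18
CHARGE_WT_SLOT = WT_SLOTS[SCALE_NAMES.index("charge")]      # 3
CHARGE_DELTA_SLOT = DELTA_SLOTS[SCALE_NAMES.index("charge")]  # 11

#: slots never z-scored: secondary structure and the two charge-coded slots
UNTRANSFORMED_SLOTS = (CHARGE_WT_SLOT, CHARGE_DELTA_SLOT, SS_SLOT)


@dataclass
class PropertyTable:
    """20×8 amino-acid descriptor table (rows: amino acids, columns: scales)."""

    values: pd.DataFrame

    def __post_init__(self):
        missing_aa = AA_SET - set(self.values.index)
        if missing_aa:
            raise ValueError(f"property table missing amino acids: {sorted(missing_aa)}")
        missing_scales = set(SCALE_NAMES) - set(self.values.columns)
        if missing_scales:
            raise ValueError(f"property table missing scales: {sorted(missing_scales)}")
        if self.values[list(SCALE_NAMES)].isna().any().any():
            raise ValueError("property table has missing values")
        if not set(self.values["charge"].unique()) <= {-1, 0, 1}:
            raise ValueError("charge scale must take values in {-1, 0, +1}")
        self.values = self.values.loc[list(AA_ALPHABET), list(SCALE_NAMES)].astype(float)

    @classmethod
    def default(cls) -> "PropertyTable":
        with resources.files("tmshift.data").joinpath("property_scales.tsv").open() as fh:
            return cls.from_tsv(fh)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "PropertyTable":
        df = pd.read_csv(path_or_buf, sep="\t").set_index("aa")
        return cls(values=df)

    def to_tsv(self, path) -> None:
        self.values.reset_index(names="aa").to_csv(path, sep="\t", index=False)

    def row(self, aa: str) -> np.ndarray:
        if aa not in AA_SET:
            raise ValueError(f"unknown amino acid: {aa!r}")
        return self.values.loc[aa].to_numpy(dtype=float)


def encode_mutation(
    wt_aa: str,
    mut_aa: str,
    features: StructuralFeatures,
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Build the 19-number input vector for one (annotated) mutation."""
    table = table or PropertyTable.default()
    wt = table.row(wt_aa)
    mut = table.row(mut_aa)
    v = np.empty(N_FEATURES, dtype=float)
    v[list(WT_SLOTS)] = wt
    v[list(DELTA_SLOTS)] = mut - wt
    v[RSA_SLOT] = features.rsa
    v[B_SLOT] = features.avg_b
    v[SS_SLOT] = float(features.ss_code)
    return v


@dataclass
class Normalizer:
    """Per-slot z-scoring statistics with an exclusion mask.

    Transformed slots with zero training variance are flagged degenerate and
    given SD 1 so tiny fixtures still train.
    """

    mean: np.ndarray
    sd: np.ndarray
    transform_mask: np.ndarray  # bool, True where z-scored
    degenerate_slots: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "transform_mask": self.transform_mask.astype(int).tolist(),
            "degenerate_slots": list(self.degenerate_slots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            transform_mask=np.asarray(d["transform_mask"], dtype=bool),
            degenerate_slots=list(d["degenerate_slots"]),
        )


def fit_normalizer(vectors) -> Normalizer:
    """Estimate per-slot mean/SD on a training collection of feature vectors."""
    X = np.asarray(list(vectors), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors to fit a normalizer")
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"feature vectors must have length {N_FEATURES}")
    mask = np.ones(N_FEATURES, dtype=bool)
    mask[list(UNTRANSFORMED_SLOTS)] = False
    mean = np.where(mask, X.mean(axis=0), 0.0)
    sd = np.where(mask, X.std(axis=0, ddof=0), 1.0)
    degenerate = [int(i) for i in np.where(mask & (sd == 0))[0]]
    sd[sd == 0] = 1.0
    return Normalizer(mean=mean, sd=sd, transform_mask=mask, degenerate_slots=degenerate)


def apply_normalizer(norm: Normalizer, v: np.ndarray) -> np.ndarray:
    """Z-score the transformed slots; pass excluded slots through unchanged."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != N_FEATURES:
        raise ValueError(f"expected length-{N_FEATURES} vector(s), got shape {v.shape}")
    return np.where(norm.transform_mask, (v - norm.mean) / norm.sd, v)


def invert_normalizer(norm: Normalizer, v: np.ndarray) -> np.ndarray:
    """Algebraic inverse of :func:`apply_normalizer`."""
    v = np.asarray(v, dtype=float)
    return np.where(norm.transform_mask, v * norm.sd + norm.mean, v)
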