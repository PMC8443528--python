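"""Synthetic ΔTm datasets with known ground truth, plus toy structure files.

The generator emulates the composition of curated ΔTm mutation collections:
~1626 entries over ~90 proteins with one dominant protein family holding
25–30% of the rows, |ΔTm| truncated below 20 °C, a strong skew toward
destabilization (~47% of entries below −2 °C vs ~12% above +2 °C), RSA-
dependent effect magnitude (buried sites hit harder than exposed ones), and
sparse large structure-specific outliers on top of a smooth per-substitution
baseline.

Each entry's ΔTm is drawn as

    ΔTm = c0 + c1·RSA + c2·B + c3·SS + ε + outlier,   ε ~ N(0, noise_sd²)

with per-ordered-substitution coefficients (c0, c1, c2, c3).  The intercept
c0 = shift − |N(0, scale)| gives a destabilizing half-normal tail with a
small stabilizing mass; the RSA slope c1 = −relief·c0 makes the effect decay
toward zero at exposed sites (the baseline effect is roughly
c0·(1 − relief·RSA)); B-factor and secondary-structure slopes are small
Gaussian draws.  Outliers are additive deviations of random sign, standing
in for structure-specific contributions.  Entries beyond the truncation
limit are resampled (default) or dropped.

The skew defaults (shift 1.8 °C, scale 5.5 °C, relief 0.9) were set once so
that, at n = 1626 with 2 °C noise and 5% outliers, the destabilizing and
stabilizing fractions land near the emulation targets above.

Structure fixtures are geometric placeholder peptides: syntactically valid
PDB text with configurable per-atom B-factors and a matching classic-format
DSSP assignment text — sufficient for parsing and feature-extraction tests,
with no pretense of physical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import AA_ALPHABET, MutationDataset, MutationEntry, TECHNIQUES
from .structure import TIEN_MAX_ACC

__all__ = [
    "DestabilizationSkew",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "simulate_dataset",
    "StructureSimConfig",
    "simulate_structure",
]

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass
class DestabilizationSkew:
    """Parameters shaping the per-substitution intercept distribution."""

    intercept_shift: float = 1.8   # °C; upper edge of the half-normal intercepts
    intercept_scale: float = 5.5   # °C; half-normal width of destabilizing tail
    rsa_relief: float = 0.9        # fraction of the intercept relieved at RSA = 1
    b_slope_sd: float = 0.02       # °C per Å²
    ss_slope_sd: float = 0.8       # °C per ss unit


@dataclass
class SyntheticConfig:
    """Generating conditions for a synthetic ΔTm dataset."""

    n_proteins: int = 90
    residues_per_protein: int = 120
    n_entries: int = 1626
    dominance_weights: tuple[float, ...] | None = None  # default: 0.28/0.13/0.08 + uniform rest
    substitutions: tuple[tuple[str, str], ...] | None = None  # default: all 380
    baseline_coefficients: dict[tuple[str, str], tuple[float, float, float, float]] | None = None
    noise_sd: float = 2.0          # °C
    outlier_fraction: float = 0.05
    outlier_magnitude_range: tuple[float, float] = (4.0, 15.0)  # °C
    truncation_limit: float = 20.0  # °C
    truncation_mode: str = "resample"  # or "drop"
    skew: DestabilizationSkew = field(default_factory=DestabilizationSkew)
    p_buried: float = 0.55
    ss_probs: tuple[float, float, float] = (0.25, 0.35, 0.40)  # P(ss = -1, 0, +1)
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1 or self.n_entries < 1:
            raise ValueError("n_proteins and n_entries must be positive")
        if self.truncation_limit <= 0:
            raise ValueError("truncation_limit must be positive")
        if not (0.0 <= self.outlier_fraction <= 1.0):
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.truncation_mode not in ("resample", "drop"):
            raise ValueError("truncation_mode must be 'resample' or 'drop'")
        if abs(sum(self.ss_probs) - 1.0) > 1e-9:
            raise ValueError("ss_probs must sum to 1")

    def resolved_weights(self) -> np.ndarray:
        if self.dominance_weights is not None:
            w = np.asarray(self.dominance_weights, dtype=float)
            if len(w) != self.n_proteins or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("invalid dominance_weights")
            return w / w.sum()
        # one dominant family plus two common ones, emulating real skew
        heads = [0.28, 0.13, 0.08][: self.n_proteins]
        w = np.full(self.n_proteins, 0.0)
        w[: len(heads)] = heads
        rest = self.n_proteins - len(heads)
        if rest > 0:
            w[len(heads):] = (1.0 - sum(heads)) / rest
        return w / w.sum()


@dataclass
class SyntheticGroundTruth:
    """The realized generating model behind a synthetic dataset."""

    baseline_coefficients: dict[tuple[str, str], tuple[float, float, float, float]]
    entry_baseline: list[float]       # c0 + c1·rsa + c2·b + c3·ss per entry
    entry_noise: list[float]
    entry_is_outlier: list[bool]
    entry_deviation: list[float]      # injected outlier deviation, 0 if none
    seed: int

    def coefficients_for(self, wt_aa: str, mut_aa: str):
        return self.baseline_coefficients[(wt_aa, mut_aa)]


def _draw_coefficients(rng: np.random.Generator, subs, skew: DestabilizationSkew):
    coeffs = {}
    for pair in subs:
        c0 = skew.intercept_shift - abs(rng.normal(0.0, skew.intercept_scale))
        c1 = -skew.rsa_relief * c0
        c2 = rng.normal(0.0, skew.b_slope_sd)
        c3 = rng.normal(0.0, skew.ss_slope_sd)
        coeffs[pair] = (float(c0), float(c1), float(c2), float(c3))
    return coeffs


def _draw_features(rng: np.random.Generator, cfg: SyntheticConfig):
    if rng.random() < cfg.p_buried:
        rsa = float(np.clip(rng.normal(0.05, 0.05), 0.0, 1.0))
    else:
        rsa = float(np.clip(rng.normal(0.5, 0.2), 0.0, 1.0))
    avg_b = float(rng.gamma(shape=4.0, scale=7.5))
    ss = int(rng.choice((-1, 0, 1), p=cfg.ss_probs))
    # features are rounded at draw time so the emitted table reproduces the
    # ground-truth baseline exactly
    return round(rsa, 4), round(avg_b, 2), ss


def _draw_ph(rng: np.random.Generator) -> float:
    # emulates the curated-collection marginals: ~20% <=3.5, ~17% (3.5,6),
    # ~50% 6-8, ~13% >8
    u = rng.random()
    if u < 0.20:
        return float(rng.uniform(2.0, 3.5))
    if u < 0.37:
        return float(rng.uniform(3.5, 6.0))
    if u < 0.87:
        return float(rng.uniform(6.0, 8.0))
    return float(rng.uniform(8.0, 10.0))


_TECH_PROBS = (0.46, 0.29, 0.18, 0.03, 0.02, 0.02)  # CD, DSC, FL, Abs, activity, other


def simulate_dataset(cfg: SyntheticConfig) -> tuple[MutationDataset, SyntheticGroundTruth]:
    """Generate a dataset and the ground truth that produced it.

    Seed-deterministic: identical configs yield byte-identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    subs = (
        list(cfg.substitutions)
        if cfg.substitutions is not None
        else [(a, b) for a in AA_ALPHABET for b in AA_ALPHABET if a != b]
    )
    for wt, mut in subs:
        if wt == mut:
            raise ValueError("substitutions must be off-diagonal")
    coeffs = cfg.baseline_coefficients or _draw_coefficients(rng, subs, cfg.skew)
    weights = cfg.resolved_weights()
    protein_ids = [f"S{i:03d}" for i in range(cfg.n_proteins)]
    protein_tm = {
        pid: float(np.clip(rng.normal(60.0, 12.0), 35.0, 99.0)) for pid in protein_ids
    }
    sub_idx = np.arange(len(subs))

    ds = MutationDataset(provenance=f"synthetic(seed={cfg.seed})")
    gt = SyntheticGroundTruth(
        baseline_coefficients=coeffs,
        entry_baseline=[],
        entry_noise=[],
        entry_is_outlier=[],
        entry_deviation=[],
        seed=cfg.seed,
    )

    for _ in range(cfg.n_entries):
        accepted = False
        for _attempt in range(1000):
            p = int(rng.choice(cfg.n_proteins, p=weights))
            pid = protein_ids[p]
            resnum = int(rng.integers(1, cfg.residues_per_protein + 1))
            wt, mut = subs[int(rng.choice(sub_idx))]
            rsa, avg_b, ss = _draw_features(rng, cfg)
            c0, c1, c2, c3 = coeffs[(wt, mut)]
            baseline = c0 + c1 * rsa + c2 * avg_b + c3 * ss
            noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
            is_outlier = rng.random() < cfg.outlier_fraction
            deviation = 0.0
            if is_outlier:
                mag = float(rng.uniform(*cfg.outlier_magnitude_range))
                deviation = mag if rng.random() < 0.5 else -mag
            d_tm = baseline + noise + deviation
            if abs(d_tm) < cfg.truncation_limit:
                accepted = True
                break
            if cfg.truncation_mode == "drop":
                break
        if not accepted:
            continue  # dropped (or resampling failed; vanishingly rare)
        ds.entries.append(
            MutationEntry(
                protein_id=pid,
                chain="A",
                residue_number=resnum,
                wt_aa=wt,
                mut_aa=mut,
                tm_wt=round(protein_tm[pid], 2),
                d_tm=round(d_tm, 4),
                ph=round(_draw_ph(rng), 2),
                technique=str(rng.choice(TECHNIQUES, p=_TECH_PROBS)),
                rsa=rsa,
                avg_b=avg_b,
                ss_code=ss,
            )
        )
        gt.entry_baseline.append(baseline)
        gt.entry_noise.append(noise)
        gt.entry_is_outlier.append(bool(is_outlier))
        gt.entry_deviation.append(deviation)
    return ds, gt


@dataclass
class StructureSimConfig:
    """Configuration of a toy peptide structure and its DSSP-style assignment.

    ``b_factors`` maps residue index (0-based) to either one B-factor for all
    atoms or a per-atom-name dict; ``ss_classes`` is one DSSP class character
    per residue; ``acc_values`` are accessible-surface areas in Å².
    """

    sequence: str = "AVL"
    chain: str = "A"
    first_residue_number: int = 1
    b_factors: dict[int, float | dict[str, float]] = field(default_factory=dict)
    default_b: float = 20.0
    ss_classes: str | None = None     # default: all coil (blank)
    acc_values: tuple[float, ...] | None = None  # default: half the max ACC

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise ValueError("toy peptide needs >= 3 residues")
        if any(aa not in _ONE_TO_THREE for aa in self.sequence):
            raise ValueError("sequence must use canonical amino acids")
        if self.ss_classes is not None and len(self.ss_classes) != len(self.sequence):
            raise ValueError("ss_classes length must match sequence")
        if self.acc_values is not None and len(self.acc_values) != len(self.sequence):
            raise ValueError("acc_values length must match sequence")


# backbone + CB offsets (Å) within a residue; geometric placeholders only
_ATOM_TEMPLATE = (
    ("N", "N", (0.0, 0.0, 0.0)),
    ("CA", "C", (1.46, 0.0, 0.0)),
    ("C", "C", (2.0, 1.4, 0.0)),
    ("O", "O", (1.4, 2.4, 0.0)),
    ("CB", "C", (2.0, -1.0, 1.0)),
)


def simulate_structure(cfg: StructureSimConfig | None = None) -> tuple[str, str]:
    """Write matching PDB coordinate text and classic-format DSSP text for a
    toy peptide."""
    cfg = cfg or StructureSimConfig()
    pdb_lines: list[str] = []
    serial = 1
    for i, aa in enumerate(cfg.sequence):
        resname = _ONE_TO_THREE[aa]
        resnum = cfg.first_residue_number + i
        bspec = cfg.b_factors.get(i, cfg.default_b)
        for name, element, (dx, dy, dz) in _ATOM_TEMPLATE:
            if name == "CB" and aa == "G":
                continue
            b = bspec.get(name, cfg.default_b) if isinstance(bspec, dict) else bspec
            x, y, z = 3.8 * i + dx, dy, dz
            pdb_lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {cfg.chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          {element:>2s}"
            )
            serial += 1
    pdb_lines.append("END")
    pdb_text = "\n".join(pdb_lines) + "\n"

    dssp_lines = [
        "==== Secondary Structure Definition; synthetic placeholder ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N",
    ]
    for i, aa in enumerate(cfg.sequence):
        resnum = cfg.first_residue_number + i
        ss = (cfg.ss_classes[i] if cfg.ss_classes else " ") or " "
        acc = (
            cfg.acc_values[i]
            if cfg.acc_values is not None
            else TIEN_MAX_ACC[aa] / 2.0
        )
        line = f"{i + 1:5d}{resnum:5d} {cfg.chain} {aa}  {ss}"
        line = line + " " * (34 - len(line)) + f"{int(round(acc)):4d}"
        dssp_lines.append(line)
    dssp_text = "\n".join(dssp_lines) + "\n"
    return pdb_text, dssp_text
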