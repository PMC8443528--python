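"""Data model, I/O, validation and descriptive statistics for ΔTm mutation tables.

A mutation dataset holds one row per single-point mutation: the protein it was
measured on, the substituted residue, the wild-type melting temperature Tm and
the change ΔTm = Tm(mutant) − Tm(wild type) in °C, together with measurement
conditions (pH, technique) and, once annotated, three structure-derived
features per residue: relative solvent accessibility (RSA), the mean B-factor
of the residue's C/N/O atoms, and a ternary secondary-structure code
(−1 sheet-like, 0 coil, +1 helical).

Curated ΔTm collections of this kind are truncated to |ΔTm| < 20 °C (larger
changes usually imply structural rearrangement rather than a clean stability
shift), are dominated by destabilizing mutations, and are heavily skewed
toward a handful of well-studied proteins.  The summary statistics here make
those imbalances explicit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

TECHNIQUES = ("CD", "DSC", "FL", "Abs", "activity", "other")
_TECH_NORM = {t.lower(): t for t in TECHNIQUES}

#: off-diagonal ordered amino-acid pairs
N_ORDERED_SUBSTITUTIONS = 20 * 19  # 380

DTM_TRUNCATION_LIMIT = 20.0  # °C; |ΔTm| beyond this is quarantined

REQUIRED_COLUMNS = (
    "protein_id",
    "chain",
    "residue_number",
    "wt_aa",
    "mut_aa",
    "tm_wt",
    "d_tm",
)
OPTIONAL_COLUMNS = ("ph", "technique", "rsa", "avg_b", "ss_code")


@dataclass
class MutationEntry:
    """One experimental ΔTm record, optionally with structural annotations."""

    protein_id: str
    chain: str
    residue_number: int
    wt_aa: str
    mut_aa: str
    tm_wt: float
    d_tm: float
    ph: float | None = None
    technique: str | None = None
    rsa: float | None = None
    avg_b: float | None = None
    ss_code: int | None = None

    @property
    def substitution(self) -> tuple[str, str]:
        return (self.wt_aa, self.mut_aa)

    @property
    def is_annotated(self) -> bool:
        return self.rsa is not None and self.avg_b is not None and self.ss_code is not None


def validate_entry(e: MutationEntry) -> list[str]:
    """Invariant check for an experimental record; returns reasons, empty if OK."""
    problems: list[str] = []
    if e.wt_aa not in AA_SET:
        problems.append(f"unknown-wt-aa:{e.wt_aa}")
    if e.mut_aa not in AA_SET:
        problems.append(f"unknown-mut-aa:{e.mut_aa}")
    if e.wt_aa == e.mut_aa:
        problems.append("self-substitution")
    if not math.isfinite(e.d_tm):
        problems.append("non-finite-d_tm")
    elif abs(e.d_tm) >= DTM_TRUNCATION_LIMIT:
        problems.append("dtm-out-of-range")
    if e.ph is not None and not (0.0 < e.ph < 14.0):
        problems.append("ph-out-of-range")
    if e.rsa is not None and e.rsa < 0:
        problems.append("negative-rsa")
    return problems


@dataclass
class MutationDataset:
    """Ordered collection of accepted entries plus a per-row validation report.

    Rows that fail invariants are quarantined in ``validation_report`` with
    their reasons — never silently dropped — so that any exclusion is
    reconstructible.
    """

    entries: list[MutationEntry] = field(default_factory=list)
    provenance: str = ""
    validation_report: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.protein_id, None)
        return list(seen)

    def annotated_entries(self) -> list[MutationEntry]:
        return [e for e in self.entries if e.is_annotated]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Dialect:
    """Input-table dialect: separator and a mapping from foreign column names
    to the canonical ones."""

    sep: str = "\t"
    column_map: Mapping[str, str] | None = None


def _parse_float(s, allow_missing: bool) -> tuple[float | None, bool]:
    if s is None or (isinstance(s, float) and math.isnan(s)) or str(s).strip() == "":
        return None, allow_missing
    try:
        return float(s), True
    except ValueError:
        return None, False


def load_dataset(path, dialect: Dialect | None = None) -> MutationDataset:
    """Read a delimited mutation table into a :class:`MutationDataset`.

    Required columns: protein_id, chain, residue_number, wt_aa, mut_aa,
    tm_wt, d_tm.  Optional: ph, technique, rsa, avg_b, ss_code.  Rows that
    fail parsing or entry invariants are quarantined with reasons.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    if dialect.column_map:
        raw = raw.rename(columns=dict(dialect.column_map))
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"missing required column: {col!r}")

    ds = MutationDataset(provenance=str(path))
    for i, row in enumerate(raw.itertuples(index=False)):
        rec = row._asdict()
        reasons: list[str] = []

        def getf(col: str, required: bool) -> float | None:
            val, ok = _parse_float(rec.get(col), allow_missing=not required)
            if not ok:
                reasons.append(f"unparseable-{col}")
            return val

        tm_wt = getf("tm_wt", required=True)
        d_tm = getf("d_tm", required=True)
        ph = getf("ph", required=False) if "ph" in raw.columns else None
        rsa = getf("rsa", required=False) if "rsa" in raw.columns else None
        avg_b = getf("avg_b", required=False) if "avg_b" in raw.columns else None
        ss_raw = rec.get("ss_code", "") if "ss_code" in raw.columns else ""
        ss_code: int | None = None
        if str(ss_raw).strip() != "":
            try:
                ss_code = int(float(ss_raw))
                if ss_code not in (-1, 0, 1):
                    reasons.append("invalid-ss_code")
                    ss_code = None
            except ValueError:
                reasons.append("unparseable-ss_code")
        try:
            residue_number = int(str(rec["residue_number"]).strip())
        except ValueError:
            reasons.append("unparseable-residue_number")
            residue_number = -1

        technique = None
        if "technique" in raw.columns and str(rec.get("technique", "")).strip():
            technique = _TECH_NORM.get(str(rec["technique"]).strip().lower(), "other")

        if reasons:
            ds.validation_report.append({"row": i, "reasons": reasons})
            continue

        entry = MutationEntry(
            protein_id=str(rec["protein_id"]).strip(),
            chain=str(rec["chain"]).strip() or " ",
            residue_number=residue_number,
            wt_aa=str(rec["wt_aa"]).strip(),
            mut_aa=str(rec["mut_aa"]).strip(),
            tm_wt=tm_wt,
            d_tm=d_tm,
            ph=ph,
            technique=technique,
            rsa=rsa,
            avg_b=avg_b,
            ss_code=ss_code,
        )
        problems = validate_entry(entry)
        if problems:
            ds.validation_report.append({"row": i, "reasons": problems})
        else:
            ds.entries.append(entry)
    return ds


def classify_stability(d_tm: float, threshold: float = 2.0) -> str:
    """Classify a ΔTm as destabilizing (< −threshold), stabilizing
    (> threshold) or neutral (closed band, boundary inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not math.isfinite(d_tm):
        raise ValueError("d_tm must be finite")
    if d_tm < -threshold:
        return "destabilizing"
    if d_tm > threshold:
        return "stabilizing"
    return "neutral"


@dataclass
class SummaryReport:
    """Composition statistics of a dataset.

    ``ph_fractions`` partitions entries-with-pH into <6 / 6–8 / >8 (pH 6 and 8
    fall in the middle band) plus an overlay share at pH ≤ 3.5.
    ``dtm_category_fractions`` uses the ±2 °C stability bands plus an overlay
    share within ±1 °C.  ``tm_histogram`` uses 1 °C left-closed bins keyed by
    the left edge.
    """

    n_entries: int
    ph_fractions: dict[str, float]
    tm_histogram: dict[int, int]
    dtm_category_fractions: dict[str, float]
    technique_fractions: dict[str, float]
    per_protein_counts: dict[str, int]
    rsa_b_correlation: float | None

    def to_json(self) -> str:
        d = dict(vars(self))
        d["tm_histogram"] = {str(k): v for k, v in self.tm_histogram.items()}
        return json.dumps(d, indent=2)


def summarize_dataset(ds: MutationDataset, threshold: float = 2.0) -> SummaryReport:
    """Compute the dataset-composition report (pH/technique/ΔTm shares,
    per-protein counts, Tm histogram, RSA–B-factor Pearson r)."""
    if len(ds) == 0:
        raise ValueError("cannot summarize an empty dataset")

    phs = [e.ph for e in ds if e.ph is not None]
    ph_fractions: dict[str, float] = {}
    if phs:
        n = len(phs)
        ph_fractions = {
            "<6": sum(p < 6 for p in phs) / n,
            "6-8": sum(6 <= p <= 8 for p in phs) / n,
            ">8": sum(p > 8 for p in phs) / n,
            "<=3.5": sum(p <= 3.5 for p in phs) / n,  # overlay within <6
        }

    tm_hist: dict[int, int] = {}
    for e in ds:
        b = int(math.floor(e.tm_wt))
        tm_hist[b] = tm_hist.get(b, 0) + 1

    n = len(ds)
    cats = [classify_stability(e.d_tm, threshold) for e in ds]
    dtm_fracs = {
        "destabilizing": cats.count("destabilizing") / n,
        "neutral": cats.count("neutral") / n,
        "stabilizing": cats.count("stabilizing") / n,
        "within_1C": sum(abs(e.d_tm) <= 1 for e in ds) / n,  # overlay
    }

    techs = [e.technique for e in ds if e.technique is not None]
    tech_fracs = {t: techs.count(t) / len(techs) for t in TECHNIQUES if t in techs} if techs else {}

    per_protein: dict[str, int] = {}
    for e in ds:
        per_protein[e.protein_id] = per_protein.get(e.protein_id, 0) + 1

    ann = [(e.rsa, e.avg_b) for e in ds if e.rsa is not None and e.avg_b is not None]
    rsa_b_r = None
    if len(ann) >= 3:
        rsa_v, b_v = zip(*ann)
        if np.std(rsa_v) > 0 and np.std(b_v) > 0:
            rsa_b_r = float(_scipy_stats.pearsonr(rsa_v, b_v).statistic)

    return SummaryReport(
        n_entries=n,
        ph_fractions=ph_fractions,
        tm_histogram=dict(sorted(tm_hist.items())),
        dtm_category_fractions=dtm_fracs,
        technique_fractions=tech_fracs,
        per_protein_counts=per_protein,
        rsa_b_correlation=rsa_b_r,
    )


@dataclass
class SubstitutionMatrix:
    """20×20 ordered-pair substitution statistics.

    ``counts`` is integer-valued; ``mean_dtm`` and ``sd_dtm`` are NaN below
    the reporting threshold (sample SD additionally requires ≥ 2 entries).
    ``coverage`` is the fraction of the 380 off-diagonal cells with ≥ 1 entry.
    """

    counts: pd.DataFrame
    mean_dtm: pd.DataFrame
    sd_dtm: pd.DataFrame
    report_threshold: int
    coverage: float

    def cell(self, wt_aa: str, mut_aa: str) -> tuple[int, float, float]:
        return (
            int(self.counts.at[wt_aa, mut_aa]),
            float(self.mean_dtm.at[wt_aa, mut_aa]),
            float(self.sd_dtm.at[wt_aa, mut_aa]),
        )

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    def to_json(self) -> str:
        cells = {}
        for wt in AA_ALPHABET:
            for mut in AA_ALPHABET:
                c = int(self.counts.at[wt, mut])
                if c == 0:
                    continue
                mean = self.mean_dtm.at[wt, mut]
                sd = self.sd_dtm.at[wt, mut]
                cells[f"{wt}{mut}"] = {
                    "count": c,
                    "mean_dtm": None if pd.isna(mean) else float(mean),
                    "sd_dtm": None if pd.isna(sd) else float(sd),
                }
        return json.dumps(
            {"report_threshold": self.report_threshold, "coverage": self.coverage, "cells": cells},
            indent=2,
        )


def substitution_matrix(
    ds: MutationDataset | Iterable[MutationEntry], report_threshold: int = 3
) -> SubstitutionMatrix:
    """Count every ordered (wt, mut) pair and report mean ± sample SD of ΔTm
    for cells at or above the reporting threshold."""
    entries = list(ds)
    idx = list(AA_ALPHABET)
    counts = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
    values: dict[tuple[str, str], list[float]] = {}
    for e in entries:
        counts.at[e.wt_aa, e.mut_aa] += 1
        values.setdefault((e.wt_aa, e.mut_aa), []).append(e.d_tm)

    mean = pd.DataFrame(np.nan, index=idx, columns=idx)
    sd = pd.DataFrame(np.nan, index=idx, columns=idx)
    for (wt, mut), vals in values.items():
        if len(vals) >= report_threshold:
            mean.at[wt, mut] = float(np.mean(vals))
        if len(vals) >= max(2, report_threshold):
            sd.at[wt, mut] = float(np.std(vals, ddof=1))

    off_diag_covered = sum(
        1 for wt in idx for mut in idx if wt != mut and counts.at[wt, mut] >= 1
    )
    coverage = off_diag_covered / N_ORDERED_SUBSTITUTIONS
    return SubstitutionMatrix(counts, mean, sd, report_threshold, coverage)


@dataclass
class BinnedProfile:
    """Per-bin ΔTm statistics of a dataset against one structural feature."""

    feature_name: str
    bin_edges: list[float]
    mean_dtm: list[float]
    sd_dtm: list[float]
    mean_abs_dtm: list[float]
    counts: list[int]


def binned_profile(
    ds: MutationDataset,
    feature: str,
    n_bins: int,
    equal_count: bool = True,
) -> BinnedProfile:
    """Bin annotated entries on ``feature`` ('rsa' or 'avg_b') and report
    per-bin ΔTm mean, sample SD, mean |ΔTm| and count.

    Equal-count binning assigns sorted entries to bins whose sizes differ by
    at most one; otherwise bins are equal-width over the observed range.
    """
    if feature not in ("rsa", "avg_b"):
        raise ValueError(f"unknown feature: {feature!r}")
    pairs = [(getattr(e, feature), e.d_tm) for e in ds if getattr(e, feature) is not None]
    if len(pairs) < n_bins:
        raise ValueError(
            f"need at least {n_bins} entries annotated with {feature}, have {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    order = np.argsort(x, kind="stable")

    if equal_count:
        groups = np.array_split(order, n_bins)
        edges = [float(x[groups[0]].min())]
        for g_prev, g_next in zip(groups[:-1], groups[1:]):
            edges.append(float((x[g_prev].max() + x[g_next].min()) / 2))
        edges.append(float(x[groups[-1]].max()))
    else:
        lin = np.linspace(x.min(), x.max(), n_bins + 1)
        # right-inclusive last bin
        assign = np.clip(np.searchsorted(lin, x, side="right") - 1, 0, n_bins - 1)
        groups = [np.where(assign == k)[0] for k in range(n_bins)]
        edges = [float(v) for v in lin]

    mean_dtm, sd_dtm, mean_abs, counts = [], [], [], []
    for g in groups:
        yy = y[g]
        counts.append(int(len(yy)))
        mean_dtm.append(float(yy.mean()) if len(yy) else math.nan)
        sd_dtm.append(float(yy.std(ddof=1)) if len(yy) > 1 else math.nan)
        mean_abs.append(float(np.abs(yy).mean()) if len(yy) else math.nan)
    return BinnedProfile(feature, edges, mean_dtm, sd_dtm, mean_abs, counts)
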