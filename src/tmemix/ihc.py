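"""Per-patient IHC staining coverages and cohort summary statistics.

The input is a small delimited table with one row per patient: stroma
and tumor areas of the stained section, the coverage of each fibroblast
class (ADH1B, FAP+aSMA-, FAP+aSMA+, FAP-aSMA+) as a fraction of the
stroma, the cancer-cell coverage of the section, and a LUAD/LUSC label.
From it we compute the cohort-level fibroblast coverage of the stroma,
the composition of the fibroblast population by class, and the
tumor-stroma ratio (TSR = tumor area / stroma area), each as mean ± sd
across patients.

A deterministic synthetic-table generator emulates the structure and the
published cohort statistics for testing without the original data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FIBROBLAST_CLASSES",
    "CoverageRecord",
    "read_coverage_table",
    "cohort_stats",
    "make_synthetic_coverage_table",
    "COHORT_PROFILES",
]

FIBROBLAST_CLASSES = ("adh1b", "fap_only", "fap_asma", "asma_only")

#: Default header mapping; override via ``column_map`` for other schemas.
DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "cancer_type": "cancer_type",
    "stroma_area": "stroma_area",
    "tumor_area": "tumor_area",
    "cancer_coverage": "cancer_coverage",
    "adh1b": "adh1b",
    "fap_only": "fap_only",
    "fap_asma": "fap_asma",
    "asma_only": "asma_only",
}


@dataclass(frozen=True)
class CoverageRecord:
    """One patient's staining coverages.

    ``coverage`` maps each fibroblast class to its coverage as a
    fraction of the stroma area; ``cancer_coverage`` is the cancer-cell
    (keratin) coverage fraction of the whole section.
    """

    patient_id: str
    cancer_type: str
    stroma_area: float
    tumor_area: float
    coverage: dict[str, float] = field(default_factory=dict)
    cancer_coverage: float = 0.0
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cancer_type not in ("LUAD", "LUSC"):
            raise ValueError(f"cancer_type must be LUAD or LUSC, got {self.cancer_type!r}")
        if self.stroma_area <= 0 or self.tumor_area <= 0:
            raise ValueError("areas must be > 0")
        for k in FIBROBLAST_CLASSES:
            v = self.coverage.get(k, 0.0)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"coverage {k}={v} outside [0, 1]")
        if sum(self.coverage.get(k, 0.0) for k in FIBROBLAST_CLASSES) > 1.0 + 1e-9:
            raise ValueError("fibroblast class coverages must sum to <= 1")
        if not 0.0 <= self.cancer_coverage <= 1.0:
            raise ValueError("cancer coverage outside [0, 1]")

    @property
    def fibroblast_coverage(self) -> float:
        """Total fibroblast coverage: sum of the class coverages."""
        return sum(self.coverage.get(k, 0.0) for k in FIBROBLAST_CLASSES)

    @property
    def tsr(self) -> float:
        """Tumor-stroma ratio (tumor area in the numerator)."""
        return self.tumor_area / self.stroma_area


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_coverage_table(
    path,
    column_map: dict[str, str] | None = None,
) -> list[CoverageRecord]:
    """Parse a delimited coverage table into validated records.

    ``column_map`` maps the canonical field names (keys of
    ``DEFAULT_COLUMNS``) to the file's actual headers when they differ.
    Unknown columns are kept as string metadata on each record.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    known = set(cols.values())
    records = []
    for idx, row in df.iterrows():
        numeric = {}
        for key in (
            "stroma_area",
            "tumor_area",
            "cancer_coverage",
            *FIBROBLAST_CLASSES,
        ):
            raw = row[cols[key]]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                value = float("nan")
            if not np.isfinite(value):
                raise ValueError(
                    f"non-numeric value {raw!r} at row {idx}, column {cols[key]!r}"
                )
            numeric[key] = value
        records.append(
            CoverageRecord(
                patient_id=str(row[cols["patient_id"]]),
                cancer_type=str(row[cols["cancer_type"]]),
                stroma_area=numeric["stroma_area"],
                tumor_area=numeric["tumor_area"],
                coverage={k: numeric[k] for k in FIBROBLAST_CLASSES},
                cancer_coverage=numeric["cancer_coverage"],
                extra={
                    c: str(row[c]) for c in df.columns if c not in known
                },
            )
        )
    return records


def cohort_stats(
    records: Iterable[CoverageRecord],
    cancer_type: str,
    pooled: bool = False,
) -> dict:
    """Summary statistics for one cohort (LUAD or LUSC).

    Returns the fibroblast coverage of the stroma (mean ± sd, percent),
    the composition of the fibroblast population by class (percent,
    summing to 100), the tumor-stroma ratio (mean ± sd) and the
    cancer-cell coverage (mean ± sd, percent).  Composition is the
    per-patient class share averaged across patients by default; with
    ``pooled=True`` class coverages are pooled by stroma area instead.
    """
    recs = [r for r in records if r.cancer_type == cancer_type]
    if not recs:
        raise ValueError(f"no records of type {cancer_type!r}")
    fb = np.array([r.fibroblast_coverage for r in recs])
    tsr = np.array([r.tsr for r in recs])
    cc = np.array([r.cancer_coverage for r in recs])
    if pooled:
        stroma = np.array([r.stroma_area for r in recs])
        pooled_cov = {
            k: float(
                np.sum([r.coverage.get(k, 0.0) * s for r, s in zip(recs, stroma)])
            )
            for k in FIBROBLAST_CLASSES
        }
        total = sum(pooled_cov.values())
        composition = {k: 100.0 * v / total for k, v in pooled_cov.items()}
    else:
        shares = []
        for r in recs:
            tot = r.fibroblast_coverage
            if tot > 0:
                shares.append(
                    [r.coverage.get(k, 0.0) / tot for k in FIBROBLAST_CLASSES]
                )
        share_mean = np.mean(shares, axis=0)
        share_mean = share_mean / share_mean.sum()
        composition = {
            k: 100.0 * float(v) for k, v in zip(FIBROBLAST_CLASSES, share_mean)
        }
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {
        "cancer_type": cancer_type,
        "n": len(recs),
        "fibroblast_coverage_pct": (100.0 * float(fb.mean()), 100.0 * sd(fb)),
        "composition_pct": composition,
        "tsr": (float(tsr.mean()), sd(tsr)),
        "cancer_coverage_pct": (100.0 * float(cc.mean()), 100.0 * sd(cc)),
    }


def stats_to_frame(stats: Sequence[dict]) -> pd.DataFrame:
    """Flatten cohort summaries into one row per cohort (CSV-friendly)."""
    rows = []
    for s in stats:
        row = {
            "cancer_type": s["cancer_type"],
            "n": s["n"],
            "cancer_coverage_pct_mean": s["cancer_coverage_pct"][0],
            "cancer_coverage_pct_sd": s["cancer_coverage_pct"][1],
            "fibroblast_coverage_pct_mean": s["fibroblast_coverage_pct"][0],
            "fibroblast_coverage_pct_sd": s["fibroblast_coverage_pct"][1],
            "tsr_mean": s["tsr"][0],
            "tsr_sd": s["tsr"][1],
        }
        for k, v in s["composition_pct"].items():
            row[f"composition_{k}_pct"] = v
        rows.append(row)
    return pd.DataFrame(rows)


#: Published cohort profiles the synthetic generator is calibrated to:
#: cancer coverage (section %), fibroblast coverage (stroma %), TSR,
#: and the class composition of the fibroblast population.
COHORT_PROFILES = {
    "LUAD": dict(
        cancer_coverage=(0.47, 0.13),
        fibroblast_coverage=(0.31, 0.17),
        tsr=(1.07, 0.68),
        composition={"adh1b": 0.48, "fap_only": 0.18, "fap_asma": 0.07, "asma_only": 0.26},
    ),
    "LUSC": dict(
        cancer_coverage=(0.54, 0.10),
        fibroblast_coverage=(0.35, 0.12),
        tsr=(1.30, 0.53),
        composition={"adh1b": 0.06, "fap_only": 0.37, "fap_asma": 0.25, "asma_only": 0.31},
    ),
}


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Truncated normal whose *truncated* mean equals ``mean``.

    Truncation shifts the mean of a plain clipped normal (cutting the
    left tail of the TSR distribution at 0.05 raises its mean by ~0.1),
    so the location parameter is corrected by fixed-point iteration
    before sampling.
    """
    from scipy.stats import truncnorm

    loc = mean
    for _ in range(50):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        shift = mean - truncnorm.mean(a, b, loc=loc, scale=sd)
        loc += shift
        if abs(shift) < 1e-10:
            break
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def make_synthetic_coverage_table(
    n_luad: int,
    n_lusc: int,
    seed: int,
    path=None,
    concentration: float = 60.0,
) -> tuple[pd.DataFrame, list[CoverageRecord]]:
    """Generate a synthetic per-patient coverage table.

    Draws per-patient fibroblast coverage, TSR and cancer coverage from
    truncated normals matching the cohort profiles, and class
    compositions from a Dirichlet centered on the cohort composition.
    The stream is fully determined by ``seed``; when ``path`` is given
    the table is also written as CSV.
    """
    if n_luad < 1 or n_lusc < 1:
        raise ValueError("cohort sizes must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for ctype, n in (("LUAD", n_luad), ("LUSC", n_lusc)):
        prof = COHORT_PROFILES[ctype]
        fb = _truncated_normal(rng, *prof["fibroblast_coverage"], 0.02, 0.95, n)
        tsr = _truncated_normal(rng, *prof["tsr"], 0.05, 5.0, n)
        cc = _truncated_normal(rng, *prof["cancer_coverage"], 0.05, 0.95, n)
        alpha = concentration * np.array(
            [prof["composition"][k] for k in FIBROBLAST_CLASSES]
        )
        shares = rng.dirichlet(alpha, size=n)
        stroma = rng.lognormal(mean=np.log(2.0e6), sigma=0.4, size=n)  # µm²
        for i in range(n):
            row = {
                "patient_id": f"{ctype}-{i + 1:03d}",
                "cancer_type": ctype,
                "stroma_area": round(stroma[i], 1),
                "tumor_area": round(stroma[i] * tsr[i], 1),
                "cancer_coverage": round(cc[i], 6),
            }
            for k, s in zip(FIBROBLAST_CLASSES, shares[i]):
                row[k] = round(fb[i] * s, 6)
            rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    records = [
        CoverageRecord(
            patient_id=r["patient_id"],
            cancer_type=r["cancer_type"],
            stroma_area=r["stroma_area"],
            tumor_area=r["tumor_area"],
            coverage={k: r[k] for k in FIBROBLAST_CLASSES},
            cancer_coverage=r["cancer_coverage"],
        )
        for r in rows
    ]
    return df, records
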