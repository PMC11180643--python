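"""Two-way mixed-effects, absolute-agreement, single-measurement ICC with
four-band reliability classification, plus cohort-level agreement summaries
for dialect-vs-dialect and CT-vs-MRI comparisons.

ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R / MS_C / MS_E are the row (subject), column (rater) and residual
mean squares of a two-way ANOVA without replication.  Negative ICC values
are reported as computed and banded poor (no clamping).  An F statistic
(MS_R / MS_E) and its p-value are reported alongside but never used for
banding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

__all__ = [
    "Band",
    "ICCResult",
    "AgreementSummary",
    "icc_single",
    "band_of",
    "compare_dialects",
    "compare_modalities",
    "report",
]

#: Minimum subjects retained after degenerate-patient dropping for a
#: feature's ICC to be considered computable.
MIN_SUBJECTS = 3


class Band(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


BAND_ORDER = [Band.EXCELLENT, Band.GOOD, Band.MODERATE, Band.POOR]


def band_of(icc: float) -> Band:
    """poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent."""
    if icc >= 0.9:
        return Band.EXCELLENT
    if icc >= 0.75:
        return Band.GOOD
    if icc >= 0.5:
        return Band.MODERATE
    return Band.POOR


@dataclass
class ICCResult:
    icc: float
    ms_r: float
    ms_e: float
    ms_c: float
    n: int
    k: int
    band: Band
    f_pvalue: float
    flagged: bool = False  # set when degenerate patients were dropped

    def __post_init__(self) -> None:
        if self.icc > 1 + 1e-12:
            raise ValueError(f"ICC cannot exceed 1 (got {self.icc})")


def icc_single(ratings: np.ndarray) -> ICCResult:
    """ICC(2-way mixed, absolute agreement, single measurement) for an
    n x k ratings matrix (rows = subjects, columns = raters)."""
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D (subjects x raters) matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain non-finite values")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        raise ValueError("ICC undefined (no variance)")
    icc = (ms_r - ms_e) / denom
    if ms_e > 0:
        f = ms_r / ms_e
        pval = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:
        pval = 0.0 if ms_r > 0 else 1.0
    return ICCResult(
        icc=float(icc),
        ms_r=float(ms_r),
        ms_e=float(ms_e),
        ms_c=float(ms_c),
        n=n,
        k=k,
        band=band_of(float(icc)),
        f_pvalue=pval,
    )


@dataclass
class AgreementSummary:
    """Per-feature ICC results for one comparison arm plus band summaries."""

    comparison: str  # "dialectA_vs_dialectB" or "CT_vs_MRI"
    held_fixed: str  # the modality (dialect comparison) or dialect (modality comparison)
    resampling: str
    per_feature: dict[str, ICCResult | None]
    dropped: dict[str, str] = field(default_factory=dict)  # feature -> reason

    def __post_init__(self) -> None:
        if set(self.per_feature) != set(FEATURE_NAMES):
            raise ValueError("per_feature must cover exactly the 66 features")

    @property
    def band_percentages(self) -> dict[Band, float]:
        """Percent of the 66 features per band; uncomputable features count
        as poor so percentages always cover all features."""
        counts = {b: 0 for b in Band}
        for res in self.per_feature.values():
            counts[res.band if res is not None else Band.POOR] += 1
        total = len(self.per_feature)
        return {b: 100.0 * c / total for b, c in counts.items()}

    @property
    def stable_features(self) -> list[str]:
        return [
            name
            for name in FEATURE_NAMES
            if self.per_feature[name] is not None
            and self.per_feature[name].band in (Band.GOOD, Band.EXCELLENT)
        ]


def _per_feature_icc(
    sub: pd.DataFrame, rater_col: str, raters: tuple[str, str]
) -> tuple[dict[str, ICCResult | None], dict[str, str]]:
    results: dict[str, ICCResult | None] = {}
    dropped: dict[str, str] = {}
    for feature in FEATURE_NAMES:
        f = sub[sub["feature"] == feature]
        wide = f.pivot(index="patient_id", columns=rater_col, values="value")
        missing = [r for r in raters if r not in wide.columns]
        if missing or wide.isna().any().any():
            gaps = [
                (pid, feature)
                for pid in wide.index[wide.isna().any(axis=1)]
            ] or [("<all>", feature)]
            raise ValueError(f"missing cells for feature {feature}: {gaps}")
        wide = wide[list(raters)]
        flagged_patients = set(
            f.loc[f["degenerate"].astype(bool), "patient_id"]
        )
        keep = wide.loc[[p for p in wide.index if p not in flagged_patients]]
        flagged = bool(flagged_patients)
        if len(keep) < MIN_SUBJECTS:
            results[feature] = None
            dropped[feature] = (
                f"only {len(keep)} non-degenerate subjects (< {MIN_SUBJECTS})"
            )
            continue
        try:
            res = icc_single(keep.to_numpy())
        except ValueError as exc:
            results[feature] = None
            dropped[feature] = str(exc)
            continue
        res.flagged = flagged
        results[feature] = res
    return results, dropped


def _check_complete(sub: pd.DataFrame, what: str) -> None:
    if sub.empty:
        raise ValueError(f"feature table has no rows for {what}")


def compare_dialects(
    table: pd.DataFrame, modality: str, resampling: str
) -> AgreementSummary:
    """Per-feature ICC of dialect A vs dialect B at fixed modality and arm."""
    sub = table[
        (table["modality"] == str(modality)) & (table["resampling"] == str(resampling))
    ]
    _check_complete(sub, f"modality={modality}, resampling={resampling}")
    dialects = sorted(sub["dialect"].unique())
    if len(dialects) != 2:
        raise ValueError(f"need exactly 2 dialects, found {dialects}")
    per_feature, dropped = _per_feature_icc(sub, "dialect", tuple(dialects))
    return AgreementSummary(
        comparison=f"dialect{dialects[0]}_vs_dialect{dialects[1]}",
        held_fixed=str(modality),
        resampling=str(resampling),
        per_feature=per_feature,
        dropped=dropped,
    )


def compare_modalities(
    table: pd.DataFrame, dialect: str, resampling: str
) -> AgreementSummary:
    """Per-feature ICC of CT vs MRI values at fixed dialect and arm."""
    sub = table[
        (table["dialect"] == str(dialect)) & (table["resampling"] == str(resampling))
    ]
    _check_complete(sub, f"dialect={dialect}, resampling={resampling}")
    per_feature, dropped = _per_feature_icc(sub, "modality", ("CT", "MRI"))
    return AgreementSummary(
        comparison="CT_vs_MRI",
        held_fixed=str(dialect),
        resampling=str(resampling),
        per_feature=per_feature,
        dropped=dropped,
    )


def summary_row(s: AgreementSummary) -> dict[str, object]:
    pct = s.band_percentages
    return {
        "comparison": s.comparison,
        "held_fixed": s.held_fixed,
        "resampling": s.resampling,
        "excellent_pct": round(pct[Band.EXCELLENT], 1),
        "good_pct": round(pct[Band.GOOD], 1),
        "moderate_pct": round(pct[Band.MODERATE], 1),
        "poor_pct": round(pct[Band.POOR], 1),
        "stable_features": "; ".join(s.stable_features) or "none",
    }


def report(
    summaries: list[AgreementSummary],
    out_dir,
    provenance: dict[str, object] | None = None,
) -> dict[str, Path]:
    """Write band-percentage CSV, per-feature JSON, and a plain-text table."""
    import json

    if not summaries:
        raise ValueError("no summaries to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [summary_row(s) for s in summaries]
    df = pd.DataFrame(rows)

    csv_path = out_dir / "agreement_bands.csv"
    with open(csv_path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)

    json_path = out_dir / "agreement_per_feature.json"
    payload = {
        "provenance": provenance or {},
        "summaries": [
            {
                "comparison": s.comparison,
                "held_fixed": s.held_fixed,
                "resampling": s.resampling,
                "band_percentages": {b.value: p for b, p in s.band_percentages.items()},
                "stable_features": s.stable_features,
                "dropped": s.dropped,
                "per_feature": {
                    name: (
                        None
                        if res is None
                        else {
                            "icc": res.icc,
                            "band": res.band.value,
                            "n": res.n,
                            "k": res.k,
                            "f_pvalue": res.f_pvalue,
                            "flagged": res.flagged,
                        }
                    )
                    for name, res in s.per_feature.items()
                },
            }
            for s in summaries
        ],
    }
    json_path.write_text(json.dumps(payload, indent=1))

    txt_path = out_dir / "agreement_bands.txt"
    with open(txt_path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        header = (
            f"{'comparison':<26}{'fixed':<8}{'resampling':<12}"
            f"{'Excellent':>10}{'Good':>8}{'Moderate':>10}{'Poor':>8}\n"
        )
        fh.write(header)
        for r in rows:
            fh.write(
                f"{r['comparison']:<26}{r['held_fixed']:<8}{r['resampling']:<12}"
                f"{r['excellent_pct']:>10.1f}{r['good_pct']:>8.1f}"
                f"{r['moderate_pct']:>10.1f}{r['poor_pct']:>8.1f}\n"
            )
        fh.write("\nStable (good/excellent) features per arm:\n")
        for r in rows:
            fh.write(
                f"- {r['comparison']} / {r['held_fixed']} / {r['resampling']}: "
                f"{r['stable_features']}\n"
            )
    return {"csv": csv_path, "json": json_path, "txt": txt_path}
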