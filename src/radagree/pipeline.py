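"""End-to-end driver: cohort -> preprocessing arms -> dialect extractions ->
tidy feature table -> agreement summaries.

Arm semantics:

* ``original``: no resampling; features come from the native grid.
* ``internal``: resampling happens inside the extraction call, using the
  dialect's grid anchor — so the two dialects see (slightly) different
  grids, as two programs with their own resamplers would.
* ``external``: resampling is a separate prior stage, corner-anchored for
  every dialect — both dialects then consume the identical resampled volume.
"""

from __future__ import annotations

import pandas as pd

from .features import BUILTIN_DIALECTS, ExtractionDialect, extract
from .image_model import Modality, PatientRecord
from .preprocess import (
    GridAnchor,
    NormalizationSpec,
    ResamplingSpec,
    Strategy,
    preprocess_pair,
)

__all__ = ["ARM_NAMES", "extract_table", "feature_table_columns"]

ARM_NAMES = tuple(s.value for s in Strategy)

feature_table_columns = [
    "patient_id",
    "modality",
    "dialect",
    "resampling",
    "feature",
    "category",
    "value",
    "degenerate",
]


def _arm_specs(arm: Strategy) -> tuple[ResamplingSpec, ResamplingSpec]:
    return (
        ResamplingSpec(strategy=arm),  # CT: default 1x1x1 target
        ResamplingSpec(strategy=arm),  # MRI: default 1.4^3 target
    )


def extract_table(
    records: list[PatientRecord],
    arms: list[str] | None = None,
    dialects: list[ExtractionDialect] | None = None,
    norm: NormalizationSpec | None = None,
    n_bins: int = 64,
) -> pd.DataFrame:
    """Tidy feature table over the full (patient, modality, dialect, arm) grid."""
    arms = [Strategy(a) for a in (arms or list(Strategy))]
    dialects = dialects or list(BUILTIN_DIALECTS.values())
    rows = []
    for record in records:
        for arm in arms:
            ct_spec, mri_spec = _arm_specs(arm)
            prepped_cache: dict[str, dict] = {}
            for dialect in dialects:
                if arm is Strategy.INTERNAL:
                    anchor = GridAnchor(dialect.grid_anchor)
                else:
                    anchor = GridAnchor.CORNER
                key = anchor.value if arm is Strategy.INTERNAL else "shared"
                if key not in prepped_cache:
                    prepped_cache[key] = preprocess_pair(
                        record, ct_spec, mri_spec, norm, n_bins, anchor
                    )
                prepped = prepped_cache[key]
                for modality in (Modality.CT, Modality.MRI):
                    pm = prepped[modality]
                    fv = extract(pm.volume, pm.mask, pm.discretized, dialect)
                    for name, value in fv.values.items():
                        rows.append(
                            {
                                "patient_id": record.patient_id,
                                "modality": modality.value,
                                "dialect": dialect.name,
                                "resampling": arm.value,
                                "feature": name,
                                "category": name.split("_", 1)[0],
                                "value": value,
                                "degenerate": name in fv.degenerate_flags,
                            }
                        )
    return pd.DataFrame(rows, columns=feature_table_columns)
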