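"""Semiquantitative scoring of TAP-MS purifications.

Two per-protein scores over a reduced MaxQuant-style intensity table:

* abundance — mean signal intensity over the detected bait replicates
  (two or one) divided by the protein's molecular weight (kDa);
* specificity — ratio of the mean detected bait intensity to the mean
  detected negative-control intensity; for proteins not detected in the
  control the background level is arbitrarily set to 1, so the specificity
  equals the mean bait intensity.

"Not detected" is encoded as NaN and is distinct from a numeric zero. The
per-condition interactome call keeps proteins absent from the control
(presence-only) and control-detected proteins whose specificity reaches
``min_specificity``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TapTable",
    "compute_abundance",
    "compute_specificity",
    "score_table",
    "call_interactome",
]


class TapDataError(ValueError):
    pass


@dataclass
class TapTable:
    """Reduced MaxQuant proteinGroups export: one row per protein.

    ``data`` needs columns ``protein_id``, ``mw_kda`` plus the intensity
    columns named in ``bait_cols`` / ``control_cols`` (NaN = not detected).
    ``condition`` and ``tissue`` label the purification the table came from.
    """

    data: pd.DataFrame
    bait_cols: list[str] = field(default_factory=lambda: ["bait_rep1", "bait_rep2"])
    control_cols: list[str] = field(default_factory=lambda: ["ctrl_rep1", "ctrl_rep2"])
    condition: str | None = None
    tissue: str | None = None

    def __post_init__(self) -> None:
        need = {"protein_id", "mw_kda", *self.bait_cols, *self.control_cols}
        missing = need - set(self.data.columns)
        if missing:
            raise TapDataError(f"intensity table lacks column(s): {sorted(missing)}")
        if (self.data["mw_kda"] <= 0).any():
            raise TapDataError("molecular weight must be positive")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "TapTable":
        return cls(data=pd.read_csv(path, sep="\t"), **kwargs)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def _detected_mean(values) -> float:
    """Mean over detected (non-NaN) replicates; NaN when none detected."""
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    if not mask.any():
        return float("nan")
    return float(arr[mask].mean())


def compute_abundance(bait_intensities, mw_kda: float) -> float:
    """Mean detected bait intensity divided by molecular weight (kDa)."""
    if mw_kda <= 0:
        raise TapDataError(f"molecular weight must be positive, got {mw_kda}")
    mean_bait = _detected_mean(bait_intensities)
    if np.isnan(mean_bait):
        raise TapDataError("no detected bait replicate; protein not in purification")
    return mean_bait / mw_kda


def compute_specificity(
    bait_intensities, control_intensities, zero_control_floor: float | None = None
) -> tuple[float, bool]:
    """Bait/control intensity ratio with the background = 1 convention.

    Returns (specificity, detected_in_control). When the protein is absent
    from every control replicate, the background level is set to 1 and the
    specificity is numerically the mean bait intensity. A detected control
    intensity of exactly 0 is floored to ``zero_control_floor`` (logged).
    """
    mean_bait = _detected_mean(bait_intensities)
    if np.isnan(mean_bait):
        raise TapDataError("no detected bait replicate; protein not in purification")
    mean_ctrl = _detected_mean(control_intensities)
    if np.isnan(mean_ctrl):
        return mean_bait / 1.0, False
    if mean_ctrl == 0:
        if zero_control_floor is None or zero_control_floor <= 0:
            raise TapDataError(
                "control detected with zero intensity and no positive floor"
            )
        logger.info("control intensity 0 floored to %g", zero_control_floor)
        mean_ctrl = zero_control_floor
    return mean_bait / mean_ctrl, True


def score_table(table: TapTable) -> pd.DataFrame:
    """Score every protein in a purification table.

    Rows without any detected bait replicate are skipped (count logged).
    Columns: protein_id, condition, tissue, abundance, specificity,
    detected_in_control, n_bait_detected.
    """
    df = table.data
    bait = df[table.bait_cols].to_numpy(dtype=float)
    ctrl = df[table.control_cols].to_numpy(dtype=float)
    detected_bait = ~np.isnan(bait)
    keep = detected_bait.any(axis=1)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("skipped %d row(s) with no detected bait replicate", n_skipped)

    positive = ctrl[np.isfinite(ctrl) & (ctrl > 0)]
    floor = float(positive.min()) if positive.size else None

    rows = []
    for i in np.flatnonzero(keep):
        spec, in_ctrl = compute_specificity(bait[i], ctrl[i], zero_control_floor=floor)
        rows.append(
            {
                "protein_id": df["protein_id"].iat[i],
                "condition": table.condition,
                "tissue": table.tissue,
                "abundance": compute_abundance(bait[i], float(df["mw_kda"].iat[i])),
                "specificity": spec,
                "detected_in_control": in_ctrl,
                "n_bait_detected": int(detected_bait[i].sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "condition", "tissue", "abundance", "specificity",
            "detected_in_control", "n_bait_detected",
        ],
    )


def call_interactome(
    scores: pd.DataFrame, min_specificity: float = 2.0
) -> set[str] | dict[tuple[str, str], set[str]]:
    """Call the co-purifying protein set from a score table.

    A protein is called when it is absent from the negative control
    (presence-only evidence) or its specificity is >= ``min_specificity``.
    If the score table carries tissue/condition labels, one set is returned
    per (tissue, condition); otherwise a single set.
    """
    if min_specificity < 1:
        raise ValueError("min_specificity must be >= 1")
    called = scores[
        (~scores["detected_in_control"])
        | (scores["specificity"] >= min_specificity)
    ]
    labelled = scores["condition"].notna().all() and scores["tissue"].notna().all()
    if labelled and len(scores):
        out: dict[tuple[str, str], set[str]] = {}
        for (tis, cond), grp in called.groupby(["tissue", "condition"]):
            out[(tis, cond)] = set(grp["protein_id"])
        return out
    return set(called["protein_id"])
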