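"""Tamoxifen metabolite panels and the (Z)-endoxifen metabolic ratio (MR).

The MR of a plasma sample is the (Z)-endoxifen concentration divided by the
sum of the concentrations of tamoxifen and the other 13 measured metabolites.
An MR of 0.0146 corresponds to the 6 ng/mL (Z)-endoxifen efficacy threshold;
samples with MR below that cutoff are treated as having impaired metabolism
directed toward endoxifen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical names of the 15 quantified compounds (ng/mL): tamoxifen plus its
#: 14 key metabolites. (Z)-endoxifen is the MR numerator; the other 14 form
#: the denominator.
ANALYTES: tuple[str, ...] = (
    "tamoxifen",
    "NDM-Tam",
    "(Z)-endoxifen",
    "(E)-endoxifen",
    "3-OH-NDM-Tam",
    "4'-OH-NDM-Tam",
    "(Z)-4-OH-Tam",
    "3-OH-Tam",
    "4'-OH-Tam",
    "(Z)-a-OH-Tam",
    "(E)-a-OH-Tam",
    "Tam-N-oxide",
    "Tam-N-gluc",
    "(E/Z)-4-OH-NDM-Tam-gluc",
    "(E)-4-OH-Tam-O-gluc",
)

ENDOXIFEN = "(Z)-endoxifen"
#: The two most active metabolites; their share of the total drives the
#: extreme-phenotype activity ratio used for GWAS sample selection.
ACTIVE_METABOLITES = (ENDOXIFEN, "(Z)-4-OH-Tam")

#: MR below this value predicts sub-therapeutic (Z)-endoxifen exposure.
MR_CUTOFF = 0.0146
#: (Z)-endoxifen plasma efficacy threshold, ng/mL.
ENDOXIFEN_THRESHOLD_NGML = 6.0


class MetaboliteError(ValueError):
    """Invalid or incomplete metabolite panel."""


@dataclass(frozen=True)
class MetabolitePanel:
    """One sample's concentrations (ng/mL) for the 15 measured compounds."""

    sample_id: str
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(ANALYTES) - set(self.concentrations)
        if missing:
            raise MetaboliteError(f"panel {self.sample_id!r} missing analytes: {sorted(missing)}")
        unknown = set(self.concentrations) - set(ANALYTES)
        if unknown:
            raise MetaboliteError(f"panel {self.sample_id!r} has unknown analytes: {sorted(unknown)}")
        for name, value in self.concentrations.items():
            if not np.isfinite(value) or value < 0:
                raise MetaboliteError(
                    f"panel {self.sample_id!r}: {name} concentration {value!r} is not a finite non-negative number"
                )


@dataclass(frozen=True)
class MrResult:
    """Metabolic ratio of one sample and its classification against the cutoff."""

    sample_id: str
    mr: float
    below_threshold: bool
    cutoff: float = MR_CUTOFF
    endoxifen_threshold_ngml: float = ENDOXIFEN_THRESHOLD_NGML


def compute_mr(panel: MetabolitePanel, cutoff: float = MR_CUTOFF) -> MrResult:
    """MR = [(Z)-endoxifen] / sum of the other 14 compound concentrations.

    Raises
    ------
    MetaboliteError
        If the denominator sum is zero (the ratio is undefined).
    """
    numerator = float(panel.concentrations[ENDOXIFEN])
    denominator = float(sum(panel.concentrations[a] for a in ANALYTES if a != ENDOXIFEN))
    if denominator <= 0:
        raise MetaboliteError(f"panel {panel.sample_id!r}: denominator sum is zero, MR undefined")
    mr = numerator / denominator
    return MrResult(panel.sample_id, mr, classify_mr(mr, cutoff), cutoff)


def classify_mr(mr: float, cutoff: float = MR_CUTOFF) -> bool:
    """True iff ``mr`` is strictly below the cutoff.

    A value exactly at the cutoff belongs to the MR >= cutoff (not-below)
    group.
    """
    if mr < 0 or not np.isfinite(mr):
        raise MetaboliteError(f"MR must be a finite non-negative ratio, got {mr!r}")
    return mr < cutoff


def activity_ratio(panel: MetabolitePanel) -> float:
    """Active-metabolite ratio used for extreme-phenotype sample selection.

    Sum of (Z)-endoxifen and (Z)-4-OH-Tam concentrations over the sum of
    tamoxifen and the remaining measured compounds.
    """
    num = float(sum(panel.concentrations[a] for a in ACTIVE_METABOLITES))
    den = float(sum(panel.concentrations[a] for a in ANALYTES if a not in ACTIVE_METABOLITES))
    if den <= 0:
        raise MetaboliteError(f"panel {panel.sample_id!r}: activity-ratio denominator is zero")
    return num / den


def calibrate_mr_cutoff(
    endoxifen_conc: Sequence[float],
    mr: Sequence[float],
    target_conc: float = ENDOXIFEN_THRESHOLD_NGML,
    *,
    invert: bool = False,
) -> float:
    """Map the (Z)-endoxifen efficacy threshold onto the MR scale by OLS.

    Default direction regresses MR on concentration and evaluates the fitted
    line at ``target_conc``. With ``invert=True`` the concentration is
    regressed on MR and the fitted line solved for ``target_conc`` instead.
    """
    x = np.asarray(endoxifen_conc, dtype=float)
    y = np.asarray(mr, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise MetaboliteError("calibration needs two equal-length 1-d vectors of length >= 3")
    if invert:
        x, y = y, x
    if np.ptp(x) == 0:
        raise MetaboliteError("degenerate calibration fit: predictor has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    if invert:
        if slope == 0:
            raise MetaboliteError("degenerate calibration fit: zero slope, cannot invert")
        return float((target_conc - intercept) / slope)
    return float(slope * target_conc + intercept)


def panels_to_frame(panels: Sequence[MetabolitePanel]) -> pd.DataFrame:
    """Tabulate panels as sample_id + one column per canonical analyte."""
    rows = [{"sample_id": p.sample_id, **{a: p.concentrations[a] for a in ANALYTES}} for p in panels]
    return pd.DataFrame(rows, columns=["sample_id", *ANALYTES])


def frame_to_panels(frame: pd.DataFrame) -> list[MetabolitePanel]:
    missing = set(ANALYTES) - set(frame.columns)
    if missing:
        raise MetaboliteError(f"concentration table missing analyte columns: {sorted(missing)}")
    return [
        MetabolitePanel(str(row["sample_id"]), {a: float(row[a]) for a in ANALYTES})
        for _, row in frame.iterrows()
    ]


def read_concentrations(path) -> list[MetabolitePanel]:
    """Read a concentrations.csv (header = sample_id + canonical analyte names)."""
    return frame_to_panels(pd.read_csv(path, comment="#"))


def write_concentrations(panels: Sequence[MetabolitePanel], path) -> None:
    panels_to_frame(panels).to_csv(path, index=False)


def mr_table(panels: Sequence[MetabolitePanel], cutoff: float = MR_CUTOFF) -> pd.DataFrame:
    """Per-sample MR and below-cutoff classification as a DataFrame."""
    results = [compute_mr(p, cutoff) for p in panels]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "mr": [r.mr for r in results],
            "below_threshold": [r.below_threshold for r in results],
        }
    )
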