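"""Drug-metabolism quantification from LC-MS/MS peak-area ratios.

A linear calibration line ``y = a x + b`` (peak-area ratio of analyte to
internal standard versus concentration in µM) is fitted per analyte by
ordinary least squares; sample concentrations come from inverse prediction
``x = (y - b) / a``. Parent-drug disappearance is referenced either to the
time-matched no-microbiome control (isolating microbial metabolism from
passive degradation) or to the nominal 500 µM dose, and inter-donor
variation is summarised as the coefficient of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("culturebench")

R2_ACCEPTANCE = 0.99  # calibration acceptance threshold, applied to r^2

#: Calibration lines printed for the six analytes of the three-drug panel
#: (slope in area-ratio per µM, intercept in area-ratio units).
PUBLISHED_CALIBRATIONS: dict[str, tuple[float, float]] = {
    "aspirin": (347.54, 0.4552),
    "salicylic_acid": (8.3759, -7.9087),
    "levodopa": (1126.8, 0.3252),
    "dopamine": (299.28, 6.4806),
    "doxifluridine": (0.5103, 0.0049),
    "5-fluorouracil": (0.1328, 0.0034),
}

#: Parent drug -> metabolite analyte.
DRUG_METABOLITES = {
    "aspirin": "salicylic_acid",
    "levodopa": "dopamine",
    "doxifluridine": "5-fluorouracil",
}


@dataclass
class CalibrationCurve:
    """One analyte's fitted calibration line and its fit quality."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError(f"zero slope for {self.analyte}")

    def predict(self, conc_um: float) -> float:
        """Forward map: concentration (µM) -> expected peak-area ratio."""
        return self.slope * np.asarray(conc_um, dtype=float) + self.intercept

    def inverse(self, area_ratio):
        """Inverse prediction without clipping; see :func:`quantify`."""
        return (np.asarray(area_ratio, dtype=float) - self.intercept) / self.slope

    def summary(self) -> str:
        sign = "+" if self.intercept >= 0 else "−"
        return (
            f"{self.analyte}: y = {self.slope:.6g}x {sign} {abs(self.intercept):.6g}"
            f"  (r² = {self.r_squared:.6f}, range {self.conc_range[0]:g}–"
            f"{self.conc_range[1]:g} µM)"
        )


def fit_calibration(points, analyte: str = "") -> CalibrationCurve:
    """Least-squares calibration line from (concentration µM, area ratio) pairs.

    Requires >= 3 points over >= 2 distinct concentrations; an r² below
    0.99 is returned but logged as failing the usual acceptance bar.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (conc, area_ratio) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all calibration concentrations identical")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 < R2_ACCEPTANCE:
        logger.warning(
            "calibration for %s has r²=%.4f < %.2f acceptance threshold",
            analyte or "analyte",
            r2,
            R2_ACCEPTANCE,
        )
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        conc_range=(float(x.min()), float(x.max())),
    )


def quantify(area_ratio: float, curve: CalibrationCurve, analyte: str | None = None) -> float:
    """Concentration (µM) from a peak-area ratio by inverse prediction.

    Values implying negative concentration are clipped to 0 (logged) —
    the "almost nondetectable" case; values outside the calibration range
    are flagged but returned.
    """
    if analyte is not None and analyte != curve.analyte:
        raise ValueError(f"analyte {analyte!r} does not match curve {curve.analyte!r}")
    x = float(curve.inverse(area_ratio))
    if x < 0:
        logger.warning(
            "area ratio %.4g below calibration intercept for %s; clipping to 0 µM",
            area_ratio,
            curve.analyte,
        )
        return 0.0
    lo, hi = curve.conc_range
    if not (lo <= x <= hi):
        logger.info(
            "concentration %.4g µM outside calibration range [%g, %g] for %s",
            x,
            lo,
            hi,
            curve.analyte,
        )
    return x


def remaining_fraction(conc_t: float, reference: float) -> float:
    """Fraction of parent drug remaining relative to a reference level."""
    if reference <= 0:
        raise ValueError("reference concentration must be positive")
    return conc_t / reference


def interdonor_variation(values) -> dict[str, float]:
    """Mean, sample SD (n-1) and CV of a per-donor quantity."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 donors")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return {"mean": mean, "sd": sd, "cv": sd / mean}


def control_correct(
    culture: pd.Series, control: pd.Series
) -> pd.Series:
    """Microbiome-attributable drug loss: control(t) - culture(t), floored at 0.

    Both series are concentration-vs-time with identical time indexes; the
    no-microbiome control removes passive (abiotic) degradation.
    """
    if list(culture.index) != list(control.index):
        raise ValueError("culture and control series are not time-matched")
    return (control - culture).clip(lower=0.0)


def read_calibration_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"analyte": str})
    required = {"analyte", "conc_uM", "area_ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"calibration table missing {sorted(required - set(df.columns))}")
    return df


def read_measurement_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"donor": str, "drug": str, "analyte": str})
    required = {"donor", "drug", "analyte", "time_h", "condition", "area_ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"measurement table missing {sorted(required - set(df.columns))}")
    return df


def quantify_assay(
    measurements: pd.DataFrame,
    curves: dict[str, CalibrationCurve],
    reference: str = "control",
    nominal_dose_um: float = 500.0,
) -> dict[str, pd.DataFrame]:
    """Full drug-metabolism summary from a long-format measurement table.

    Returns concentration table (per donor/drug/analyte/time/condition),
    remaining fractions of the parent drug per time point, microbiome-
    attributable loss, and inter-donor CV per drug (remaining fraction at
    the last time point). ``reference`` selects the denominator for the
    remaining fraction: the time-matched no-microbiome control, or the
    nominal dose.
    """
    if reference not in ("control", "nominal"):
        raise ValueError("reference must be 'control' or 'nominal'")
    df = measurements.copy()
    df["conc_uM"] = [
        quantify(row.area_ratio, curves[row.analyte]) for row in df.itertuples()
    ]

    parent = df[df["analyte"] == df["drug"]]
    cultures = parent[parent["condition"] == "culture"]
    controls = parent[parent["condition"] == "control"].set_index(["drug", "time_h"])

    missing = []
    rows = []
    for (donor, drug), grp in cultures.groupby(["donor", "drug"]):
        for row in grp.itertuples():
            key = (drug, row.time_h)
            if reference == "control":
                if key not in controls.index:
                    missing.append((donor, drug, row.time_h))
                    continue
                ref = float(np.atleast_1d(controls.loc[key, "conc_uM"])[0])
            else:
                ref = nominal_dose_um
            rows.append(
                {
                    "donor": donor,
                    "drug": drug,
                    "time_h": row.time_h,
                    "conc_uM": row.conc_uM,
                    "remaining_fraction": remaining_fraction(row.conc_uM, ref),
                }
            )
    if missing:
        raise ValueError(f"unmatched control series for (donor, drug, time): {missing}")
    remaining = pd.DataFrame(rows)

    last_t = remaining["time_h"].max()
    final = remaining[remaining["time_h"] == last_t]
    variation = pd.DataFrame(
        {
            drug: interdonor_variation(g["remaining_fraction"])
            for drug, g in final.groupby("drug")
        }
    ).T
    variation.index.name = "drug"
    return {"concentrations": df, "remaining": remaining, "interdonor": variation}
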