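"""Packaged summary panel of a published veterinary reference study.

The raw per-animal measurements behind the published tables are not
deposited; what is public are per-row summaries (n, mean, SD, median, min,
max, Shapiro-Wilk p, distribution label, method label) for ~40 measurands,
pooled and split by sex.  This module freezes those printed summaries so
that

* the synthetic generator can emulate the panel's statistical structure, and
* method-routing can be regression-tested against every printed row.

Row layout: ``(group, measurand, unit, sex, n, mean, sd, median, min, max,
shapiro_p, distribution, method)``.  ``sex`` is "All", "M" or "F";
``distribution`` is "G"/"NG" or None where not printed; ``method`` is
"P"/"NP" or None where the row reports descriptive values only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PanelRow", "PANEL_ROWS", "panel_summary_frame"]


@dataclass(frozen=True)
class PanelRow:
    group: str
    measurand: str
    unit: str
    sex: str
    n: int
    mean: float | None
    sd: float | None
    median: float | None
    min: float | None
    max: float | None
    shapiro_p: float | None
    distribution: str | None
    method: str | None


_R = PanelRow

PANEL_ROWS: tuple[PanelRow, ...] = (
    # --- hematology ---
    _R("hematology", "Hb", "g/dl", "All", 86, 11.91, 1.86, 11.75, 7.8, 16.9, 0.07425, "NG", "NP"),
    _R("hematology", "Hb", "g/dl", "M", 57, 11.52, 1.44, 11.40, 7.8, 13.9, 0.1375, "NG", "NP"),
    _R("hematology", "Hb", "g/dl", "F", 28, 12.51, 2.21, 12.85, 8.7, 16.8, None, None, "NP"),
    _R("hematology", "RBC", "x10^12/L", "All", 77, 2.91, 0.87, 2.65, 1.8, 4.9, 1.62e-07, "NG", "NP"),
    _R("hematology", "RBC", "x10^12/L", "M", 46, 2.60, 0.35, 2.60, 1.8, 3.3, 0.61, "G", "P"),
    _R("hematology", "RBC", "x10^12/L", "F", 29, 3.29, 1.38, 2.92, 1.1, 5.6, None, None, "NP"),
    _R("hematology", "PCV", "%", "All", 85, 33.03, 6.35, 31.90, 19.0, 50.0, 0.1253, "NG", "NP"),
    _R("hematology", "PCV", "%", "M", 57, 31.63, 4.96, 31.40, 19.0, 41.0, 0.353, "G", "P"),
    _R("hematology", "PCV", "%", "F", 29, 35.23, 8.49, 35.50, 16.7, 50.0, None, None, "NP"),
    _R("hematology", "MCV", "fl", "All", 67, 121.90, 4.82, 121.70, 110.5, 133.2, 0.9496, "G", "P"),
    _R("hematology", "MCV", "fl", "M", 41, 121.20, 3.49, 121.20, 113.5, 128.7, 0.937, "G", "P"),
    _R("hematology", "MCV", "fl", "F", 28, 129.60, 11.80, 126.30, 114.4, 156.4, None, None, "NP"),
    _R("hematology", "MCH", "pg/cell", "All", 82, 45.94, 5.77, 44.45, 39.1, 62.5, 1.20e-08, "NG", "NP"),
    _R("hematology", "MCH", "pg/cell", "M", 50, 44.47, 3.61, 44.00, 39.1, 54.7, 0.0002278, "NG", "NP"),
    _R("hematology", "MCH", "pg/cell", "F", 28, 46.26, 5.83, 44.90, 39.3, 62.0, None, None, "NP"),
    _R("hematology", "MCHC", "g/dL", "All", 80, 36.38, 1.98, 36.10, 33.3, 41.4, 0.0001729, "NG", "NP"),
    _R("hematology", "MCHC", "g/dL", "M", 57, 36.63, 2.04, 36.20, 33.5, 41.4, 0.0001624, "NG", "NP"),
    _R("hematology", "MCHC", "g/dL", "F", 28, 35.95, 2.57, 36.10, 32.6, 42.7, None, None, "NP"),
    _R("hematology", "Platelet", "lakhs/cumm", "All", 86, 477.00, 189.97, 449.00, 150.0, 991.0, 0.05444, "NG", "NP"),
    _R("hematology", "Platelet", "lakhs/cumm", "M", 58, 495.60, 173.21, 492.50, 201.0, 991.0, 0.257, "G", "P"),
    _R("hematology", "Platelet", "lakhs/cumm", "F", 29, 432.20, 217.65, 380.00, 150.0, 966.0, None, None, "NP"),
    # --- leukocytes / differential count ---
    _R("leukocyte", "TLC", "cell/cumm", "All", 84, 17796.0, 5051.55, 16750.0, 9900.0, 32800.0, 0.00611, "NG", "NP"),
    _R("leukocyte", "TLC", "cell/cumm", "M", 57, 17744.0, 5638.96, 16300.0, 9900.0, 39800.0, 0.0004072, "NG", "NP"),
    _R("leukocyte", "TLC", "cell/cumm", "F", 29, 18310.0, 5718.41, 16900.0, 7700.0, 32800.0, None, None, "NP"),
    _R("leukocyte", "Neutrophil", "%", "All", 84, 44.78, 13.79, 41.90, 26.6, 88.6, 1.42e-05, "NG", "NP"),
    _R("leukocyte", "Neutrophil", "%", "M", 55, 44.40, 13.22, 42.50, 19.9, 79.4, 0.01078, "NG", "NP"),
    _R("leukocyte", "Neutrophil", "%", "F", 29, 43.13, 13.31, 38.50, 28.8, 80.9, None, None, "NP"),
    _R("leukocyte", "Lymphocyte", "%", "All", 86, 35.60, 16.40, 37.75, 5.8, 62.4, 0.0003317, "NG", "NP"),
    _R("leukocyte", "Lymphocyte", "%", "M", 57, 35.22, 16.29, 37.00, 5.8, 60.5, 0.002885, "NG", "NP"),
    _R("leukocyte", "Lymphocyte", "%", "F", 29, 36.35, 16.89, 39.00, 7.0, 62.4, None, None, "NP"),
    _R("leukocyte", "Eosinophil", "%", "All", 17, 10.35, 3.18, 11.00, 3.0, 15.0, None, None, None),
    _R("leukocyte", "Eosinophil", "%", "M", 6, None, None, None, None, None, None, None, None),
    _R("leukocyte", "Eosinophil", "%", "F", 11, 10.18, 3.46, 11.00, 3.0, 14.0, None, None, None),
    _R("leukocyte", "Monocyte", "%", "All", 70, 22.30, 18.89, 12.15, 4.0, 79.5, 1.25e-09, "NG", "NP"),
    _R("leukocyte", "Monocyte", "%", "M", 38, 12.01, 3.12, 11.15, 7.9, 22.6, None, None, "NP"),
    _R("leukocyte", "Monocyte", "%", "F", 20, 23.66, 19.61, 12.65, 1.0, 54.6, None, None, "NP"),
    _R("leukocyte", "Basophil", "%", "All", 87, 0.0, 0.0, 0.0, 0.0, 0.0, None, None, None),
    _R("leukocyte", "Basophil", "%", "M", 58, 0.0, 0.0, 0.0, 0.0, 0.0, None, None, None),
    _R("leukocyte", "Basophil", "%", "F", 29, 0.0, 0.0, 0.0, 0.0, 0.0, None, None, None),
    # --- muscle / liver biochemistry ---
    _R("liver", "SGPT", "U/L", "All", 85, 9.52, 3.65, 9.31, 3.41, 21.60, 0.002987, "NG", "NP"),
    _R("liver", "SGPT", "U/L", "M", 53, 8.93, 2.42, 9.31, 4.35, 13.70, 0.261206, "G", "P"),
    _R("liver", "SGPT", "U/L", "F", 28, 9.95, 4.36, 8.95, 4.00, 21.00, None, None, "NP"),
    _R("liver", "SGOT", "U/L", "All", 89, 43.67, 22.07, 41.31, 12.10, 121.88, 6.88e-05, "NG", "NP"),
    _R("liver", "SGOT", "U/L", "M", 60, 45.60, 23.59, 41.45, 15.70, 121.88, 1.18e-04, "NG", "NP"),
    _R("liver", "SGOT", "U/L", "F", 29, 39.68, 18.26, 39.20, 12.10, 82.60, None, None, "NP"),
    _R("liver", "ALP", "U/L", "All", 88, 258.10, 105.82, 234.20, 103.20, 593.10, 4.36e-06, "NG", "NP"),
    _R("liver", "ALP", "U/L", "M", 60, 256.70, 107.25, 241.30, 132.80, 593.10, 2.91e-06, "NG", "NP"),
    _R("liver", "ALP", "U/L", "F", 28, 261.20, 104.55, 231.60, 103.20, 499.00, None, None, "NP"),
    _R("liver", "Total Bilirubin", "mg/dl", "All", 86, 0.15, 0.05, 0.15, 0.09, 0.38, 4.81e-08, "NG", "NP"),
    _R("liver", "Total Bilirubin", "mg/dl", "M", 57, 0.15, 0.06, 0.14, 0.09, 0.38, 4.78e-07, "NG", "NP"),
    _R("liver", "Total Bilirubin", "mg/dl", "F", 28, 0.15, 0.04, 0.16, 0.09, 0.22, None, None, "NP"),
    _R("liver", "Direct Bilirubin", "mg/dl", "All", 88, 0.08, 0.04, 0.07, 0.03, 0.25, 5.37e-10, "NG", "NP"),
    _R("liver", "Direct Bilirubin", "mg/dl", "M", 60, 0.08, 0.03, 0.07, 0.03, 0.22, 4.42e-07, "NG", "NP"),
    _R("liver", "Direct Bilirubin", "mg/dl", "F", 27, 0.07, 0.03, 0.07, 0.04, 0.13, None, None, "NP"),
    _R("liver", "Total Protein", "g/dl", "All", 88, 7.75, 0.95, 7.99, 5.10, 9.38, 0.01891, "NG", "NP"),
    _R("liver", "Total Protein", "g/dl", "M", 59, 7.63, 0.99, 7.90, 5.10, 9.38, 0.1107, "NG", "NP"),
    _R("liver", "Total Protein", "g/dl", "F", 29, 8.00, 0.83, 8.10, 6.14, 9.30, None, None, "NP"),
    _R("liver", "Albumin", "g/dl", "All", 87, 2.47, 0.24, 2.50, 2.00, 2.92, 0.09341, "NG", "NP"),
    _R("liver", "Albumin", "g/dl", "M", 59, 2.41, 0.22, 2.40, 2.00, 2.89, 0.4109, "G", "P"),
    _R("liver", "Albumin", "g/dl", "F", 28, 2.61, 0.23, 2.60, 2.13, 2.92, None, None, "NP"),
    _R("liver", "Globulin", "g/dl", "All", 87, 5.32, 0.92, 5.40, 2.90, 6.90, 0.07148, "NG", "NP"),
    _R("liver", "Globulin", "g/dl", "M", 58, 5.30, 0.97, 5.45, 2.90, 6.90, 0.1972, "NG", "NP"),
    _R("liver", "Globulin", "g/dl", "F", 29, 5.37, 0.83, 5.40, 4.00, 6.90, None, None, "NP"),
    _R("liver", "GGT", "U/L", "All", 87, 8.12, 4.51, 7.66, 1.91, 24.30, 1.96e-06, "NG", "NP"),
    _R("liver", "GGT", "U/L", "M", 58, 7.94, 4.30, 7.64, 2.32, 23.70, 8.49e-05, "NG", "NP"),
    _R("liver", "GGT", "U/L", "F", 28, 7.91, 3.98, 7.60, 1.91, 19.00, None, None, "NP"),
    # --- kidney biochemistry ---
    _R("kidney", "CRT", "mg/dl", "All", 88, 1.26, 0.38, 1.23, 0.64, 2.70, 0.003256, "NG", "NP"),
    _R("kidney", "CRT", "mg/dl", "M", 59, 1.30, 0.40, 1.26, 0.65, 2.70, 0.02334, "NG", "NP"),
    _R("kidney", "CRT", "mg/dl", "F", 29, 1.19, 0.33, 1.12, 0.64, 2.03, None, None, "NP"),
    _R("kidney", "BUN", "mg/dl", "All", 89, 10.83, 4.80, 10.00, 3.80, 24.72, 3.68e-05, "NG", "NP"),
    _R("kidney", "BUN", "mg/dl", "M", 60, 10.78, 5.26, 9.45, 3.80, 24.72, 6.01e-05, "NG", "NP"),
    _R("kidney", "BUN", "mg/dl", "F", 29, 10.94, 3.79, 10.80, 4.31, 20.27, None, None, "NP"),
    _R("kidney", "A/G Ratio", "", "All", 89, 0.49, 0.13, 0.50, 0.30, 0.80, 1.34e-05, "NG", "NP"),
    _R("kidney", "A/G Ratio", "", "M", 60, 0.48, 0.13, 0.45, 0.30, 0.80, 1.13e-04, "NG", "NP"),
    _R("kidney", "A/G Ratio", "", "F", 26, 0.47, 0.09, 0.50, 0.30, 0.60, None, None, "NP"),
    # --- lipid profile ---
    _R("lipid", "Total Cholesterol", "mg/dl", "All", 86, 48.17, 10.82, 47.45, 20.70, 73.40, 0.9184, "G", "P"),
    _R("lipid", "Total Cholesterol", "mg/dl", "M", 57, 48.99, 11.54, 47.30, 20.70, 73.40, 0.697751, "G", "P"),
    _R("lipid", "Total Cholesterol", "mg/dl", "F", 29, 46.57, 9.24, 47.60, 28.30, 63.60, None, None, "NP"),
    _R("lipid", "Triglyceride", "mg/dl", "All", 84, 26.28, 10.09, 24.60, 9.87, 56.50, 0.0006691, "NG", "NP"),
    _R("lipid", "Triglyceride", "mg/dl", "M", 55, 25.78, 9.62, 23.10, 9.87, 52.50, 0.04407, "NG", "NP"),
    _R("lipid", "Triglyceride", "mg/dl", "F", 29, 27.25, 11.04, 25.50, 13.90, 56.50, None, None, "NP"),
    _R("lipid", "HDL", "mg/dl", "All", 83, 18.40, 8.23, 16.30, 9.00, 40.00, 9.37e-09, "NG", "NP"),
    _R("lipid", "HDL", "mg/dl", "M", 56, 18.72, 8.44, 16.80, 9.00, 40.00, 4.07e-06, "NG", "NP"),
    _R("lipid", "HDL", "mg/dl", "F", 27, 17.75, 7.89, 15.70, 10.30, 39.20, None, None, "NP"),
    _R("lipid", "LDL", "mg/dl", "All", 80, 26.85, 11.34, 27.25, 7.50, 59.50, 0.2088, "G", "P"),
    _R("lipid", "LDL", "mg/dl", "M", 54, 27.49, 11.52, 28.05, 7.50, 59.50, 0.42772, "G", "P"),
    _R("lipid", "LDL", "mg/dl", "F", 26, 25.53, 11.05, 24.40, 8.30, 54.60, None, None, "NP"),
    _R("lipid", "VLDL", "mg/dl", "All", 84, 5.26, 2.02, 4.90, 2.00, 11.30, 6.00e-04, "NG", "NP"),
    _R("lipid", "VLDL", "mg/dl", "M", 55, 5.16, 1.92, 4.60, 2.00, 10.50, 4.15e-02, "NG", "NP"),
    _R("lipid", "VLDL", "mg/dl", "F", 29, 5.46, 2.21, 5.10, 2.80, 11.30, None, None, "NP"),
    _R("lipid", "TC/HDL", "", "All", 85, 2.92, 1.01, 3.00, 1.00, 5.30, 0.1234, "NG", "NP"),
    _R("lipid", "TC/HDL", "", "M", 57, 2.98, 1.07, 3.10, 1.00, 5.30, 0.4446, "G", "P"),
    _R("lipid", "TC/HDL", "", "F", 28, 2.78, 0.89, 2.90, 1.20, 4.30, None, None, "NP"),
    _R("lipid", "LDL/HDL", "", "All", 84, 1.62, 0.90, 1.70, 0.10, 3.80, 0.09903, "NG", "NP"),
    _R("lipid", "LDL/HDL", "", "M", 56, 1.69, 0.95, 1.70, 0.10, 3.80, 0.2567, "G", "P"),
    _R("lipid", "LDL/HDL", "", "F", 28, 1.49, 0.79, 1.55, 0.10, 2.90, None, None, "NP"),
    # --- electrolytes ---
    _R("electrolyte", "Calcium", "mg/dl", "All", 88, 9.04, 1.44, 9.00, 5.60, 11.80, 0.04604, "NG", "NP"),
    _R("electrolyte", "Calcium", "mg/dl", "M", 60, 8.91, 1.43, 8.70, 6.10, 11.80, 0.07623, "NG", "NP"),
    _R("electrolyte", "Calcium", "mg/dl", "F", 28, 9.31, 1.43, 9.60, 5.60, 11.30, None, None, "NP"),
    _R("electrolyte", "Phosphorus", "mg/dl", "All", 85, 4.60, 0.87, 4.62, 2.80, 6.75, 0.6884, "G", "P"),
    _R("electrolyte", "Phosphorus", "mg/dl", "M", 58, 4.54, 0.81, 4.61, 2.80, 6.39, 0.866337, "G", "P"),
    _R("electrolyte", "Phosphorus", "mg/dl", "F", 27, 4.72, 0.99, 4.64, 2.80, 6.75, None, None, "NP"),
    _R("electrolyte", "Sodium", "mmol/L", "All", 88, 152.40, 9.26, 150.10, 133.10, 177.00, 0.05136, "NG", "NP"),
    _R("electrolyte", "Sodium", "mmol/L", "M", 59, 151.00, 9.14, 149.80, 133.10, 177.00, 0.1898, "NG", "NP"),
    _R("electrolyte", "Sodium", "mmol/L", "F", 29, 155.30, 8.95, 154.00, 143.70, 175.00, None, None, "NP"),
    _R("electrolyte", "Potassium", "mmol/L", "All", 89, 4.82, 1.53, 4.80, 1.80, 8.50, 0.2364, "G", "P"),
    _R("electrolyte", "Potassium", "mmol/L", "M", 60, 4.69, 1.54, 4.63, 1.80, 8.50, 0.1784, "NG", "NP"),
    _R("electrolyte", "Potassium", "mmol/L", "F", 29, 5.08, 1.49, 4.90, 2.50, 7.70, None, None, "NP"),
    _R("electrolyte", "Chloride", "mmol/L", "All", 89, 106.00, 6.86, 106.40, 89.90, 121.80, 0.3755, "G", "P"),
    _R("electrolyte", "Chloride", "mmol/L", "M", 60, 106.60, 6.20, 106.80, 91.20, 117.30, 0.276328, "G", "P"),
    _R("electrolyte", "Chloride", "mmol/L", "F", 29, 104.80, 8.04, 103.60, 89.90, 121.80, None, None, "NP"),
    # --- arterial blood gas (pooled only) ---
    _R("blood_gas", "pH", "", "All", 33, 7.427, 0.038, 7.422, 7.368, 7.515, None, None, "NP"),
    _R("blood_gas", "pCO2", "mmHg", "All", 36, 39.22, 5.042, 39.85, 28.5, 47.9, None, None, "NP"),
    _R("blood_gas", "pO2", "mmHg", "All", 35, 92.4, 12.983, 90.5, 71.0, 120.8, None, None, "NP"),
    _R("blood_gas", "cHCO3", "mmol/L", "All", 36, 26.32, 1.938, 25.6, 23.0, 30.1, None, None, "NP"),
    _R("blood_gas", "sO2", "%", "All", 35, 97.25, 1.268, 97.5, 94.4, 99.6, None, None, "NP"),
    _R("blood_gas", "tCO2", "mmol/L", "All", 36, 25.94, 1.831, 25.3, 22.8, 29.5, None, None, "NP"),
    _R("blood_gas", "BE(ecf)", "mmol/L", "All", 36, 2.136, 2.202, 1.65, -0.8, 8.2, None, None, "NP"),
    _R("blood_gas", "BE(b)", "mmol/L", "All", 36, 2.031, 2.029, 1.75, -0.7, 8.0, None, None, "NP"),
)


def panel_summary_frame() -> pd.DataFrame:
    """The frozen panel as a tidy DataFrame (one row per measurand x sex)."""
    return pd.DataFrame([vars(r) for r in PANEL_ROWS])
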