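"""Bundled reference tables of probe readouts in GUV membranes.

Published condition summaries (mean +/- SD over >= 50 vesicles, n given as
the stated minimum) for DOPC and binary-mixture GUVs incubated with
methyl-beta-cyclodextrin/cholesterol (MbCD-CL) complexes, plus the
gel-swelling calibration series of known cholesterol content.  These tables
parametrize the phantom generators (they define the study conditions for
recovery experiments) and feed the calibration fits.
"""

from __future__ import annotations

import pandas as pd

from .calibration import CalibrationPoint

N_VESICLES_CONDITION = 50  # stated minimum per condition
N_VESICLES_CALIBRATION = 30  # stated minimum per calibration point


def dopc_edice_conditions() -> pd.DataFrame:
    """NR12A GP and Flipper-TR lifetime of eDICE DOPC GUVs vs MbCD-CL dose."""
    return pd.DataFrame(
        {
            "mbcd_cl_uM": [0, 10, 30, 100],
            "gp_mean": [-0.51, -0.44, -0.25, -0.10],
            "gp_sd": [0.05, 0.08, 0.09, 0.11],
            "lifetime_mean_ns": [2.96, 3.41, 4.05, 4.37],
            "lifetime_sd_ns": [0.06, 0.05, 0.13, 0.20],
            "n_vesicles": [N_VESICLES_CONDITION] * 4,
        }
    )


def gel_swelling_calibration() -> pd.DataFrame:
    """Readouts of gel-swollen DOPC GUVs with defined cholesterol mol%."""
    return pd.DataFrame(
        {
            "chol_molpct": [0.0, 10.0, 25.0, 40.0],
            "gp_mean": [-0.53, -0.45, -0.30, -0.09],
            "gp_sd": [0.04, 0.05, 0.07, 0.09],
            "lifetime_mean_ns": [2.92, 3.32, 3.78, 4.50],
            "lifetime_sd_ns": [0.03, 0.07, 0.11, 0.16],
            "n_vesicles": [N_VESICLES_CALIBRATION] * 4,
        }
    )


def binary_mixture_gp() -> pd.DataFrame:
    """NR12A GP of eDICE GUVs from binary lipid mixtures vs MbCD-CL dose."""
    return pd.DataFrame(
        {
            "mbcd_cl_uM": [0, 10, 30, 100],
            "dopc_dmpc_mean": [-0.38, -0.29, -0.10, 0.09],
            "dopc_dmpc_sd": [0.07, 0.07, 0.12, 0.09],
            "dopc_pc18014_mean": [-0.41, -0.30, -0.15, -0.02],
            "dopc_pc18014_sd": [0.05, 0.06, 0.09, 0.09],
            "n_vesicles": [N_VESICLES_CONDITION] * 4,
        }
    )


def binary_mixture_lifetime() -> pd.DataFrame:
    """Flipper-TR lifetime (ns) of binary-mixture eDICE GUVs vs MbCD-CL dose."""
    return pd.DataFrame(
        {
            "mbcd_cl_uM": [0, 10, 30, 100],
            "dopc_dmpc_mean": [3.05, 3.68, 4.43, 4.80],
            "dopc_dmpc_sd": [0.10, 0.12, 0.18, 0.19],
            "dopc_pc18014_mean": [2.98, 3.57, 4.15, 4.63],
            "dopc_pc18014_sd": [0.11, 0.21, 0.17, 0.22],
            "n_vesicles": [N_VESICLES_CONDITION] * 4,
        }
    )


def reference_cholesterol_estimates() -> pd.DataFrame:
    """Published cholesterol mol% estimates for MbCD-CL-treated DOPC GUVs.

    Derived by the original analysis from unrounded per-GUV data; estimates
    recomputed from the rounded condition means agree only to ~2 mol%.
    """
    return pd.DataFrame(
        {
            "mbcd_cl_uM": [10, 30, 100],
            "from_gp_molpct": [9.78, 27.75, 42.38],
            "from_gp_se": [0.89, 1.06, 1.36],
            "from_lifetime_molpct": [12.92, 30.07, 38.57],
            "from_lifetime_se": [0.16, 0.45, 0.68],
        }
    )


def phase_domain_lifetime_ranges() -> dict:
    """Lifetime ranges (ns) of coexisting membrane phases in phase-separated
    DOPC:DMPC GUVs after cholesterol loading: liquid-ordered (Lo) vs
    liquid-disordered (Ld) domains."""
    return {"Lo": (4.83, 4.91), "Ld": (3.78, 3.99)}


def calibration_points(modality: str = "GP") -> list[CalibrationPoint]:
    """Gel-swelling calibration series as :class:`CalibrationPoint` objects."""
    df = gel_swelling_calibration()
    if modality == "GP":
        mean, sd = df["gp_mean"], df["gp_sd"]
    elif modality == "lifetime":
        mean, sd = df["lifetime_mean_ns"], df["lifetime_sd_ns"]
    else:
        raise ValueError("modality must be 'GP' or 'lifetime'")
    return [
        CalibrationPoint(
            chol_molpct=float(x), readout_mean=float(m), readout_sd=float(s),
            n_vesicles=int(n),
        )
        for x, m, s, n in zip(df["chol_molpct"], mean, sd, df["n_vesicles"])
    ]
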