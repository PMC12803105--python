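"""Reporter-assay and morphometry statistics.

Covers the three validation readouts: sequential dual-luciferase
normalization with per-construct one-sample t tests and Benjamini-Hochberg
correction, the defect-proportion chi-square, and paired eye/lens
morphometry where each area is the product of the minor and major diameters
and the two sides of each larva form the pairs.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import ContingencyResult, chi_square_2x2

WELL_COLUMNS = ["construct_id", "condition", "biological_replicate",
                "technical_replicate", "firefly", "renilla"]


def normalize_luciferase(wells: pd.DataFrame, control_construct: str,
                         with_effector_norm: bool = True) -> pd.DataFrame:
    """Sequential normalization of dual-luciferase wells.

    Per well, the firefly/renilla (F/R) ratio is computed; technical
    replicates are collapsed by the median within each (construct, condition,
    biological replicate); each median is divided by the control construct's
    median of the same condition and biological replicate; finally, when
    ``with_effector_norm`` is on, the effector value is divided by the
    control-effector value of the same construct and biological replicate.
    The result is reported as log2, one row per (construct, biological
    replicate); values significantly below 0 indicate effector-dependent
    repression.

    The chain is exactly multiplicative, so any per-replicate scaling of
    firefly (or renilla) cancels through the control construct.
    """
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"wells table missing columns: {missing}")
    if (wells["renilla"] <= 0).any() or (wells["firefly"] <= 0).any():
        raise ValueError("luminescence values must be positive")

    df = wells.copy()
    df["fr"] = df["firefly"] / df["renilla"]
    med = (df.groupby(["construct_id", "condition", "biological_replicate"])["fr"]
             .median().rename("fr_med").reset_index())

    ctrl = med[med["construct_id"] == control_construct]
    if ctrl.empty:
        raise ValueError(f"control construct {control_construct!r} absent from wells")
    ctrl = ctrl.rename(columns={"fr_med": "fr_ctrl"}).drop(columns="construct_id")
    merged = med.merge(ctrl, on=["condition", "biological_replicate"], how="left")
    if merged["fr_ctrl"].isna().any():
        bad = merged[merged["fr_ctrl"].isna()][["condition", "biological_replicate"]]
        raise ValueError(f"missing control-construct wells for: {bad.to_dict('records')}")
    merged["rel"] = merged["fr_med"] / merged["fr_ctrl"]

    if with_effector_norm:
        eff = merged[merged["condition"] == "effector"]
        ctl = merged[merged["condition"] == "control_effector"]
        if eff.empty or ctl.empty:
            raise ValueError("both effector and control_effector wells are required "
                             "for the effector normalization step")
        ctl = ctl.rename(columns={"rel": "rel_ctl"})[
            ["construct_id", "biological_replicate", "rel_ctl"]]
        out = eff.merge(ctl, on=["construct_id", "biological_replicate"], how="left")
        if out["rel_ctl"].isna().any():
            bad = out[out["rel_ctl"].isna()][["construct_id", "biological_replicate"]]
            raise ValueError(f"missing control-effector pairing for: {bad.to_dict('records')}")
        out["log2_activity"] = np.log2(out["rel"] / out["rel_ctl"])
    else:
        out = merged[merged["condition"] == "effector"].copy()
        if out.empty:  # single-condition design (no effector contrast recorded)
            out = merged.copy()
        out["log2_activity"] = np.log2(out["rel"])

    out = out[["construct_id", "biological_replicate", "log2_activity"]]
    return out.sort_values(["construct_id", "biological_replicate"],
                           kind="mergesort", ignore_index=True)


def one_sample_tests(activities: pd.DataFrame,
                     value_col: str = "log2_activity") -> pd.DataFrame:
    """Two-sided one-sample t test (H0: mean = 0) per construct on biological
    replicates, with Benjamini-Hochberg adjustment across constructs.

    Constructs with fewer than 2 replicates are excluded with a warning;
    zero-variance constructs report p = 1 with a warning flag.
    """
    rows = []
    for construct, grp in activities.groupby("construct_id", sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"construct {construct!r} has n < 2; excluded from testing")
            continue
        if np.allclose(vals, vals[0]):
            rows.append((construct, vals.size, float(vals.mean()), 0.0, 1.0, True))
            warnings.warn(f"construct {construct!r} has zero variance; p set to 1")
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        rows.append((construct, vals.size, float(vals.mean()), float(t), float(p), False))
    out = pd.DataFrame(rows, columns=["construct_id", "n", "mean_log2",
                                      "t_statistic", "p", "zero_variance"])
    if len(out):
        out["padj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["padj"] = []
    return out


def proportion_test(defect_a: int, normal_a: int, defect_b: int,
                    normal_b: int) -> ContingencyResult:
    """Chi-square comparison of defect proportions between two groups."""
    return chi_square_2x2([[defect_a, normal_a], [defect_b, normal_b]])


def paired_morphometry(measurements: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired injected-vs-control morphometry.

    ``measurements`` columns: larva_id, side ({injected, control}), structure
    ({eye, lens}), minor_diameter, major_diameter, optionally
    cornea_thickness.  Per record, area = minor x major; per larva and side,
    ratio = lens area / eye area.  A two-sided paired t test across larvae is
    run for eye area, lens area, the ratio and (when present) cornea
    thickness.  Larvae missing either side are dropped with a warning; a
    zero-variance difference reports p = 1 with a flag.

    Returns (records with area, per larva-side summary, test table).
    """
    df = measurements.copy()
    if (df["minor_diameter"] <= 0).any() or (df["major_diameter"] <= 0).any():
        raise ValueError("diameters must be positive")
    df["area"] = df["minor_diameter"] * df["major_diameter"]

    wide = df.pivot_table(index=["larva_id", "side"], columns="structure",
                          values="area", aggfunc="first").reset_index()
    wide = wide.rename(columns={"eye": "eye_area", "lens": "lens_area"})
    wide["lens_eye_ratio"] = wide["lens_area"] / wide["eye_area"]
    if "cornea_thickness" in df.columns and df["cornea_thickness"].notna().any():
        cor = (df.dropna(subset=["cornea_thickness"])
                 .groupby(["larva_id", "side"])["cornea_thickness"].mean().reset_index())
        wide = wide.merge(cor, on=["larva_id", "side"], how="left")

    endpoints = [c for c in ("eye_area", "lens_area", "lens_eye_ratio", "cornea_thickness")
                 if c in wide.columns]
    inj = wide[wide["side"] == "injected"].set_index("larva_id")
    ctl = wide[wide["side"] == "control"].set_index("larva_id")
    paired_ids = sorted(set(inj.index) & set(ctl.index))
    dropped = sorted(set(wide["larva_id"]) - set(paired_ids))
    if dropped:
        warnings.warn(f"unpaired larvae dropped: {dropped}")

    rows = []
    for ep in endpoints:
        a = inj.loc[paired_ids, ep].to_numpy(dtype=float)
        b = ctl.loc[paired_ids, ep].to_numpy(dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        diff = a - b
        if diff.size < 2 or np.allclose(diff, diff[0]) and np.ptp(diff) == 0:
            rows.append((ep, diff.size, float(np.mean(diff)) if diff.size else np.nan,
                         np.nan, 1.0, True))
            if diff.size >= 2:
                warnings.warn(f"endpoint {ep!r}: zero-variance differences; p set to 1")
            continue
        t, p = stats.ttest_rel(a, b)
        rows.append((ep, diff.size, float(np.mean(diff)), float(t), float(p), False))
    tests = pd.DataFrame(rows, columns=["endpoint", "n_pairs", "mean_difference",
                                        "t_statistic", "p", "zero_variance"])
    return df, wide, tests
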