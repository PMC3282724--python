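"""Stand structural and diversity attributes from stem-level inventories.

The inventory uses nested DBH-class sampling: large stems (DBH >= 5 cm) are
recorded over four 20x5 m transects (400 m2), medium stems (2.5-5 cm) over
half of that area (200 m2) and small stems (1-2.5 cm) over a quarter
(100 m2).  All per-hectare quantities weight each stem by the expansion
factor 10,000 / sampled-area of its class.

Fourteen attributes are produced per plot: Age, Hgt, and — for both the
total community (T) and the upper-canopy subset (U) — stem density Dn,
canopy cover CC, basal area BA, species richness S, Shannon diversity H'
(natural-log units) and Simpson dominance D' = sum(p_i^2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: sampled area (m2) per DBH sampling class
CLASS_AREA_M2 = {"large": 400.0, "medium": 200.0, "small": 100.0}

#: Table-2-style output schema
ATTRIBUTE_COLUMNS = [
    "Age", "Hgt", "S_T", "S_U", "Dn_T", "Dn_U", "BA_T", "BA_U",
    "CC_T", "CC_U", "H_T", "H_U", "D_T", "D_U",
]


class SamplingClassError(ValueError):
    """A stem carries an unknown sampling class."""


def expansion_factors(stems: pd.DataFrame) -> pd.Series:
    """Per-stem scaling weight to 1 ha: 10,000 / sampled area of the class."""
    unknown = set(stems["sampling_class"]) - set(CLASS_AREA_M2)
    if unknown:
        raise SamplingClassError(f"unknown sampling class(es): {sorted(unknown)}")
    return 10_000.0 / stems["sampling_class"].map(CLASS_AREA_M2)


def scale_to_hectare(stems: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with an ``expansion`` column (stems/ha each stem stands for)."""
    out = stems.copy()
    out["expansion"] = expansion_factors(stems)
    return out


def crown_area(stems: pd.DataFrame) -> pd.Series:
    """Individual crown area: ellipse from the two orthogonal crown diameters."""
    return np.pi * (stems["crown_d1_m"] / 2.0) * (stems["crown_d2_m"] / 2.0)


def basal_area_m2(dbh_cm: pd.Series) -> pd.Series:
    """Stem cross-section at breast height in m2 (DBH given in cm)."""
    return np.pi * (dbh_cm / 200.0) ** 2


def upper_set(stems: pd.DataFrame) -> pd.DataFrame:
    """Upper-canopy subset: the stems contributing the top half of canopy cover.

    Stems are ranked by individual crown area (descending, ties broken by
    larger DBH, then stable input order); the subset is the minimal prefix
    whose cumulative expansion-weighted crown area reaches >= 50% of the
    plot's total CC.  This operationalizes "plants above the median of the
    cumulative canopy-cover distribution".
    """
    s = scale_to_hectare(stems) if "expansion" not in stems else stems.copy()
    s["_ca"] = crown_area(s)
    if (s["_ca"] <= 0).all():
        raise ValueError("degenerate input: all crown areas are zero")
    order = s.sort_values(["_ca", "dbh_cm"], ascending=[False, False],
                          kind="stable").index
    weighted = (s.loc[order, "_ca"] * s.loc[order, "expansion"]).to_numpy()
    cum = np.cumsum(weighted)
    n_keep = int(np.searchsorted(cum, 0.5 * cum[-1]) + 1)
    return s.loc[order[:n_keep]].drop(columns="_ca")


def _diversity(weights: pd.Series) -> tuple[float, float]:
    """Shannon H' (nats) and Simpson dominance D' from abundance weights."""
    p = weights.to_numpy(dtype=float)
    p = p / p.sum()
    p = p[p > 0]
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((p ** 2).sum())
    return shannon, simpson


def _set_attributes(s: pd.DataFrame) -> dict[str, float]:
    ba = float((s["expansion"] * basal_area_m2(s["dbh_cm"])).sum())
    cc = float((s["expansion"] * crown_area(s)).sum())
    dn = float(s["expansion"].sum())
    abund = s.groupby("species")["expansion"].sum()
    h, d = _diversity(abund)
    return {"Dn": dn, "CC": cc, "BA": ba, "S": int(abund.size), "H": h, "D": d}


def mean_top_height(stems: pd.DataFrame) -> float:
    """Hgt: mean of 8 heights, each the tallest stem in a two-quadrat zone.

    The 16 quadrats pair into 8 zones of two adjacent quadrats
    (1-2, 3-4, ..., 15-16); zones with no sampled stem are skipped.
    """
    if stems["height_m"].isna().any():
        raise ValueError("missing heights: Hgt requires height_m for all stems")
    zones = (stems["quadrat"].astype(int) - 1) // 2
    return float(stems.groupby(zones)["height_m"].max().mean())


def compute_attributes(stems: pd.DataFrame, age: float | str) -> dict:
    """One attribute record (Table-2 schema) for a single plot's stems."""
    if len(stems) == 0:
        raise ValueError("empty stem table")
    s = scale_to_hectare(stems)
    total = _set_attributes(s)
    upper = _set_attributes(upper_set(s))
    rec = {"Age": age, "Hgt": mean_top_height(stems)}
    for key in ("S", "Dn", "BA", "CC", "H", "D"):
        rec[f"{key}_T"] = total[key]
        rec[f"{key}_U"] = upper[key]
    return {c: rec[c] for c in ATTRIBUTE_COLUMNS}


def attribute_table(stems: pd.DataFrame, plot_ages: dict[str, float]) -> pd.DataFrame:
    """Attribute records for every plot in a multi-plot stem table."""
    rows = []
    for plot, grp in stems.groupby("plot_id", sort=True):
        rec = compute_attributes(grp, plot_ages[plot])
        rec["plot_id"] = plot
        rows.append(rec)
    return pd.DataFrame(rows)[["plot_id", *ATTRIBUTE_COLUMNS]]


def validate_attribute_table(table: pd.DataFrame) -> list[str]:
    """Invariant check per row; returns human-readable violation messages."""
    problems = []
    for idx, r in table.iterrows():
        for a in ("BA", "CC", "S", "Dn"):
            if r[f"{a}_U"] > r[f"{a}_T"] + 1e-9:
                problems.append(f"row {idx}: {a}_U > {a}_T")
        for suff in ("T", "U"):
            if r[f"H_{suff}"] < -1e-12:
                problems.append(f"row {idx}: H_{suff} < 0")
            if not (0.0 < r[f"D_{suff}"] <= 1.0 + 1e-12):
                problems.append(f"row {idx}: D_{suff} outside (0, 1]")
            if r[f"S_{suff}"] == 1 and not (
                abs(r[f"H_{suff}"]) < 1e-9 and abs(r[f"D_{suff}"] - 1) < 1e-9
            ):
                problems.append(f"row {idx}: S_{suff}=1 but H,D not (0, 1)")
    return problems
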