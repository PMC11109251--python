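"""Conservation-priority scoring of 3D realms.

Combines the two realm-level indicators — protection coverage (%) and
fishing pressure (hours km⁻² yr⁻¹) — three ways:

* a log–log ordinary least squares regression of coverage on pressure
  (Pearson correlation), testing whether protection is sited away from
  fished areas ("residual conservation");
* a 4 × 4 grid of quartile fishing-pressure categories against fixed
  coverage bins tied to the 2030 area-based conservation targets (30%
  total coverage, 10% strict Ia/Ib coverage), scored 1–16;
* a 2 × 2 simplification into four priority profiles using the median
  pressure and the halfway point to the 2030 target (20% total coverage,
  or 5% for the strict assessment) as thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PROFILES",
    "RegressionResult",
    "loglog_regression",
    "fishing_categories",
    "coverage_categories",
    "grid_score",
    "priority_profile",
    "profile_shares",
    "build_summary",
    "prioritize",
]

PROFILES = (
    "highest_priority",
    "lowest_priority",
    "fills_conservation_gaps",
    "mitigates_fishing_pressure",
)

#: Coverage bin edges (right-inclusive) for the two assessments;
#: category 4 is the best-covered bin (past the 2030 target).
COVERAGE_BINS = {"all": (10.0, 20.0, 30.0), "strict": (2.5, 5.0, 10.0)}
#: Halfway progress from the 2020 to the 2030 coverage target.
HALFWAY_PCT = {"all": 20.0, "strict": 5.0}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p_value: float
    n_used: int
    n_dropped: int


def loglog_regression(
    summaries: pd.DataFrame,
    coverage_field: str = "coverage_all_pct",
    pressure_field: str = "pressure_hr_km2_yr",
    pseudo_offset: float | None = None,
) -> RegressionResult:
    """OLS of log10(coverage) on log10(pressure) with Pearson r and p.

    Realms with zero (or negative) coverage or pressure have no logarithm;
    by default they are dropped and counted in ``n_dropped``.  Passing a
    ``pseudo_offset`` adds it to both variables instead, keeping every
    realm.  Fewer than three usable realms is undefined and raises.
    """
    cov = summaries[coverage_field].to_numpy(dtype=float)
    prs = summaries[pressure_field].to_numpy(dtype=float)
    if pseudo_offset is not None:
        cov = cov + pseudo_offset
        prs = prs + pseudo_offset
    ok = np.isfinite(cov) & np.isfinite(prs) & (cov > 0) & (prs > 0)
    n_dropped = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError(
            f"regression undefined: only {int(ok.sum())} realms with positive "
            f"coverage and pressure ({n_dropped} dropped)"
        )
    res = stats.linregress(np.log10(prs[ok]), np.log10(cov[ok]))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n_used=int(ok.sum()),
        n_dropped=n_dropped,
    )


def fishing_categories(pressures) -> np.ndarray:
    """Quartile category 1–4 per realm (4 = highest pressure).

    Quartiles use inclusive linear interpolation over the realm-level
    pressures; a value equal to a quartile boundary falls in the lower
    category, so identical pressures are all category 1.
    """
    p = np.asarray(pressures, dtype=float)
    if p.size < 4:
        raise ValueError("need at least four realms to form quartiles")
    q25, q50, q75 = np.quantile(p, [0.25, 0.5, 0.75])
    return (1 + (p > q25).astype(int) + (p > q50) + (p > q75)).astype(int)


def coverage_categories(coverage_pct, assessment: str = "all") -> np.ndarray:
    """Fixed-bin coverage category 1–4 (4 = highest coverage).

    Bins are right-inclusive: for the ``all`` assessment 0–10 / 10–20 /
    20–30 / >30%, for ``strict`` 0–2.5 / 2.5–5 / 5–10 / >10%.
    """
    c = np.asarray(coverage_pct, dtype=float)
    if np.any((c < 0) | (c > 100)):
        raise ValueError("coverage must lie in [0, 100]")
    e1, e2, e3 = COVERAGE_BINS[assessment]
    out = (1 + (c > e1).astype(int) + (c > e2) + (c > e3)).astype(int)
    return out if out.ndim else int(out)


def grid_score(fishing_cat, coverage_cat):
    """Position 1–16 in the 4 × 4 pressure × coverage grid.

    ``score = (fishing_cat − 1) × 4 + (5 − coverage_cat)``: the score
    grows with fishing pressure and with the protection deficit, so 1 is
    the least-pressured, best-covered corner and 16 the most-pressured,
    least-covered one.  The mapping is a bijection onto 1..16.
    """
    f = np.asarray(fishing_cat, dtype=int)
    c = np.asarray(coverage_cat, dtype=int)
    if np.any((f < 1) | (f > 4)) or np.any((c < 1) | (c > 4)):
        raise ValueError("categories must lie in 1..4")
    out = (f - 1) * 4 + (5 - c)
    return out if out.ndim else int(out)


def priority_profile(
    pressure: float,
    coverage_pct: float,
    median_pressure: float,
    halfway_pct: float,
) -> str:
    """One of the four conservation-priority profiles.

    High fishing means pressure at or above the realm-level median; past
    halfway means coverage at or above half the 2030 target.  High fishing
    with coverage behind halfway is the highest priority; the reverse is
    the lowest; both behind fills conservation gaps; both at/above
    mitigates fishing pressure.
    """
    high_fishing = pressure >= median_pressure
    past_halfway = coverage_pct >= halfway_pct
    if high_fishing and not past_halfway:
        return "highest_priority"
    if not high_fishing and past_halfway:
        return "lowest_priority"
    if not high_fishing and not past_halfway:
        return "fills_conservation_gaps"
    return "mitigates_fishing_pressure"


def profile_shares(profiles, areas) -> pd.DataFrame:
    """Share of realms and of ocean area per profile (each sums to 1)."""
    df = pd.DataFrame({"profile": list(profiles), "area": np.asarray(areas, dtype=float)})
    if not len(df):
        return pd.DataFrame(columns=["profile", "realm_share", "area_share"])
    g = df.groupby("profile")
    out = pd.DataFrame(
        {
            "realm_share": g.size() / len(df),
            "area_share": g["area"].sum() / df["area"].sum(),
        }
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# assembly

def build_summary(
    coverage: pd.DataFrame,
    pressure: pd.DataFrame,
) -> pd.DataFrame:
    """Merge coverage and pressure tables into one row per 3D realm.

    ``pressure_hr_km2_yr`` is the yearly mean over the years present of
    summed pressure across gears (unspecified-depth rows excluded, since
    they carry no realm).  Realms with no recorded fishing get pressure 0.
    """
    key = ["ecoregion", "band", "domain"]
    cov_all = (
        coverage[coverage["group"] == "all"]
        .set_index(key)[["coverage_pct", "realm_area_km2"]]
        .rename(columns={"coverage_pct": "coverage_all_pct", "realm_area_km2": "area_km2"})
    )
    cov_strict = (
        coverage[coverage["group"] == "Ia_Ib"]
        .set_index(key)["coverage_pct"]
        .rename("coverage_strict_pct")
    )
    realm_pressure = pressure[pressure["domain"].isin(["benthic", "pelagic"])]
    if len(realm_pressure):
        yearly = realm_pressure.groupby(key + ["year"])["pressure_hr_per_km2"].sum()
        mean_pressure = yearly.groupby(key).mean().rename("pressure_hr_km2_yr")
    else:
        mean_pressure = pd.Series(name="pressure_hr_km2_yr", dtype=float)
    out = cov_all.join(cov_strict).join(mean_pressure)
    out["coverage_strict_pct"] = out["coverage_strict_pct"].fillna(0.0)
    out["pressure_hr_km2_yr"] = out["pressure_hr_km2_yr"].fillna(0.0)
    return out.reset_index()[
        ["ecoregion", "band", "domain", "area_km2",
         "coverage_all_pct", "coverage_strict_pct", "pressure_hr_km2_yr"]
    ]


def prioritize(
    summary: pd.DataFrame,
    assessment: str = "all",
    halfway_pct: float | None = None,
) -> pd.DataFrame:
    """Attach categories, 1–16 score, and priority profile to a summary.

    The median pressure and the pressure quartiles are computed over the
    realm-level pressure distribution, unweighted by area.
    """
    if assessment not in COVERAGE_BINS:
        raise ValueError("assessment must be 'all' or 'strict'")
    cov_field = "coverage_all_pct" if assessment == "all" else "coverage_strict_pct"
    halfway = HALFWAY_PCT[assessment] if halfway_pct is None else halfway_pct
    out = summary.copy()
    pressures = out["pressure_hr_km2_yr"].to_numpy(dtype=float)
    out["fishing_cat"] = fishing_categories(pressures)
    out["coverage_cat"] = coverage_categories(out[cov_field].to_numpy(), assessment)
    out["score"] = grid_score(out["fishing_cat"], out["coverage_cat"])
    median_pressure = float(np.median(pressures))
    out["profile"] = [
        priority_profile(p, c, median_pressure, halfway)
        for p, c in zip(pressures, out[cov_field])
    ]
    return out
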