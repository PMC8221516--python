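"""Per-chemical effects curves: application scenario -> (s_p, f_e).

For each number of applications (the label's seasonal maximum divided
evenly into 1-4 applications at the minimum interval) a moving window of
first-application dates is scanned weekly through the exposure and nest
models, producing a curve of season survival s_p and seasonal fecundity
f_e indexed by date of first application.  The population engine then
assigns each patch a random scenario (number of applications x first
date), interpolates the curve linearly, and mixes exposed and unexposed
vital rates by the patch's crop proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import PesticideEffect
from .exposure import (
    ApplicationSchedule,
    Chemical,
    ForagerProfile,
    Season,
    simulate_female_exposure,
)
from .nest import BreedingParams, PhaseNOAELs, enumerate_season_exact

__all__ = [
    "EffectsCurve",
    "build_application_scenarios",
    "build_effects_curve",
    "interpolate_effect",
    "realize_landscape_use",
    "curves_to_csv",
    "curves_from_csv",
]

#: Weekly scan grid of first-application dates (day-of-year, Jan 1 - Oct 1).
DEFAULT_SCAN_GRID = tuple(range(1, 275, 7))


@dataclass(frozen=True)
class EffectsCurve:
    """Grid of (s_p, f_e) against first-application day for one scenario family."""

    chemical: str
    n_apps: int
    first_dates: np.ndarray
    s_p: np.ndarray
    f_e: np.ndarray
    f_baseline: float

    def __post_init__(self) -> None:
        if len(self.first_dates) == 0:
            raise ValueError("empty effects curve")
        d = np.diff(self.first_dates)
        if len(d) and (np.any(d <= 0)):
            raise ValueError("first-application dates must be strictly increasing")


def build_application_scenarios(chem: Chemical, n_apps: int) -> ApplicationSchedule:
    """Template schedule: the seasonal maximum split evenly into n_apps doses.

    Applications are exactly the minimum interval apart, anchored at day
    0 (shift with :meth:`ApplicationSchedule.shifted` to place the first
    application).
    """
    if n_apps not in (1, 2, 3, 4):
        raise ValueError("n_apps must be 1, 2, 3 or 4")
    sched = ApplicationSchedule(
        dates=tuple(i * chem.min_interval for i in range(n_apps)),
        rate_per_app=chem.max_seasonal_rate / n_apps,
    )
    sched.validate_against(chem)
    return sched


def build_effects_curve(
    chem: Chemical,
    n_apps: int,
    breeding: BreedingParams,
    profile: ForagerProfile | None = None,
    scan_grid: tuple[int, ...] = DEFAULT_SCAN_GRID,
    residue_sigma_log10: float = 0.23,
    season: Season | None = None,
) -> EffectsCurve:
    """Scan the moving window of first-application dates through the models.

    For each weekly first-application date the exposure model supplies
    the female's median dose series and acute season survival s_p, and
    the nest model's exact enumeration (with the lognormal residue noise
    integrated analytically) supplies the expected seasonal fecundity
    f_e.  Deterministic: no Monte Carlo is involved, so curves are
    exactly reproducible.
    """
    profile = profile if profile is not None else ForagerProfile()
    template = build_application_scenarios(chem, n_apps)
    span = template.dates[-1] - template.dates[0]
    if season is None:
        season = Season(start=1, end=max(breeding.horizon(), max(scan_grid) + span) + 1)
    noaels = PhaseNOAELs.uniform(chem.noael_diet)
    n_doy = season.end + 2

    zero_dose = np.zeros(n_doy)
    f_baseline = enumerate_season_exact(breeding, zero_dose, noaels).fecundity

    s_p = np.empty(len(scan_grid))
    f_e = np.empty(len(scan_grid))
    for i, d0 in enumerate(scan_grid):
        sched = template.shifted(d0)
        series, sp = simulate_female_exposure(profile, sched, chem, season)
        s_p[i] = sp
        conc = series.concentration_by_doy(n_doy)
        f_e[i] = enumerate_season_exact(
            breeding, conc, noaels, residue_sigma_log10=residue_sigma_log10
        ).fecundity
    return EffectsCurve(
        chemical=chem.name,
        n_apps=n_apps,
        first_dates=np.asarray(scan_grid, dtype=float),
        s_p=s_p,
        f_e=f_e,
        f_baseline=f_baseline,
    )


def interpolate_effect(curve: EffectsCurve, date: float) -> PesticideEffect:
    """Linear interpolation of (s_p, f_e) at an arbitrary first-application date.

    Exact at grid nodes; dates outside the grid clamp to the end values.
    """
    sp = float(np.interp(date, curve.first_dates, curve.s_p))
    fe = float(np.interp(date, curve.first_dates, curve.f_e))
    return PesticideEffect(s_p=min(max(sp, 0.0), 1.0), f_e=max(fe, 0.0))


def realize_landscape_use(
    crop_proportion: np.ndarray,
    curves: dict[int, EffectsCurve],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One year's random assignment of application scenarios to patches.

    Every patch with crop proportion p > 0 independently draws a number
    of applications (uniform over the supplied curves) and a first
    application date (uniform over that curve's scan grid); patches with
    p = 0 stay unexposed (s_p = 1, f_e = baseline).  Returns per-patch
    arrays ``(s_p, f_e)`` of exposed-population vital rates; the caller
    mixes them with unexposed rates by p.
    """
    if not curves:
        raise ValueError("need at least one effects curve")
    crop_proportion = np.asarray(crop_proportion, dtype=float)
    n = len(crop_proportion)
    any_curve = next(iter(curves.values()))
    s_p = np.ones(n)
    f_e = np.full(n, any_curve.f_baseline)
    exposed = np.flatnonzero(crop_proportion > 0.0)
    if len(exposed) == 0:
        return s_p, f_e
    n_apps_options = sorted(curves)
    napp_draw = rng.choice(n_apps_options, size=len(exposed))
    for k, patch_indices in [
        (k, exposed[napp_draw == k]) for k in n_apps_options
    ]:
        if len(patch_indices) == 0:
            continue
        curve = curves[k]
        date_idx = rng.integers(0, len(curve.first_dates), size=len(patch_indices))
        s_p[patch_indices] = curve.s_p[date_idx]
        f_e[patch_indices] = curve.f_e[date_idx]
    return s_p, f_e


def curves_to_csv(curves: dict[int, EffectsCurve], path) -> None:
    """Write effects curves as tidy CSV (chemical, n_apps, first_app_doy, s_p, f_e, f_baseline)."""
    frames = []
    for k in sorted(curves):
        c = curves[k]
        frames.append(
            pd.DataFrame(
                {
                    "chemical": c.chemical,
                    "n_apps": c.n_apps,
                    "first_app_doy": c.first_dates,
                    "s_p": c.s_p,
                    "f_e": c.f_e,
                    "f_baseline": c.f_baseline,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def curves_from_csv(path) -> dict[int, EffectsCurve]:
    """Read curves written by :func:`curves_to_csv`; lossless round trip."""
    df = pd.read_csv(path)
    out: dict[int, EffectsCurve] = {}
    for (chem_name, k), grp in df.groupby(["chemical", "n_apps"], sort=True):
        grp = grp.sort_values("first_app_doy")
        out[int(k)] = EffectsCurve(
            chemical=str(chem_name),
            n_apps=int(k),
            first_dates=grp["first_app_doy"].to_numpy(dtype=float),
            s_p=grp["s_p"].to_numpy(dtype=float),
            f_e=grp["f_e"].to_numpy(dtype=float),
            f_baseline=float(grp["f_baseline"].iloc[0]),
        )
    return out
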