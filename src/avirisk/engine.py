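"""Multi-year scenario engine.

Yearly cycle per patch: draw an environmental multiplier (uniform on
[1-v, 1+v], applied identically to s_a, s_j and f), assemble effective
vital rates (habitat-quality coefficients, crop-proportion mixing of
exposed and unexposed rates, pesticide season survival s_p), advance
the 2x2 projection matrix, then integerize juveniles and run
density-dependent dispersal with culling, and finally record the
census.  Scenarios follow the realization/trial/replicate design: a
pool of random pesticide-use maps is generated once, each trial fixes a
year-indexed resample of that pool, and replicate population
trajectories are run against the fixed sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import HabitatCoefficients, VitalRates, mix_vital
from .dispersal import DispersalParams, disperse
from .effects import EffectsCurve, realize_landscape_use
from .landscape import PatchSet

__all__ = [
    "ScenarioConfig",
    "draw_environmental_multiplier",
    "initialize_population",
    "run_year",
    "run_trial",
    "run_scenario",
    "summarize",
    "equilibration_year",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Run design and stochasticity controls for one scenario."""

    years: int = 50
    n_realization_maps: int = 100
    n_trials: int = 10
    n_replicates: int = 10
    env_variability: float = 0.10
    seed: int = 0
    chemical: str = "control"
    initial_fraction_of_k: float = 0.5
    global_env_draw: bool = False
    dispersal_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("years", "n_realization_maps", "n_trials", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.env_variability < 0:
            raise ValueError("env_variability must be non-negative")


def draw_environmental_multiplier(
    config: ScenarioConfig, rng: np.random.Generator, n_patches: int
) -> np.ndarray:
    """Per-patch yearly vital-rate multipliers, uniform on [1-v, 1+v].

    The same multiplier scales s_a, s_j and f within a patch (perfectly
    correlated environmental stochasticity); with ``global_env_draw``
    one draw is shared by all patches.
    """
    v = config.env_variability
    if v == 0.0:
        return np.ones(n_patches)
    if config.global_env_draw:
        return np.full(n_patches, rng.uniform(1.0 - v, 1.0 + v))
    return rng.uniform(1.0 - v, 1.0 + v, size=n_patches)


def initialize_population(patches: PatchSet, fraction_of_k: float = 0.5) -> None:
    """Seed adults at a fraction of carrying capacity; no juveniles."""
    patches.n_a = fraction_of_k * patches.K.copy()
    patches.n_j = np.zeros(patches.n_patches)


def run_year(
    patches: PatchSet,
    vitals: VitalRates,
    coeffs: HabitatCoefficients,
    effects: tuple[np.ndarray, np.ndarray] | None,
    config: ScenarioConfig,
    rng: np.random.Generator,
    dispersal_params: DispersalParams | None = None,
) -> dict[str, float]:
    """Advance the whole landscape one year in place; returns the census.

    ``effects`` is the year's realization map as per-patch arrays
    (s_p, f_e) of exposed-population rates, or None for the control
    scenario.  Exposed and unexposed rates are mixed by each patch's
    crop proportion before the habitat and environmental scalings.
    """
    m = draw_environmental_multiplier(config, rng, patches.n_patches)
    c_f = coeffs.c_f(patches.q)
    c_s = coeffs.c_s(patches.q)
    if effects is None:
        f_mix = np.full(patches.n_patches, vitals.f)
        sp_mix = np.ones(patches.n_patches)
    else:
        s_p_exposed, f_e_exposed = effects
        f_mix = mix_vital(patches.p, f_e_exposed, vitals.f)
        sp_mix = mix_vital(patches.p, s_p_exposed, 1.0)
    s_j_eff = np.clip(vitals.s_j * m, 0.0, 1.0) * c_s
    s_a_eff = np.clip(vitals.s_a * m, 0.0, 1.0) * c_s
    fec = f_mix * m * c_f
    n_j, n_a = patches.n_j, patches.n_a
    patches.n_j = sp_mix * fec * (s_j_eff * n_j + s_a_eff * n_a)
    patches.n_a = sp_mix * (s_j_eff * n_j + s_a_eff * n_a)
    if config.dispersal_enabled:
        disperse(patches, dispersal_params or DispersalParams(), rng)
    adults = float(patches.n_a.sum())
    return {
        "n_j": float(patches.n_j.sum()),
        "n_a": adults,
        "pairs": float(np.floor(adults / 2.0)),
    }


def _copy_patches(patches: PatchSet) -> PatchSet:
    out = PatchSet(
        grid=patches.grid,
        q=patches.q,
        p=patches.p,
        K=patches.K,
        n_hex=patches.n_hex,
        centroid_x=patches.centroid_x,
        centroid_y=patches.centroid_y,
        hex_patch=patches.hex_patch,
        n_j=patches.n_j.copy(),
        n_a=patches.n_a.copy(),
    )
    return out


def run_trial(
    patches: PatchSet,
    vitals: VitalRates,
    coeffs: HabitatCoefficients,
    maps: list[tuple[np.ndarray, np.ndarray]] | None,
    config: ScenarioConfig,
    trial: int,
    seed_seq: np.random.SeedSequence,
    dispersal_params: DispersalParams | None = None,
) -> list[dict]:
    """One trial: a fixed year-indexed resample of the realization-map pool,
    run by ``n_replicates`` independent population trajectories."""
    trial_rng = np.random.default_rng(seed_seq)
    if maps is not None:
        year_seq = trial_rng.integers(0, len(maps), size=config.years)
    else:
        year_seq = None
    rows = []
    for rep, rep_ss in enumerate(seed_seq.spawn(config.n_replicates)):
        rng = np.random.default_rng(rep_ss)
        state = _copy_patches(patches)
        initialize_population(state, config.initial_fraction_of_k)
        for year in range(1, config.years + 1):
            effects = maps[year_seq[year - 1]] if maps is not None else None
            census = run_year(
                state, vitals, coeffs, effects, config, rng, dispersal_params
            )
            rows.append({"trial": trial, "replicate": rep, "year": year, **census})
    return rows


def run_scenario(
    patches: PatchSet,
    vitals: VitalRates,
    coeffs: HabitatCoefficients,
    config: ScenarioConfig,
    curves: dict[int, EffectsCurve] | None = None,
    dispersal_params: DispersalParams | None = None,
) -> pd.DataFrame:
    """Full scenario: realization maps -> trials -> replicate trajectories.

    Deterministic for a fixed ``config.seed``: the master seed spawns
    independent streams for map generation and for every trial and
    replicate.  Returns a tidy trajectory table
    (trial, replicate, year, n_j, n_a, pairs).
    """
    master = np.random.SeedSequence(config.seed)
    maps_ss, trials_root = master.spawn(2)
    if curves:
        maps_rng = np.random.default_rng(maps_ss)
        maps = [
            realize_landscape_use(patches.p, curves, maps_rng)
            for _ in range(config.n_realization_maps)
        ]
    else:
        maps = None
    rows: list[dict] = []
    for trial, trial_ss in enumerate(trials_root.spawn(config.n_trials)):
        rows.extend(
            run_trial(
                patches, vitals, coeffs, maps, config, trial, trial_ss, dispersal_params
            )
        )
    return pd.DataFrame(rows)


def summarize(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-year abundance summaries across all trials and replicates.

    Returns mean, 5% and 95% quantiles of total abundance (n_j + n_a)
    plus mean pairs, indexed by year.
    """
    if len(trajectories) == 0:
        raise ValueError("no trajectories to summarize")
    df = trajectories.copy()
    df["total"] = df["n_j"] + df["n_a"]
    g = df.groupby("year")["total"]
    out = pd.DataFrame(
        {
            "mean": g.mean(),
            "q05": g.quantile(0.05),
            "q95": g.quantile(0.95),
            "mean_pairs": df.groupby("year")["pairs"].mean(),
        }
    )
    return out


def equilibration_year(series: np.ndarray, window: int = 5, tol: float = 0.01) -> int:
    """First year after which the rolling mean stops changing by >= tol.

    The series is indexed from year 1; the rolling mean uses the given
    window (shorter at the start).  Returns the earliest year such that
    every subsequent year-over-year relative change of the rolling mean
    is below ``tol``; a perfectly flat series equilibrates at year 1.
    """
    s = pd.Series(np.asarray(series, dtype=float))
    r = s.rolling(window, min_periods=1, center=True).mean().to_numpy()
    denom = np.maximum(np.abs(r[:-1]), 1e-12)
    change = np.abs(np.diff(r)) / denom
    ok = change < tol
    # last index where the change still exceeded tol
    bad = np.flatnonzero(~ok)
    if len(bad) == 0:
        return 1
    return int(bad[-1] + 2)  # year indexing from 1, change[i] is year i+1 -> i+2


def plot_trajectories(summary: pd.DataFrame, ax=None, label: str | None = None):
    """Plot the mean total-abundance trajectory with its 5-95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(summary.index, summary["mean"], label=label)
    ax.fill_between(summary.index, summary["q05"], summary["q95"], alpha=0.25)
    ax.set_xlabel("year")
    ax.set_ylabel("total abundance")
    if label:
        ax.legend()
    return ax
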