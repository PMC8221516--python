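"""Individual-based juvenile dispersal between habitat patches.

Patches over carrying capacity shed their excess juveniles, which walk a
highly autocorrelated random path over the hexagon lattice.  Each
disperser draws a maximum dispersal distance uniformly between 0.5 and
10 km and settles in the first patch encountered with headroom (N < K);
a walker that exhausts its distance budget stops where it is, and any
resulting overflow is culled back to N = K.  Adults never disperse and,
by construction of the annual cycle, never exceed K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import PatchSet

__all__ = [
    "DispersalParams",
    "integerize_juveniles",
    "identify_dispersers",
    "walk_disperser",
    "disperse",
    "cull_overflow",
]

# headings: N, NE, SE, S, SW, NW; (dcol, drow) depends on column parity
_DIRS_EVEN = ((0, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0))
_DIRS_ODD = ((0, 1), (1, 1), (1, 0), (0, -1), (-1, 0), (-1, 1))


@dataclass(frozen=True)
class DispersalParams:
    """Juvenile dispersal rules.

    The per-disperser maximum path length is uniform between
    ``min_max_distance_km`` and ``max_max_distance_km``; the walk keeps
    its previous heading with probability ``autocorrelation`` and
    otherwise turns to a uniformly random one of the six hexagon
    directions.  Step length is the lattice pitch.
    """

    min_max_distance_km: float = 0.5
    max_max_distance_km: float = 10.0
    autocorrelation: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.min_max_distance_km < self.max_max_distance_km):
            raise ValueError("need 0 < min_max_distance < max_max_distance")
        if not (0.0 <= self.autocorrelation < 1.0):
            raise ValueError("autocorrelation must be in [0, 1)")


def integerize_juveniles(n_j: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Probabilistic rounding: floor plus a Bernoulli draw on the fraction."""
    n_j = np.asarray(n_j, dtype=float)
    base = np.floor(n_j)
    frac = n_j - base
    return (base + (rng.random(len(n_j)) < frac)).astype(int)


def identify_dispersers(n_j_int: np.ndarray, n_a: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Number of juveniles that must leave each patch.

    A patch over carrying capacity (N > K) sheds N - K juveniles
    (rounded against floor(K)); never more juveniles than it holds, and
    adults never disperse.
    """
    n = np.rint(np.asarray(n_j_int) + np.asarray(n_a)).astype(int)
    excess = np.maximum(0, n - np.floor(K).astype(int))
    return np.minimum(excess, np.asarray(n_j_int, dtype=int))


def walk_disperser(
    start_hex: int,
    natal_patch: int,
    params: DispersalParams,
    patches: PatchSet,
    occupancy: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Walk one juvenile; returns (settlement patch index or -1, path length m).

    The walker settles in the first patch along its path with
    occupancy < K (strict); on exceeding its drawn maximum distance it
    settles wherever it stands — or is lost (-1) if standing on missing
    habitat outside any patch.
    """
    grid = patches.grid
    pitch = grid.pitch
    d_max = rng.uniform(params.min_max_distance_km, params.max_max_distance_km) * 1000.0
    col = start_hex % grid.ncols
    row = start_hex // grid.ncols
    heading = int(rng.integers(6))
    dist = 0.0
    guard = int(10 * d_max / pitch) + 100
    for _ in range(guard):
        if rng.random() >= params.autocorrelation:
            heading = int(rng.integers(6))
        dirs = _DIRS_ODD if col % 2 else _DIRS_EVEN
        dc, dr = dirs[heading]
        nc, nr = col + dc, row + dr
        if not (0 <= nc < grid.ncols and 0 <= nr < grid.nrows):
            heading = int(rng.integers(6))  # bounced off the study-extent edge
            continue
        col, row = nc, nr
        dist += pitch
        pid = int(patches.hex_patch[row * grid.ncols + col])
        if pid >= 0 and pid != natal_patch and occupancy[pid] < patches.K[pid]:
            return pid, dist
        if dist >= d_max:
            return (pid if pid >= 0 else -1), dist
    pid = int(patches.hex_patch[row * grid.ncols + col])
    return (pid if pid >= 0 else -1), dist


def disperse(
    patches: PatchSet,
    params: DispersalParams,
    rng: np.random.Generator,
    log: bool = False,
) -> pd.DataFrame | None:
    """Integerize juveniles, move the over-capacity excess, cull overflow.

    Mutates ``patches.n_j`` in place: juveniles become integer counts,
    dispersers leave their natal patch in randomized order (occupancy is
    updated online as settlers arrive), and any post-dispersal overflow
    is culled back to N = K.  Returns the event log as a DataFrame when
    ``log`` is requested.
    """
    n_j_int = integerize_juveniles(patches.n_j, rng)
    counts = identify_dispersers(n_j_int, patches.n_a, patches.K)
    patches.n_j = (n_j_int - counts).astype(float)
    occupancy = patches.n_j + patches.n_a

    natal = np.repeat(np.arange(patches.n_patches), counts)
    rng.shuffle(natal)
    members: dict[int, np.ndarray] = {}
    records = []
    for pid in natal:
        pid = int(pid)
        if pid not in members:
            members[pid] = np.flatnonzero(patches.hex_patch == pid)
        start_hex = int(rng.choice(members[pid]))
        dest, path_len = walk_disperser(start_hex, pid, params, patches, occupancy, rng)
        if dest >= 0:
            patches.n_j[dest] += 1
            occupancy[dest] += 1
        if log:
            records.append(
                {
                    "natal_patch": pid,
                    "settlement_patch": dest,
                    "path_length_m": path_len,
                    "fate": "settled" if dest >= 0 else "lost",
                }
            )
    culled = cull_overflow(patches, rng)
    if log:
        df = pd.DataFrame(
            records,
            columns=["natal_patch", "settlement_patch", "path_length_m", "fate"],
        )
        df.attrs["n_culled"] = culled
        return df
    return None


def cull_overflow(patches: PatchSet, rng: np.random.Generator) -> int:
    """Remove juveniles from any patch with N > K until N <= K; returns total culled.

    Adults are never culled; the removal count per patch is the smallest
    integer bringing N back to (at most) K, limited by the juveniles
    present.
    """
    n = patches.n_j + patches.n_a
    over = np.flatnonzero(n > patches.K)
    total = 0
    for pid in over:
        excess = int(np.ceil(n[pid] - patches.K[pid]))
        take = min(excess, int(patches.n_j[pid]))
        patches.n_j[pid] -= take
        total += take
    return total
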