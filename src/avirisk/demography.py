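"""Two-stage matrix demography for a territorial songbird.

The within-patch model is a post-breeding-census 2x2 projection matrix

    N(t+1) = [[s_j f, s_a f],
              [s_j,   s_a  ]] N(t),      N = (n_j, n_a)

where ``s_j``/``s_a`` are annual juvenile/adult survival and ``f`` is
annual fecundity (female offspring per female), all expressed for ideal
habitat (q = 1).  Sub-optimal habitat quality q degrades each maximal
vital rate through a saturating coefficient ``c = 1 - (1 - q)**alpha``
with separate exponents for fecundity and survival.  Pesticide exposure
enters as an extra season-survival factor ``s_p`` multiplying the whole
matrix and a replacement seasonal fecundity ``f_e``.

Because the matrix rows are proportional (both stages reproduce at the
same rate f), its determinant is zero and the dominant eigenvalue has
the closed form ``lambda = s_a + s_j * f``, which the analytic toolkit
(sensitivities, elasticities, source-sink threshold) exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VitalRates",
    "HabitatCoefficients",
    "PesticideEffect",
    "PatchState",
    "habitat_coefficient",
    "build_projection_matrix",
    "finite_rate",
    "sensitivities",
    "elasticities",
    "source_sink_threshold",
    "mix_vital",
    "patch_step",
]


@dataclass(frozen=True)
class VitalRates:
    """Maximal demographic rates in ideal habitat (q = 1).

    s_j, s_a are annual survival probabilities; f is annual fecundity in
    female offspring per female.
    """

    s_j: float
    s_a: float
    f: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_j <= 1.0):
            raise ValueError(f"s_j must be in [0, 1], got {self.s_j}")
        if not (0.0 <= self.s_a <= 1.0):
            raise ValueError(f"s_a must be in [0, 1], got {self.s_a}")
        if self.f < 0.0:
            raise ValueError(f"f must be non-negative, got {self.f}")


@dataclass(frozen=True)
class HabitatCoefficients:
    """Exponents of the habitat-quality coefficient c = 1-(1-q)**alpha.

    Larger alpha makes vital rates saturate faster with quality; alpha=1
    is the linear limit c = q.
    """

    alpha_f: float = 3.0
    alpha_s: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha_f < 1.0 or self.alpha_s < 1.0:
            raise ValueError("habitat exponents must be >= 1")

    def c_f(self, q):
        return habitat_coefficient(q, self.alpha_f)

    def c_s(self, q):
        return habitat_coefficient(q, self.alpha_s)


@dataclass(frozen=True)
class PesticideEffect:
    """Seasonal pesticide outcome: survival probability s_p and fecundity f_e."""

    s_p: float
    f_e: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_p <= 1.0):
            raise ValueError(f"s_p must be in [0, 1], got {self.s_p}")
        if self.f_e < 0.0:
            raise ValueError(f"f_e must be non-negative, got {self.f_e}")


@dataclass
class PatchState:
    """Stage abundances (juveniles, adults) within one patch."""

    n_j: float
    n_a: float

    def __post_init__(self) -> None:
        if self.n_j < 0 or self.n_a < 0:
            raise ValueError("abundances must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.n_j, self.n_a], dtype=float)


def habitat_coefficient(q, alpha):
    """Vital-rate coefficient c = 1 - (1 - q)**alpha for habitat quality q.

    Strictly increasing in q on [0, 1]; c(0) = 0, c(1) = 1.  Accepts
    scalars or arrays in q.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0.0) or np.any(q > 1.0):
        raise ValueError("habitat quality q must be in [0, 1]")
    if alpha < 1.0:
        raise ValueError("alpha must be >= 1")
    c = 1.0 - (1.0 - q) ** alpha
    return float(c) if c.ndim == 0 else c


def build_projection_matrix(
    vitals: VitalRates,
    q: float = 1.0,
    coeffs: HabitatCoefficients | None = None,
    effect: PesticideEffect | None = None,
) -> np.ndarray:
    """Assemble the 2x2 post-breeding projection matrix for one patch.

    Habitat quality scales survival by c_s(q) and fecundity by c_f(q).
    A pesticide effect replaces the maximal fecundity f by the exposed
    seasonal fecundity f_e (then habitat-scaled the same way) and
    multiplies the whole matrix by the season survival s_p.  With
    ``effect=None`` or ``s_p=1, f_e=f`` the matrix reduces to the
    unexposed form.
    """
    coeffs = coeffs if coeffs is not None else HabitatCoefficients()
    c_f = coeffs.c_f(q)
    c_s = coeffs.c_s(q)
    f = vitals.f if effect is None else effect.f_e
    s_p = 1.0 if effect is None else effect.s_p
    sj = vitals.s_j * c_s
    sa = vitals.s_a * c_s
    fe = f * c_f
    return s_p * np.array([[sj * fe, sa * fe], [sj, sa]])


def finite_rate(matrix: np.ndarray) -> float:
    """Dominant eigenvalue (finite rate of increase, lambda) of a projection matrix.

    For any non-negative matrix the dominant eigenvalue is real
    (Perron-Frobenius); for the rank-1-fecundity structure used here it
    equals ``c_s * (s_a + s_j * f * c_f)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.any(matrix < 0):
        raise ValueError("projection matrix must be non-negative")
    eigvals = np.linalg.eigvals(matrix)
    return float(np.max(eigvals.real))


def sensitivities(vitals: VitalRates) -> tuple[float, float, float]:
    """Analytic sensitivities of lambda = s_a + s_j f.

    Returns ``(d lambda/d s_a, d lambda/d f, d lambda/d s_j)`` =
    ``(1, s_j, f)``.
    """
    return (1.0, vitals.s_j, vitals.f)


def elasticities(vitals: VitalRates) -> tuple[float, float]:
    """Proportional sensitivities (e_sa, e_f) of lambda to s_a and f.

    e_sa = s_a / lambda and e_f = s_j f / lambda; they sum to one for
    this matrix structure.  Raises if lambda = 0.
    """
    lam = vitals.s_a + vitals.s_j * vitals.f
    if lam <= 0.0:
        raise ValueError("elasticities undefined: lambda = 0")
    return (vitals.s_a / lam, vitals.s_j * vitals.f / lam)


def source_sink_threshold(
    vitals: VitalRates,
    coeffs: HabitatCoefficients | None = None,
    tol: float = 1e-6,
) -> float:
    """Habitat quality q* at which a patch switches between source and sink.

    Solves ``c_s(q) * (s_a + s_j f c_f(q)) = 1`` by bisection on
    q in [0, 1] to |dq| < tol.  Requires lambda(0) < 1 < lambda(1);
    otherwise no threshold exists and a ValueError is raised.
    """
    coeffs = coeffs if coeffs is not None else HabitatCoefficients()

    def g(q: float) -> float:
        return coeffs.c_s(q) * (vitals.s_a + vitals.s_j * vitals.f * coeffs.c_f(q)) - 1.0

    lo, hi = 0.0, 1.0
    if g(lo) >= 0.0 or g(hi) <= 0.0:
        raise ValueError("no source-sink threshold: lambda(q) does not cross 1 on [0, 1]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mix_vital(p, v_e, v_u):
    """Binomial mixing of exposed and unexposed vital rates.

    E(v) = p * v_e + (1 - p) * v_u, with p the proportion of the patch
    under the treated crop.  Accepts scalars or arrays.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("crop proportion p must be in [0, 1]")
    out = p * np.asarray(v_e, dtype=float) + (1.0 - p) * np.asarray(v_u, dtype=float)
    return float(out) if out.ndim == 0 else out


def patch_step(
    state: PatchState, matrix: np.ndarray, env_multiplier: float = 1.0
) -> PatchState:
    """Advance one patch one year: new state = (env_multiplier * matrix) @ state.

    The step is deterministic (expectation dynamics) and linear in both
    the state and the multiplier; demographic integerization happens
    only at the dispersal stage.
    """
    if state.n_j < 0 or state.n_a < 0:
        raise ValueError("abundances must be non-negative")
    if env_multiplier < 0:
        raise ValueError("environmental multiplier must be non-negative")
    new = env_multiplier * (np.asarray(matrix, dtype=float) @ state.as_vector())
    return PatchState(n_j=float(new[0]), n_a=float(new[1]))
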