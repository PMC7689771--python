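"""Equivalent current dipole modeling in a three-shell spherical head.

The scalp potential of a current dipole inside a set of concentric
conducting shells (brain, skull, scalp) has a closed-form Legendre series.
With the dipole at radius ``b`` on the local z-axis, radial moment ``m_r``
and tangential moment ``m_t`` (along the local x-axis), the potential at a
scalp electrode with polar angle ``theta`` and azimuth ``phi`` in that
frame is

    V = 1/(4*pi*sigma_1) * sum_n b**(n-1) * g_n *
        [ n*m_r*P_n(cos theta) + m_t*P_n^1(cos theta)*cos(phi) ]

where ``g_n`` collects the boundary conditions of the shells (for a single
homogeneous sphere of radius R, ``g_n = (2n+1)/n * R**-(n+1)``, the classic
single-sphere series).  ``P_n^1`` is the associated Legendre function
*without* the Condon-Shortley phase.

Inverse fits minimize residual variance, the fraction of topography
variance the model leaves unexplained: the dipole position is found by a
coarse grid search followed by Nelder-Mead refinement, with the moment
solved linearly at every candidate position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize

__all__ = [
    "HeadModel",
    "DipoleFit",
    "potential_at_electrodes",
    "leadfield",
    "fit_single_dipole",
    "fit_symmetric_pair",
    "residual_variance",
]


@dataclass(frozen=True)
class HeadModel:
    """Concentric three-shell spherical volume conductor.

    Radii in meters (brain, skull, scalp), conductivities in S/m.  The
    defaults are the textbook 0.33 / 0.0042 / 0.33 S/m shells with an
    8.0 / 8.5 / 9.2 cm geometry.
    """

    radii: tuple[float, float, float] = (0.080, 0.085, 0.092)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    n_terms: int = 60

    def __post_init__(self) -> None:
        if not all(r2 > r1 for r1, r2 in zip(self.radii, self.radii[1:])):
            raise ValueError("shell radii must be strictly increasing")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.n_terms < 20:
            raise ValueError("series truncation must keep at least 20 terms")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]


@dataclass
class DipoleFit:
    """Result of an equivalent-dipole fit.

    Head frame: +x right, +y anterior, +z superior, origin at the sphere
    center.  ``rv`` is ``||observed - modeled||^2 / ||observed||^2``.
    """

    position: np.ndarray
    moment: np.ndarray
    rv: float
    modeled: np.ndarray
    observed: np.ndarray
    pair: bool = False
    twin: "DipoleFit | None" = field(default=None, repr=False)

    def summary(self) -> str:
        x, y, z = 1e3 * self.position
        lines = [
            "Equivalent current dipole fit"
            + (" (symmetric pair member)" if self.pair else ""),
            f"  position [mm]   x={x:7.1f}  y={y:7.1f}  z={z:7.1f}",
            f"  moment (a.u.)   {np.array2string(self.moment, precision=3)}",
            f"  residual variance {100 * self.rv:.2f}%",
        ]
        return "\n".join(lines)


@lru_cache(maxsize=32)
def _shell_gains(model: HeadModel) -> np.ndarray:
    """Series coefficients g_n for the outer-surface potential.

    For each harmonic order n, solve the boundary-value problem for the
    radial factors A_j r^n + B_j r^-(n+1) in the three shells, with the
    source term normalized to 1 (the caller scales by b**(n-1) and the
    moment).  Returns g_n = R_3(scalp radius) for n = 1..n_terms.
    """
    r1, r2, r3 = model.radii
    s1, s2, s3 = model.conductivities
    gains = np.empty(model.n_terms)
    for i, n in enumerate(range(1, model.n_terms + 1)):
        m = n + 1
        # unknowns: A1, A2, B2, A3, B3 ; source B1 = 1
        A = np.array(
            [
                # potential continuity at r1
                [r1**n, -(r1**n), -(r1**-m), 0.0, 0.0],
                # current continuity at r1
                [s1 * n * r1 ** (n - 1), -s2 * n * r1 ** (n - 1),
                 s2 * m * r1 ** (-n - 2), 0.0, 0.0],
                # potential continuity at r2
                [0.0, r2**n, r2**-m, -(r2**n), -(r2**-m)],
                # current continuity at r2
                [0.0, s2 * n * r2 ** (n - 1), -s2 * m * r2 ** (-n - 2),
                 -s3 * n * r2 ** (n - 1), s3 * m * r2 ** (-n - 2)],
                # no current through the scalp surface
                [0.0, 0.0, 0.0, n * r3 ** (n - 1), -m * r3 ** (-n - 2)],
            ]
        )
        rhs = np.array(
            [
                -(r1**-m),
                s1 * m * r1 ** (-n - 2),
                0.0,
                0.0,
                0.0,
            ]
        )
        a1, a2, b2, a3, b3 = np.linalg.solve(A, rhs)
        gains[i] = a3 * r3**n + b3 * r3**-m
    return gains


def _legendre_pair(n_max: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and P_n^1(x) (no Condon-Shortley phase) for n = 1..n_max.

    Returns arrays of shape (n_max, len(x)) via the standard three-term
    recurrences.
    """
    x = np.asarray(x, dtype=float)
    p = np.empty((n_max + 1, x.size))
    p[0] = 1.0
    p[1] = x
    for n in range(1, n_max):
        p[n + 1] = ((2 * n + 1) * x * p[n] - n * p[n - 1]) / (n + 1)
    s = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    q = np.zeros((n_max + 1, x.size))
    q[1] = s  # P_1^1 without CS phase
    if n_max >= 2:
        q[2] = 3.0 * x * s
    for n in range(2, n_max):
        q[n + 1] = ((2 * n + 1) * x * q[n] - (n + 1) * q[n - 1]) / n
    return p[1:], q[1:]


def potential_at_electrodes(
    position: np.ndarray,
    moment: np.ndarray,
    model: HeadModel,
    electrodes: np.ndarray,
) -> np.ndarray:
    """Scalp potential of one dipole at each electrode position.

    ``electrodes`` is (n, 3) in meters; positions are projected radially to
    the scalp shell so that montage and model share a geometry.  Output is
    linear in ``moment`` and carries no reference (subtract whatever
    reference the analysis chain uses).
    """
    position = np.asarray(position, dtype=float)
    moment = np.asarray(moment, dtype=float)
    electrodes = np.atleast_2d(np.asarray(electrodes, dtype=float))
    b = float(np.linalg.norm(position))
    if b >= model.brain_radius:
        raise ValueError(
            f"dipole at radius {b:.4f} m lies outside the brain shell "
            f"({model.brain_radius:.4f} m)"
        )
    r3 = model.scalp_radius
    elec = electrodes / np.linalg.norm(electrodes, axis=1, keepdims=True) * r3

    # local frame: z' along the dipole position, x' along the tangential moment
    if b > 1e-12:
        ez = position / b
    else:
        nm = np.linalg.norm(moment)
        ez = moment / nm if nm > 0 else np.array([0.0, 0.0, 1.0])
    m_r = float(moment @ ez)
    m_tvec = moment - m_r * ez
    m_t = float(np.linalg.norm(m_tvec))
    ex = m_tvec / m_t if m_t > 1e-15 * max(1.0, np.linalg.norm(moment)) else None

    cos_th = np.clip(elec @ ez / r3, -1.0, 1.0)
    if ex is not None:
        u = elec - np.outer(elec @ ez, ez)
        un = np.linalg.norm(u, axis=1)
        cos_phi = np.where(un > 1e-12, (u @ ex) / np.where(un > 0, un, 1.0), 0.0)
    else:
        cos_phi = np.zeros(elec.shape[0])
        m_t = 0.0

    g = _shell_gains(model)
    n = np.arange(1, model.n_terms + 1, dtype=float)
    with np.errstate(divide="ignore"):
        bpow = np.where(n == 1, 1.0, b ** (n - 1))  # b**0 == 1 also at b == 0
    pn, pn1 = _legendre_pair(model.n_terms, cos_th)
    coef = g * bpow  # (n_terms,)
    radial = (coef * n) @ pn
    tangential = coef @ pn1
    v = (m_r * radial + m_t * tangential * cos_phi) / (
        4.0 * np.pi * model.conductivities[0]
    )
    return v


def leadfield(
    position: np.ndarray, model: HeadModel, electrodes: np.ndarray
) -> np.ndarray:
    """(n_electrodes, 3) matrix L with potential = L @ moment."""
    cols = [
        potential_at_electrodes(position, e, model, electrodes)
        for e in np.eye(3)
    ]
    return np.column_stack(cols)


def residual_variance(observed: np.ndarray, modeled: np.ndarray) -> float:
    """Fraction of topography variance unexplained by the model."""
    observed = np.asarray(observed, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    if observed.shape != modeled.shape:
        raise ValueError("observed and modeled topographies differ in length")
    denom = float(observed @ observed)
    if denom == 0.0:
        raise ValueError("observed topography has zero norm")
    diff = observed - modeled
    return float(diff @ diff) / denom


def _reference(v: np.ndarray, reference: str) -> np.ndarray:
    if reference == "average":
        return v - v.mean()
    if reference == "none":
        return v
    raise ValueError(f"unknown reference {reference!r}")


def _solve_moment(
    L: np.ndarray, topo: np.ndarray, reference: str
) -> tuple[np.ndarray, np.ndarray, float]:
    if reference == "average":
        L = L - L.mean(axis=0, keepdims=True)
    m, *_ = np.linalg.lstsq(L, topo, rcond=None)
    modeled = L @ m
    diff = topo - modeled
    return m, modeled, float(diff @ diff) / float(topo @ topo)


def _grid_positions(model: HeadModel, n: int) -> np.ndarray:
    r = model.brain_radius
    ax = np.linspace(-r, r, n)
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return g[np.linalg.norm(g, axis=1) < 0.9 * r]


def _fit(
    topography: np.ndarray,
    model: HeadModel,
    electrodes: np.ndarray,
    symmetric: bool,
    reference: str,
    grid_n: int,
    n_restarts: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    topo = np.asarray(topography, dtype=float)
    if topo.ndim != 1 or topo.shape[0] != np.atleast_2d(electrodes).shape[0]:
        raise ValueError("topography length must match electrode count")
    if not np.any(topo):
        raise ValueError("cannot fit an all-zero topography")
    if topo.shape[0] < 16:
        raise ValueError("dipole fitting needs at least 16 electrodes")

    rb = model.brain_radius

    def lead(pos: np.ndarray) -> np.ndarray:
        if symmetric:
            mirrored = pos * np.array([-1.0, 1.0, 1.0])
            return np.hstack(
                [leadfield(pos, model, electrodes),
                 leadfield(mirrored, model, electrodes)]
            )
        return leadfield(pos, model, electrodes)

    def objective(pos: np.ndarray) -> float:
        r = np.linalg.norm(pos)
        if r >= 0.95 * rb:
            return 1.0 + r / rb  # push back inside
        _, _, rv = _solve_moment(lead(pos), topo, reference)
        return rv

    grid = _grid_positions(model, grid_n)
    if symmetric:
        grid = grid[grid[:, 0] >= 0.0]
    scores = np.array([objective(p) for p in grid])
    order = np.argsort(scores)

    best: tuple[float, np.ndarray] | None = None
    for start in grid[order[:n_restarts]]:
        res = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 400},
        )
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.asarray(res.x))
    assert best is not None
    pos = best[1]
    m, modeled, rv = _solve_moment(lead(pos), topo, reference)
    return pos, m, modeled, rv


def fit_single_dipole(
    topography: np.ndarray,
    model: HeadModel,
    electrodes: np.ndarray,
    *,
    reference: str = "average",
    grid_n: int = 11,
    n_restarts: int = 3,
) -> DipoleFit:
    """Fit one equivalent dipole to a scalp topography.

    Coarse grid search inside the brain shell, Nelder-Mead refinement from
    the ``n_restarts`` best grid points, linear moment solve throughout.
    ``reference='average'`` compares average-referenced forward potentials
    with the (implicitly average-referenced) topography.
    """
    pos, m, modeled, rv = _fit(
        topography, model, electrodes, False, reference, grid_n, n_restarts
    )
    topo = np.asarray(topography, dtype=float)
    return DipoleFit(position=pos, moment=m, rv=rv, modeled=modeled, observed=topo)


def fit_symmetric_pair(
    topography: np.ndarray,
    model: HeadModel,
    electrodes: np.ndarray,
    *,
    reference: str = "average",
    grid_n: int = 11,
    n_restarts: int = 3,
) -> tuple[DipoleFit, DipoleFit]:
    """Fit two dipoles mirrored across the midsagittal plane (x <-> -x).

    Positions are constrained to be mirror images; both moments are free
    and solved jointly.  x = 0 is admissible: the pair may coincide in
    position while keeping independent moment orientations.
    """
    pos, m6, modeled, rv = _fit(
        topography, model, electrodes, True, reference, grid_n, n_restarts
    )
    topo = np.asarray(topography, dtype=float)
    mirrored = pos * np.array([-1.0, 1.0, 1.0])
    left = DipoleFit(
        position=pos, moment=m6[:3], rv=rv, modeled=modeled, observed=topo,
        pair=True,
    )
    right = DipoleFit(
        position=mirrored, moment=m6[3:], rv=rv, modeled=modeled, observed=topo,
        pair=True,
    )
    left.twin, right.twin = right, left
    return left, right
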