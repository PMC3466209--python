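"""Single-scattering Monte-Carlo electron transport through a layered film.

The model is the classic single-scattering scheme used by low-voltage SEM
simulators: elastic deflections are drawn from the screened-Rutherford
angular distribution, energy loss between deflections follows the Joy–Luo
continuous-slowing-down stopping power, and no secondaries are generated.
An electron's history ends when it leaves the stack through the top
(backscattered), through the bottom (transmitted), or when its energy falls
to the 0.05 keV cutoff (absorbed, residual energy booked as deposited).

The engine steps all in-flight electrons of a chunk in lock-step with numpy,
which keeps a 10^5-electron run at a few kV within tens of seconds on one
core.  Chunks draw their random numbers from seed-sequence children of the
run seed, so results are bit-reproducible for a given (seed, n_electrons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .materials import (
    BeamSpec,
    FilmStack,
    Material,
    partial_inverse_mfps,
    stopping_power,
)

_BOUNDARY_NUDGE_NM = 1e-6
_CHUNK = 20_000


# --- elementary sampling operations --------------------------------------


def sample_free_path(mfp, u):
    """Exponential free-path sample ``s = -mfp ln(u)`` for u in (0, 1]."""
    mfp = np.asarray(mfp, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(mfp <= 0):
        raise DomainError("mean free path must be positive")
    if np.any((u <= 0) | (u > 1)):
        raise DomainError("uniform variate must lie in (0, 1]")
    s = -mfp * np.log(u)
    return s if s.shape else float(s)


def sample_polar_angle(alpha, u):
    """Inverse-CDF sample of cos(theta) from the screened-Rutherford
    angular distribution: ``cos(theta) = 1 - 2 alpha u / (1 + alpha - u)``."""
    alpha = np.asarray(alpha, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(alpha <= 0):
        raise DomainError("screening parameter must be positive")
    if np.any((u < 0) | (u > 1)):
        raise DomainError("uniform variate must lie in [0, 1]")
    c = 1.0 - 2.0 * alpha * u / (1.0 + alpha - u)
    c = np.clip(c, -1.0, 1.0)
    return c if c.shape else float(c)


def sample_scattering_cosine(model: str, Z, energy, u_theta, u_split=None):
    """Sample cos(theta) of one elastic deflection under the given model.

    ``screened_rutherford`` uses the inverse-CDF of the screened-Rutherford
    angular distribution.  ``browning`` uses the two-component empirical
    Mott-fit picture: a strongly forward screened-Rutherford-shaped lobe
    (screening 7e-3/E, element independent) taken with probability
    R/(1+R) where R = 300 E / Z, and an isotropic large-angle component
    otherwise; ``u_split`` selects the component.
    """
    Z = np.asarray(Z, dtype=float)
    e = np.asarray(energy, dtype=float)
    if model == "screened_rutherford":
        alpha = 3.4e-3 * Z ** 0.67 / e
        return sample_polar_angle(alpha, u_theta)
    if model == "browning":
        if u_split is None:
            raise DomainError("browning model needs a second uniform variate")
        ratio = 300.0 * e / Z
        p_forward = ratio / (1.0 + ratio)
        cos_fwd = sample_polar_angle(7e-3 / e, u_theta)
        cos_iso = 1.0 - 2.0 * np.asarray(u_theta, dtype=float)
        out = np.where(np.asarray(u_split) < p_forward, cos_fwd, cos_iso)
        return out if out.shape else float(out)
    raise DomainError(f"unknown elastic model {model!r}")


def rotate_direction(direction, theta, phi):
    """Rotate unit vector(s) by polar angle theta about themselves, with
    azimuth phi measured in a fixed right-handed frame around the vector.

    Accepts a single 3-vector or an (n, 3) array; preserves the norm to
    better than 1e-9.
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise DomainError("cannot rotate a zero-norm direction")
    d = d / norms[:, None]
    theta = np.broadcast_to(np.asarray(theta, dtype=float), d.shape[0])
    phi = np.broadcast_to(np.asarray(phi, dtype=float), d.shape[0])

    # Orthonormal frame (u, v, d); fall back to the x-axis helper when d is
    # nearly parallel to z.
    helper = np.zeros_like(d)
    near_z = np.abs(d[:, 2]) > 0.99999
    helper[~near_z, 2] = 1.0
    helper[near_z, 0] = 1.0
    u = np.cross(helper, d)
    u /= np.linalg.norm(u, axis=1)[:, None]
    v = np.cross(d, u)

    st = np.sin(theta)
    out = (
        np.cos(theta)[:, None] * d
        + (st * np.cos(phi))[:, None] * u
        + (st * np.sin(phi))[:, None] * v
    )
    out /= np.linalg.norm(out, axis=1)[:, None]
    if np.asarray(direction).ndim == 1:
        return out[0]
    return out


# --- single-electron state and step --------------------------------------


@dataclass
class ElectronState:
    """State of one electron; z = 0 at the beam-entry surface, increasing
    downward into the stack."""

    position: np.ndarray  # (x, y, z) nm
    direction: np.ndarray  # unit 3-vector
    energy: float  # keV
    status: str = "in-flight"  # transmitted | backscattered | absorbed
    deposited: float = 0.0  # keV left in the film so far

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise DomainError("direction must be a unit vector")
        if self.energy < 0:
            raise DomainError("energy must be non-negative")


def step_electron(
    state: ElectronState,
    stack: FilmStack,
    rng: np.random.Generator,
    cutoff_energy: float = 0.05,
    elastic_model: str = "browning",
) -> ElectronState:
    """Apply one free flight plus (if still inside) one elastic deflection.

    The sampled flight is truncated at layer interfaces: the electron is
    moved to the boundary, nudged 1e-6 nm into the next medium and the free
    path is resampled there on the next call.  Energy decreases by stopping
    power times the path actually travelled, floored at zero.  This scalar
    routine mirrors the vectorized engine and exists for trajectory-level
    diagnostics (energy bookkeeping) and for readability.
    """
    if state.status != "in-flight":
        raise DomainError("electron is no longer in flight")
    tables = _StackTables(stack)
    z = state.position[2]
    li = int(np.clip(np.searchsorted(tables.z_hi, z, side="right"), 0, len(tables.materials) - 1))
    mat = tables.materials[li]
    e = state.energy

    partial = partial_inverse_mfps(mat, e, model=elastic_model).ravel()
    mfp = 1.0 / partial.sum()
    sp = stopping_power(mat, e)

    u = 1.0 - rng.random()
    s = sample_free_path(mfp, u)
    dz = state.direction[2]
    if dz > 1e-12:
        dist = (tables.z_hi[li] - z) / dz
    elif dz < -1e-12:
        dist = (tables.z_lo[li] - z) / dz
    else:
        dist = math.inf
    crossing = s >= dist
    t = min(s, dist)

    d_e = min(sp * t, e)
    state.energy = e - d_e
    state.deposited += d_e
    state.position = state.position + state.direction * t

    if crossing:
        if dz < 0 and li == 0:
            state.status = "backscattered"
        elif dz > 0 and li == len(tables.materials) - 1:
            state.status = "transmitted"
        else:
            state.position[2] += math.copysign(_BOUNDARY_NUDGE_NM, dz)
    if state.status == "in-flight" and state.energy <= cutoff_energy:
        state.status = "absorbed"
        state.deposited += state.energy
        state.energy = 0.0
    elif state.status == "in-flight" and not crossing:
        u_elem = rng.random()
        cum = np.cumsum(partial / partial.sum())
        choice = int((u_elem > cum).sum())
        z_sel = mat.elements[min(choice, len(mat.elements) - 1)].Z
        cos_t = sample_scattering_cosine(
            elastic_model,
            z_sel,
            max(state.energy, cutoff_energy),
            rng.random(),
            rng.random(),
        )
        phi = 2.0 * np.pi * rng.random()
        state.direction = rotate_direction(state.direction, math.acos(cos_t), phi)
    return state


# --- configuration and results -------------------------------------------


@dataclass(frozen=True)
class TransportConfig:
    """Run-control parameters for the transport engine."""

    n_electrons: int = 100_000
    cutoff_energy: float = 0.05  # keV
    max_steps: int = 10_000
    rng_seed: int = 0
    beam_profile: str = "gaussian"  # or "disk"
    bin_width: float = 2.0  # nm, for exit histograms
    track_deposition: bool = False  # per-electron energy bookkeeping arrays
    #: Elastic scattering model: "browning" (empirical Mott fit; default,
    #: appropriate for heavy layers at a few keV) or "screened_rutherford".
    elastic_model: str = "browning"

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise DomainError("n_electrons must be >= 1")
        if self.cutoff_energy <= 0:
            raise DomainError("cutoff energy must be positive")
        if self.max_steps < 1:
            raise DomainError("max_steps must be >= 1")
        if self.beam_profile not in ("gaussian", "disk"):
            raise DomainError(
                f"beam_profile must be 'gaussian' or 'disk', got {self.beam_profile!r}"
            )
        if self.elastic_model not in ("browning", "screened_rutherford"):
            raise DomainError(
                f"elastic_model must be 'browning' or 'screened_rutherford', "
                f"got {self.elastic_model!r}"
            )
        if self.bin_width <= 0:
            raise DomainError("bin width must be positive")


@dataclass(frozen=True)
class TransportSummary:
    """Electron fates and exit-position statistics of one transport run."""

    n_electrons: int
    n_transmitted: int
    n_backscattered: int
    n_absorbed: int
    bin_width: float
    exit_radial_histogram: np.ndarray  # counts, bins of width bin_width from r=0
    radial_bin_edges: np.ndarray
    exit_lateral_profile: np.ndarray  # counts of exit x positions
    lateral_bin_edges: np.ndarray
    exit_x: np.ndarray  # nm, bottom-exit positions
    exit_y: np.ndarray
    exit_energy: np.ndarray  # keV at bottom exit
    voltage: float
    rng_seed: int
    # Diagnostic bookkeeping (present when track_deposition=True):
    deposited_energy: np.ndarray | None = None  # keV per electron
    exit_kinetic_energy: np.ndarray | None = None  # keV per electron (0 if absorbed)

    @property
    def fraction_transmitted(self) -> float:
        return self.n_transmitted / self.n_electrons

    @property
    def fraction_backscattered(self) -> float:
        return self.n_backscattered / self.n_electrons

    @property
    def fraction_absorbed(self) -> float:
        return self.n_absorbed / self.n_electrons

    def as_dict(self) -> dict:
        return {
            "n_electrons": self.n_electrons,
            "n_transmitted": self.n_transmitted,
            "n_backscattered": self.n_backscattered,
            "n_absorbed": self.n_absorbed,
            "fraction_transmitted": self.fraction_transmitted,
            "fraction_backscattered": self.fraction_backscattered,
            "fraction_absorbed": self.fraction_absorbed,
            "voltage_kV": self.voltage,
            "rng_seed": self.rng_seed,
        }


# --- the engine -----------------------------------------------------------


class _StackTables:
    """Precomputed per-layer geometry and composition arrays."""

    def __init__(self, stack: FilmStack):
        self.materials: list[Material] = [l.material for l in stack.layers]
        upper = stack.boundaries()
        self.z_hi = upper.astype(float)
        self.z_lo = np.concatenate(([0.0], upper[:-1])).astype(float)
        self.total = float(upper[-1])
        self.atomic_numbers = [
            np.array([e.Z for e in m.elements], dtype=float) for m in self.materials
        ]


def _sample_entry(rng: np.random.Generator, n: int, beam: BeamSpec, profile: str):
    if profile == "gaussian":
        sigma = beam.spot_diameter / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return rng.normal(0.0, sigma, size=(n, 2))
    # top-hat disk of diameter spot_diameter
    r = beam.spot_diameter / 2.0 * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    return np.column_stack((r * np.cos(phi), r * np.sin(phi)))


def _transport_chunk(
    tables: _StackTables,
    beam: BeamSpec,
    config: TransportConfig,
    n: int,
    seed_seq: np.random.SeedSequence,
):
    rng = np.random.default_rng(seed_seq)
    e0 = beam.voltage  # keV
    cutoff = config.cutoff_energy

    pos = np.zeros((n, 3))
    pos[:, :2] = _sample_entry(rng, n, beam, config.beam_profile)
    dirs = np.zeros((n, 3))
    dirs[:, 2] = 1.0
    energy = np.full(n, e0)
    deposited = np.zeros(n)

    # status codes: 0 in-flight, 1 transmitted, 2 backscattered, 3 absorbed
    status = np.zeros(n, dtype=np.int8)
    exit_ke = np.zeros(n)
    alive = np.arange(n)

    n_layers = len(tables.materials)
    for _ in range(config.max_steps):
        if alive.size == 0:
            break
        z = pos[alive, 2]
        li = np.searchsorted(tables.z_hi, z, side="right")
        li = np.clip(li, 0, n_layers - 1)
        e = energy[alive]

        mfp = np.empty(alive.size)
        sp = np.empty(alive.size)
        elem_cum = [None] * n_layers  # per-layer cumulative element probabilities
        layer_masks = []
        for ell in range(n_layers):
            m = li == ell
            layer_masks.append(m)
            if not m.any():
                continue
            partial = partial_inverse_mfps(
                tables.materials[ell], e[m], model=config.elastic_model
            )  # (k, nm^-1)
            inv_tot = partial.sum(axis=0)
            mfp[m] = 1.0 / inv_tot
            sp[m] = stopping_power(tables.materials[ell], e[m])
            elem_cum[ell] = np.cumsum(partial / inv_tot, axis=0)

        u_path = 1.0 - rng.random(alive.size)  # in (0, 1]
        s = -mfp * np.log(u_path)

        dz = dirs[alive, 2]
        dist = np.full(alive.size, np.inf)
        down = dz > 1e-12
        up = dz < -1e-12
        dist[down] = (tables.z_hi[li[down]] - z[down]) / dz[down]
        dist[up] = (tables.z_lo[li[up]] - z[up]) / dz[up]
        crossing = s >= dist
        t = np.where(crossing, dist, s)

        d_e = np.minimum(sp * t, e)
        e_new = e - d_e
        deposited[alive] += d_e
        energy[alive] = e_new
        pos[alive] += dirs[alive] * t[:, None]

        # resolve fates of crossing electrons
        new_z = pos[alive, 2]
        at_top = crossing & up & (li == 0)
        at_bottom = crossing & down & (li == n_layers - 1)
        interior = crossing & ~at_top & ~at_bottom

        gidx = alive  # global indices
        status[gidx[at_top]] = 2
        exit_ke[gidx[at_top]] = e_new[at_top]
        status[gidx[at_bottom]] = 1
        exit_ke[gidx[at_bottom]] = e_new[at_bottom]
        # nudge interior crossers into the next layer and resample there
        pos[gidx[interior], 2] = new_z[interior] + np.sign(dz[interior]) * _BOUNDARY_NUDGE_NM

        # scatter the electrons that completed a free flight in-material
        scatter = ~crossing
        # absorption check (after energy decrement)
        dead = (e_new <= config.cutoff_energy) & (status[gidx] == 0)
        status[gidx[dead]] = 3
        deposited[gidx[dead]] += e_new[dead]
        energy[gidx[dead]] = 0.0
        scatter &= ~dead

        if scatter.any():
            sc = np.flatnonzero(scatter)
            u_elem = rng.random(sc.size)
            u_theta = rng.random(sc.size)
            u_phi = rng.random(sc.size)
            u_split = rng.random(sc.size)
            z_sel = np.empty(sc.size)
            for ell in range(n_layers):
                m_l = layer_masks[ell][sc]
                if not m_l.any():
                    continue
                cum = elem_cum[ell]
                # columns of `cum` index electrons of layer ell in order
                col_of = np.cumsum(layer_masks[ell]) - 1
                cols = col_of[sc[m_l]]
                choice = (u_elem[m_l][None, :] > cum[:, cols]).sum(axis=0)
                choice = np.minimum(choice, cum.shape[0] - 1)
                z_sel[m_l] = tables.atomic_numbers[ell][choice]
            e_sc = np.maximum(e_new[sc], config.cutoff_energy)
            cos_t = sample_scattering_cosine(
                config.elastic_model, z_sel, e_sc, u_theta, u_split
            )
            theta = np.arccos(cos_t)
            phi = 2.0 * np.pi * u_phi
            dirs[gidx[sc]] = rotate_direction(dirs[gidx[sc]], theta, phi)

        alive = alive[status[alive] == 0]

    # anything still alive after max_steps is booked as absorbed
    if alive.size:
        status[alive] = 3
        deposited[alive] += energy[alive]
        energy[alive] = 0.0

    transmitted = status == 1
    return {
        "status": status,
        "exit_x": pos[transmitted, 0],
        "exit_y": pos[transmitted, 1],
        "exit_energy": exit_ke[transmitted],
        "deposited": deposited,
        "exit_ke": exit_ke,
    }


def run_transport(
    stack: FilmStack, beam: BeamSpec, config: TransportConfig
) -> TransportSummary:
    """Trace ``config.n_electrons`` electrons through ``stack`` and summarize
    their fates and bottom-exit positions.

    Electrons start at z = 0 travelling straight down, with entry (x, y)
    drawn from the beam profile (Gaussian of FWHM = spot diameter by
    default).  Deterministic for a given ``config.rng_seed``.
    """
    tables = _StackTables(stack)
    root = np.random.SeedSequence(config.rng_seed)
    n_chunks = (config.n_electrons + _CHUNK - 1) // _CHUNK
    children = root.spawn(n_chunks)

    statuses, xs, ys, ees, deps, kes = [], [], [], [], [], []
    remaining = config.n_electrons
    for child in children:
        n = min(_CHUNK, remaining)
        remaining -= n
        out = _transport_chunk(tables, beam, config, n, child)
        statuses.append(out["status"])
        xs.append(out["exit_x"])
        ys.append(out["exit_y"])
        ees.append(out["exit_energy"])
        if config.track_deposition:
            deps.append(out["deposited"])
            kes.append(out["exit_ke"])

    status = np.concatenate(statuses)
    exit_x = np.concatenate(xs)
    exit_y = np.concatenate(ys)
    exit_energy = np.concatenate(ees)

    n_tr = int((status == 1).sum())
    n_bs = int((status == 2).sum())
    n_ab = int((status == 3).sum())

    bw = config.bin_width
    if n_tr:
        r = np.hypot(exit_x, exit_y)
        r_edges = np.arange(0.0, (math.floor(r.max() / bw) + 2) * bw, bw)
        radial, _ = np.histogram(r, bins=r_edges)
        half_span = (math.floor(max(abs(exit_x.min()), abs(exit_x.max())) / bw) + 1) * bw
        x_edges = np.arange(-half_span - bw / 2.0, half_span + bw, bw)
        lateral, _ = np.histogram(exit_x, bins=x_edges)
    else:
        r_edges = np.array([0.0, bw])
        radial = np.zeros(1, dtype=int)
        x_edges = np.array([-bw / 2.0, bw / 2.0])
        lateral = np.zeros(1, dtype=int)

    return TransportSummary(
        n_electrons=config.n_electrons,
        n_transmitted=n_tr,
        n_backscattered=n_bs,
        n_absorbed=n_ab,
        bin_width=bw,
        exit_radial_histogram=radial,
        radial_bin_edges=r_edges,
        exit_lateral_profile=lateral,
        lateral_bin_edges=x_edges,
        exit_x=exit_x,
        exit_y=exit_y,
        exit_energy=exit_energy,
        voltage=beam.voltage,
        rng_seed=config.rng_seed,
        deposited_energy=np.concatenate(deps) if config.track_deposition else None,
        exit_kinetic_energy=np.concatenate(kes) if config.track_deposition else None,
    )


def half_intensity_width(profile, bin_width: float) -> float:
    """Full width (nm) of a binned 1D profile at half its peak value, with
    linear interpolation between neighbouring bins."""
    p = np.asarray(profile, dtype=float)
    if p.size == 0 or p.max() <= 0:
        raise DomainError("profile must contain positive mass")
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    peak = int(np.argmax(p))
    half = p[peak] / 2.0

    def _cross(idx_range, neighbour_step):
        for i in idx_range:
            j = i + neighbour_step
            if p[i] < half <= p[j]:
                return i + (half - p[i]) / (p[j] - p[i]) * neighbour_step
        # profile never falls below half on this side: clamp to the end
        return idx_range[-1] if len(idx_range) else peak

    left = _cross(range(peak - 1, -1, -1), +1) if peak > 0 else peak - 0.5
    right = _cross(range(peak + 1, p.size), -1) if peak < p.size - 1 else peak + 0.5
    if peak == 0:
        left = peak - 0.5
    if peak == p.size - 1:
        right = peak + 0.5
    return float((right - left) * bin_width)


def transmission_curve(
    stack: FilmStack,
    voltages,
    beam: BeamSpec,
    config: TransportConfig,
) -> pd.DataFrame:
    """Transmitted-electron fraction versus accelerating voltage.

    One transport run per voltage; run i uses seed ``rng_seed + i`` so the
    table is reproducible and voltages can be appended without disturbing
    earlier rows.
    """
    rows = []
    for i, v in enumerate(voltages):
        b = replace(beam, voltage=float(v))
        c = replace(config, rng_seed=config.rng_seed + i)
        summary = run_transport(stack, b, c)
        rows.append(
            {
                "voltage_kV": float(v),
                "fraction_transmitted": summary.fraction_transmitted,
                "fraction_backscattered": summary.fraction_backscattered,
                "fraction_absorbed": summary.fraction_absorbed,
            }
        )
    return pd.DataFrame(rows)
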