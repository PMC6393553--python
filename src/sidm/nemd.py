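"""Nonequilibrium shear simulations and the bulk-interface friction coefficient.

A slab system (interfaces normal to z) is sheared along x with
Lees-Edwards boundaries. At steady state the shear stress sigma_xz is
uniform; near a stabilized interface the velocity profile develops a
plateau (the film moves as a nearly rigid layer), so the bulk velocity
extrapolated to the interface plane, v_x, differs from the film's surface
velocity v_x^s. The momentum-transfer (friction) coefficient couples them:

    sigma_xz = zeta_xx * (v_x - v_x^s)

zeta_xx is the rate constant for momentum exchange between bulk and
interface -- the relaxation mode that dominates the stretched-exponential
step response of these interfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .md import (
    H, O, T, W, DEFAULT_DT, ForceField, ParticleSystem, Simulation, Topology,
    create_slab_system, insert_copolymers_by_identity_swap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SlabProfiles", "FrictionEstimate", "ShearRunResult", "run_shear",
    "velocity_profile", "locate_interface", "friction_coefficient",
    "DESK_PRESETS", "PAPER_PRESETS", "build_preset_system",
]


@dataclass
class SlabProfiles:
    """Per-bin density and x-velocity along the interface normal z.

    density has shape (4, n_bins) indexed by species (W, H, T, O);
    vx_mean / vx_stderr are frame-averaged bin velocities with standard
    errors over frames; empty_bins flags bins that never held a particle
    (they are flagged, never silently zeroed). sigma_xz is the global
    virial shear stress averaged over the sampled steady-state frames.
    """

    z_centers: np.ndarray
    density: np.ndarray
    vx_mean: np.ndarray
    vx_stderr: np.ndarray
    counts: np.ndarray
    empty_bins: np.ndarray
    sigma_xz: float = np.nan
    sigma_xz_stderr: float = np.nan
    n_frames: int = 0
    box: np.ndarray | None = None
    shear_rate: float = 0.0

    def to_dict(self) -> dict:
        out = {}
        for k in ("z_centers", "density", "vx_mean", "vx_stderr", "counts",
                  "empty_bins"):
            out[k] = np.asarray(getattr(self, k)).tolist()
        out.update(sigma_xz=self.sigma_xz, sigma_xz_stderr=self.sigma_xz_stderr,
                   n_frames=self.n_frames, shear_rate=self.shear_rate,
                   box=None if self.box is None else list(self.box))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SlabProfiles":
        kw = {k: np.asarray(d[k]) for k in
              ("z_centers", "density", "vx_mean", "vx_stderr", "counts")}
        kw["empty_bins"] = np.asarray(d["empty_bins"], dtype=bool)
        kw.update(sigma_xz=d["sigma_xz"], sigma_xz_stderr=d["sigma_xz_stderr"],
                  n_frames=d["n_frames"], shear_rate=d.get("shear_rate", 0.0),
                  box=None if d.get("box") is None else np.asarray(d["box"]))
        return cls(**kw)


@dataclass
class FrictionEstimate:
    """zeta_xx and its ingredients for one interface.

    resolved is False in the perfect-coupling limit (the velocity jump is
    smaller than its own uncertainty), in which case zeta_xx is NaN and
    the note explains why.
    """

    sigma_xz: float
    v_bulk_extrapolated: float
    v_surface: float
    zeta_xx: float
    zeta_stderr: float
    shear_rate: float
    resolved: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sigma_xz", "v_bulk_extrapolated", "v_surface", "zeta_xx",
                 "zeta_stderr", "shear_rate", "resolved", "note")}


@dataclass
class ShearRunResult:
    profiles: SlabProfiles
    frames: list
    log: object
    system: ParticleSystem


def run_shear(system: ParticleSystem, topology: Topology | None,
              forcefield: ForceField, shear_rate: float, steps: int,
              seed: int = 0, temperature: float = 1.0, damping: float = 1.0,
              dt: float = DEFAULT_DT, sample_every: int = 50,
              runin_fraction: float = 2.0 / 3.0,
              n_bins: int = 60) -> ShearRunResult:
    """Shear the box along x (gradient along z) and sample the steady state.

    Lees-Edwards sliding-brick boundaries impose the rate; the Langevin
    thermostat acts only on the velocity components transverse to the flow
    (y, z). The first ``runin_fraction`` of the steps is discarded as the
    approach to steady state; afterwards frames and the virial sigma_xz
    are sampled every ``sample_every`` steps.
    """
    sim = Simulation(system, forcefield, topology, dt=dt,
                     thermostat_t=temperature, damping=damping,
                     shear_rate=shear_rate, seed=seed)
    runin = int(round(steps * runin_fraction))
    sim.run(runin)
    log, frames = sim.run(steps - runin, sample_every=sample_every,
                          store_frames_every=sample_every)
    profiles = velocity_profile(frames, system.box, n_bins)
    profiles.shear_rate = shear_rate
    sxz = np.asarray(log.sigma_xz)
    if len(sxz):
        profiles.sigma_xz = float(sxz.mean())
        profiles.sigma_xz_stderr = float(sxz.std(ddof=1) / np.sqrt(len(sxz))) \
            if len(sxz) > 1 else np.nan
    # species densities from the sampled frames
    profiles.density = _species_density(frames, system, n_bins)
    logger.info("shear run: rate=%g steps=%d sigma_xz=%.4g", shear_rate, steps,
                profiles.sigma_xz)
    return ShearRunResult(profiles, frames, log, system)


def _species_density(frames: list, system: ParticleSystem,
                     n_bins: int) -> np.ndarray:
    lx, ly, lz = system.box
    vol = lx * ly * (lz / n_bins)
    dens = np.zeros((4, n_bins))
    for pos, _ in frames:
        z = pos[:, 2] % lz
        for s in (W, H, T, O):
            sel = system.species == s
            if np.any(sel):
                cnt, _ = np.histogram(z[sel], bins=n_bins, range=(0.0, lz))
                dens[s] += cnt
    if frames:
        dens /= len(frames) * vol
    return dens


def velocity_profile(frames: list, box: np.ndarray, n_bins: int) -> SlabProfiles:
    """Bin the x-velocity along z over steady-state frames.

    Bin means are first computed per frame, then averaged over frames; the
    standard error is the frame-to-frame scatter. Bins never visited by a
    particle are flagged in ``empty_bins``.
    """
    if not frames:
        raise ValueError("no frames to analyze")
    box = np.asarray(box, dtype=float)
    lz = box[2]
    edges = np.linspace(0.0, lz, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_frame = np.full((len(frames), n_bins), np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    for fi, (pos, vel) in enumerate(frames):
        z = pos[:, 2] % lz
        bins = np.minimum((z / lz * n_bins).astype(np.int64), n_bins - 1)
        cnt = np.bincount(bins, minlength=n_bins)
        vsum = np.bincount(bins, weights=vel[:, 0], minlength=n_bins)
        nz = cnt > 0
        per_frame[fi, nz] = vsum[nz] / cnt[nz]
        counts += cnt
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        vx_mean = np.nanmean(per_frame, axis=0)
        nobs = np.sum(~np.isnan(per_frame), axis=0)
        vx_sd = np.nanstd(per_frame, axis=0, ddof=1)
    vx_stderr = np.where(nobs > 1, vx_sd / np.sqrt(np.maximum(nobs, 1)), np.nan)
    empty = counts == 0
    dens_total = counts / (len(frames) * box[0] * box[1] * (lz / n_bins))
    density = np.zeros((4, n_bins))
    density[W] = dens_total  # refined per species by run_shear when available
    return SlabProfiles(z_centers=centers, density=density, vx_mean=vx_mean,
                        vx_stderr=vx_stderr, counts=counts, empty_bins=empty,
                        n_frames=len(frames), box=box)


def locate_interface(profiles: SlabProfiles) -> np.ndarray:
    """z positions of the two interfaces from the density profiles.

    Liquid-vapor systems (no O particles): the equimolar (Gibbs) dividing
    planes, where the solvent density crosses the midpoint between its
    liquid and vapor plateaus. Liquid-liquid systems: the planes where the
    W and O densities cross.
    """
    z = profiles.z_centers
    rho_w = profiles.density[W]
    rho_o = profiles.density[O]
    if rho_o.sum() > 0:
        f = rho_w - rho_o
    else:
        lo = np.percentile(rho_w, 10)
        hi = np.percentile(rho_w, 90)
        if hi - lo < 1e-6 or hi < 5.0 * max(lo, 1e-12):
            raise ValueError("no density transition found along z")
        f = rho_w - 0.5 * (hi + lo)
    crossings = []
    n = len(z)
    lz = z[-1] + (z[1] - z[0]) * 0.5
    for i in range(n):
        j = (i + 1) % n
        zi, zj = z[i], z[j] if j else lz + z[0]
        if f[i] == 0.0:
            crossings.append((zi, abs(f[i - 1]) + abs(f[j])))
        elif f[i] * f[j] < 0:
            zc = zi + (zj - zi) * f[i] / (f[i] - f[j])
            crossings.append((zc % lz, abs(f[i]) + abs(f[j])))
    if len(crossings) < 2:
        raise ValueError("no density transition found along z")
    crossings.sort(key=lambda c: -c[1])
    return np.asarray(sorted(c[0] for c in crossings[:2]))


def _auto_regions(profiles: SlabProfiles, interface_z: float,
                  bulk_side: int) -> tuple[tuple, tuple]:
    """Default bulk-fit and surface regions around one interface.

    Bulk: [interface + 3, interface + 10] sigma on the bulk side.
    Surface: +/- half the film thickness (FWHM of the copolymer density)
    around the film's density peak; falls back to +/-1.5 sigma around the
    interface when no film is present.
    """
    z = profiles.z_centers
    bulk = (interface_z + 3.0 * bulk_side, interface_z + 10.0 * bulk_side)
    bulk = (min(bulk), max(bulk))
    film = profiles.density[H] + profiles.density[T]
    if film.sum() > 0:
        near = np.abs(z - interface_z) < 4.0
        if near.any() and film[near].max() > 0:
            zpk = z[near][np.argmax(film[near])]
            pk = film[near].max()
            above = film >= 0.5 * pk
            half = min(max(0.5 * (z[1] - z[0]) * above.sum(), 0.5), 2.5)
            s0, s1 = zpk - half, zpk + half
            # keep the surface region clear of the bulk-fit region
            if bulk_side > 0:
                s1 = min(s1, interface_z + 2.9)
            else:
                s0 = max(s0, interface_z - 2.9)
            return bulk, (s0, s1)
    return bulk, (interface_z - 1.5, interface_z + 1.5)


def friction_coefficient(profiles: SlabProfiles, interface_z: float,
                         bulk_fit_region: tuple | None = None,
                         surface_region: tuple | None = None,
                         bulk_side: int = 1,
                         sigma_xz: float | None = None) -> FrictionEstimate:
    """Extract zeta_xx = sigma_xz / (v_x - v_x^s) at one interface.

    v_x is the bulk velocity profile fitted linearly over
    ``bulk_fit_region`` and extrapolated to ``interface_z``; v_x^s is the
    mean velocity over ``surface_region`` (the film's plateau -- the
    interfacial layer moves nearly uniformly in z). Uncertainties are
    propagated from the bin standard errors; if the velocity jump is
    within its own uncertainty the estimate is reported as unresolved
    (perfect-coupling limit) rather than as a number.
    """
    if bulk_fit_region is None or surface_region is None:
        auto_bulk, auto_surf = _auto_regions(profiles, interface_z, bulk_side)
        bulk_fit_region = bulk_fit_region or auto_bulk
        surface_region = surface_region or auto_surf
    b0, b1 = min(bulk_fit_region), max(bulk_fit_region)
    s0, s1 = min(surface_region), max(surface_region)
    if max(b0, s0) < min(b1, s1):
        raise ValueError("bulk and surface regions overlap")
    z = profiles.z_centers
    ok = ~profiles.empty_bins & np.isfinite(profiles.vx_mean)
    bulk_sel = ok & (z >= b0) & (z <= b1)
    surf_sel = ok & (z >= s0) & (z <= s1)
    if bulk_sel.sum() < 3:
        raise ValueError("fewer than 3 usable bins in the bulk fit region")
    if surf_sel.sum() < 1:
        raise ValueError("no usable bins in the surface region")

    # weighted linear fit of the bulk velocity profile
    w = profiles.vx_stderr[bulk_sel]
    w = np.where(np.isfinite(w) & (w > 0), w, np.nanmedian(w[np.isfinite(w)]) or 1.0)
    coef, cov = np.polyfit(z[bulk_sel], profiles.vx_mean[bulk_sel], 1,
                           w=1.0 / w, cov="unscaled")
    v_bulk = float(np.polyval(coef, interface_z))
    jvec = np.array([interface_z, 1.0])
    var_bulk = float(jvec @ cov @ jvec)

    vs = profiles.vx_mean[surf_sel]
    se = profiles.vx_stderr[surf_sel]
    se = np.where(np.isfinite(se) & (se > 0), se, np.nanmax(se) if np.isfinite(se).any() else 0.0)
    v_surf = float(vs.mean())
    var_surf = float(np.sum(se ** 2)) / max(surf_sel.sum(), 1) ** 2

    sxz = profiles.sigma_xz if sigma_xz is None else sigma_xz
    dv = v_bulk - v_surf
    u_dv = np.sqrt(var_bulk + var_surf)
    if not np.isfinite(dv) or abs(dv) <= u_dv:
        return FrictionEstimate(
            sigma_xz=sxz, v_bulk_extrapolated=v_bulk, v_surface=v_surf,
            zeta_xx=np.nan, zeta_stderr=np.nan,
            shear_rate=profiles.shear_rate, resolved=False,
            note="perfect-coupling limit: velocity jump below its uncertainty")
    zeta = sxz / dv
    rel_var = (u_dv / dv) ** 2
    if np.isfinite(profiles.sigma_xz_stderr) and sxz != 0:
        rel_var += (profiles.sigma_xz_stderr / sxz) ** 2
    rel = np.sqrt(rel_var)
    return FrictionEstimate(
        sigma_xz=sxz, v_bulk_extrapolated=v_bulk, v_surface=v_surf,
        zeta_xx=float(zeta), zeta_stderr=float(abs(zeta) * rel),
        shear_rate=profiles.shear_rate, resolved=True)


def friction_both_interfaces(profiles: SlabProfiles) -> tuple[list, float, float]:
    """zeta_xx at both interfaces, plus the combined magnitude.

    The two interfaces have opposite orientation, so the jump balance
    yields zeta of opposite sign when evaluated with the literal
    sigma/(v_bulk - v_surf) formula on each side; the physical transfer
    coefficient is the magnitude. Returns (per-interface estimates,
    combined |zeta| weighted by inverse variance, its stderr).
    """
    planes = locate_interface(profiles)
    lz = profiles.box[2] if profiles.box is not None else profiles.z_centers[-1]
    ests = []
    for z0 in planes:
        side = -1 if z0 < 0.5 * lz else 1
        ests.append(friction_coefficient(profiles, z0, bulk_side=side))
    vals = np.array([abs(e.zeta_xx) for e in ests if e.resolved])
    errs = np.array([e.zeta_stderr for e in ests if e.resolved])
    if len(vals) == 0:
        return ests, np.nan, np.nan
    w = 1.0 / np.maximum(errs, 1e-12) ** 2
    comb = float(np.sum(w * vals) / np.sum(w))
    comb_err = float(1.0 / np.sqrt(np.sum(w)))
    return ests, comb, comb_err


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Desk-scale presets: small boxes and short runs that finish in minutes on
#: one core while retaining the two-interface geometry.
DESK_PRESETS = {
    "desk-hn5": dict(mode="liquid-liquid", density=0.7, box=(10.0, 10.0, 24.0),
                     temperature=1.0, architecture="H5T5", n_chains=16,
                     bond_type="fene", shear_rate=0.1, steps=30000,
                     runin_fraction=0.5),
    "desk-hn10": dict(mode="liquid-liquid", density=0.7, box=(10.0, 10.0, 24.0),
                      temperature=1.0, architecture="H10T10", n_chains=8,
                      bond_type="fene", shear_rate=0.1, steps=30000,
                      runin_fraction=0.5),
    "desk-hn15": dict(mode="liquid-liquid", density=0.7, box=(10.0, 10.0, 30.0),
                      temperature=1.0, architecture="H15T15", n_chains=6,
                      bond_type="fene", shear_rate=0.1, steps=30000,
                      runin_fraction=0.5),
    "desk-lv": dict(mode="liquid-vapor", density=0.8, box=(12.0, 12.0, 12.0),
                    temperature=0.723, architecture=None, n_chains=0,
                    bond_type="harmonic", shear_rate=0.0, steps=10000),
}

#: Publication-scale protocols (~1e5 particles, ~1e6 steps); long-running,
#: provided for completeness and not exercised by the test suite.
PAPER_PRESETS = {
    "paper-equilibrium-h30t10": dict(
        mode="liquid-vapor", density=0.8, box=(50.56, 50.56, 46.77),
        extend_lz=92.96, temperature=0.723, architecture="H30T10",
        n_chains=150, bond_type="harmonic", shear_rate=0.0,
        steps=int(2.5e5), long_running=True),
    "paper-equilibrium-t5h10t5": dict(
        mode="liquid-vapor", density=0.8, box=(50.56, 50.56, 46.77),
        extend_lz=92.96, temperature=0.723, architecture="T5H10T5",
        n_chains=400, bond_type="harmonic", shear_rate=0.0,
        steps=int(2.5e5), long_running=True),
    "paper-nemd-hn10": dict(
        mode="liquid-liquid", density=0.7, box=(50.56, 50.56, 92.96),
        temperature=1.0, architecture="H10T10", n_chains=100,
        bond_type="fene", shear_rate=0.01, steps=int(5e5), long_running=True),
}


def build_preset_system(name: str, seed: int = 0,
                        equil_steps: int = 3000) -> tuple[ParticleSystem, Topology | None, ForceField, dict]:
    """Build the (equilibrated) system for a named preset."""
    presets = {**DESK_PRESETS, **PAPER_PRESETS}
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(presets)}")
    cfg = dict(presets[name])
    if cfg.get("long_running"):
        logger.warning("preset %s is publication-scale and long-running", name)
    ff = ForceField.liquid_liquid() if cfg["mode"] == "liquid-liquid" \
        else ForceField.liquid_vapor()
    system = create_slab_system(
        density=cfg["density"], box=cfg["box"], mode=cfg["mode"],
        temperature=cfg["temperature"], forcefield=ff, seed=seed,
        equil_steps=equil_steps, post_steps=equil_steps)
    topo = None
    if cfg.get("n_chains"):
        system, topo = insert_copolymers_by_identity_swap(
            system, cfg["architecture"], cfg["n_chains"], seed=seed + 7,
            bond_type=cfg["bond_type"])
        sim = Simulation(system, ff, topo, thermostat_t=cfg["temperature"],
                         seed=seed + 11)
        sim.run(equil_steps)
    return system, topo, ff, cfg
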