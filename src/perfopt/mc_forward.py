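"""Monte Carlo photon transport and the reflectance lookup table (MCLUT).

The DRS forward model is a probe-specific lookup table f_LUT(mu_a, mu_s')
giving the fraction of launched photons collected by the detector fiber for
a semi-infinite homogeneous medium. The table is built by photon-packet
Monte Carlo transport in the MCML tradition:

* launch uniformly over the source fiber footprint, direction uniform in
  solid angle within the fiber NA acceptance cone (in-tissue);
* exponential step sampling with mu_t = mu_a + mu_s; implicit weighted
  absorption (albedo multiplication, mu_a/mu_t deposited per interaction);
* Henyey-Greenstein sampling of the deflection angle (anisotropy g);
* Fresnel reflection/refraction at the tissue surface (tissue n vs the
  fiber-face silica above);
* a packet scores if it exits inside the detector fiber footprint AND
  within the NA acceptance cone;
* Russian roulette below weight 1e-4 with survival probability 0.1.

Also here: a steady-state diffusion-approximation closed form (extrapolated
boundary) used as an independent oracle in the diffusive regime, and Mie
theory for the polystyrene-microsphere calibration phantom.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit
from scipy.special import spherical_jn, spherical_yn

from .exceptions import LUTRangeError

DEFAULT_ANISOTROPY = 0.9
DEFAULT_TISSUE_N = 1.4
DEFAULT_FIBER_N = 1.457  # fused silica fiber face above the tissue

_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVAL = 0.1
_MAX_INTERACTIONS = 1_000_000


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties; mu_s' = mu_s (1-g) is always derived."""

    mua: float  # absorption, 1/cm
    mus: float  # scattering, 1/cm
    g: float = DEFAULT_ANISOTROPY
    n: float = DEFAULT_TISSUE_N

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be >= 0")
        if not -1 < self.g < 1:
            raise ValueError("|g| must be < 1")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def musp(self) -> float:
        return self.mus * (1.0 - self.g)

    @classmethod
    def from_musp(cls, mua: float, musp: float, g: float = DEFAULT_ANISOTROPY,
                  n: float = DEFAULT_TISSUE_N) -> "OpticalProperties":
        mus = musp / (1.0 - g) if musp > 0 else 0.0
        return cls(mua=mua, mus=mus, g=g, n=n)


@dataclass(frozen=True)
class ProbeGeometry:
    """Source/detector fiber pair on the tissue surface."""

    separation_mm: float = 1.1
    source_radius_mm: float = 0.1   # 200-um core DRS source fiber
    detector_radius_mm: float = 0.1
    numerical_aperture: float = 0.22
    n_medium_above: float = DEFAULT_FIBER_N

    def __post_init__(self):
        if self.separation_mm <= 0:
            raise ValueError("separation must be positive")
        if self.source_radius_mm <= 0 or self.detector_radius_mm <= 0:
            raise ValueError("fiber radii must be positive")
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("NA must be in (0, 1)")

    def content_hash(self) -> str:
        txt = (
            f"{self.separation_mm:.6g}|{self.source_radius_mm:.6g}|"
            f"{self.detector_radius_mm:.6g}|{self.numerical_aperture:.6g}|"
            f"{self.n_medium_above:.6g}"
        )
        return hashlib.md5(txt.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# transport kernel (numba)


@njit(cache=True)
def _hg_cos(g):
    u = np.random.random()
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - s * s) / (2.0 * g)


@njit(cache=True)
def _fresnel_unpolarized(n_i, n_t, cos_i):
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_i * sin_i / n_t
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t * sin_t)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_i * cos_t - n_t * cos_i) / (n_i * cos_t + n_t * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _spin(ux, uy, uz, cos_t, phi):
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp, sp = np.cos(phi), np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cp
        ny = sin_t * sp
        nz = cos_t * (1.0 if uz >= 0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cp - uy * sp) / den + ux * cos_t
        ny = sin_t * (uy * uz * cp + ux * sp) / den + uy * cos_t
        nz = -sin_t * cp * den + uz * cos_t
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def _transport(n_photons, mua, mus, g, n_in, n_out, src_r, det_r, det_cx,
               na, collect_all, r_edges, seed):
    """Semi-infinite medium transport; all lengths in cm.

    Returns (collected_w, collected_w2, absorbed_w, exited_w, roulette_net,
    radial_hist) where roulette_net is the signed weight created/destroyed
    by Russian roulette (zero-mean) plus weight lost to the interaction cap,
    and radial_hist tallies ALL diffusely exiting weight by exit radius from
    the source axis (for diffusion-theory comparisons).
    """
    np.random.seed(seed)
    mut = mua + mus
    albedo = mus / mut if mut > 0 else 0.0
    col_w = 0.0
    col_w2 = 0.0
    absorbed = 0.0
    exited = 0.0
    roulette_net = 0.0
    nb = r_edges.size - 1
    if nb < 0:
        nb = 0
    hist = np.zeros(nb)
    sin_max = min(na / n_in, 1.0)
    cos_min = np.sqrt(1.0 - sin_max * sin_max)
    for _ in range(n_photons):
        rr = src_r * np.sqrt(np.random.random())
        psi = 2.0 * np.pi * np.random.random()
        x = rr * np.cos(psi)
        y = rr * np.sin(psi)
        z = 0.0
        cz = cos_min + (1.0 - cos_min) * np.random.random()
        st = np.sqrt(1.0 - cz * cz)
        psi = 2.0 * np.pi * np.random.random()
        ux = st * np.cos(psi)
        uy = st * np.sin(psi)
        uz = cz
        w = 1.0
        if mus == 0.0:
            absorbed += w  # ballistic into the half-space, never returns
            continue
        alive = True
        n_int = 0
        while alive:
            s = -np.log(np.random.random()) / mut
            zn = z + uz * s
            if zn <= 0.0 and uz < 0.0:
                sb = -z / uz
                x += ux * sb
                y += uy * sb
                z = 0.0
                ci = -uz
                refl = _fresnel_unpolarized(n_in, n_out, ci)
                if np.random.random() < refl:
                    uz = -uz
                    srem = s - sb
                    x += ux * srem
                    y += uy * srem
                    z += uz * srem
                else:
                    exited += w
                    rex = np.sqrt(x * x + y * y)
                    if nb > 0 and r_edges[0] <= rex < r_edges[nb]:
                        b = np.searchsorted(r_edges, rex) - 1
                        if 0 <= b < nb:
                            hist[b] += w
                    # azimuth-averaged detector overlap: the transport is
                    # azimuthally symmetric, so score the arc fraction of the
                    # exit circle of radius rex that falls inside the
                    # detector disc (unbiased, far lower variance than a
                    # binary disc-hit test)
                    if det_cx - det_r < rex < det_cx + det_r or rex <= det_r - det_cx:
                        if collect_all or n_in * np.sqrt(1.0 - ci * ci) <= na:
                            if rex <= det_r - det_cx:
                                alpha = 1.0
                            else:
                                carg = (rex * rex + det_cx * det_cx - det_r * det_r) / (
                                    2.0 * rex * det_cx
                                )
                                if carg > 1.0:
                                    carg = 1.0
                                elif carg < -1.0:
                                    carg = -1.0
                                alpha = np.arccos(carg) / np.pi
                            c = w * alpha
                            col_w += c
                            col_w2 += c * c
                    break
            else:
                x += ux * s
                y += uy * s
                z = zn
            absorbed += w * (mua / mut)
            w *= albedo
            cos_t = _hg_cos(g)
            phi = 2.0 * np.pi * np.random.random()
            ux, uy, uz = _spin(ux, uy, uz, cos_t, phi)
            n_int += 1
            if w < _ROULETTE_THRESHOLD:
                if np.random.random() < _ROULETTE_SURVIVAL:
                    gained = w * (1.0 / _ROULETTE_SURVIVAL) - w
                    roulette_net -= gained
                    w /= _ROULETTE_SURVIVAL
                else:
                    roulette_net += w
                    alive = False
            if n_int >= _MAX_INTERACTIONS:
                roulette_net += w
                alive = False
    return col_w, col_w2, absorbed, exited, roulette_net, hist


def mc_reflectance(
    props: OpticalProperties,
    geom: ProbeGeometry,
    n_photons: int = 100_000,
    seed: int = 0,
    return_budget: bool = False,
):
    """Collected weight fraction for the fiber pair, with standard error.

    The standard error is the per-photon sample deviation of the collected
    weight (binomial-style for unit weights).
    """
    if n_photons < 1_000:
        raise ValueError("n_photons must be >= 1000")
    if props.mus == 0.0:
        out = (0.0, 0.0)
        return out + ({"absorbed": float(n_photons), "exited": 0.0, "roulette_net": 0.0},) if return_budget else out
    r_edges = np.empty(0)
    col_w, col_w2, absorbed, exited, roulette, _ = _transport(
        int(n_photons), props.mua, props.mus, props.g, props.n,
        geom.n_medium_above,
        geom.source_radius_mm / 10.0, geom.detector_radius_mm / 10.0,
        geom.separation_mm / 10.0, geom.numerical_aperture,
        False, r_edges, int(seed),
    )
    n = float(n_photons)
    mean = col_w / n
    var = max(0.0, col_w2 / n - mean**2)
    se = np.sqrt(var / n)
    if return_budget:
        return mean, se, {
            "absorbed": absorbed,
            "exited": exited,
            "roulette_net": roulette,
            "collected": col_w,
        }
    return mean, se


def mc_radial_reflectance(
    props: OpticalProperties,
    r_edges_mm,
    n_photons: int = 1_000_000,
    seed: int = 0,
    matched_boundary: bool = True,
) -> np.ndarray:
    """Diffuse reflectance per unit area R(rho) [1/cm^2] from a pencil beam.

    All exit angles are tallied, which is what the diffusion-approximation
    closed form predicts; used as the oracle comparison geometry.
    """
    r_edges = np.asarray(r_edges_mm, dtype=float) / 10.0  # cm
    n_out = props.n if matched_boundary else DEFAULT_FIBER_N
    _, _, _, _, _, hist = _transport(
        int(n_photons), props.mua, props.mus, props.g, props.n, n_out,
        1e-5, 1e-5, 0.0, 0.99, True, r_edges, int(seed),
    )
    areas = np.pi * (r_edges[1:] ** 2 - r_edges[:-1] ** 2)
    return hist / (areas * n_photons)


def sample_hg_cosines(g: float, n: int, seed: int = 0) -> np.ndarray:
    """Vectorized Henyey-Greenstein deflection-cosine sampler (for checks)."""
    u = np.random.default_rng(seed).random(n)
    if abs(g) < 1e-8:
        return 2 * u - 1
    s = (1 - g * g) / (1 - g + 2 * g * u)
    return (1 + g * g - s * s) / (2 * g)


# ---------------------------------------------------------------------------
# lookup table


def standard_mua_grid() -> np.ndarray:
    """Absorption grid: 0.01, 0.5, then 1..19 step 2 (12 values, 1/cm)."""
    return np.concatenate(([0.01, 0.5], np.arange(1.0, 19.0 + 1e-9, 2.0)))


def standard_musp_grid() -> np.ndarray:
    """Reduced-scattering grid: 0..40 step 2 (21 values, 1/cm)."""
    return np.arange(0.0, 40.0 + 1e-9, 2.0)


@dataclass(frozen=True)
class ReflectanceLUT:
    """Gridded forward reflectance f_LUT(mu_a, mu_s') for one probe."""

    mua_grid: np.ndarray
    musp_grid: np.ndarray
    reflectance: np.ndarray  # shape (len(mua_grid), len(musp_grid))
    geometry: ProbeGeometry
    n_photons_per_cell: int
    seed: int
    g: float = DEFAULT_ANISOTROPY
    standard_error: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        mua = np.asarray(self.mua_grid, dtype=float)
        musp = np.asarray(self.musp_grid, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "mua_grid", mua)
        object.__setattr__(self, "musp_grid", musp)
        object.__setattr__(self, "reflectance", refl)
        if np.any(np.diff(mua) <= 0) or np.any(np.diff(musp) <= 0):
            raise ValueError("grids must be strictly increasing")
        if refl.shape != (mua.size, musp.size):
            raise ValueError("reflectance shape must be (n_mua, n_musp)")
        if refl.min() < 0 or refl.max() > 1:
            raise ValueError("reflectance must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return int(self.mua_grid.size * self.musp_grid.size)


def build_lut(
    mua_grid,
    musp_grid,
    geom: ProbeGeometry,
    n_photons: int = 100_000,
    seed: int = 0,
    g: float = DEFAULT_ANISOTROPY,
    n_tissue: float = DEFAULT_TISSUE_N,
) -> ReflectanceLUT:
    """One transport run per (mu_a, mu_s') cell with decorrelated sub-seeds.

    Deterministic for a fixed seed. mu_s' = 0 cells are defined as zero
    reflectance (no scattering means no diffuse collection), keeping the
    degenerate column well-defined for interpolation.
    """
    mua_grid = np.asarray(mua_grid, dtype=float)
    musp_grid = np.asarray(musp_grid, dtype=float)
    refl = np.zeros((mua_grid.size, musp_grid.size))
    se = np.zeros_like(refl)
    for i, mua in enumerate(mua_grid):
        for j, musp in enumerate(musp_grid):
            if musp == 0.0:
                continue
            sub_seed = int(
                np.random.SeedSequence([int(seed), i, j]).generate_state(1)[0]
                % (2**31 - 1)
            )
            props = OpticalProperties.from_musp(mua, musp, g=g, n=n_tissue)
            refl[i, j], se[i, j] = mc_reflectance(props, geom, n_photons, sub_seed)
    return ReflectanceLUT(
        mua_grid=mua_grid,
        musp_grid=musp_grid,
        reflectance=refl,
        geometry=geom,
        n_photons_per_cell=int(n_photons),
        seed=int(seed),
        g=g,
        standard_error=se,
    )


def cell_seed(seed: int, i: int, j: int) -> int:
    """The decorrelated sub-seed build_lut uses for cell (i, j)."""
    return int(np.random.SeedSequence([int(seed), i, j]).generate_state(1)[0] % (2**31 - 1))


def lut_lookup(lut: ReflectanceLUT, mua, musp, clip: bool = False):
    """Bilinear interpolation on the (mu_a, mu_s') rectangle.

    Out-of-hull queries raise :class:`LUTRangeError` naming the offending
    axis unless ``clip`` is set (used inside bounded optimizers, which may
    probe slightly outside the box).
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if clip:
        mua = np.clip(mua, lut.mua_grid[0], lut.mua_grid[-1])
        musp = np.clip(musp, lut.musp_grid[0], lut.musp_grid[-1])
    else:
        if np.any(mua < lut.mua_grid[0]) or np.any(mua > lut.mua_grid[-1]):
            raise LUTRangeError(
                f"mua query outside grid [{lut.mua_grid[0]}, {lut.mua_grid[-1]}]",
                axis="mua",
            )
        if np.any(musp < lut.musp_grid[0]) or np.any(musp > lut.musp_grid[-1]):
            raise LUTRangeError(
                f"musp query outside grid [{lut.musp_grid[0]}, {lut.musp_grid[-1]}]",
                axis="musp",
            )
    ia = np.clip(np.searchsorted(lut.mua_grid, mua) - 1, 0, lut.mua_grid.size - 2)
    js = np.clip(np.searchsorted(lut.musp_grid, musp) - 1, 0, lut.musp_grid.size - 2)
    a0, a1 = lut.mua_grid[ia], lut.mua_grid[ia + 1]
    s0, s1 = lut.musp_grid[js], lut.musp_grid[js + 1]
    fa = (mua - a0) / (a1 - a0)
    fs = (musp - s0) / (s1 - s0)
    r = lut.reflectance
    val = (
        r[ia, js] * (1 - fa) * (1 - fs)
        + r[ia + 1, js] * fa * (1 - fs)
        + r[ia, js + 1] * (1 - fa) * fs
        + r[ia + 1, js + 1] * fa * fs
    )
    return val if val.shape else float(val)


def save_lut(lut: ReflectanceLUT, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mua_grid", data=lut.mua_grid)
        fh.create_dataset("musp_grid", data=lut.musp_grid)
        fh.create_dataset("reflectance", data=lut.reflectance)
        if lut.standard_error is not None:
            fh.create_dataset("standard_error", data=lut.standard_error)
        fh.attrs["separation_mm"] = lut.geometry.separation_mm
        fh.attrs["source_radius_mm"] = lut.geometry.source_radius_mm
        fh.attrs["detector_radius_mm"] = lut.geometry.detector_radius_mm
        fh.attrs["numerical_aperture"] = lut.geometry.numerical_aperture
        fh.attrs["n_medium_above"] = lut.geometry.n_medium_above
        fh.attrs["n_photons_per_cell"] = lut.n_photons_per_cell
        fh.attrs["seed"] = lut.seed
        fh.attrs["g"] = lut.g
        fh.attrs["geometry_hash"] = lut.geometry.content_hash()


def load_lut(path) -> ReflectanceLUT:
    with h5py.File(path, "r") as fh:
        geom = ProbeGeometry(
            separation_mm=float(fh.attrs["separation_mm"]),
            source_radius_mm=float(fh.attrs["source_radius_mm"]),
            detector_radius_mm=float(fh.attrs["detector_radius_mm"]),
            numerical_aperture=float(fh.attrs["numerical_aperture"]),
            n_medium_above=float(fh.attrs["n_medium_above"]),
        )
        se = fh["standard_error"][()] if "standard_error" in fh else None
        return ReflectanceLUT(
            mua_grid=fh["mua_grid"][()],
            musp_grid=fh["musp_grid"][()],
            reflectance=fh["reflectance"][()],
            geometry=geom,
            n_photons_per_cell=int(fh.attrs["n_photons_per_cell"]),
            seed=int(fh.attrs["seed"]),
            g=float(fh.attrs["g"]),
            standard_error=se,
        )


# ---------------------------------------------------------------------------
# diffusion-approximation oracle


def diffusion_reflectance(
    props: OpticalProperties, separation_mm: float, n_outside: float | None = None
) -> float:
    """Steady-state diffuse reflectance R(rho) [1/cm^2], semi-infinite medium.

    Extrapolated-boundary dipole solution: an isotropic source at depth
    z0 = 1/(mua + musp) and its image above the extrapolated boundary
    z = -2*A*D, with A the internal-reflection parameter from the index
    mismatch. ``n_outside=None`` means an index-matched boundary (A = 1).
    Valid when musp >> mua and rho is at least a transport mean free path
    or two.
    """
    import warnings

    mua, musp = props.mua, props.musp
    if musp <= 0:
        raise ValueError("diffusion approximation needs musp > 0")
    if musp < 10 * mua:
        warnings.warn("diffusion approximation dubious: musp < 10*mua", stacklevel=2)
    rho = separation_mm / 10.0
    mutp = mua + musp
    D = 1.0 / (3.0 * mutp)
    mueff = np.sqrt(3.0 * mua * mutp)
    nrel = 1.0 if n_outside is None else props.n / n_outside
    # Groenhuis polynomial for the internal reflection parameter; nrel=1 -> A ~ 1
    ri = -1.440 / nrel**2 + 0.710 / nrel + 0.668 + 0.0636 * nrel
    A = (1.0 + ri) / (1.0 - ri)
    z0 = 1.0 / mutp
    zb = 2.0 * A * D
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2 * zb) ** 2 + rho**2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return float((term1 + term2) / (4.0 * np.pi))


# ---------------------------------------------------------------------------
# Mie theory for the polystyrene calibration phantom


def _mie_q_g(x: float, m: float) -> tuple[float, float]:
    """Scattering efficiency Q_sca and asymmetry g for size parameter x,
    relative index m (real). Bohren-Huffman series with the logarithmic
    derivative computed by downward recurrence."""
    if x <= 0:
        raise ValueError("size parameter must be positive")
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    nmx = max(nmax, int(np.ceil(abs(m * x)))) + 16
    mx = m * x
    D = np.zeros(nmx + 1)
    for k in range(nmx, 0, -1):
        D[k - 1] = k / mx - 1.0 / (D[k] + k / mx)
    ns = np.arange(1, nmax + 1)
    psi = x * spherical_jn(ns, x)
    chi = -x * spherical_yn(ns, x)
    psi0 = np.sin(x)       # psi_0(x)
    chi0 = np.cos(x)       # chi_0(x)
    psim1 = np.concatenate(([psi0], psi[:-1]))
    chim1 = np.concatenate(([chi0], chi[:-1]))
    xi = psi - 1j * chi
    xim1 = psim1 - 1j * chim1
    Dn = D[1 : nmax + 1]
    ta = Dn / m + ns / x
    tb = Dn * m + ns / x
    a = (ta * psi - psim1) / (ta * xi - xim1)
    b = (tb * psi - psim1) / (tb * xi - xim1)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ArithmeticError("Mie series did not converge")
    qsca = (2.0 / x**2) * np.sum((2 * ns + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    # asymmetry parameter
    an, an1 = a[:-1], a[1:]
    bn, bn1 = b[:-1], b[1:]
    n1 = ns[:-1]
    t1 = np.sum(n1 * (n1 + 2) / (n1 + 1) * np.real(an * np.conj(an1) + bn * np.conj(bn1)))
    t2 = np.sum((2 * ns + 1) / (ns * (ns + 1)) * np.real(a * np.conj(b)))
    g = (4.0 / x**2) * (t1 + t2) / qsca
    return float(qsca), float(g)


def mie_properties(
    diameter_um: float,
    n_sphere: float,
    n_medium: float,
    wavelength_nm: float,
    volume_fraction: float,
) -> OpticalProperties:
    """Optical properties of a dilute microsphere suspension.

    mu_s = N sigma_geo Q_sca with N the number density from the volume
    fraction (independent-scatterer regime, volume_fraction < 0.1); the
    suspension is non-absorbing (mua = 0) and g is the Mie asymmetry.
    """
    if diameter_um <= 0 or wavelength_nm <= 0:
        raise ValueError("diameter and wavelength must be positive")
    if not 0 < volume_fraction < 0.1:
        raise ValueError("volume_fraction must be in (0, 0.1)")
    x = np.pi * diameter_um * 1e3 * n_medium / wavelength_nm
    qsca, g = _mie_q_g(x, n_sphere / n_medium)
    d_cm = diameter_um * 1e-4
    number_density = volume_fraction / ((np.pi / 6.0) * d_cm**3)  # 1/cm^3
    sigma_geo = (np.pi / 4.0) * d_cm**2  # cm^2
    mus = number_density * sigma_geo * qsca  # 1/cm
    # clamp numerically negligible |g|>=1 never occurs for physical x, m
    return OpticalProperties(mua=0.0, mus=mus, g=g, n=n_medium)
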