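"""Ground-truth spin systems for synthetic CPMG relaxation-dispersion data.

An :class:`ExchangeSystem` is a set of per-residue sites sharing global
two-state exchange parameters ``(kex, p_b)``. Two templates are provided:

``sh3_like``
    an exchanging, folded-protein-like system (modelled on an SH3 domain
    partially saturated with a binding peptide: kex ~ 182 1/s, p_b ~ 2.9%,
    per-residue |dw| spread over 0.2-3 ppm);
``idp_flat``
    a disordered-protein-like system without millisecond exchange, whose
    dispersion profiles are flat (all |dw| = 0).

Positions and linewidths are drawn per spectral dimension (direct 1H first,
then the indirect dimension(s): 15N and, for HNCO-type 3D data, 13CO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import exchange
from .constants import DEFAULT_FIELD_TESLA, larmor_mhz  # noqa: F401  (re-exported)

__all__ = [
    "ExchangeSite",
    "ExchangeSystem",
    "CpmgSeriesSpec",
    "make_system",
    "r2eff_true",
    "write_system",
    "read_system",
]

#: default half-width (ppm) of the usable position window per dimension,
#: ordered (1H direct, 15N, 13CO); chosen to keep peaks inside the default
#: spectral windows with margin for linewidth tails.
_POSITION_WINDOW_PPM = {"1H": 0.55, "15N": 10.0, "13CO": 2.5}

#: typical linewidth draw ranges (Hz) per nucleus for a small protein.
_LINEWIDTH_HZ = {"1H": (18.0, 28.0), "15N": (8.0, 16.0), "13CO": (6.0, 12.0)}


@dataclass
class ExchangeSite:
    """One residue: spectral identity plus its exchange contrast |dw|."""

    residue_id: str
    position_ppm: tuple          # per spectral dim (direct, indirect...)
    linewidth_hz: tuple          # per spectral dim, > 0
    r2_0: float                  # intrinsic transverse rate, 1/s
    delta_omega_ppm: float       # |dw| of the probed nucleus, ppm
    amplitude: float = 1.0

    def __post_init__(self):
        if len(self.position_ppm) != len(self.linewidth_hz):
            raise ValueError("position and linewidth dimensionality differ")
        if any(lw <= 0 for lw in self.linewidth_hz):
            raise ValueError("linewidths must be > 0")
        if self.r2_0 < 0:
            raise ValueError("r2_0 must be >= 0")
        if self.delta_omega_ppm < 0:
            raise ValueError("delta_omega must be >= 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass
class ExchangeSystem:
    sites: list
    kex: float
    p_b: float
    flat: bool = False
    nucleus: str = "15N"        # the CPMG-probed nucleus

    def __post_init__(self):
        if not self.flat:
            if self.kex <= 0:
                raise ValueError("kex must be > 0 for an exchanging system")
            if not 0.0 < self.p_b < 0.5:
                raise ValueError("p_b must be in (0, 0.5)")

    @property
    def ndim(self) -> int:
        return len(self.sites[0].position_ppm)


@dataclass
class CpmgSeriesSpec:
    """The CPMG series: refocusing frequencies, delay, field, probed nucleus.

    ``nu_hz`` may contain repeated values (declared duplicate measurements);
    plane 0 of any synthesized series is always the reference plane recorded
    without the relaxation delay.
    """

    nu_hz: tuple = (25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0, 750.0, 1000.0)
    t_relax: float = 0.04
    field_tesla: float = DEFAULT_FIELD_TESLA
    nucleus: str = "15N"

    def __post_init__(self):
        if any(nu <= 0 for nu in self.nu_hz):
            raise ValueError("all nu_cpmg must be > 0")
        if self.t_relax <= 0:
            raise ValueError("t_relax must be > 0")

    @property
    def obs_mhz(self) -> float:
        """Larmor frequency (MHz) of the probed nucleus."""
        return larmor_mhz(self.field_tesla, self.nucleus)

    @property
    def n_planes(self) -> int:
        """Total planes including the reference plane (index 0)."""
        return len(self.nu_hz) + 1


def make_system(
    template: str,
    n_sites: int,
    seed: int,
    ndim: int = 2,
    kex: float = 182.0,
    p_b: float = 0.029,
    dw_range_ppm: tuple = (0.2, 3.0),
    r2_0_range: tuple = (8.0, 16.0),
    nucleus: str = "15N",
    position_window_ppm: dict | None = None,
) -> ExchangeSystem:
    """Draw a reproducible ground-truth system from a named template.

    ``sh3_like`` gives every site a |dw| drawn uniformly from
    ``dw_range_ppm`` with the shared global ``(kex, p_b)``; ``idp_flat``
    sets ``flat=True`` and all |dw| to zero. Defaults for the exchanging
    template correspond to the 15N regime of a peptide-bound SH3 domain
    (kex = 182 1/s, p_b = 2.9%).
    """
    if template not in ("sh3_like", "idp_flat"):
        raise ValueError(f"unknown template {template!r}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if ndim not in (2, 3):
        raise ValueError("ndim must be 2 or 3")
    windows = dict(_POSITION_WINDOW_PPM)
    if position_window_ppm:
        windows.update(position_window_ppm)
    # 2D: the indirect dimension carries the probed nucleus; 3D is HNCO-type
    if ndim == 2:
        dims = ["1H", nucleus]
    else:
        dims = ["1H", "15N", "13CO"]

    rng = np.random.default_rng(seed)
    flat = template == "idp_flat"
    sites = []
    for i in range(n_sites):
        pos = tuple(float(rng.uniform(-windows[d], windows[d])) for d in dims)
        lws = tuple(float(rng.uniform(*_LINEWIDTH_HZ[d])) for d in dims)
        dw = 0.0 if flat else float(rng.uniform(*dw_range_ppm))
        r20 = float(rng.uniform(*r2_0_range))
        amp = float(rng.uniform(0.7, 1.3))
        sites.append(
            ExchangeSite(
                residue_id=f"R{i + 1:03d}",
                position_ppm=pos,
                linewidth_hz=lws,
                r2_0=r20,
                delta_omega_ppm=dw,
                amplitude=amp,
            )
        )
    return ExchangeSystem(
        sites=sites,
        kex=kex if not flat else 0.0,
        p_b=p_b if not flat else 0.0,
        flat=flat,
        nucleus=nucleus,
    )


def r2eff_true(system: ExchangeSystem, site: ExchangeSite, nu: float,
               spec: CpmgSeriesSpec) -> float:
    """Ground-truth R2,eff of *site* at CPMG frequency *nu*.

    Flat systems and sites with |dw| = 0 return ``r2_0`` exactly; otherwise
    the numerical Bloch-McConnell propagation is evaluated.
    """
    if nu <= 0:
        raise ValueError("nu must be > 0")
    if system.flat or site.delta_omega_ppm == 0.0:
        return float(site.r2_0)
    dw_rad = site.delta_omega_ppm * 2.0 * np.pi * spec.obs_mhz
    return exchange.bm_r2eff(nu, site.r2_0, system.kex, system.p_b, dw_rad,
                             spec.t_relax)


# ---------------------------------------------------------------------------
# serialization: one site per row, globals in the header
# ---------------------------------------------------------------------------

def write_system(system: ExchangeSystem, path) -> None:
    ndim = system.ndim
    with open(path, "w") as fh:
        fh.write(f"# kex {system.kex!r}\n# p_b {system.p_b!r}\n")
        fh.write(f"# flat {int(system.flat)}\n# nucleus {system.nucleus}\n")
        fh.write(f"# ndim {ndim}\n")
        cols = (["id"] + [f"pos{i}_ppm" for i in range(ndim)]
                + [f"lw{i}_hz" for i in range(ndim)]
                + ["r2_0", "dw_ppm", "amplitude"])
        fh.write("\t".join(cols) + "\n")
        for s in system.sites:
            row = ([s.residue_id] + [repr(p) for p in s.position_ppm]
                   + [repr(w) for w in s.linewidth_hz]
                   + [repr(s.r2_0), repr(s.delta_omega_ppm), repr(s.amplitude)])
            fh.write("\t".join(row) + "\n")


def read_system(path) -> ExchangeSystem:
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition(" ")
                header[key] = val
            else:
                rows.append(line.split("\t"))
    ndim = int(header["ndim"])
    body = rows[1:]  # first non-comment row is the column header
    sites = []
    for r in body:
        sites.append(
            ExchangeSite(
                residue_id=r[0],
                position_ppm=tuple(float(x) for x in r[1 : 1 + ndim]),
                linewidth_hz=tuple(float(x) for x in r[1 + ndim : 1 + 2 * ndim]),
                r2_0=float(r[1 + 2 * ndim]),
                delta_omega_ppm=float(r[2 + 2 * ndim]),
                amplitude=float(r[3 + 2 * ndim]),
            )
        )
    return ExchangeSystem(
        sites=sites,
        kex=float(header["kex"]),
        p_b=float(header["p_b"]),
        flat=bool(int(header["flat"])),
        nucleus=header.get("nucleus", "15N"),
    )
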