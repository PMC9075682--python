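"""Trans-bilayer volume-probability and contrast profiles.

A symmetric bilayer is parsed into an error-function hydrocarbon slab (CH2 +
CH methines), a single midplane Gaussian holding both terminal methyls, and
mirrored Gaussian pairs for the three headgroup moieties.  A hydration shell
— an error-function layer of denser water (molecular volume V_BW < bulk V_W)
wrapped around the headgroup — completes the unit cell.  Water fills
whatever volume the lipid leaves; an overfilled cell ("negative water") is
permitted and flagged so the fit can penalize it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .volumetrics import (
    CHAIN_MOIETIES,
    HEADGROUP_MOIETIES,
    LipidSpec,
    SolventSpec,
    moiety_density,
    solvent_scattering,
)

SIGMA_CH2 = 2.5       # Å, fixed smearing of the hydrocarbon slab edges
SIGMA_CHOLCH3 = 3.0   # Å, fixed width of the choline-methyl Gaussian

#: hydration-shell outer-boundary conventions (the wording "reaching up to
#: the choline position plus its width" vs "a width of 3.1 Å around the
#: headgroup" admits two readings; both are provided)
SHELL_MODES = ("choline_plus_shell", "choline")


class GridExtentError(ValueError):
    """z-grid too short to contain headgroup plus hydration shell."""


@dataclass(frozen=True)
class StructureParams:
    """Adjustable trans-bilayer structure of a symmetric bilayer.

    Positions are Gaussian centers measured from the bilayer midplane [Å];
    ``s_poly`` is the Gaussian polydispersity width of the hydrocarbon
    half-thickness D_C [Å].  ``sig_CH2`` and ``sig_CholCH3`` are normally
    held at their fixed values.
    """

    A: float
    z_CG: float
    z_PCN: float
    z_CholCH3: float
    sig_CG: float
    sig_PCN: float
    sig_CH3: float
    s_poly: float = 0.0
    sig_CH2: float = SIGMA_CH2
    sig_CholCH3: float = SIGMA_CHOLCH3

    def validate(self) -> None:
        if self.A <= 0:
            raise ValueError("area per lipid A must be > 0")
        for name in ("sig_CG", "sig_PCN", "sig_CH3", "sig_CH2",
                     "sig_CholCH3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.z_CG < self.z_PCN < self.z_CholCH3:
            raise ValueError("headgroup ordering 0 < z_CG < z_PCN < "
                             "z_CholCH3 violated")
        if self.s_poly < 0:
            raise ValueError("s_poly must be >= 0")

    def D_C(self, lipid: LipidSpec) -> float:
        """Hydrocarbon half-thickness V_HC/A [Å]."""
        return lipid.V_HC / self.A

    def D_H1(self) -> float:
        return self.z_PCN - self.z_CG

    def d_Chol(self) -> float:
        return self.z_CholCH3 - self.z_PCN


@dataclass
class ProfileSet:
    """z-gridded volume probabilities of one bilayer unit cell (2 lipids)."""

    z: np.ndarray
    components: dict[str, np.ndarray]   # moiety name -> p_i(z)
    shell: np.ndarray                   # hydration-shell region S(z) in [0,1]
    p_water: np.ndarray
    overfill: np.ndarray                # max(sum p_i - 1, 0)
    params: StructureParams
    lipid_name: str
    d_c: float                          # hydrocarbon half-thickness used
    meta: dict = field(default_factory=dict)

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    @property
    def total_lipid(self) -> np.ndarray:
        return sum(self.components.values())

    @property
    def overfilled(self) -> bool:
        return bool(np.any(self.overfill > 1e-9))


def _gauss(z: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((z - center) / sigma) ** 2) \
        / (np.sqrt(2.0 * np.pi) * sigma)


def _slab(z: np.ndarray, half_width: float, sigma: float) -> np.ndarray:
    """Symmetric error-function slab: 1 inside |z| < half_width, 0 outside."""
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((half_width - z) / s) + erf((half_width + z) / s))


def shell_outer_edge(params: StructureParams, solvent: SolventSpec,
                     shell_mode: str = "choline_plus_shell") -> float:
    if shell_mode == "choline_plus_shell":
        return params.z_CholCH3 + params.sig_CholCH3 + solvent.d_shell
    if shell_mode == "choline":
        return params.z_CholCH3 + params.sig_CholCH3
    raise ValueError(f"shell_mode must be one of {SHELL_MODES}")


def default_grid(params: StructureParams, solvent: SolventSpec,
                 dz: float = 0.1, margin: float = 15.0) -> np.ndarray:
    """Uniform symmetric grid covering headgroup + shell + bulk margin."""
    z_max = shell_outer_edge(params, solvent) + margin
    n = int(np.ceil(z_max / dz))
    return np.arange(-n, n + 1) * dz


def build_profiles(params: StructureParams, lipid: LipidSpec,
                   solvent: SolventSpec, z: np.ndarray | None = None,
                   shell_mode: str = "choline_plus_shell",
                   d_c: float | None = None,
                   headgroup_shift: float = 0.0) -> ProfileSet:
    """Build the volume-probability profiles of one unit cell.

    ``d_c`` overrides the hydrocarbon half-thickness (used by the thickness-
    polydispersity average) and ``headgroup_shift`` rides the headgroup
    Gaussians and the shell along with the moving hydrocarbon edge.
    """
    if z is None:
        z = default_grid(params, solvent)
    z = np.asarray(z, dtype=float)
    d_c0 = params.D_C(lipid)
    if d_c is None:
        d_c = d_c0
    outer = shell_outer_edge(params, solvent, shell_mode) + headgroup_shift
    if z[-1] < outer + 5.0:
        raise GridExtentError(
            f"grid reaches {z[-1]:.1f} Å but headgroup + shell extend to "
            f"{outer:.1f} Å; need at least {outer + 5.0:.1f} Å")

    A = params.A
    components: dict[str, np.ndarray] = {}

    # terminal methyls: one midplane Gaussian shared by both leaflets
    v_ch3 = lipid.V_CH3
    components["CH3"] = (2.0 * v_ch3 / A) * _gauss(z, 0.0, params.sig_CH3)

    # hydrocarbon slab minus the methyls; CH methines are folded in
    slab = _slab(z, d_c, params.sig_CH2)
    components["CH2"] = slab - components["CH3"]

    # headgroup Gaussians, mirrored across the midplane
    centers = {"CG": params.z_CG, "PCN": params.z_PCN,
               "CholCH3": params.z_CholCH3}
    widths = {"CG": params.sig_CG, "PCN": params.sig_PCN,
              "CholCH3": params.sig_CholCH3}
    for name in HEADGROUP_MOIETIES:
        c = centers[name] + headgroup_shift
        v = lipid.moiety(name).volume
        components[name] = (v / A) * (_gauss(z, c, widths[name])
                                      + _gauss(z, -c, widths[name]))

    # hydration shell: error-function layer between the hydrocarbon edge and
    # the outer headgroup boundary, both smeared with sig_CH2
    shell = _slab(z, outer, params.sig_CH2) - _slab(z, d_c, params.sig_CH2)
    shell = np.clip(shell, 0.0, 1.0)

    total = sum(components.values())
    p_water = np.clip(1.0 - total, 0.0, None)
    overfill = np.clip(total - 1.0, 0.0, None)

    return ProfileSet(z=z, components=components, shell=shell,
                      p_water=p_water, overfill=overfill, params=params,
                      lipid_name=lipid.name, d_c=d_c,
                      meta={"shell_mode": shell_mode,
                            "headgroup_shift": headgroup_shift})


def negative_water(profiles: ProfileSet, solvent: SolventSpec) -> float:
    """Number of negative water molecules per unit cell.

    n_H2O = (A/V_W) ∫ max(Σ p_i − 1, 0) dz; zero iff nothing overfills.
    """
    excess = np.trapezoid(profiles.overfill, profiles.z)
    return profiles.params.A * excess / solvent.V_W


def contrast_profile(profiles: ProfileSet, lipid: LipidSpec,
                     solvent: SolventSpec, probe: str) -> np.ndarray:
    """Contrast Δρ(z) against bulk solvent (Å⁻² neutron, e⁻/Å³ X-ray)."""
    rho_bulk, rho_bound = solvent_scattering(solvent, probe)
    rho = np.zeros_like(profiles.z)
    for name, p in profiles.components.items():
        if name == "CH2" and lipid.has_moiety("CH"):
            # methines share the slab: use the volume-weighted joint density
            m_ch2, m_ch = lipid.moiety("CH2"), lipid.moiety("CH")
            b = (m_ch2.neutron_b(solvent.d2o_fraction)
                 + m_ch.neutron_b(solvent.d2o_fraction))
            vol = m_ch2.volume + m_ch.volume
            if probe == "neutron":
                dens = b * 1.0e-5 / vol
            else:
                dens = (m_ch2.electrons + m_ch.electrons) / vol
        else:
            dens = moiety_density(lipid.moiety(name), solvent, probe)
        rho += p * dens
    rho_water = profiles.shell * rho_bound + (1.0 - profiles.shell) * rho_bulk
    rho += profiles.p_water * rho_water
    return rho - rho_bulk


def luzzati_thickness(profiles: ProfileSet) -> float:
    """Luzzati (Gibbs dividing surface) thickness D_B = ∫(1 − p_W) dz [Å]."""
    return float(np.trapezoid(1.0 - profiles.p_water, profiles.z))


def bound_water_count(profiles: ProfileSet, solvent: SolventSpec) -> float:
    """Waters per lipid inside the Luzzati thickness.

    n_W = (A/V_BW) ∫_{|z| < D_B/2} p_W dz, normalized with the bound-water
    molecular volume.  The integral runs over both leaflets of the
    two-lipid unit cell, matching the per-lipid convention of the model.
    """
    d_b = luzzati_thickness(profiles)
    mask = np.abs(profiles.z) < 0.5 * d_b
    inner = np.trapezoid(np.where(mask, profiles.p_water, 0.0), profiles.z)
    return profiles.params.A * inner / solvent.V_BW


def profiles_to_table(profiles: ProfileSet, lipid: LipidSpec,
                      solvent: SolventSpec) -> str:
    """Tab-separated export (z, p_i..., p_W, S, Δρ_neutron, Δρ_xray)."""
    names = [n for n in ("CH2", "CH3", *HEADGROUP_MOIETIES)
             if n in profiles.components]
    dn = contrast_profile(profiles, lipid, solvent, "neutron")
    dx = contrast_profile(profiles, lipid, solvent, "xray")
    buf = io.StringIO()
    p = profiles.params
    buf.write(f"# lipid: {lipid.name}\n")
    buf.write(f"# A = {p.A} Å², z_CG = {p.z_CG} Å, z_PCN = {p.z_PCN} Å, "
              f"z_CholCH3 = {p.z_CholCH3} Å\n")
    buf.write(f"# sig_CG = {p.sig_CG} Å, sig_PCN = {p.sig_PCN} Å, "
              f"sig_CH3 = {p.sig_CH3} Å, sig_CH2 = {p.sig_CH2} Å, "
              f"sig_CholCH3 = {p.sig_CholCH3} Å, s_poly = {p.s_poly} Å\n")
    buf.write(f"# d2o_fraction = {solvent.d2o_fraction}, "
              f"V_BW = {solvent.V_BW} Å³, d_shell = {solvent.d_shell} Å, "
              f"shell_mode = {profiles.meta.get('shell_mode')}\n")
    buf.write("# z\t" + "\t".join(f"p_{n}" for n in names)
              + "\tp_W\tS\tdrho_neutron\tdrho_xray\n")
    for i, zi in enumerate(profiles.z):
        row = [f"{zi:.3f}"]
        row += [f"{profiles.components[n][i]:.6e}" for n in names]
        row += [f"{profiles.p_water[i]:.6e}", f"{profiles.shell[i]:.6e}",
                f"{dn[i]:.6e}", f"{dx[i]:.6e}"]
        buf.write("\t".join(row) + "\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# per-lipid structural templates (reference values for starts & simulations)
# ---------------------------------------------------------------------------

def template_structure(lipid: LipidSpec, table: dict | None = None
                       ) -> StructureParams:
    """Reference ``StructureParams`` for a registered lipid.

    Area and terminal-methyl width come from the shipped table of fluid-phase
    joint-refinement results; headgroup positions are placed geometrically
    relative to the hydrocarbon edge (backbone Gaussian ~0.9 Å outside the
    edge, phosphate ~5.7 Å, choline ~7.5 Å), with literature-typical widths.
    """
    from .chains import load_structural_table  # local import, no cycle
    if table is None:
        table = load_structural_table().loc[lipid.name].to_dict()
    A = float(table["A"])
    d_c = lipid.V_HC / A
    return StructureParams(
        A=A, z_CG=d_c + 0.9, z_PCN=d_c + 5.7, z_CholCH3=d_c + 7.5,
        sig_CG=2.4, sig_PCN=2.6, sig_CH3=float(table["sigma_CH3"]),
        s_poly=0.6)
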