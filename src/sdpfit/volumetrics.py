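"""Composition-specific constants of the SDP bilayer model.

The scattering-density-profile (SDP) description of a lipid bilayer parses
each lipid into quasimolecular moieties (carbonyl-glycerol backbone CG,
phosphate+CH2CH2N group PCN, choline methyls CholCH3, methylenes CH2,
methines CH, terminal methyls CH3).  Each moiety carries a fixed volume,
neutron scattering length and electron count per lipid; these constants, not
the z-profiles, are what make the model composition specific.  This module
holds those constants, a registry of built-in lipids and the solvent
scattering properties as a function of D2O fraction.

Units used package-wide: Å, Å⁻¹, Å², Å³; neutron scattering lengths in fm
(1 fm = 1e-5 Å, so SLDs come out in Å⁻²); X-ray densities in e⁻/Å³.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources

import yaml

FM_PER_ANG = 1.0e-5  # 1 fm in Å

#: coherent neutron scattering lengths, fm
B_H = -3.739
B_D = 6.671
B_O = 5.803

WATER_ELECTRONS = 10.0

HEADGROUP_MOIETIES = ("CG", "PCN", "CholCH3")
CHAIN_MOIETIES = ("CH2", "CH", "CH3")


class LipidRegistryError(KeyError):
    """Requested lipid is not in the registry."""


@dataclass(frozen=True)
class MoietySpec:
    """One quasimolecular fragment, aggregated over all copies in one lipid.

    ``b_neutron`` is the scattering length of the non-exchangeable part;
    ``n_exch`` labile hydrogens are added with an H/D scattering length
    interpolated linearly in the solvent D2O fraction.
    """

    name: str
    volume: float       # Å³ per lipid
    b_neutron: float    # fm per lipid (non-exchangeable part)
    electrons: float    # e⁻ per lipid
    n_exch: int = 0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"moiety {self.name}: volume must be > 0")
        if self.electrons < 0 or self.n_exch < 0:
            raise ValueError(f"moiety {self.name}: counts must be >= 0")

    def neutron_b(self, d2o_fraction: float) -> float:
        """Neutron scattering length [fm] at the given solvent D2O fraction."""
        b_hd = (1.0 - d2o_fraction) * B_H + d2o_fraction * B_D
        return self.b_neutron + self.n_exch * b_hd


@dataclass(frozen=True)
class SolventSpec:
    """Aqueous solvent: D2O fraction and hydration-shell water volume.

    ``V_BW`` is the molecular volume of bound (hydration-shell) water; the
    bulk value ``V_W`` is its upper limit.  ``d_shell`` is the width of the
    hydration layer wrapped around the headgroup (about one water diameter).
    """

    d2o_fraction: float = 1.0
    V_W: float = 30.28
    V_BW: float = 29.3
    d_shell: float = 3.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_fraction <= 1.0:
            raise ValueError("d2o_fraction must lie in [0, 1]")
        if not 0.0 < self.V_BW <= self.V_W:
            raise ValueError("require 0 < V_BW <= V_W (bulk value is the "
                             "upper limit for bound water volume)")

    def with_d2o(self, x: float) -> "SolventSpec":
        return replace(self, d2o_fraction=x)


@dataclass(frozen=True)
class LipidSpec:
    """A lipid: its moieties plus chain composition.

    Chains are (carbon count, double-bond count) tuples.  For
    glycerophospholipids the sn1/sn2 labels are the two ester-linked acyls;
    for sphingolipids sn1 denotes the sphingoid base and sn2 the amide-linked
    acyl.
    """

    name: str
    moieties: tuple[MoietySpec, ...]
    sn1: tuple[int, int]
    sn2: tuple[int, int]
    backbone: str = "glycerophospholipid"
    V_L_declared: float | None = None
    V_H_declared: float | None = None

    # -- aggregate volumes -------------------------------------------------
    def moiety(self, name: str) -> MoietySpec:
        for m in self.moieties:
            if m.name == name:
                return m
        raise KeyError(f"{self.name} has no moiety {name!r}")

    def has_moiety(self, name: str) -> bool:
        return any(m.name == name for m in self.moieties)

    @property
    def V_L(self) -> float:
        """Total lipid volume [Å³]."""
        return sum(m.volume for m in self.moieties)

    @property
    def V_H(self) -> float:
        """Headgroup volume [Å³] (CG + PCN + CholCH3)."""
        return sum(m.volume for m in self.moieties
                   if m.name in HEADGROUP_MOIETIES)

    @property
    def V_HC(self) -> float:
        """Hydrocarbon volume [Å³] (CH2 + CH + CH3)."""
        return sum(m.volume for m in self.moieties
                   if m.name in CHAIN_MOIETIES)

    @property
    def V_CH3(self) -> float:
        """Total terminal-methyl volume per lipid [Å³] (both chains)."""
        return self.moiety("CH3").volume

    # -- chain bookkeeping -------------------------------------------------
    def chain_unit_counts(self) -> dict[str, int]:
        """CH2/CH/CH3 multiplicities implied by the chain composition.

        Each chain contributes one terminal CH3 and each double bond two CH
        methines.  Ester-linked acyls lose their C1 (carbonyl) to the CG
        moiety; the sphingoid base loses C1-C3 to the backbone moiety.
        """
        counts = {"CH2": 0, "CH": 0, "CH3": 0}
        for label, (n, db) in (("sn1", self.sn1), ("sn2", self.sn2)):
            counts["CH3"] += 1
            counts["CH"] += 2 * db
            # CG-owned carbons: the ester carbonyl C1, or C1-C3 of the
            # sphingoid base (which also carries the amide carbonyl).
            cg_owned = 3 if (self.backbone == "sphingolipid"
                             and label == "sn1") else 1
            counts["CH2"] += n - cg_owned - 1 - 2 * db
        return counts

    def validate(self) -> None:
        """Check the registry invariants; raise ``ValueError`` on failure."""
        if self.V_L_declared is not None and \
                abs(self.V_L - self.V_L_declared) > 1e-6 * self.V_L_declared:
            raise ValueError(
                f"{self.name}: moiety volumes sum to {self.V_L:.2f} Å³, "
                f"declared V_L = {self.V_L_declared:.2f} Å³")
        if self.V_H_declared is not None and \
                abs(self.V_H - self.V_H_declared) > 1e-6 * self.V_H_declared:
            raise ValueError(
                f"{self.name}: headgroup volumes sum to {self.V_H:.2f} Å³, "
                f"declared V_H = {self.V_H_declared:.2f} Å³")
        counts = self.chain_unit_counts()
        per_unit = {"CH2": 28.1, "CH": 25.6, "CH3": 56.2}
        for unit, n_units in counts.items():
            if n_units == 0:
                continue
            vol = self.moiety(unit).volume
            if abs(vol / per_unit[unit] - n_units) > 1e-6:
                raise ValueError(
                    f"{self.name}: {unit} volume {vol:.1f} Å³ implies "
                    f"{vol / per_unit[unit]:.2f} units, chain composition "
                    f"requires {n_units}")

    def with_headgroup_volume(self, V_H: float) -> "LipidSpec":
        """Rescale the three headgroup moiety volumes to a new total V_H.

        Scattering lengths and electron counts are untouched; used when the
        headgroup volume is treated as an adjustable parameter.
        """
        factor = V_H / self.V_H
        new = tuple(replace(m, volume=m.volume * factor)
                    if m.name in HEADGROUP_MOIETIES else m
                    for m in self.moieties)
        return replace(self, moieties=new, V_L_declared=None,
                       V_H_declared=None)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _registry() -> dict:
    with resources.files("sdpfit.data").joinpath("lipids.yaml").open() as fh:
        return yaml.safe_load(fh)


def registry_constants() -> dict:
    """Solvent and isotope constants shipped with the registry."""
    return dict(_registry()["constants"])


def available_lipids() -> list[str]:
    return sorted(_registry()["lipids"])


def builtin_lipid(name: str) -> LipidSpec:
    """Return a fully populated, validated ``LipidSpec`` from the registry."""
    lipids = _registry()["lipids"]
    if name not in lipids:
        raise LipidRegistryError(
            f"lipid {name!r} not in registry; available: "
            f"{', '.join(sorted(lipids))}")
    rec = lipids[name]
    moieties = tuple(
        MoietySpec(name=mname, volume=m["volume"], b_neutron=m["b"],
                   electrons=m["electrons"], n_exch=m.get("n_exch", 0))
        for mname, m in rec["moieties"].items())
    lipid = LipidSpec(
        name=name, moieties=moieties,
        sn1=tuple(rec["chains"]["sn1"]), sn2=tuple(rec["chains"]["sn2"]),
        backbone=rec["backbone"],
        V_L_declared=rec["V_L"], V_H_declared=rec["V_H"])
    lipid.validate()
    return lipid


# ---------------------------------------------------------------------------
# solvent scattering
# ---------------------------------------------------------------------------

def water_neutron_b(d2o_fraction: float) -> float:
    """Scattering length of one water molecule [fm] at D2O fraction x."""
    return 2.0 * ((1.0 - d2o_fraction) * B_H + d2o_fraction * B_D) + B_O


def solvent_scattering(solvent: SolventSpec, probe: str) -> tuple[float, float]:
    """Scattering density of (bulk, bound) water.

    Neutron: scattering length density in Å⁻², linear in the D2O fraction.
    X-ray: electron density in e⁻/Å³.  Bound water shares the molecular
    scattering power of bulk water but occupies the smaller volume V_BW, so
    its density is the bulk value times V_W/V_BW.
    """
    if probe == "neutron":
        bulk = water_neutron_b(solvent.d2o_fraction) * FM_PER_ANG / solvent.V_W
    elif probe == "xray":
        bulk = WATER_ELECTRONS / solvent.V_W
    else:
        raise ValueError(f"probe must be 'xray' or 'neutron', got {probe!r}")
    return bulk, bulk * solvent.V_W / solvent.V_BW


def moiety_density(moiety: MoietySpec, solvent: SolventSpec,
                   probe: str) -> float:
    """Scattering density of one moiety (Å⁻² neutron, e⁻/Å³ X-ray)."""
    if probe == "neutron":
        return moiety.neutron_b(solvent.d2o_fraction) * FM_PER_ANG \
            / moiety.volume
    if probe == "xray":
        return moiety.electrons / moiety.volume
    raise ValueError(f"probe must be 'xray' or 'neutron', got {probe!r}")
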