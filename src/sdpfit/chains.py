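"""Hydrocarbon chain-asymmetry metrics.

The width σ_CH3 of the midplane terminal-methyl Gaussian measures how far
chain termini stray from the bilayer center.  Two derived quantities anchor
it: σ_CH3⁰, the minimal width at which the methyl volume probability just
reaches one at the midplane (no overlap), and the dimensionless overlap

    ϒ = (σ_CH3 − σ_CH3⁰) / (D_C/3 − σ_CH3⁰),

which is 0 with no chain overlap and 1 when the methyl volume smears over
the whole hydrocarbon region (3σ_CH3 = D_C).  Across lipids, σ_CH3 grows
linearly with the chain-length mismatch |Δl_C,corr|, where the glycerol
backbone tilt adds a constant offset d_tilt that effectively lengthens the
sn1 chain:

    Δl_C,corr = l_C(sn1) − l_C(sn2) + d_tilt,
    σ_CH3 = k · |Δl_C,corr| + σ_CH3^sym.

d_tilt, the slope k and the chain-symmetric intercept are estimated by
alternating an ordinary least-squares line fit with a one-dimensional search
over d_tilt.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .volumetrics import LipidSpec, builtin_lipid

SQRT_2PI = np.sqrt(2.0 * np.pi)

#: lipids entering the default mismatch regression, with their chain labels
DEFAULT_RECORD_SET = ("DPPC", "MSPC", "SMPC", "PMPC", "MSM")
MONOUNSATURATED = ("POPC", "SOPC")


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def sigma_ch3_zero(A: float, V_CH3: float) -> float:
    """Minimal methyl width σ_CH3⁰ = 2 V_CH3 / (√(2π) A) [Å].

    This is the width at which the midplane methyl Gaussian (integral
    2V_CH3/A, shared by both leaflets) peaks at exactly 1: any narrower
    distribution would overfill the bilayer center.
    """
    if A <= 0:
        raise ValueError("area per lipid must be > 0")
    if V_CH3 < 0:
        raise ValueError("methyl volume must be >= 0")
    return 2.0 * V_CH3 / (SQRT_2PI * A)


def upsilon(sigma_ch3: float, d_c: float, sigma_ch3_0: float) -> float:
    """Relative methyl overlap ϒ = (σ_CH3 − σ_CH3⁰)/(D_C/3 − σ_CH3⁰)."""
    scale = d_c / 3.0 - sigma_ch3_0
    if scale <= 0:
        raise ValueError(
            f"degenerate overlap scale: D_C/3 = {d_c / 3.0:.3f} Å must "
            f"exceed σ_CH3⁰ = {sigma_ch3_0:.3f} Å")
    return (sigma_ch3 - sigma_ch3_0) / scale


def corrected_mismatch(l_sn1: float, l_sn2: float, d_tilt: float) -> float:
    """Backbone-tilt-corrected chain length mismatch Δl_C,corr [Å]."""
    if l_sn1 <= 0 or l_sn2 <= 0:
        raise ValueError("chain lengths must be > 0")
    return l_sn1 - l_sn2 + d_tilt


# ---------------------------------------------------------------------------
# shipped tables
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def load_chain_length_table() -> dict[str, float]:
    """Chain label -> hydrophobic length l_C [Å] (editable shipped table)."""
    with resources.files("sdpfit.data").joinpath("chain_lengths.csv").open() \
            as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df["chain"], df["l_C"].astype(float)))


@lru_cache(maxsize=1)
def load_structural_table() -> pd.DataFrame:
    """Reference fluid-phase structural parameters, indexed by lipid."""
    with resources.files("sdpfit.data") \
            .joinpath("fluid_structural_params.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("lipid")


def chain_label(chain: tuple[int, int], sphingoid: bool = False) -> str:
    n, db = chain
    return f"d{n}:{db}" if sphingoid else f"{n}:{db}"


def chain_length(chain: tuple[int, int], sphingoid: bool = False) -> float:
    """l_C for one chain via the shipped table [Å]."""
    table = load_chain_length_table()
    label = chain_label(chain, sphingoid)
    try:
        return table[label]
    except KeyError:
        raise KeyError(f"no l_C entry for chain {label!r}; table has "
                       f"{sorted(table)}") from None


# ---------------------------------------------------------------------------
# mismatch records and the iterative tilt regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MismatchRecord:
    """One lipid's entry in the mismatch regression."""

    name: str
    sigma_ch3: float
    l_sn1: float
    l_sn2: float
    saturation: str = "saturated"

    def __post_init__(self) -> None:
        if self.sigma_ch3 <= 0 or self.l_sn1 <= 0 or self.l_sn2 <= 0:
            raise ValueError("σ_CH3 and chain lengths must be > 0")

    @property
    def mismatch(self) -> float:
        return self.l_sn1 - self.l_sn2


@dataclass
class TiltFitResult:
    d_tilt: float
    k: float
    sigma_ch3_sym: float
    iterations: int
    converged: bool
    residuals: np.ndarray
    record_names: tuple[str, ...]

    def predict(self, mismatch: float) -> float:
        return self.k * abs(mismatch + self.d_tilt) + self.sigma_ch3_sym


def record_for_lipid(lipid: LipidSpec | str,
                     sigma_ch3: float | None = None) -> MismatchRecord:
    """Build a ``MismatchRecord`` from the registry and shipped tables."""
    if isinstance(lipid, str):
        lipid = builtin_lipid(lipid)
    if sigma_ch3 is None:
        sigma_ch3 = float(load_structural_table().loc[lipid.name,
                                                      "sigma_CH3"])
    sphingo = lipid.backbone == "sphingolipid"
    unsat = "monounsaturated" if (lipid.sn1[1] or lipid.sn2[1]) \
        and not sphingo else "saturated"
    return MismatchRecord(
        name=lipid.name, sigma_ch3=sigma_ch3,
        l_sn1=chain_length(lipid.sn1, sphingoid=sphingo),
        l_sn2=chain_length(lipid.sn2),
        saturation=unsat)


def default_records(include_monounsaturated: bool = True
                    ) -> list[MismatchRecord]:
    """The default regression set (all studied lipids).

    With ``include_monounsaturated=False`` the set restricts to the fully
    saturated PCs plus sphingomyelin.
    """
    names = DEFAULT_RECORD_SET + (MONOUNSATURATED
                                  if include_monounsaturated else ())
    return [record_for_lipid(n) for n in names]


def _ols(x: np.ndarray, y: np.ndarray,
         w: np.ndarray | None) -> tuple[float, float, np.ndarray]:
    design = np.column_stack([x, np.ones_like(x)])
    if w is not None:
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    return float(coef[0]), float(coef[1]), resid


def fit_backbone_tilt(records: list[MismatchRecord],
                      tolerance: float = 1e-8,
                      max_iterations: int = 200,
                      d_tilt_bounds: tuple[float, float] = (-2.0, 2.0),
                      weights: np.ndarray | None = None) -> TiltFitResult:
    """Alternating estimation of (d_tilt, k, σ_CH3^sym).

    Holding d_tilt fixed, σ_CH3 = k|Δl_C + d_tilt| + σ_sym is an ordinary
    least-squares line in |Δl_C,corr|; the alternate step is a bounded
    scalar minimization of the summed squared residuals over d_tilt (the
    line is re-solved at every trial value, i.e. the scalar step works on
    the profiled objective).  Iteration stops when d_tilt moves less than
    ``tolerance`` between rounds.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    dl = np.array([r.mismatch for r in records])
    sig = np.array([r.sigma_ch3 for r in records])
    if np.ptp(dl) < 1e-12:
        raise ValueError("degenerate design: all chain mismatches equal")
    if weights is not None:
        weights = np.asarray(weights, float)

    def profiled_sse(d: float) -> float:
        _, _, resid = _ols(np.abs(dl + d), sig, weights)
        return float(resid @ resid if weights is None
                     else (resid ** 2 * weights).sum())

    d_tilt, converged, it = 0.0, False, 0
    for it in range(1, max_iterations + 1):
        res = minimize_scalar(profiled_sse, bounds=d_tilt_bounds,
                              method="bounded",
                              options={"xatol": min(tolerance, 1e-10)})
        step = abs(res.x - d_tilt)
        d_tilt = float(res.x)
        if step < tolerance:
            converged = True
            break
    k, s_sym, resid = _ols(np.abs(dl + d_tilt), sig, weights)
    return TiltFitResult(d_tilt=d_tilt, k=k, sigma_ch3_sym=s_sym,
                         iterations=it, converged=converged,
                         residuals=resid,
                         record_names=tuple(r.name for r in records))


def lipid_metrics(lipid: LipidSpec | str, A: float, two_d_c: float,
                  sigma_ch3: float) -> dict[str, float]:
    """σ_CH3⁰ and ϒ for one lipid from (A, 2D_C, σ_CH3)."""
    if isinstance(lipid, str):
        lipid = builtin_lipid(lipid)
    s0 = sigma_ch3_zero(A, lipid.V_CH3)
    return {"sigma_CH3_0": s0,
            "upsilon": upsilon(sigma_ch3, two_d_c / 2.0, s0)}
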