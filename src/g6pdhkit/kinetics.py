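"""Mechanistic rate laws for glucose-6-phosphate dehydrogenase (G6PDH).

G6PDH oxidizes glucose-6-phosphate (G6P) while reducing NAD(P)+, following a
rapid-equilibrium random-ordered bi-bi mechanism: either substrate may bind
first, all binding steps equilibrate fast relative to turnover, and catalysis
occurs only from the ternary complex E.G6P.NAD(P)+.

For one cofactor branch (A = G6P, B = the oxidized cofactor) the rate is

    v = kcat.e0.[A][B] / ( Kia.Kb.(1+p) + Kb.[A].(1+p) + Ka.[B] + [A][B].s )

where Ka (``km_g6p``) is the dissociation of G6P from the ternary complex,
Kb (``km_cofactor``) the dissociation of the cofactor from the ternary
complex, Kia the dissociation of G6P from free enzyme, p = the branch's own
reduced cofactor over the competitive inhibition constant ``kic_product``
(each kic was measured against the product of its own branch; cross-branch
inhibition constants are not modeled), and
s = 1 + [B]/``kis_cofactor`` when substrate inhibition is present (dead-end
ternary.B complex), else 1.  Kia is not measured directly; it is closed via
the thermodynamic box Kia.Kb = Kib.Ka, i.e. Kia = ki_cofactor.km_g6p /
km_cofactor.

The cofactor specificity constant phi = (kcat/Km)_NADP / (kcat/Km)_NAD
summarizes cofactor preference: phi > 1 means NADP+-preferring.

Units package-wide: concentrations in uM, time in s, rates in uM/s.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import yaml

from .errors import InputError, ParameterError, UsageError

__all__ = [
    "Cofactor",
    "RateMode",
    "CofactorBranch",
    "EnzymeKinetics",
    "AssayMix",
    "DualRateResult",
    "specificity_constant",
    "derived_kia",
    "branch_rate",
    "dual_cofactor_rates",
    "output_ratio",
    "load_kt2440",
    "load_enzyme",
    "ECOLI_PHI",
]

#: Literature cofactor specificity constant of the single (NADP+-preferring)
#: G6PDH of Escherichia coli, used as an external comparator.
ECOLI_PHI = 410.0


class Cofactor(str, enum.Enum):
    NAD = "NAD"
    NADP = "NADP"


class RateMode(str, enum.Enum):
    """How the two cofactor branches share the enzyme.

    ``independent``: each branch obeys its own single-branch rate law in which
    the opposite oxidized cofactor enters as a competitive species at the
    cofactor site and the branch's own reduced cofactor inhibits through its
    kic.  ``shared_pool``: a single rapid-equilibrium species enumeration over
    one enzyme pool with one free-enzyme G6P constant.
    """

    INDEPENDENT = "independent"
    SHARED_POOL = "shared_pool"


def _require_positive(name: str, value: Optional[float], allow_none: bool = False):
    if value is None:
        if allow_none:
            return
        raise ParameterError(f"{name} is required")
    if not math.isfinite(value) or value <= 0:
        raise ParameterError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class CofactorBranch:
    """Kinetic constants of one cofactor branch of a G6PDH isozyme."""

    cofactor_id: Cofactor
    kcat: float  # 1/s
    km_cofactor: float  # uM, cofactor off the ternary complex
    ki_cofactor: float  # uM, cofactor off free enzyme
    km_g6p: float  # uM, G6P off the enzyme-cofactor complex
    kic_product: float  # uM, competitive inhibition by the reduced cofactor
    kis_cofactor: Optional[float] = None  # uM, substrate inhibition (optional)

    def __post_init__(self):
        self.validate()

    def validate(self):
        _require_positive("kcat", self.kcat)
        _require_positive("km_cofactor", self.km_cofactor)
        _require_positive("ki_cofactor", self.ki_cofactor)
        _require_positive("km_g6p", self.km_g6p)
        _require_positive("kic_product", self.kic_product)
        _require_positive("kis_cofactor", self.kis_cofactor, allow_none=True)
        kia = self.ki_cofactor * self.km_g6p / self.km_cofactor
        if not math.isfinite(kia) or kia <= 0:
            raise ParameterError(f"derived kia is not positive/finite: {kia!r}")

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency kcat/Km for the cofactor, 1/(uM.s)."""
        return self.kcat / self.km_cofactor


@dataclass(frozen=True)
class EnzymeKinetics:
    """Both cofactor branches of one G6PDH isozyme."""

    name: str
    nad: CofactorBranch
    nadp: CofactorBranch

    def __post_init__(self):
        if self.nad.cofactor_id is not Cofactor.NAD:
            raise ParameterError("nad branch must carry cofactor_id NAD")
        if self.nadp.cofactor_id is not Cofactor.NADP:
            raise ParameterError("nadp branch must carry cofactor_id NADP")
        phi = specificity_constant(self)
        if not math.isfinite(phi) or phi <= 0:
            raise ParameterError(f"phi is not positive/finite: {phi!r}")


@dataclass(frozen=True)
class AssayMix:
    """Concentrations in one reaction mixture (uM)."""

    g6p: float = 0.0
    nad_ox: float = 0.0
    nadp_ox: float = 0.0
    nadh: float = 0.0
    nadph: float = 0.0
    e0: float = 0.0  # total enzyme, uM

    def __post_init__(self):
        for f in ("g6p", "nad_ox", "nadp_ox", "nadh", "nadph", "e0"):
            v = getattr(self, f)
            if not math.isfinite(v) or v < 0:
                raise InputError(f"{f} must be a finite nonnegative concentration, got {v!r}")

    def require_enzyme(self):
        if self.e0 <= 0:
            raise InputError("e0 must be > 0 to compute a rate")


@dataclass(frozen=True)
class DualRateResult:
    v_nadh: float  # uM/s, flux through the NAD+ branch
    v_nadph: float  # uM/s, flux through the NADP+ branch
    mode: RateMode


def specificity_constant(enzyme: EnzymeKinetics) -> float:
    """Cofactor specificity constant phi = (kcat/Km)_NADP / (kcat/Km)_NAD."""
    return enzyme.nadp.efficiency / enzyme.nad.efficiency


def derived_kia(branch: CofactorBranch) -> float:
    """Free-enzyme G6P dissociation constant closed via the thermodynamic box.

    Kia = ki_cofactor * km_g6p / km_cofactor (uM).
    """
    return branch.ki_cofactor * branch.km_g6p / branch.km_cofactor


def branch_rate(branch: CofactorBranch, mix: AssayMix) -> float:
    """Single-branch initial rate (uM/s) at the given mixture.

    The opposite cofactor pair in ``mix`` is ignored by this form; the
    branch's own reduced cofactor inhibits competitively through its kic.
    """
    mix.require_enzyme()
    a = mix.g6p
    if branch.cofactor_id is Cofactor.NAD:
        b, p = mix.nad_ox, mix.nadh
    else:
        b, p = mix.nadp_ox, mix.nadph
    return _branch_rate_terms(branch, a, b, p, mix.e0,
                              comp_conc=0.0, comp_ki=None, comp_km=None)


def _branch_rate_terms(branch, a, b, p_own, e0, comp_conc, comp_ki, comp_km):
    """Rate law denominator assembled term by term.

    ``p_own`` is the branch's own reduced cofactor.  ``comp_conc`` is the
    concentration of a competing oxidized cofactor at the cofactor site; it
    binds free enzyme with ``comp_ki`` and the enzyme-G6P complex with
    ``comp_km`` (the competitor branch's own constants).
    """
    ka = branch.km_g6p
    kb = branch.km_cofactor
    kia = derived_kia(branch)
    p = p_own / branch.kic_product
    free_occ = 1.0 + p + (comp_conc / comp_ki if comp_ki else 0.0)
    ea_occ = 1.0 + p + (comp_conc / comp_km if comp_km else 0.0)
    s = 1.0 + (b / branch.kis_cofactor if branch.kis_cofactor else 0.0)
    den = kia * kb * free_occ + kb * a * ea_occ + ka * b + a * b * s
    return branch.kcat * e0 * a * b / den


def dual_cofactor_rates(enzyme: EnzymeKinetics, mix: AssayMix,
                        mode: RateMode | str = RateMode.INDEPENDENT) -> DualRateResult:
    """Simultaneous NADH- and NADPH-producing fluxes when both oxidized
    cofactors compete for the enzyme."""
    try:
        mode = RateMode(mode)
    except ValueError:
        raise UsageError(f"unknown mode {mode!r}; expected 'independent' or 'shared_pool'")
    mix.require_enzyme()
    if mode is RateMode.INDEPENDENT:
        v_nadh = _branch_rate_terms(
            enzyme.nad, mix.g6p, mix.nad_ox, mix.nadh, mix.e0,
            comp_conc=mix.nadp_ox, comp_ki=enzyme.nadp.ki_cofactor,
            comp_km=enzyme.nadp.km_cofactor)
        v_nadph = _branch_rate_terms(
            enzyme.nadp, mix.g6p, mix.nadp_ox, mix.nadph, mix.e0,
            comp_conc=mix.nad_ox, comp_ki=enzyme.nad.ki_cofactor,
            comp_km=enzyme.nad.km_cofactor)
    else:
        v_nadh, v_nadph = _shared_pool_rates(enzyme, mix)
    return DualRateResult(v_nadh=v_nadh, v_nadph=v_nadph, mode=mode)


def shared_kia(enzyme: EnzymeKinetics) -> float:
    """Single free-enzyme G6P constant for the shared-pool scheme.

    The two branches imply different box-closed Kia values; their geometric
    mean is used.
    """
    return math.sqrt(derived_kia(enzyme.nad) * derived_kia(enzyme.nadp))


def _shared_pool_rates(enzyme: EnzymeKinetics, mix: AssayMix):
    """One rapid-equilibrium enumeration over the species set
    {E, E.G6P, E.B1, E.B2, E.P1, E.P2, E.G6P.B1, E.G6P.B2, E.G6P.P1, E.G6P.P2}
    with B1 = NAD+, B2 = NADP+, P1 = NADH, P2 = NADPH.

    Relative abundances are taken against free enzyme = 1; each branch's flux
    is kcat_i * e0 * fraction(E.G6P.B_i).
    """
    kia = shared_kia(enzyme)
    a = mix.g6p / kia  # E.G6P
    species = [1.0, a]
    # binary and G6P-ternary complexes of the oxidized cofactors
    tern = {}
    for branch, b in ((enzyme.nad, mix.nad_ox), (enzyme.nadp, mix.nadp_ox)):
        species.append(b / branch.ki_cofactor)            # E.B_i
        tern[branch.cofactor_id] = a * b / branch.km_cofactor  # E.G6P.B_i
        species.append(tern[branch.cofactor_id])
    # reduced cofactors on free enzyme and on E.G6P, each via its branch kic
    for branch, pconc in ((enzyme.nad, mix.nadh), (enzyme.nadp, mix.nadph)):
        species.append(pconc / branch.kic_product)        # E.P_i
        species.append(a * pconc / branch.kic_product)    # E.G6P.P_i
    total = sum(species)
    v_nadh = enzyme.nad.kcat * mix.e0 * tern[Cofactor.NAD] / total
    v_nadph = enzyme.nadp.kcat * mix.e0 * tern[Cofactor.NADP] / total
    return v_nadh, v_nadph


def output_ratio(enzyme: EnzymeKinetics, mix: AssayMix,
                 mode: RateMode | str = RateMode.INDEPENDENT) -> float:
    """NADH-to-NADPH flux ratio v_NADH / v_NADPH.

    Returns ``inf`` when only the NAD branch carries flux and ``nan`` when
    both fluxes are zero (undefined).
    """
    rates = dual_cofactor_rates(enzyme, mix, mode)
    if rates.v_nadph == 0.0:
        return math.inf if rates.v_nadh > 0.0 else math.nan
    return rates.v_nadh / rates.v_nadph


# ---------------------------------------------------------------------------
# Packaged parameters


def _branch_from_dict(cofactor: Cofactor, d: dict) -> CofactorBranch:
    return CofactorBranch(
        cofactor_id=cofactor,
        kcat=float(d["kcat"]),
        km_cofactor=float(d["km_cofactor"]),
        ki_cofactor=float(d["ki_cofactor"]),
        km_g6p=float(d["km_g6p"]),
        kic_product=float(d["kic_product"]),
        kis_cofactor=float(d["kis_cofactor"]) if d.get("kis_cofactor") is not None else None,
    )


def enzyme_from_dict(name: str, d: dict) -> EnzymeKinetics:
    """Build an :class:`EnzymeKinetics` from a {'nad': {...}, 'nadp': {...}} dict."""
    return EnzymeKinetics(
        name=name,
        nad=_branch_from_dict(Cofactor.NAD, d["nad"]),
        nadp=_branch_from_dict(Cofactor.NADP, d["nadp"]),
    )


def load_params(path) -> dict[str, EnzymeKinetics]:
    """Load an enzyme parameter YAML file ({'enzymes': {name: {nad, nadp}}})."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "enzymes" not in doc:
        raise InputError(f"{path}: expected a top-level 'enzymes' mapping")
    return {name: enzyme_from_dict(name, d) for name, d in doc["enzymes"].items()}


def load_kt2440() -> dict[str, EnzymeKinetics]:
    """The packaged central parameter values of the three P. putida KT2440
    isozymes (G6PDH-A, G6PDH-B, G6PDH-C)."""
    ref = resources.files("g6pdhkit.data").joinpath("kt2440_g6pdh_params.yaml")
    doc = yaml.safe_load(ref.read_text())
    return {name: enzyme_from_dict(name, d) for name, d in doc["enzymes"].items()}


def load_enzyme(name: str) -> EnzymeKinetics:
    """One packaged isozyme by name (e.g. ``'G6PDH-A'``)."""
    table = load_kt2440()
    try:
        return table[name]
    except KeyError:
        raise UsageError(f"unknown packaged enzyme {name!r}; have {sorted(table)}")
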