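"""Buffer speciation, ionic strength, Debye screening, and osmolarity.

Solutes are speciated across protonation states with the
Henderson-Hasselbalch relation at the recipe pH, monovalent counter-ions
(Na+ or Cl-) are added for electroneutrality, and the ionic strength
``I = 1/2 * sum(c_i * z_i**2)`` feeds the Debye length

    kappa^-1 = sqrt(eps_r * eps_0 * k_B * T / (2 * N_A * e**2 * I * 1e3))

Ideal-solution assumptions throughout: no activity coefficients,
van 't Hoff osmolarity.  The screened-Coulomb repulsion index is an
interpretive ranking tool, not a physical model taken from any source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from scipy.constants import Avogadro, Boltzmann, e as ELEM_CHARGE, epsilon_0

from .errors import InputError

WATER_EPS_R = 78.5  # relative permittivity of water near 298 K


@dataclass(frozen=True)
class Solute:
    """One named solute of a recipe.

    Exactly one behavior applies:
      * nonionic=True — contributes to osmolarity only;
      * ions given — a fully dissociated salt, e.g. NaCl -> [("Na+", +1, 1), ("Cl-", -1, 1)];
      * pkas given — an acid/base speciated at the recipe pH; ``charge_fully_protonated``
        is the charge of the species with all protons attached.
    """

    name: str
    conc: float  # total concentration, mol/L
    nonionic: bool = False
    ions: tuple[tuple[str, int, int], ...] = ()  # (ion name, charge, stoichiometry)
    pkas: tuple[float, ...] = ()
    charge_fully_protonated: int = 0

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise InputError(f"negative concentration for {self.name}")
        modes = sum([self.nonionic, bool(self.ions), bool(self.pkas)])
        if modes != 1:
            raise InputError(
                f"solute {self.name}: declare exactly one of nonionic / ions / pkas"
            )


@dataclass(frozen=True)
class BufferRecipe:
    name: str
    solutes: tuple[Solute, ...]
    pH: float
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise InputError(f"pH out of [0, 14]: {self.pH}")
        if self.temperature <= 0:
            raise InputError("temperature must be > 0")


@dataclass
class IonicState:
    """Speciated ion composition of a buffer."""

    recipe_name: str
    ions: dict[str, tuple[float, int]]  # name -> (conc mol/L, charge)
    nonionic_osmolytes: dict[str, float]
    pH: float
    temperature: float

    @property
    def ionic_strength(self) -> float:
        """I = 1/2 sum c_i z_i^2, mol/L."""
        return 0.5 * sum(c * z * z for c, z in self.ions.values())

    @property
    def net_charge_conc(self) -> float:
        """sum c_i z_i, mol/L (should be ~0 after counter-ion balancing)."""
        return sum(c * z for c, z in self.ions.values())

    @property
    def osmolarity_mosm(self) -> float:
        """Ideal van 't Hoff osmolarity, mOsm/L (ions + nonionic particles)."""
        particles = sum(c for c, _ in self.ions.values())
        particles += sum(self.nonionic_osmolytes.values())
        return particles * 1000.0

    @property
    def debye_length_nm(self) -> Optional[float]:
        return debye_length(self.ionic_strength, self.temperature)


def _speciation_fractions(pkas: Sequence[float], pH: float) -> list[float]:
    """Fraction of each protonation state (0..n protons removed) at the given pH."""
    log_rel = [0.0]
    acc = 0.0
    for pka in pkas:
        acc += pH - pka
        log_rel.append(acc)
    m = max(log_rel)
    rel = [10.0 ** (lr - m) for lr in log_rel]
    total = sum(rel)
    return [r / total for r in rel]


def speciate(recipe: BufferRecipe) -> IonicState:
    """Distribute each solute across its ionic species and balance charge.

    Water autoionization (H+ at 10^-pH, OH- at 10^(pH-14)) is always
    included.  Residual charge is balanced with Na+ or Cl-.
    """
    ions: dict[str, tuple[float, int]] = {}
    nonionic: dict[str, float] = {}

    def add(name: str, conc: float, z: int) -> None:
        if conc <= 0.0:
            return
        c0, _ = ions.get(name, (0.0, z))
        ions[name] = (c0 + conc, z)

    add("H+", 10.0 ** (-recipe.pH), +1)
    add("OH-", 10.0 ** (recipe.pH - 14.0), -1)

    for sol in recipe.solutes:
        if sol.nonionic:
            nonionic[sol.name] = nonionic.get(sol.name, 0.0) + sol.conc
        elif sol.ions:
            for ion_name, z, stoich in sol.ions:
                add(ion_name, sol.conc * stoich, z)
        else:
            fracs = _speciation_fractions(sol.pkas, recipe.pH)
            for j, f in enumerate(fracs):
                z = sol.charge_fully_protonated - j
                conc = sol.conc * f
                if conc < 1e-15:
                    continue
                if z == 0:
                    nonionic[f"{sol.name}(0)"] = nonionic.get(f"{sol.name}(0)", 0.0) + conc
                else:
                    add(f"{sol.name}({z:+d})", conc, z)

    net = sum(c * z for c, z in ions.values())
    if net < 0:
        add("Na+ (counter)", -net, +1)
    elif net > 0:
        add("Cl- (counter)", net, -1)

    return IonicState(recipe.name, ions, nonionic, recipe.pH, recipe.temperature)


def debye_length(
    ionic_strength: float, temperature: float = 298.15, eps_r: float = WATER_EPS_R
) -> Optional[float]:
    """Debye screening length in nm; None (infinite) when I = 0."""
    if ionic_strength < 0:
        raise InputError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return None
    k2 = (2.0 * Avogadro * ELEM_CHARGE**2 * ionic_strength * 1e3) / (
        eps_r * epsilon_0 * Boltzmann * temperature
    )
    return 1e9 / math.sqrt(k2)


def repulsion_index(
    charge_per_subunit: float,
    subunit_spacing_nm: float,
    debye_length_nm: Optional[float],
) -> float:
    """Screened-Coulomb (Yukawa) pair-energy scale, dimensionless.

    index = Z^2 * exp(-d / kappa^-1) / d.  INTERPRETIVE: a ranking tool
    for like-charge repulsion between neighboring subunits, monotone in
    |Z|, spacing, and screening; not a quantitative energy.
    """
    if subunit_spacing_nm <= 0:
        raise InputError("subunit spacing must be > 0")
    if debye_length_nm is None:
        screen = 1.0  # unscreened limit
    else:
        screen = math.exp(-subunit_spacing_nm / debye_length_nm)
    return charge_per_subunit**2 * screen / subunit_spacing_nm

REPULSION_INDEX_PROVENANCE = "interpretive"


# ---------------------------------------------------------------------------
# Presets: the experimental media plus plain controls.

PHOSPHATE_PKAS = (2.15, 7.20, 12.35)
ACETATE_PKA = (4.76,)
CAPSO_PKA = (9.6,)


def _phosphate(conc: float) -> Solute:
    return Solute("phosphate", conc, pkas=PHOSPHATE_PKAS, charge_fully_protonated=0)


BUFFER_PRESETS: dict[str, BufferRecipe] = {
    "water": BufferRecipe("water", (), pH=7.0),
    "nacl150": BufferRecipe(
        "nacl150",
        (Solute("NaCl", 0.150, ions=(("Na+", +1, 1), ("Cl-", -1, 1))),),
        pH=7.0,
    ),
    "phosphate5_pH7.3_glucose350": BufferRecipe(
        "phosphate5_pH7.3_glucose350",
        (_phosphate(0.005), Solute("glucose", 0.350, nonionic=True)),
        pH=7.3,
    ),
    "phosphate5_pH7.3": BufferRecipe(
        "phosphate5_pH7.3", (_phosphate(0.005),), pH=7.3
    ),
    "dpbs": BufferRecipe(
        "dpbs",
        (
            Solute("NaCl", 0.1379, ions=(("Na+", +1, 1), ("Cl-", -1, 1))),
            Solute("KCl", 0.0027, ions=(("K+", +1, 1), ("Cl-", -1, 1))),
            Solute("Na2HPO4-Na", 0.0081, ions=(("Na+", +1, 2),)),
            _phosphate(0.0081),
            Solute("KH2PO4-K", 0.0015, ions=(("K+", +1, 1),)),
            _phosphate(0.0015),
        ),
        pH=7.3,
    ),
    "acetate5_pH5.0": BufferRecipe(
        "acetate5_pH5.0",
        (Solute("acetate", 0.005, pkas=ACETATE_PKA, charge_fully_protonated=0),),
        pH=5.0,
    ),
    "capso5_pH9.0": BufferRecipe(
        "capso5_pH9.0",
        (Solute("CAPSO", 0.005, pkas=CAPSO_PKA, charge_fully_protonated=0),),
        pH=9.0,
    ),
    "capso5_pH10.0": BufferRecipe(
        "capso5_pH10.0",
        (Solute("CAPSO", 0.005, pkas=CAPSO_PKA, charge_fully_protonated=0),),
        pH=10.0,
    ),
}


def get_preset(name: str) -> BufferRecipe:
    try:
        return BUFFER_PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown buffer preset {name!r}; available: {sorted(BUFFER_PRESETS)}"
        ) from None


def recipe_from_dict(data: dict) -> BufferRecipe:
    """Build a recipe from a YAML/JSON-style mapping.

    Schema: {name, pH, temperature?, solutes: [{name, mM, nonionic? |
    ions: [[ion, charge, stoich], ...] | pkas: [...], charge_fully_protonated?}]}
    """
    solutes = []
    for s in data.get("solutes", []):
        solutes.append(
            Solute(
                name=s["name"],
                conc=float(s["mM"]) / 1000.0,
                nonionic=bool(s.get("nonionic", False)),
                ions=tuple((i[0], int(i[1]), int(i[2])) for i in s.get("ions", [])),
                pkas=tuple(float(p) for p in s.get("pkas", [])),
                charge_fully_protonated=int(s.get("charge_fully_protonated", 0)),
            )
        )
    return BufferRecipe(
        name=data["name"],
        solutes=tuple(solutes),
        pH=float(data["pH"]),
        temperature=float(data.get("temperature", 298.15)),
    )


def ionic_report(state: IonicState, charge_per_subunit: float = -18.0,
                 subunit_spacing_nm: float = 5.0) -> dict:
    """JSON-ready summary of one speciated buffer."""
    kappa = state.debye_length_nm
    return {
        "recipe": state.recipe_name,
        "pH": state.pH,
        "temperature_K": state.temperature,
        "ions_mM": {k: round(c * 1000.0, 6) for k, (c, _) in sorted(state.ions.items())},
        "ionic_strength_mM": state.ionic_strength * 1000.0,
        "debye_length_nm": kappa if kappa is not None else "infinite",
        "osmolarity_mOsm": state.osmolarity_mosm,
        "repulsion_index": {
            "value": repulsion_index(charge_per_subunit, subunit_spacing_nm, kappa),
            "charge_per_subunit": charge_per_subunit,
            "subunit_spacing_nm": subunit_spacing_nm,
            "provenance": REPULSION_INDEX_PROVENANCE,
        },
    }
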