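"""Sequence-based protein charge model.

Net charge as a function of pH is computed with the per-group
Henderson-Hasselbalch protonation model: every ionizable side chain
(D, E, C, Y acidic; H, K, R basic) and the two chain termini contribute
a fractional charge

    basic:   +1 / (1 + 10**(pH - pKa))
    acidic:  -1 / (1 + 10**(pKa - pH))

summed over the residue composition.  No structural pKa shifts are
applied; the model is sequence-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight as _bio_mw

from .errors import InputError

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ACIDIC = ("D", "E", "C", "Y")
BASIC = ("K", "R", "H")


@dataclass(frozen=True)
class PkaSet:
    """Named table of pKa values for ionizable side chains and termini."""

    name: str
    D: float
    E: float
    C: float
    Y: float
    H: float
    K: float
    R: float
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for group in ("D", "E", "C", "Y", "H", "K", "R", "n_term", "c_term"):
            v = getattr(self, group)
            if not 0.0 < v < 14.0:
                raise InputError(f"pKa for {group} out of (0, 14): {v}")


#: pKa presets.  "protcalc" mirrors the constants documented by the
#: Protein Calculator web tool; "emboss" is the EMBOSS iep table.
PKA_PRESETS: dict[str, PkaSet] = {
    "protcalc": PkaSet("protcalc", D=4.4, E=4.4, C=8.5, Y=10.0,
                       H=6.5, K=10.0, R=12.0, n_term=8.0, c_term=3.1),
    "emboss": PkaSet("emboss", D=3.9, E=4.1, C=8.5, Y=10.1,
                     H=6.5, K=10.8, R=12.5, n_term=8.6, c_term=3.6),
}

DEFAULT_PKA = "protcalc"


def get_pka_set(preset: Union[str, PkaSet]) -> PkaSet:
    if isinstance(preset, PkaSet):
        return preset
    try:
        return PKA_PRESETS[preset]
    except KeyError:
        raise InputError(
            f"unknown pKa preset {preset!r}; available: {sorted(PKA_PRESETS)}"
        ) from None


def _clean_sequence(sequence: str, permissive: bool = False) -> str:
    seq = "".join(sequence.split()).upper()
    bad = set(seq) - STANDARD_AA
    if bad:
        if not permissive:
            raise InputError(f"non-standard residue letters in sequence: {sorted(bad)}")
        logger.warning("skipping %d non-standard residue letters: %s",
                       sum(seq.count(b) for b in bad), sorted(bad))
        seq = "".join(c for c in seq if c in STANDARD_AA)
    return seq


@dataclass
class ProteinSpecies:
    """A protein defined by its one-letter amino-acid sequence."""

    name: str
    sequence: str
    residue_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.sequence = _clean_sequence(self.sequence)
        if not self.sequence:
            raise InputError("empty sequence")
        self.residue_counts = {aa: self.sequence.count(aa) for aa in sorted(STANDARD_AA)}

    @property
    def molecular_weight_kda(self) -> float:
        return molecular_weight(self.sequence)

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ProteinSpecies":
        records = read_fasta(path)
        if len(records) != 1:
            raise InputError(f"{path}: expected a single FASTA record, found {len(records)}")
        return records[0]


def read_fasta(path: Union[str, Path]) -> list[ProteinSpecies]:
    """Read one or more protein records from a FASTA file."""
    records = [ProteinSpecies(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def bundled_fasta(accession: str) -> Path:
    """Path to a sequence fixture shipped with the package (e.g. 'P08670')."""
    p = resources.files("ifkit.data").joinpath(f"{accession}.fasta")
    return Path(str(p))


def molecular_weight(sequence: str) -> float:
    """Average-isotope molecular weight of the chain in kDa (residues + one water)."""
    seq = _clean_sequence(sequence)
    if not seq:
        raise InputError("empty sequence")
    return _bio_mw(seq, seq_type="protein", monoisotopic=False) / 1000.0


def net_charge(
    sequence: str,
    pH: float,
    pka_set: Union[str, PkaSet] = DEFAULT_PKA,
    include_termini: bool = True,
    include_cys_tyr: bool = True,
    permissive: bool = False,
) -> float:
    """Net charge (elementary units) of a sequence at the given pH.

    ``include_termini=False`` treats the chain as an internal segment
    (no free amino or carboxyl terminus), which is the right mode for
    linkers embedded in a fusion construct.
    """
    if not 0.0 <= pH <= 14.0:
        raise InputError(f"pH out of [0, 14]: {pH}")
    seq = _clean_sequence(sequence, permissive=permissive)
    if not seq:
        raise InputError("empty sequence")
    pk = get_pka_set(pka_set)

    def basic(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))

    def acidic(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - pH))

    z = 0.0
    for aa in BASIC:
        z += seq.count(aa) * basic(getattr(pk, aa))
    acid_groups = ACIDIC if include_cys_tyr else ("D", "E")
    for aa in acid_groups:
        z += seq.count(aa) * acidic(getattr(pk, aa))
    if include_termini:
        z += basic(pk.n_term) + acidic(pk.c_term)
    return z


@dataclass
class ChargeCurve:
    """Net charge evaluated on a pH grid, with the zero crossing (pI)."""

    pH: np.ndarray
    Z: np.ndarray
    pI: float | None  # None when the curve never crosses zero

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"pH": self.pH, "Z": self.Z})


def isoelectric_point(
    sequence: str,
    pka_set: Union[str, PkaSet] = DEFAULT_PKA,
    tol: float = 1e-4,
    **charge_kwargs,
) -> float | None:
    """pH at which the net charge crosses zero, by bisection to ``tol`` pH units.

    Returns None when the charge has the same sign across the whole pH range
    (no ionizable groups of one sign).
    """
    lo, hi = 0.0, 14.0
    z_lo = net_charge(sequence, lo, pka_set, **charge_kwargs)
    z_hi = net_charge(sequence, hi, pka_set, **charge_kwargs)
    if z_lo <= 0.0 or z_hi >= 0.0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set, **charge_kwargs) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charge_curve(
    sequence: str,
    pH_lo: float = 2.0,
    pH_hi: float = 12.0,
    step: float = 0.1,
    pka_set: Union[str, PkaSet] = DEFAULT_PKA,
    **charge_kwargs,
) -> ChargeCurve:
    """Evaluate Z(pH) on a uniform grid and locate the isoelectric point."""
    if pH_lo >= pH_hi:
        raise InputError("pH_lo must be < pH_hi")
    grid = np.arange(pH_lo, pH_hi + 0.5 * step, step)
    z = np.array([net_charge(sequence, p, pka_set, **charge_kwargs) for p in grid])
    pi = isoelectric_point(sequence, pka_set, **charge_kwargs)
    return ChargeCurve(pH=grid, Z=z, pI=pi)


Component = Union[str, float, int]


def fusion_charge(
    components: Sequence[Component],
    pH: float,
    pka_set: Union[str, PkaSet] = DEFAULT_PKA,
    single_chain: bool = True,
    **charge_kwargs,
) -> float:
    """Net charge of a fusion construct.

    Components are either amino-acid sequences or fixed-charge tags
    (numbers passed through unchanged, e.g. -2 per phosphosite).  In
    single-chain mode all sequence components are concatenated first so
    internal junctions contribute no extra termini; termini are counted
    exactly once for the assembled chain.
    """
    if not components:
        raise InputError("fusion requires at least one component")
    fixed = sum(float(c) for c in components if isinstance(c, (int, float)))
    seqs = [c for c in components if isinstance(c, str)]
    z = fixed
    if seqs:
        if single_chain:
            z += net_charge("".join(seqs), pH, pka_set, **charge_kwargs)
        else:
            z += sum(net_charge(s, pH, pka_set, **charge_kwargs) for s in seqs)
    return z
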