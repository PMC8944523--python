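"""Physicochemical protein properties: length, molecular weight, pI.

Molecular weight is the sum of average residue masses plus one water
mass, reported in kDa.  The isoelectric point is the pH at which the
Henderson–Hasselbalch net charge over the termini and the ionisable side
chains (D, E, C, Y, H, K, R) crosses zero; the charge is strictly
decreasing in pH so bisection on [0, 14] always converges.  The pKa set
is an EMBOSS-style table shipped as a JSON data file and swappable — the
numbers are a published convention, not a universal constant, so tests
assert internal consistency rather than equality with any one web tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

WATER_DA = 18.01528

#: average (isotope-abundance weighted) residue masses, Da
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_MEAN_RESIDUE_MASS = sum(RESIDUE_MASS_DA.values()) / len(RESIDUE_MASS_DA)


def _default_pka() -> dict:
    with resources.files("genefamkit.data").joinpath("pka_emboss.json").open() as fh:
        return json.load(fh)


_PKA = _default_pka()


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    mw_kda: float
    pi: float
    localization: str | None = None  # imported annotation only


def molecular_weight(sequence: str) -> float:
    """Average molecular weight of a protein in kDa.

    'X' is scored with the mean residue mass; any other non-standard
    letter is an error, as is an empty sequence.
    """
    sequence = sequence.upper().rstrip("*")
    if not sequence:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    total = WATER_DA
    for aa in sequence:
        if aa == "X":
            total += _MEAN_RESIDUE_MASS
        elif aa in RESIDUE_MASS_DA:
            total += RESIDUE_MASS_DA[aa]
        else:
            raise ValueError(f"unknown amino acid {aa!r}")
    return total / 1000.0


def net_charge(sequence: str, ph: float, pka: dict | None = None) -> float:
    """Net charge (elementary charges) at the given pH."""
    pka = pka or _PKA
    sequence = sequence.upper().rstrip("*")
    charge = 1.0 / (1.0 + 10 ** (ph - pka["n_terminus"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["c_terminus"] - ph))
    for aa, k in pka["positive"].items():
        charge += sequence.count(aa) / (1.0 + 10 ** (ph - k))
    for aa, k in pka["negative"].items():
        charge -= sequence.count(aa) / (1.0 + 10 ** (k - ph))
    return charge


def isoelectric_point(sequence: str, pka: dict | None = None, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    sequence = sequence.upper().rstrip("*")
    if not sequence:
        raise ValueError("cannot compute pI of an empty sequence")
    for aa in sequence:
        if aa != "X" and aa not in RESIDUE_MASS_DA:
            raise ValueError(f"unknown amino acid {aa!r}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_properties(sequence: str, localization: str | None = None) -> ProteinProperties:
    seq = sequence.upper().rstrip("*")
    return ProteinProperties(
        length=len(seq),
        mw_kda=molecular_weight(seq),
        pi=isoelectric_point(seq),
        localization=localization,
    )
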