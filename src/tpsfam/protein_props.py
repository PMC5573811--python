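"""Protein physicochemical properties and mono-/sesquiterpene-synthase heuristics.

Molecular weight is the ExPasy-style theoretical MW: sum of average (not
monoisotopic) residue masses plus one water. The isoelectric point is found
by bisection on the Henderson-Hasselbalch net charge, which is strictly
decreasing in pH, so the root is unique; the default pKa set is Bjellqvist's
(the table behind ExPasy's Compute pI/MW), with EMBOSS and Sillero sets
selectable since published pI values depend on the pKa table used.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import ProteinRecord

#: Average residue masses (Da), ExPasy/IUPAC standard amino acid residues.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

#: pKa tables: (positive groups: Nterm, K, R, H) and (negative: Cterm, D, E, C, Y)
PKA_SETS: dict[str, dict[str, float]] = {
    # Bjellqvist et al. — the set used by ExPasy Compute pI/MW
    "bjellqvist": {
        "Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98,
        "Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
    "emboss": {
        "Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5,
        "Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "sillero": {
        "Nterm": 8.2, "K": 10.4, "R": 12.0, "H": 6.4,
        "Cterm": 3.2, "D": 4.0, "E": 4.5, "C": 9.0, "Y": 10.0,
    },
}

#: Predicted proteins at least this long are treated as putatively functional.
MIN_FUNCTIONAL_LENGTH = 400

#: Sesquiterpene synthases are typically <= this many residues (monoterpene
#: synthases run 600-650 aa because of the N-terminal plastid transit peptide).
MAX_SESQUI_LENGTH = 600


@dataclass
class ProteinProperties:
    protein_id: str
    length_aa: int
    mw_kda: float
    pi: float
    putative_functional: bool
    transit_peptide: str = "unknown"  # predicted | absent | unknown
    tps_type_hint: str = "unknown"  # mono | sesqui | unknown


def is_putative_functional(protein: ProteinRecord) -> bool:
    """True iff the predicted product is at least 400 residues long."""
    return protein.length >= MIN_FUNCTIONAL_LENGTH


def molecular_weight(protein: ProteinRecord | str, kda: bool = True) -> float:
    """Theoretical average molecular weight (kDa by default, 2-decimal scale).

    Raises on empty sequences and on X residues (unknown residues have no
    defined mass); callers wanting a value for degenerate proteins must strip
    or impute X explicitly.
    """
    residues = protein if isinstance(protein, str) else protein.residues
    if not residues:
        raise ValueError("empty sequence has no molecular weight")
    x_at = residues.find("X")
    if x_at != -1:
        raise ValueError(f"X residue at position {x_at + 1}: mass undefined")
    dalton = sum(AVERAGE_RESIDUE_MASS[r] for r in residues) + WATER_MASS
    return round(dalton / 1000.0, 2) if kda else round(dalton, 2)


def net_charge(residues: str, ph: float, pka: dict[str, float]) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Positive groups (N-terminus, K, R, H) contribute 1/(1+10^(pH-pKa));
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)).
    X residues are chargeless.
    """
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in "KRH":
        n = residues.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in "DECY":
        n = residues.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    protein: ProteinRecord | str,
    pka_set: str = "bjellqvist",
    tol: float = 0.005,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Composition-only (permutation-invariant). Poly-X input degenerates to the
    termini-only charge and still has a unique root.
    """
    residues = protein if isinstance(protein, str) else protein.residues
    if not residues:
        raise ValueError("empty sequence has no isoelectric point")
    pka = PKA_SETS[pka_set]
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(residues, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


def predict_transit_peptide(protein: ProteinRecord, window: int = 60) -> str:
    """Crude, approximate chloroplast transit-peptide heuristic.

    Transit peptides are serine/threonine-rich and net positive; this flags
    "predicted" when the N-terminal ``window`` residues have S+T fraction
    > 20% and more K+R than D+E. It is a documented stand-in for dedicated
    targeting predictors and is always to be read as approximate.
    """
    nterm = protein.residues[:window]
    if len(nterm) < window // 2:
        return "unknown"
    st = (nterm.count("S") + nterm.count("T")) / len(nterm)
    positive = nterm.count("K") + nterm.count("R") - nterm.count("D") - nterm.count("E")
    return "predicted" if (st > 0.20 and positive > 0) else "absent"


def classify_tps_type(length_aa: int, transit_peptide: str) -> str:
    """mono if a transit peptide is predicted; sesqui if absent and <= 600 aa."""
    if transit_peptide == "predicted":
        return "mono"
    if transit_peptide == "absent" and length_aa <= MAX_SESQUI_LENGTH:
        return "sesqui"
    return "unknown"


def protein_properties(
    protein: ProteinRecord,
    pka_set: str = "bjellqvist",
    transit_peptide: str | None = None,
) -> ProteinProperties:
    """Full property record for one protein.

    ``transit_peptide`` may be user-supplied ("predicted"/"absent"/"unknown");
    otherwise the heuristic in :func:`predict_transit_peptide` is applied.
    Degenerate (X-containing) proteins get NaN MW.
    """
    if transit_peptide is None:
        transit_peptide = predict_transit_peptide(protein)
    try:
        mw = molecular_weight(protein)
    except ValueError:
        mw = float("nan")
    return ProteinProperties(
        protein_id=protein.protein_id,
        length_aa=protein.length,
        mw_kda=mw,
        pi=isoelectric_point(protein, pka_set=pka_set),
        putative_functional=is_putative_functional(protein),
        transit_peptide=transit_peptide,
        tps_type_hint=classify_tps_type(protein.length, transit_peptide),
    )
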