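"""Physicochemical profiling: molecular weight, net charge, isoelectric
point, and the polarity of the CXC-motif X residue.

Molecular weights default to average isotopic residue masses plus one water,
matching the convention of the common web calculators for whole proteins.
Charge follows the Henderson-Hasselbalch sum over the ionizable side chains
(D, E, C, Y negative; H, K, R positive) and the two termini, with a
Bjellqvist-style pKa set; the table is injectable so alternative schemes can
be swapped in and serialized alongside results.

The CXC X-residue polarity partition is a declared convention:
hydrophilic = {S,T,N,Q,D,E,K,R,H}, hydrophobic = {A,V,L,I,M,F,W,Y}, and
other = {G,P,C,X} (glycine, proline, cysteine and unknowns are deliberately
left out of both camps).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .core_io import STANDARD_AA, ProteinSequence
from .errors import NsltpError
from .motif import CysMotif

HYDROPHILIC = frozenset("STNQDEKRH")
HYDROPHOBIC = frozenset("AVLIMFWY")
POLARITY_OTHER = frozenset("GPCX")

#: average isotopic residue masses (Da); monoisotopic alongside
AVERAGE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONOISOTOPIC_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.01528
WATER_MONO = 18.01056


@dataclass(frozen=True)
class PKaTable:
    """Side-chain and terminal pKa values (pH units)."""

    n_terminus: float = 7.50
    c_terminus: float = 3.55
    D: float = 4.05
    E: float = 4.45
    C: float = 9.00
    Y: float = 10.00
    H: float = 5.98
    K: float = 10.00
    R: float = 12.00

    def __post_init__(self):
        for name in ("n_terminus", "c_terminus", "D", "E", "C", "Y", "H", "K", "R"):
            v = getattr(self, name)
            if not (0.0 < v < 14.0):
                raise ValueError(f"pKa {name}={v} outside (0, 14)")


DEFAULT_PKA = PKaTable()


@dataclass(frozen=True)
class PhyschemReport:
    mw_da: Optional[float]
    pi: float
    charge_ph7: float
    cxc_x: Optional[str] = None
    cxc_polarity: Optional[str] = None


def _res(seq) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else str(seq)


def molecular_weight(seq, mode: str = "average") -> float:
    """Protein mass in daltons: sum of residue masses plus one water."""
    res = _res(seq)
    if not res:
        raise NsltpError("cannot compute mass of an empty sequence")
    table, water = {
        "average": (AVERAGE_MASS, WATER_AVERAGE),
        "monoisotopic": (MONOISOTOPIC_MASS, WATER_MONO),
    }[mode]
    unknown = [i + 1 for i, c in enumerate(res) if c not in table]
    if unknown:
        raise NsltpError(
            f"unknown residue(s) at position(s) {unknown} "
            "(X or gaps have no defined mass)"
        )
    return sum(table[c] for c in res) + water


def net_charge(seq, pH: float, pka: PKaTable = DEFAULT_PKA) -> float:
    """Net charge (elementary charges) at the given pH.

    Positive contributions from the N-terminus, H, K, R; negative from the
    C-terminus, D, E, C, Y.  Unknown residues contribute nothing.
    """
    if not (0.0 <= pH <= 14.0):
        raise ValueError(f"pH {pH} outside [0, 14]")
    res = _res(seq)
    pos = 0.0
    neg = 0.0
    pos += 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    neg += 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    for aa, pk in (("H", pka.H), ("K", pka.K), ("R", pka.R)):
        n = res.count(aa)
        if n:
            pos += n / (1.0 + 10.0 ** (pH - pk))
    for aa, pk in (("D", pka.D), ("E", pka.E), ("C", pka.C), ("Y", pka.Y)):
        n = res.count(aa)
        if n:
            neg += n / (1.0 + 10.0 ** (pk - pH))
    return pos - neg


def isoelectric_point(
    seq, pka: PKaTable = DEFAULT_PKA, tol: float = 1e-4
) -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14].

    With the two termini always ionizable the charge is positive at pH 0 and
    negative at pH 14, so a crossing always exists; if an injected pKa table
    somehow removes it the nearer boundary is returned.
    """
    lo, hi = 0.0, 14.0
    c_lo = net_charge(seq, lo, pka)
    c_hi = net_charge(seq, hi, pka)
    if c_lo <= 0.0:
        return lo
    if c_hi >= 0.0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def polarity_of(residue: str) -> str:
    """Polarity class of one residue: hydrophilic | hydrophobic | other."""
    r = residue.upper()
    if r in HYDROPHILIC:
        return "hydrophilic"
    if r in HYDROPHOBIC:
        return "hydrophobic"
    if r in POLARITY_OTHER:
        return "other"
    raise ValueError(f"unknown residue {residue!r}")


def cxc_polarity(motif: CysMotif) -> str:
    """Polarity of the residue between Cys5 and Cys6."""
    return polarity_of(motif.cxc_x)


def compute_report(
    seq: ProteinSequence,
    motif: Optional[CysMotif] = None,
    pka: PKaTable = DEFAULT_PKA,
) -> PhyschemReport:
    """Mw, pI and charge at pH 7 for one record; CXC polarity if a motif is
    supplied.  Mw is None when the sequence contains unknown residues."""
    try:
        mw = molecular_weight(seq)
    except NsltpError:
        mw = None
    return PhyschemReport(
        mw_da=mw,
        pi=isoelectric_point(seq, pka),
        charge_ph7=net_charge(seq, 7.0, pka),
        cxc_x=motif.cxc_x if motif else None,
        cxc_polarity=cxc_polarity(motif) if motif else None,
    )


def load_pka_config(source) -> PKaTable:
    """Build a pKa table from a key=value file.

    Recognized keys: ``n_terminus``, ``c_terminus`` and the one-letter codes
    D, E, C, Y, H, K, R.  Unknown keys are an error.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    overrides = {}
    valid = {"n_terminus", "c_terminus", "D", "E", "C", "Y", "H", "K", "R"}
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, val = line.partition("=")
        key = key.strip()
        if not sep or key not in valid:
            raise NsltpError(f"unknown pKa config entry {line!r} (line {lineno})")
        overrides[key] = float(val.strip())
    return replace(DEFAULT_PKA, **overrides)


def write_physchem_tsv(rows, dest) -> None:
    """TSV: sequence_id, mw_da, pi, charge_ph7, cxc_x, cxc_polarity."""
    own = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w", encoding="utf-8")
        own = True
    try:
        dest.write("sequence_id\tmw_da\tpi\tcharge_ph7\tcxc_x\tcxc_polarity\n")
        for seq_id, rep in rows:
            mw = f"{rep.mw_da:.2f}" if rep.mw_da is not None else "."
            dest.write(
                f"{seq_id}\t{mw}\t{rep.pi:.3f}\t{rep.charge_ph7:.3f}\t"
                f"{rep.cxc_x or '.'}\t{rep.cxc_polarity or '.'}\n"
            )
    finally:
        if own:
            dest.close()
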