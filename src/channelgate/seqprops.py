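"""Peptide net charge and isoelectric point (Henderson–Hasselbalch).

The four transmembrane helices differ sharply in electrostatics — S4
carries the gating-charge arginines and titrates basic, S3 is the most
acidic — and their isoelectric points summarize this in one number each.
Net charge at a given pH is the Henderson–Hasselbalch sum

    Q(pH) = Σ_basic 1/(1 + 10^(pH − pKa))  −  Σ_acidic 1/(1 + 10^(pKa − pH)),

over sidechain groups (Arg, Lys, His basic; Asp, Glu, Cys, Tyr acidic)
plus the termini when requested.  Q is strictly decreasing in pH, so the
pI — the root of Q — is unique and found by bisection.

Two bundled pKa tables (EMBOSS-style and Lehninger-style) are packaged
as CSV; published pI values for the same peptide differ between tools
precisely because of this table choice, so rank orderings are more
portable than absolute values.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

__all__ = [
    "PeptideSequence",
    "load_pka_table",
    "net_charge_at_pH",
    "isoelectric_point",
    "read_fasta_sequences",
    "BASIC_GROUPS",
    "ACIDIC_GROUPS",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
BASIC_GROUPS = ("K", "R", "H", "Nterm")
ACIDIC_GROUPS = ("D", "E", "C", "Y", "Cterm")


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter peptide; termini ionization optional."""

    residues: str
    include_termini: bool = True

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")

    @property
    def sequence(self) -> str:
        return self.residues.upper()


def load_pka_table(name: str = "emboss") -> dict[str, float]:
    """Load a bundled pKa table ('emboss' or 'lehninger') or a CSV path.

    The CSV has columns ``group,pka`` with groups drawn from the one-letter
    ionizable residues plus ``Nterm``/``Cterm``.
    """
    if name in ("emboss", "lehninger"):
        ref = resources.files("channelgate.data") / f"pka_{name}.csv"
        text = ref.read_text()
    else:
        with open(name) as fh:
            text = fh.read()
    table = {}
    for row in csv.DictReader(text.splitlines()):
        table[row["group"]] = float(row["pka"])
    return table


def net_charge_at_pH(seq: PeptideSequence | str, pH: float,
                     pka_table: dict[str, float] | str = "emboss") -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    if isinstance(seq, str):
        seq = PeptideSequence(seq)
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    if isinstance(pka_table, str):
        pka_table = load_pka_table(pka_table)
    s = seq.sequence
    charge = 0.0
    for group in BASIC_GROUPS:
        if group == "Nterm":
            n = 1 if seq.include_termini else 0
        else:
            n = s.count(group)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pka_table[group]))
    for group in ACIDIC_GROUPS:
        if group == "Cterm":
            n = 1 if seq.include_termini else 0
        else:
            n = s.count(group)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka_table[group] - pH))
    return charge


def isoelectric_point(seq: PeptideSequence | str,
                      pka_table: dict[str, float] | str = "emboss",
                      tol: float = 1e-9) -> float:
    """pH at which the peptide's net charge is zero, by bisection on [0, 14].

    The charge curve is strictly decreasing, so the root is unique.  A
    peptide whose charge does not change sign over [0, 14] (e.g. only
    basic or only acidic groups) gets the boundary pH with a warning.
    """
    if isinstance(seq, str):
        seq = PeptideSequence(seq)
    if isinstance(pka_table, str):
        pka_table = load_pka_table(pka_table)
    lo, hi = 0.0, 14.0
    q_lo = net_charge_at_pH(seq, lo, pka_table)
    q_hi = net_charge_at_pH(seq, hi, pka_table)
    if q_lo <= 0.0:
        warnings.warn("net charge non-positive over the whole pH range; "
                      "pI reported as boundary 0")
        return lo
    if q_hi >= 0.0:
        warnings.warn("net charge non-negative over the whole pH range; "
                      "pI reported as boundary 14")
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge_at_pH(seq, mid, pka_table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def read_fasta_sequences(path, include_termini: bool = True
                         ) -> dict[str, PeptideSequence]:
    """Read peptide sequences from FASTA, keyed by record id."""
    out = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id] = PeptideSequence(str(record.seq),
                                         include_termini=include_termini)
    return out
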