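"""Lipid shorthand nomenclature, molecular formulas, monoisotopic masses and adduct m/z.

The library is the reference against which observed features are annotated.
Species are named in shorthand notation at one of three resolution levels:
sum composition (``PE(38:4)``), acyl combination (``PE(18:0/20:4)``) or, for
free fatty acids, positional isomer (``FA(18:1n-9)``).  Ether
glycerophospholipids carry an ``O-`` (plasmanyl) or ``P-`` (plasmenyl) prefix
on the first chain; a plasmenyl species is isobaric with the plasmanyl species
carrying one more double bond, which ESI-MS alone cannot distinguish.

Molecular formulas are assembled from building blocks (glycerol, fatty
acid/alcohol chains, phospho-headgroups, cholesterol, the d18:1 sphingoid
base), removing one H2O per condensation bond.  Element monoisotopic masses
are pinned in a versioned constants table so results are bit-stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FAMILIES",
    "MolecularFormula",
    "Chain",
    "LipidSpecies",
    "AdductSpec",
    "ADDUCTS",
    "DEFAULT_FAMILY_ADDUCTS",
    "LipidParseError",
    "parse_shorthand",
    "molecular_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "build_library",
    "write_library",
    "read_library",
]

# Monoisotopic element masses in Da (IUPAC/CODATA); pinned for bit-stability.
ELEMENT_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
}

PROTON_MASS = 1.007276466  # Da, mass of H+
ELECTRON_MASS = 0.00054857990907  # Da

FAMILIES = (
    "FA", "LPC", "PC", "etherPC", "LPE", "PE", "etherPE", "PG",
    "LPI", "PI", "LPS", "PS", "DG", "TG", "sterol", "CE", "Cer", "SM",
)

#: number of radyl chains per family (sterol has none)
_N_CHAINS = {
    "FA": 1, "LPC": 1, "LPE": 1, "LPI": 1, "LPS": 1, "CE": 1,
    "PC": 2, "etherPC": 2, "PE": 2, "etherPE": 2, "PG": 2, "PI": 2,
    "PS": 2, "DG": 2, "TG": 3, "Cer": 2, "SM": 2, "sterol": 0,
}

_GPL_HEAD = {"PC": "PC", "etherPC": "PC", "LPC": "PC",
             "PE": "PE", "etherPE": "PE", "LPE": "PE",
             "PG": "PG", "PI": "PI", "LPI": "PI",
             "PS": "PS", "LPS": "PS"}


class LipidParseError(ValueError):
    """Malformed lipid shorthand; carries the character position of failure."""

    def __init__(self, text: str, pos: int, why: str):
        self.text, self.pos, self.why = text, pos, why
        super().__init__(f"cannot parse {text!r} at position {pos}: {why}")


@dataclass(frozen=True)
class MolecularFormula:
    """Element→count map over C, H, N, O, P."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {e: int(c) for e, c in self.counts.items() if c != 0}
        for e, c in clean.items():
            if e not in ELEMENT_MASS:
                raise ValueError(f"unknown element {e!r}")
            if c < 0:
                raise ValueError(f"negative count for {e}: {c}")
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self.counts)
        for e, c in other.counts.items():
            out[e] = out.get(e, 0) + c
        return MolecularFormula(out)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self.counts)
        for e, c in other.counts.items():
            out[e] = out.get(e, 0) - c
        return MolecularFormula(out)  # validation rejects negatives

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({e: c * k for e, c in self.counts.items()})

    def hill(self) -> str:
        """Hill notation (C, H, then alphabetical)."""
        order = ["C", "H"] + sorted(e for e in self.counts if e not in ("C", "H"))
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e
            for e in order if e in self.counts
        )


def _F(**counts: int) -> MolecularFormula:
    return MolecularFormula(counts)


_H2O = _F(H=2, O=1)
_H2 = _F(H=2)
_GLYCEROL = _F(C=3, H=8, O=3)
_CHOLESTEROL = _F(C=27, H=46, O=1)
_SPHINGOSINE = _F(C=18, H=37, N=1, O=2)  # d18:1 sphingoid base

# phospho-headgroup = head alcohol + H3PO4 − H2O
_HEADGROUPS = {
    "PC": _F(C=5, H=14, N=1, O=4, P=1),  # phosphocholine
    "PE": _F(C=2, H=8, N=1, O=4, P=1),   # phosphoethanolamine
    "PG": _F(C=3, H=9, O=6, P=1),        # phosphoglycerol
    "PI": _F(C=6, H=13, O=9, P=1),       # phosphoinositol
    "PS": _F(C=3, H=8, N=1, O=6, P=1),   # phosphoserine
}


def fatty_acid_formula(carbons: int, double_bonds: int) -> MolecularFormula:
    """CnH(2n−2d)O2 — a free fatty acid with ``d`` C=C bonds."""
    if carbons <= 0:
        raise ValueError("fatty acid needs carbons > 0")
    return _F(C=carbons, H=2 * carbons - 2 * double_bonds, O=2)


def fatty_alcohol_formula(carbons: int, double_bonds: int) -> MolecularFormula:
    """CnH(2n+2−2d)O — the plasmanyl (O-alkyl) chain precursor."""
    if carbons <= 0:
        raise ValueError("fatty alcohol needs carbons > 0")
    return _F(C=carbons, H=2 * carbons + 2 - 2 * double_bonds, O=1)


@dataclass(frozen=True)
class Chain:
    """One radyl chain: carbons, double bonds and the linkage chemistry."""

    carbons: int
    double_bonds: int
    link: str = "acyl"  # acyl | alkyl (O-) | alkenyl (P-) | sphingoid (d)

    def __post_init__(self):
        if self.carbons <= 0:
            raise ValueError("chain carbons must be > 0")
        if self.double_bonds < 0:
            raise ValueError("chain double bonds must be >= 0")
        if self.link not in ("acyl", "alkyl", "alkenyl", "sphingoid"):
            raise ValueError(f"unknown chain link {self.link!r}")

    def shorthand(self) -> str:
        prefix = {"acyl": "", "alkyl": "O-", "alkenyl": "P-", "sphingoid": "d"}[self.link]
        return f"{prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid identified by family, total carbons/double bonds and linkage.

    ``chains`` is optional: ``None`` means sum-composition resolution.  For
    free fatty acids, ``n_position`` retains an ``n-x`` isomer annotation.
    """

    family: str
    total_carbons: int
    total_double_bonds: int
    linkage: str = "ester"  # ester | plasmanyl | plasmenyl | ether (unresolved)
    chains: tuple[Chain, ...] | None = None
    n_position: str | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown lipid family {self.family!r}")
        if self.family != "sterol" and self.total_carbons <= 0:
            raise ValueError("total carbons must be > 0")
        if self.total_double_bonds < 0:
            raise ValueError("double bonds must be >= 0")
        if self.linkage != "ester" and self.family not in ("etherPC", "etherPE"):
            raise ValueError(
                f"non-ester linkage {self.linkage!r} only valid for etherPC/etherPE"
            )
        if self.family in ("etherPC", "etherPE") and self.linkage == "ester":
            raise ValueError(f"{self.family} requires an ether linkage")
        if self.chains is not None:
            nc = sum(c.carbons for c in self.chains)
            nd = sum(c.double_bonds for c in self.chains)
            if (nc, nd) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    f"chains sum to {nc}:{nd}, species says "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )

    @property
    def shorthand(self) -> str:
        if self.family == "sterol":
            return "sterol"
        head = _GPL_HEAD.get(self.family, self.family)
        if self.chains is not None:
            body = "/".join(c.shorthand() for c in self.chains)
            if self.family == "FA" and self.n_position:
                body += self.n_position
        else:
            prefix = ""
            if self.family in ("etherPC", "etherPE"):
                prefix = {"plasmanyl": "O-", "plasmenyl": "P-", "ether": "O-"}[self.linkage]
            body = f"{prefix}{self.total_carbons}:{self.total_double_bonds}"
            if self.n_position:
                body += self.n_position
        return f"{head}({body})"

    def is_pufa_containing(self) -> bool:
        """At least one chain (or the sum composition) carries >=2 double bonds."""
        if self.chains is not None:
            return any(c.double_bonds >= 2 for c in self.chains if c.link != "sphingoid")
        return self.total_double_bonds >= 2


_CHAIN_RE = re.compile(r"(O-|P-|d)?(\d+):(\d+)(n-\d+)?")


def parse_shorthand(text: str) -> LipidSpecies:
    """Parse shorthand like ``PC(16:0/18:1)``, ``PE(O-38:4)`` or ``FA(18:1n-9)``.

    Raises :class:`LipidParseError` with the position of the first offending
    character on malformed input.
    """
    if not text:
        raise LipidParseError(text, 0, "empty string")
    s = text.strip()
    if s in ("sterol", "cholesterol", "ST"):
        return LipidSpecies("sterol", 27, 1)
    m = re.match(r"([A-Za-z]+)\(", s)
    if not m:
        raise LipidParseError(text, 0, "expected 'FAMILY(' prefix")
    head = m.group(1)
    if not s.endswith(")"):
        raise LipidParseError(text, len(s), "unbalanced parenthesis")
    body = s[m.end():-1]
    if not body:
        raise LipidParseError(text, m.end(), "empty composition")

    parts = body.split("/")
    chains: list[Chain] = []
    pos = m.end()
    for part in parts:
        cm = _CHAIN_RE.fullmatch(part)
        if not cm:
            raise LipidParseError(text, pos, f"bad chain token {part!r}")
        prefix, c, d, ntag = cm.group(1), int(cm.group(2)), int(cm.group(3)), cm.group(4)
        link = {"O-": "alkyl", "P-": "alkenyl", "d": "sphingoid", None: "acyl"}[prefix]
        chains.append(Chain(c, d, link))
        if ntag and not (head == "FA" and len(parts) == 1):
            raise LipidParseError(text, pos, "n-position tag only valid on FA")
        pos += len(part) + 1

    ether_prefix = next((c.link for c in chains if c.link in ("alkyl", "alkenyl")), None)
    if head in ("PC", "PE") and ether_prefix:
        family = "etherPC" if head == "PC" else "etherPE"
        linkage = "plasmanyl" if ether_prefix == "alkyl" else "plasmenyl"
    elif head in FAMILIES:
        family, linkage = head, "ester"
    else:
        raise LipidParseError(text, 0, f"unknown family {head!r}")
    if family in ("etherPC", "etherPE") and not ether_prefix:
        raise LipidParseError(text, m.end(), f"{family} requires O- or P- prefix")

    n_chains_expected = _N_CHAINS[family]
    total_c = sum(c.carbons for c in chains)
    total_d = sum(c.double_bonds for c in chains)
    ntag = None
    if head == "FA":
        fm = _CHAIN_RE.fullmatch(parts[0])
        ntag = fm.group(4)

    if len(parts) == 1 and n_chains_expected > 1:
        # sum composition, e.g. PE(38:4)
        return LipidSpecies(family, total_c, total_d, linkage, None)
    if len(chains) != n_chains_expected:
        raise LipidParseError(
            text, m.end(),
            f"{family} expects {n_chains_expected} chains, got {len(chains)}",
        )
    return LipidSpecies(family, total_c, total_d, linkage, tuple(chains), ntag)


def molecular_formula(species: LipidSpecies) -> MolecularFormula:
    """Assemble the neutral molecular formula from building blocks.

    One H2O is removed per condensation bond (ester, ether, amide or the
    headgroup phosphodiester), so e.g. a diacyl glycerophospholipid is
    glycerol + 2 fatty acids + phospho-headgroup − 3 H2O.
    """
    fam = species.family
    N, D = species.total_carbons, species.total_double_bonds

    if fam == "sterol":
        return _CHOLESTEROL
    if fam == "FA":
        return fatty_acid_formula(N, D)
    if fam == "CE":
        return _CHOLESTEROL + fatty_acid_formula(N, D) - _H2O

    def acyl_block(k: int) -> MolecularFormula:
        # k acyl chains with N carbons and D double bonds in total
        return _F(C=N, H=2 * N - 2 * D, O=2 * k)

    if fam in ("DG", "TG"):
        k = _N_CHAINS[fam]
        return _GLYCEROL + acyl_block(k) - _H2O * k
    if fam in ("Cer", "SM"):
        # total composition includes the d18:1 base (18 carbons, 1 double bond)
        n_acyl, d_acyl = N - 18, D - 1
        if n_acyl <= 0 or d_acyl < 0:
            raise ValueError(f"{species.shorthand}: composition below the d18:1 base")
        amide = _SPHINGOSINE + fatty_acid_formula(n_acyl, d_acyl) - _H2O
        if fam == "Cer":
            return amide
        return amide + _HEADGROUPS["PC"] - _H2O

    head = _GPL_HEAD.get(fam)
    if head is None:  # pragma: no cover - families above are exhaustive
        raise ValueError(f"no formula template for family {fam!r}")
    k = _N_CHAINS[fam]
    if fam in ("etherPC", "etherPE"):
        # one O-alkyl (or O-alkenyl) chain, one acyl chain
        radyl = _F(C=N, H=2 * N + 2 - 2 * D, O=3)
        if species.linkage == "plasmenyl":
            radyl = radyl - _H2
        return _GLYCEROL + radyl + _HEADGROUPS[head] - _H2O * (k + 1)
    return _GLYCEROL + acyl_block(k) + _HEADGROUPS[head] - _H2O * (k + 1)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da: Σ count × element mass."""
    return sum(ELEMENT_MASS[e] * c for e, c in formula.counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """An ESI adduct: name, polarity, mass shift (Da, electron-corrected), charge."""

    name: str
    polarity: str  # 'pos' | 'neg'
    mass_shift: float
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if (self.charge > 0) != (self.polarity == "pos"):
            raise ValueError(f"{self.name}: polarity inconsistent with charge sign")


ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M+H]+", "pos", PROTON_MASS, 1),
        AdductSpec("[M+Na]+", "pos", 22.9897692809 - ELECTRON_MASS, 1),
        AdductSpec("[M+NH4]+", "pos",
                   ELEMENT_MASS["N"] + 4 * ELEMENT_MASS["H"] - ELECTRON_MASS, 1),
        AdductSpec("[M-H]-", "neg", -PROTON_MASS, -1),
        AdductSpec("[M+HCOO]-", "neg",
                   ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["O"] + ELEMENT_MASS["H"]
                   + ELECTRON_MASS, -1),
    ]
}

#: default adducts observed per family (user-overridable in build_library)
DEFAULT_FAMILY_ADDUCTS: dict[str, tuple[str, ...]] = {
    "PC": ("[M+H]+",), "LPC": ("[M+H]+",), "etherPC": ("[M+H]+",),
    "SM": ("[M+H]+",), "Cer": ("[M+H]+",), "sterol": ("[M+H]+",),
    "DG": ("[M+NH4]+",), "TG": ("[M+NH4]+",), "CE": ("[M+NH4]+",),
    "FA": ("[M-H]-",), "LPE": ("[M-H]-",), "PE": ("[M-H]-",),
    "etherPE": ("[M-H]-",), "PG": ("[M-H]-",), "LPI": ("[M-H]-",),
    "PI": ("[M-H]-",), "LPS": ("[M-H]-",), "PS": ("[M-H]-",),
}


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """m/z = (M + shift) / |charge| for the given adduct."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be > 0")
    return (neutral_mass + adduct.mass_shift) / abs(adduct.charge)


def build_library(
    species: Iterable[LipidSpecies],
    family_adducts: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Tabulate theoretical adduct m/z for a species list.

    Returns a DataFrame with columns ``shorthand, family, formula,
    neutral_mass, adduct, polarity, mz`` — one row per (species, adduct).
    """
    fam_adducts = dict(DEFAULT_FAMILY_ADDUCTS)
    if family_adducts:
        fam_adducts.update(family_adducts)
    rows = []
    for sp in species:
        f = molecular_formula(sp)
        mass = monoisotopic_mass(f)
        for name in fam_adducts[sp.family]:
            add = ADDUCTS[name]
            rows.append(
                dict(shorthand=sp.shorthand, family=sp.family, formula=f.hill(),
                     neutral_mass=mass, adduct=name, polarity=add.polarity,
                     mz=adduct_mz(mass, add))
            )
    return pd.DataFrame(rows)


def write_library(library: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# lipidfc library seed={seed}\n")
        library.to_csv(fh, sep="\t", index=False)


def read_library(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
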