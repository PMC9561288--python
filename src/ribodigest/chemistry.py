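"""Monoisotopic mass chemistry for (modified) RNA oligonucleotides.

All masses are neutral monoisotopic masses in daltons.  Oligonucleotide
masses are assembled from nucleoside elemental compositions joined by
phosphodiester condensation (each internucleotide linkage adds HPO3 and
removes H2O), plus terminal-group or 5'-cap deltas.  This is the mass
model that underlies every deconvoluted-MS1 comparison in the package:
charge deconvolution happens upstream on the instrument side, so the
package only ever sees and predicts neutral masses.

"Same mass" questions (isomer detection, uniquely-mappable products) are
decided on exact integer elemental compositions, never on floating-point
equality: pseudouridine is a C-glycoside isomer of uridine and must
compare equal by construction.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

# Monoisotopic atomic masses (CODATA/AME-derived standard table).
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

MASS_ATOL = 1e-6  # internal assertion tolerance, Da


def parse_formula(formula: str | Mapping[str, int]) -> Counter:
    """Parse 'C9H12N2O6'-style formulas into element->count Counters."""
    if isinstance(formula, Mapping):
        counts = Counter({el: int(n) for el, n in formula.items() if n})
    else:
        counts = Counter()
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"malformed formula {formula!r} at offset {pos}")
            pos = match.end()
            el, num = match.group(1), match.group(2)
            counts[el] += int(num) if num else 1
        if pos != len(formula):
            raise ValueError(f"malformed formula {formula!r} at offset {pos}")
    for el, n in counts.items():
        if el not in ATOMIC_MASS:
            raise ValueError(f"unknown element symbol {el!r}")
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
    return counts


def formula_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, in Da.

    String formulas must have non-negative counts; mapping inputs may
    carry signed counts (composition deltas such as a cyclic phosphate,
    which is one water lighter than a linear monophosphate).
    """
    if isinstance(formula, Mapping):
        for el in formula:
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
        return sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    counts = parse_formula(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


def fadd(*formulas: Mapping[str, int]) -> Counter:
    """Signed sum of compositions (Counter arithmetic drops negatives;
    this keeps them, which deltas require)."""
    out: Counter = Counter()
    for f in formulas:
        for el, n in f.items():
            out[el] += n
    return Counter({el: n for el, n in out.items() if n})


def fscale(formula: Mapping[str, int], k: int) -> Counter:
    return Counter({el: n * k for el, n in formula.items() if n * k})


def fsub(a: Mapping[str, int], b: Mapping[str, int]) -> Counter:
    return fadd(a, fscale(b, -1))


WATER = parse_formula("H2O")
HPO3 = parse_formula("HPO3")
CH2 = parse_formula("CH2")

WATER_MASS = formula_mass(WATER)
HPO3_MASS = formula_mass(HPO3)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed parts-per-million mass error relative to the theoretical mass."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# Monomers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonomerDef:
    """One registered (possibly modified) ribonucleoside.

    ``formula`` is the elemental composition of the free nucleoside;
    ``base`` is the canonical identity (A/C/G/U) used for enzyme-site
    pattern matching; ``ribose_methylated`` marks 2'-O-methyl residues,
    which block ribonucleases that proceed through a 2',3'-cyclic
    phosphate intermediate.
    """

    code: str
    base: str
    formula: Counter
    ribose_methylated: bool = False

    @property
    def mass(self) -> float:
        return formula_mass(self.formula)


def _monomer(code: str, base: str, formula: str, ribose_methylated: bool = False) -> MonomerDef:
    return MonomerDef(code, base, parse_formula(formula), ribose_methylated)


#: Built-in monomer table: the four canonical ribonucleosides plus the
#: modified uridines relevant to IVT mRNA work (N1-methylpseudouridine,
#: 5-methoxyuridine, pseudouridine, 2'-O-methyluridine, 5-methyluridine,
#: 5,2'-O-dimethyluridine, 4-thiouridine, dihydrouridine).
BUILTIN_MONOMERS: dict[str, MonomerDef] = {
    m.code: m
    for m in (
        _monomer("A", "A", "C10H13N5O4"),
        _monomer("C", "C", "C9H13N3O5"),
        _monomer("G", "G", "C10H13N5O5"),
        _monomer("U", "U", "C9H12N2O6"),
        _monomer("psi", "U", "C9H12N2O6"),        # pseudouridine, isomer of U
        _monomer("m1psi", "U", "C10H14N2O6"),     # N1-methylpseudouridine
        _monomer("mo5U", "U", "C10H14N2O7"),      # 5-methoxyuridine
        _monomer("m5U", "U", "C10H14N2O6"),       # 5-methyluridine
        _monomer("Um", "U", "C10H14N2O6", True),  # 2'-O-methyluridine
        _monomer("m5Um", "U", "C11H16N2O6", True),
        _monomer("s4U", "U", "C9H12N2O5S"),       # 4-thiouridine
        _monomer("D", "U", "C9H14N2O6"),          # dihydrouridine
    )
}

#: Unicode spellings accepted as input aliases.
MONOMER_ALIASES = {"Ψ": "psi", "m1Ψ": "m1psi"}


def resolve_code(code: str) -> str:
    return MONOMER_ALIASES.get(code, code)


def load_monomers(path: str) -> dict[str, MonomerDef]:
    """Load a monomer table from YAML (code -> {formula, base, ribose_methylated}).

    Entries extend/override the built-in table.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = dict(BUILTIN_MONOMERS)
    for code, entry in raw.items():
        table[code] = MonomerDef(
            code=code,
            base=entry.get("base", "U"),
            formula=parse_formula(entry["formula"]),
            ribose_methylated=bool(entry.get("ribose_methylated", False)),
        )
    return table


# ---------------------------------------------------------------------------
# Terminal groups and cap adducts
# ---------------------------------------------------------------------------

#: Composition delta of each terminal-group kind relative to a hydroxyl
#: terminus.  cyclic_phosphate (2',3'-cyclic) is only meaningful at the
#: 3' end and is one water lighter than a linear monophosphate.
TERMINAL_DELTAS: dict[str, Counter] = {
    "hydroxyl": Counter(),
    "monophosphate": Counter(HPO3),
    "cyclic_phosphate": fsub(HPO3, WATER),
    "diphosphate": Counter({"H": 2, "P": 2, "O": 6}),
    "triphosphate": Counter({"H": 3, "P": 3, "O": 9}),
}


@dataclass(frozen=True)
class TerminalGroup:
    end: str  # "five_prime" | "three_prime"
    kind: str  # key of TERMINAL_DELTAS

    def __post_init__(self):
        if self.end not in ("five_prime", "three_prime"):
            raise ValueError(f"bad end {self.end!r}")
        if self.kind not in TERMINAL_DELTAS:
            raise ValueError(f"unknown terminal-group kind {self.kind!r}")
        if self.kind == "cyclic_phosphate" and self.end != "three_prime":
            raise ValueError("cyclic phosphate is only valid at the 3' end")

    @property
    def delta(self) -> Counter:
        return TERMINAL_DELTAS[self.kind]


def five_prime(kind: str = "hydroxyl") -> TerminalGroup:
    return TerminalGroup("five_prime", kind)


def three_prime(kind: str = "hydroxyl") -> TerminalGroup:
    return TerminalGroup("three_prime", kind)


# m7G nucleoside = guanosine + CH2; the cap is joined to the mRNA 5'-OH
# through a triphosphate bridge: delta = m7G nucleoside + 3xHPO3 - H2O.
_M7G_NUCLEOSIDE = parse_formula("C11H15N5O5")
_M7GPPP = fsub(fadd(_M7G_NUCLEOSIDE, Counter({"H": 3, "P": 3, "O": 9})), WATER)


@dataclass(frozen=True)
class CapAdduct:
    """A 5'-terminal adduct searched during cap analysis.

    ``delta`` is the composition added relative to a plain 5'-hydroxyl
    terminus.  The dimethyl variant models an m7GpppNm cap: the
    cap-adjacent 2'-O-methyl is folded into the adduct delta (equivalent
    by mass to a monomer substitution, simpler to configure).
    """

    name: str
    delta: Counter

    @property
    def mass_delta(self) -> float:
        return formula_mass(self.delta)


#: The variable 5'-terminal additions searched in cap analysis: mono-,
#: di- and triphosphate, methylguanosine triphosphate (m7Gppp) and
#: dimethyl (m7Gppp plus a cap-adjacent 2'-O-methyl, the m7GpppNm cap).
BUILTIN_CAP_ADDUCTS: dict[str, CapAdduct] = {
    a.name: a
    for a in (
        CapAdduct("none", Counter()),
        CapAdduct("p", Counter(HPO3)),
        CapAdduct("pp", Counter({"H": 2, "P": 2, "O": 6})),
        CapAdduct("ppp", Counter({"H": 3, "P": 3, "O": 9})),
        CapAdduct("m7Gppp", Counter(_M7GPPP)),
        CapAdduct("m7Gppp_2OMe", fadd(_M7GPPP, CH2)),
    )
}


# ---------------------------------------------------------------------------
# Substitution profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionProfile:
    """Transcript-wide replacement of canonical monomers (e.g. all U -> m1psi).

    The mapping must be total on {A, C, G, U}; unspecified bases map to
    themselves.
    """

    mapping: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "SubstitutionProfile":
        resolved = {}
        for src, dst in mapping.items():
            if src not in "ACGU":
                raise ValueError(f"substitution source {src!r} is not a canonical base")
            resolved[src] = resolve_code(dst)
        return cls(tuple(sorted(resolved.items())))

    def apply(self, codes: Sequence[str]) -> tuple[str, ...]:
        table = dict(self.mapping)
        return tuple(table.get(c, c) for c in codes)

    @classmethod
    def identity(cls) -> "SubstitutionProfile":
        return cls(())


# ---------------------------------------------------------------------------
# Oligonucleotide masses
# ---------------------------------------------------------------------------

def _lookup(code: str, monomers: Mapping[str, MonomerDef]) -> MonomerDef:
    code = resolve_code(code)
    try:
        return monomers[code]
    except KeyError:
        raise KeyError(f"unregistered monomer code {code!r}") from None


def oligo_formula(
    sequence: Sequence[str],
    five_prime_group: TerminalGroup | CapAdduct | None = None,
    three_prime_group: TerminalGroup | None = None,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> Counter:
    """Elemental composition of a linear oligoribonucleotide.

    Nucleosides joined by (n-1) phosphodiester linkages (+HPO3, -H2O
    each), plus terminal deltas.  Default termini are hydroxyl at both
    ends.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    parts = [_lookup(code, monomers).formula for code in sequence]
    parts.append(fscale(HPO3, n - 1))
    parts.append(fscale(WATER, -(n - 1)))
    if five_prime_group is not None:
        if isinstance(five_prime_group, TerminalGroup) and five_prime_group.end != "five_prime":
            raise ValueError("five_prime_group must be a 5' group")
        parts.append(five_prime_group.delta)
    if three_prime_group is not None:
        if three_prime_group.end != "three_prime":
            raise ValueError("three_prime_group must be a 3' group")
        parts.append(three_prime_group.delta)
    return fadd(*parts)


def oligo_mass(
    sequence: Sequence[str],
    five_prime_group: TerminalGroup | CapAdduct | None = None,
    three_prime_group: TerminalGroup | None = None,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> float:
    """Neutral monoisotopic mass (Da) of a linear oligoribonucleotide."""
    return formula_mass(oligo_formula(sequence, five_prime_group, three_prime_group, monomers))


def composition_key(
    sequence: Sequence[str],
    five_prime_group: TerminalGroup | CapAdduct | None = None,
    three_prime_group: TerminalGroup | None = None,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> tuple[tuple[str, int], ...]:
    """Exact-composition identity key (element, count) for "same mass" tests."""
    total = oligo_formula(sequence, five_prime_group, three_prime_group, monomers)
    return tuple(sorted((el, n) for el, n in total.items() if n))


# ---------------------------------------------------------------------------
# Fragment ions (annotation aid for MS/MS spectra)
# ---------------------------------------------------------------------------

FRAGMENT_SERIES = ("a-B", "a", "b", "c", "d", "w", "x", "y", "z")

_RIBOSE_LESS_WATER = parse_formula("C5H8O4")  # nucleoside - neutral base


def _base_formula(mono: MonomerDef) -> Counter:
    """Neutral nucleobase composition (BH) of a monomer."""
    sugar = Counter(_RIBOSE_LESS_WATER)
    if mono.ribose_methylated:
        sugar = fadd(sugar, CH2)
    return fsub(mono.formula, sugar)


def fragment_ion_masses(
    sequence: Sequence[str],
    series: Iterable[str],
    five_prime_group: TerminalGroup | CapAdduct | None = None,
    three_prime_group: TerminalGroup | None = None,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[tuple[str, int, float]]:
    """Neutral backbone fragment masses in the standard a/b/c/d, w/x/y/z
    nucleic-acid nomenclature (plus a-B, base loss from the a ion).

    5' series (a, b, c, d) keep the parent 5' terminus; 3' series
    (w, x, y, z) keep the parent 3' terminus.  For an n-mer each series
    has n-1 members.  The complementary relation c_i + y_(n-i) =
    precursor + H2O holds by construction.
    """
    seq = [resolve_code(c) for c in sequence]
    if len(seq) < 2:
        raise ValueError("fragment ions require length >= 2")
    wanted = list(series)
    for s in wanted:
        if s not in FRAGMENT_SERIES:
            raise ValueError(f"unknown fragment series {s!r}")

    n = len(seq)
    out: list[tuple[str, int, float]] = []
    # prefix b_i: 5' portion (i residues) with a 3'-OH, parent 5' terminus
    for i in range(1, n):
        b = oligo_formula(seq[:i], five_prime_group, None, monomers)
        for s in wanted:
            if s == "b":
                frag = b
            elif s == "a":
                frag = fsub(b, WATER)
            elif s == "a-B":
                frag = fsub(fsub(b, WATER), _base_formula(_lookup(seq[i - 1], monomers)))
            elif s == "c":
                frag = fadd(b, HPO3)
            elif s == "d":
                frag = fadd(b, HPO3, WATER)
            else:
                continue
            out.append((s, i, formula_mass(frag)))
    # suffix y_j: 3' portion (j residues) with a 5'-OH, parent 3' terminus
    for j in range(1, n):
        y = oligo_formula(seq[n - j:], None, three_prime_group, monomers)
        for s in wanted:
            if s == "y":
                frag = y
            elif s == "w":
                frag = fadd(y, HPO3)
            elif s == "x":
                frag = fadd(y, fsub(HPO3, WATER))
            elif s == "z":
                frag = fsub(y, WATER)
            else:
                continue
            out.append((s, j, formula_mass(frag)))
    return out
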