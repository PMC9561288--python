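"""In-silico endoribonuclease digestion of RNA transcripts.

An :class:`EnzymeSpec` describes where an endoribonuclease cleaves the
phosphodiester backbone as a set of sequence contexts around the
scissile bond, how modified nucleotides affect cleavage, and the
terminal chemistry of the products it releases.  Digestion operates on
tuples of monomer codes (see :mod:`ribodigest.chemistry`), so fully
substituted transcripts (e.g. all U replaced by m1psi) digest under the
enzyme's modification-sensitivity rules automatically.

Coordinates are 0-based, half-open.  A cut position is a bond index
``b`` meaning the bond between residues ``b-1`` and ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml

from . import chemistry
from .chemistry import (
    BUILTIN_MONOMERS,
    CapAdduct,
    MonomerDef,
    TerminalGroup,
    composition_key,
    oligo_mass,
    resolve_code,
)

#: Cleavability levels for modified nucleotides at a cut context.
#: "reduced" sites are treated as cleavable for site finding (the
#: quantitative rate difference is not modelled); "none" blocks the cut.
CLEAVABILITY = ("full", "reduced", "none")


@dataclass(frozen=True)
class CutContext:
    """One cleavage context: the bond between ``upstream`` and
    ``downstream`` is cut when both patterns match.

    Patterns are tuples of sets of canonical bases (A/C/G/U), read 5'->3'
    and anchored at the bond.  E.g. hRNase 4 (cleaves UpR) has
    ``upstream=({U},), downstream=({A,G},)``; MazF (cleaves 5' of ACA)
    has ``upstream=(), downstream=({A},{C},{A})``.
    """

    upstream: tuple[frozenset[str], ...]
    downstream: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.upstream and not self.downstream:
            raise ValueError("a cut context needs at least one pattern position")


def _ctx(upstream: Sequence[str], downstream: Sequence[str]) -> CutContext:
    return CutContext(
        tuple(frozenset(p) for p in upstream),
        tuple(frozenset(p) for p in downstream),
    )


@dataclass(frozen=True)
class EnzymeSpec:
    """Cleavage specificity of one endoribonuclease.

    ``product_termini`` gives the default (5', 3') terminal-group kinds
    of internal digestion products; transcript-terminal products inherit
    the molecule's own ends on the uncut side.
    """

    name: str
    contexts: tuple[CutContext, ...]
    cleavable_mods: Mapping[str, str] = field(default_factory=dict)
    product_termini: tuple[str, str] = ("hydroxyl", "monophosphate")

    def cleavability(self, code: str) -> str:
        code = resolve_code(code)
        if code in ("A", "C", "G", "U"):
            return "full"
        return self.cleavable_mods.get(code, "full")


# Built-in enzymes.
#
# hRNase 4 cleaves 3' of uridine when the next residue is a purine
# (UpA / UpG); uridine nucleobase modifications (psi, m1psi, D, and with
# reduced efficiency s4U, m5U) remain cleavable, whereas 2'-O-methylated
# uridines (Um, m5Um) block the 2',3'-cyclic intermediate and are never
# cut.  mo5U-substituted transcripts digest normally.  The shipped
# default terminal chemistry is the hRNase 4 + T4 PNK workflow
# (uniformly hydroxylated products); see `with_termini` for the
# PNK-free phosphorylated species.
HRNASE4 = EnzymeSpec(
    name="hRNase4",
    contexts=(_ctx(["U"], ["AG"]),),
    cleavable_mods={
        "psi": "full",
        "m1psi": "full",
        "mo5U": "full",
        "D": "full",
        "s4U": "reduced",
        "m5U": "reduced",
        "Um": "none",
        "m5Um": "none",
    },
    product_termini=("hydroxyl", "hydroxyl"),
)

# RNase T1 cleaves 3' of guanosine, leaving 3'-phosphorylated products.
RNASET1 = EnzymeSpec(
    name="RNaseT1",
    contexts=(_ctx(["G"], []),),
    product_termini=("hydroxyl", "monophosphate"),
)

# MC1 cleaves 5' of uridine (base recognition on the downstream U:
# m1psi blocks it, ribose methylation does not).
MC1 = EnzymeSpec(
    name="MC1",
    contexts=(_ctx([], ["U"]),),
    cleavable_mods={
        "psi": "full",
        "Um": "full",
        "m5Um": "full",
        "m5U": "full",
        "m1psi": "none",
    },
    product_termini=("hydroxyl", "monophosphate"),
)

# Cusativin: C-specific (plain CpN model; the consecutive-C refinement
# can be expressed in a user config).
CUSATIVIN = EnzymeSpec(
    name="Cusativin",
    contexts=(_ctx(["C"], []),),
    product_termini=("hydroxyl", "monophosphate"),
)

# Colicin E5 cleaves between G and U of GpU.
COLICIN_E5 = EnzymeSpec(
    name="ColicinE5",
    contexts=(_ctx(["G"], ["U"]),),
    product_termini=("hydroxyl", "monophosphate"),
)

# E. coli MazF cleaves within ACA, 5' of the first A.
MAZF = EnzymeSpec(
    name="MazF",
    contexts=(_ctx([], ["A", "C", "A"]),),
    product_termini=("hydroxyl", "monophosphate"),
)

BUILTIN_ENZYMES: dict[str, EnzymeSpec] = {
    e.name: e for e in (HRNASE4, RNASET1, MC1, CUSATIVIN, COLICIN_E5, MAZF)
}


def get_enzyme(name: str) -> EnzymeSpec:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        known = ", ".join(sorted(BUILTIN_ENZYMES))
        raise KeyError(f"unknown enzyme {name!r} (built-ins: {known})") from None


def with_termini(enzyme: EnzymeSpec, five: str, three: str) -> EnzymeSpec:
    """Same specificity, different product terminal chemistry (e.g.
    hRNase 4 without T4 PNK leaves 3'-phosphorylated / cyclic species)."""
    return replace(enzyme, product_termini=(five, three))


def load_enzymes(path: str) -> dict[str, EnzymeSpec]:
    """Load enzyme specs from YAML; entries extend/override built-ins.

    Schema per enzyme::

        name:
          contexts: [{upstream: ["U"], downstream: ["AG"]}, ...]
          cleavable_mods: {Um: none, s4U: reduced}
          product_termini: [hydroxyl, monophosphate]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = dict(BUILTIN_ENZYMES)
    for name, entry in raw.items():
        contexts = tuple(
            _ctx(c.get("upstream", []), c.get("downstream", []))
            for c in entry["contexts"]
        )
        termini = tuple(entry.get("product_termini", ("hydroxyl", "monophosphate")))
        mods = dict(entry.get("cleavable_mods", {}))
        for v in mods.values():
            if v not in CLEAVABILITY:
                raise ValueError(f"bad cleavability {v!r} in enzyme {name!r}")
        table[name] = EnzymeSpec(name, contexts, mods, termini)  # type: ignore[arg-type]
    return table


# ---------------------------------------------------------------------------
# Products
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageProduct:
    """A contiguous digestion fragment with transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    sequence: tuple[str, ...]
    missed_cleavages: int
    five_prime: TerminalGroup | CapAdduct
    three_prime: TerminalGroup
    mass: float
    #: canonical dinucleotide context of each internal uncut site
    missed_site_contexts: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def sequence_str(self) -> str:
        return "-".join(self.sequence) if any(len(c) > 1 for c in self.sequence) else "".join(self.sequence)

    def composition_key(self, monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS):
        return composition_key(self.sequence, self.five_prime, self.three_prime, monomers)


def _canonical(codes: Sequence[str], monomers: Mapping[str, MonomerDef]) -> list[str]:
    out = []
    for c in codes:
        c = resolve_code(c)
        try:
            out.append(monomers[c].base)
        except KeyError:
            raise KeyError(f"unregistered monomer code {c!r}") from None
    return out


def find_sites(
    sequence: Sequence[str],
    enzyme: EnzymeSpec,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[int]:
    """Bond indices (1..n-1) cut by ``enzyme`` in ``sequence``.

    A bond is cut when some context matches the canonical bases around it
    and no monomer inside the matched window has cleavability "none" for
    this enzyme.
    """
    seq = [resolve_code(c) for c in sequence]
    bases = _canonical(seq, monomers)
    n = len(seq)
    sites: set[int] = set()
    for ctx in enzyme.contexts:
        lu, ld = len(ctx.upstream), len(ctx.downstream)
        for b in range(max(1, lu), min(n, n - ld) + 1):
            if b + ld > n or b - lu < 0 or b == 0 or b == n:
                continue
            window = range(b - lu, b + ld)
            if all(
                bases[i] in (ctx.upstream + ctx.downstream)[i - (b - lu)]
                for i in window
            ) and all(enzyme.cleavability(seq[i]) != "none" for i in window):
                sites.add(b)
    return sorted(sites)


def complete_digest(
    sequence: Sequence[str],
    enzyme: EnzymeSpec,
    transcript_id: str = "",
    molecule_five_prime: TerminalGroup | CapAdduct | None = None,
    molecule_three_prime: TerminalGroup | None = None,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[CleavageProduct]:
    """Complete (0 missed cleavages) digest; products partition the input.

    Transcript-terminal products inherit the molecule's own termini
    (default: hydroxyl at both ends — cap variants are handled by the
    cap-search workflow) on the uncut side; internal boundaries get the
    enzyme's ``product_termini``.
    """
    seq = tuple(resolve_code(c) for c in sequence)
    if not seq:
        raise ValueError("empty transcript")
    mol5 = molecule_five_prime if molecule_five_prime is not None else chemistry.five_prime("hydroxyl")
    mol3 = molecule_three_prime if molecule_three_prime is not None else chemistry.three_prime("hydroxyl")
    p5, p3 = enzyme.product_termini
    sites = find_sites(seq, enzyme, monomers)
    bounds = [0] + sites + [len(seq)]
    products = []
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        fp = mol5 if s == 0 else chemistry.five_prime(p5)
        tp = mol3 if e == len(seq) else chemistry.three_prime(p3)
        frag = seq[s:e]
        products.append(
            CleavageProduct(
                transcript_id=transcript_id,
                start=s,
                end=e,
                sequence=frag,
                missed_cleavages=0,
                five_prime=fp,
                three_prime=tp,
                mass=oligo_mass(frag, fp, tp, monomers),
            )
        )
    return products


def digest_with_missed(
    sequence: Sequence[str],
    enzyme: EnzymeSpec,
    max_missed: int = 1,
    transcript_id: str = "",
    molecule_five_prime: TerminalGroup | CapAdduct | None = None,
    molecule_three_prime: TerminalGroup | None = None,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[CleavageProduct]:
    """All concatenations of 1..max_missed+1 adjacent complete-digest
    fragments, annotated with their missed-cleavage count and the
    canonical dinucleotide context of each skipped site."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    base = complete_digest(
        sequence, enzyme, transcript_id, molecule_five_prime, molecule_three_prime, monomers
    )
    if max_missed == 0:
        return base
    bases = _canonical([resolve_code(c) for c in sequence], monomers)
    out: list[CleavageProduct] = []
    nfrag = len(base)
    for i in range(nfrag):
        for k in range(0, max_missed + 1):
            j = i + k
            if j >= nfrag:
                break
            first, last = base[i], base[j]
            frag = tuple(c for f in base[i : j + 1] for c in f.sequence)
            contexts = tuple(
                bases[base[m].end - 1] + bases[base[m].end]
                for m in range(i, j)
            )
            out.append(
                CleavageProduct(
                    transcript_id=transcript_id,
                    start=first.start,
                    end=last.end,
                    sequence=frag,
                    missed_cleavages=k,
                    five_prime=first.five_prime,
                    three_prime=last.three_prime,
                    mass=oligo_mass(frag, first.five_prime, last.three_prime, monomers),
                    missed_site_contexts=contexts,
                )
            )
    return out


def length_filter(
    products: Iterable[CleavageProduct], min_len: int = 4, max_len: int = 40
) -> list[CleavageProduct]:
    """Retain products with min_len <= length <= max_len (both in nt)."""
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    return [p for p in products if min_len <= len(p) <= max_len]


def terminal_variants(
    products: Iterable[CleavageProduct],
    three_prime_kinds: Sequence[str] = ("cyclic_phosphate", "monophosphate", "hydroxyl"),
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[CleavageProduct]:
    """Enumerate alternative 3'-terminal species of internal products.

    RNase A-family digestion without a downstream phosphatase yields a
    mixture of 2',3'-cyclic-phosphorylated, 3'-phosphorylated and
    hydroxylated products; each non-molecule-terminal product is expanded
    into one entry per requested kind.
    """
    out = []
    for p in products:
        for kind in three_prime_kinds:
            tp = chemistry.three_prime(kind)
            out.append(
                replace(p, three_prime=tp, mass=oligo_mass(p.sequence, p.five_prime, tp, monomers))
            )
    return out
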