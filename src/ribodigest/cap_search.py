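"""5'-terminal cap and phosphorylation-state detection.

The 5'-most digestion products of a transcript (with up to ``max_missed``
missed cleavages from the 5' end) are computed with a plain hydroxyl
5' terminus, then each candidate cap/phosphate adduct's mass delta is
added and the resulting theoretical masses searched in the deconvoluted
peak list.  A capped preparation shows terminal products shifted by the
cap mass (m7Gppp plus, for an m7GpppNm cap, one additional methyl);
an uncapped control shows only the hydroxyl/phosphate states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .chemistry import (
    BUILTIN_CAP_ADDUCTS,
    BUILTIN_MONOMERS,
    CapAdduct,
    MonomerDef,
    ppm_error,
)
from .digestion import CleavageProduct, EnzymeSpec, digest_with_missed
from .ms1_match import DeconvolutedPeak


@dataclass(frozen=True)
class TerminalSpeciesHit:
    product: CleavageProduct
    adduct: CapAdduct
    theoretical_mass: float
    observed_mass: float
    ppm: float
    intensity: float


def five_prime_products(
    sequence: Sequence[str],
    enzyme: EnzymeSpec,
    max_missed: int = 2,
    transcript_id: str = "",
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[CleavageProduct]:
    """The 1..max_missed+1 products anchored at transcript position 0.

    If the enzyme finds no site at all, the single product is the whole
    transcript (callers should treat that as a degenerate search space).
    """
    prods = digest_with_missed(
        sequence, enzyme, max_missed, transcript_id, monomers=monomers
    )
    return sorted((p for p in prods if p.start == 0), key=lambda p: p.end)


def adduct_search(
    peaks: Sequence[DeconvolutedPeak],
    terminal_products: Sequence[CleavageProduct],
    adducts: Mapping[str, CapAdduct] = BUILTIN_CAP_ADDUCTS,
    ppm_tol: float = 10.0,
) -> tuple[list[TerminalSpeciesHit], pd.DataFrame]:
    """Search every (terminal product, adduct) mass against the peaks.

    Product masses must be computed with a 5'-hydroxyl terminus; adduct
    deltas are relative to that baseline.  Returns the hit list plus a
    per-adduct intensity summary across terminal products.
    """
    if not adducts:
        raise ValueError("adduct set must be non-empty")
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    hits: list[TerminalSpeciesHit] = []
    for prod in terminal_products:
        for adduct in adducts.values():
            theo = prod.mass + adduct.mass_delta
            for peak in peaks:
                err = ppm_error(peak.mass, theo)
                if abs(err) <= ppm_tol:
                    hits.append(
                        TerminalSpeciesHit(prod, adduct, theo, peak.mass, err, peak.intensity)
                    )
    summary_rows = []
    for name in adducts:
        sub = [h for h in hits if h.adduct.name == name]
        summary_rows.append(
            {
                "adduct": name,
                "n_hits": len(sub),
                "total_intensity": sum(h.intensity for h in sub),
            }
        )
    summary = pd.DataFrame(summary_rows, columns=["adduct", "n_hits", "total_intensity"])
    return hits, summary
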