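"""Predicted sequence coverage from theoretical digests.

The retained products of a complete digest (within the length window)
are classified as

* ``excluded_nonunique_sequence`` — the same sequence string occurs at
  more than one locus of the transcript; such products can never be
  placed and are excluded from coverage;
* ``uniquely_mappable`` — the product's exact elemental composition
  (sequence composition + terminal chemistry) occurs once among the
  retained products, i.e. its monoisotopic mass identifies it;
* ``isomeric`` — a distinct sequence sharing its composition (hence
  mass) with another retained product.

Coverage is the fraction of transcript positions under the union of the
retained (optionally uniquely-mappable only) product intervals; for a
complete digest this coincides with the summed-length definition because
products are disjoint.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import BUILTIN_MONOMERS, MonomerDef
from .digestion import CleavageProduct, EnzymeSpec, complete_digest, length_filter

UNIQUE = "uniquely_mappable"
ISOMERIC = "isomeric"
EXCLUDED = "excluded_nonunique_sequence"


def classify_products(
    products: Sequence[CleavageProduct],
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> dict[CleavageProduct, str]:
    """Classify one transcript's retained complete-digest products."""
    ids = {p.transcript_id for p in products}
    if len(ids) > 1:
        raise ValueError(f"products from multiple transcripts: {sorted(ids)}")
    if any(p.missed_cleavages for p in products):
        raise ValueError("classification is defined on complete digests only")
    seq_counts = Counter(p.sequence for p in products)
    retained = [p for p in products if seq_counts[p.sequence] == 1]
    comp_counts = Counter(p.composition_key(monomers) for p in retained)
    labels: dict[CleavageProduct, str] = {}
    for p in products:
        if seq_counts[p.sequence] > 1:
            labels[p] = EXCLUDED
        elif comp_counts[p.composition_key(monomers)] == 1:
            labels[p] = UNIQUE
        else:
            labels[p] = ISOMERIC
    return labels


def position_coverage_map(
    products: Iterable[CleavageProduct | tuple[int, int]],
    transcript_length: int,
) -> tuple[np.ndarray, float]:
    """Union-of-intervals boolean map plus covered fraction."""
    covered = np.zeros(transcript_length, dtype=bool)
    for p in products:
        s, e = (p.start, p.end) if isinstance(p, CleavageProduct) else p
        if not (0 <= s < e <= transcript_length):
            raise ValueError(f"interval ({s}, {e}) out of bounds for length {transcript_length}")
        covered[s:e] = True
    return covered, float(covered.mean()) if transcript_length else 0.0


def replicate_position_coverage(
    replicate_products: Sequence[Iterable[CleavageProduct | tuple[int, int]]],
    transcript_length: int,
    min_replicates: int = 1,
) -> tuple[np.ndarray, float]:
    """Positions covered in at least ``min_replicates`` independent runs."""
    support = np.zeros(transcript_length, dtype=int)
    for prods in replicate_products:
        covered, _ = position_coverage_map(prods, transcript_length)
        support += covered
    hit = support >= min_replicates
    return hit, float(hit.mean()) if transcript_length else 0.0


def predicted_coverage(
    sequence: Sequence[str],
    enzyme: EnzymeSpec,
    min_len: int = 4,
    max_len: int = 40,
    unique_only: bool = False,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> float:
    """Predicted coverage fraction of one transcript for one enzyme."""
    if not sequence:
        raise ValueError("empty transcript")
    products = length_filter(
        complete_digest(sequence, enzyme, monomers=monomers), min_len, max_len
    )
    labels = classify_products(products, monomers)
    if unique_only:
        kept = [p for p in products if labels[p] == UNIQUE]
    else:
        kept = [p for p in products if labels[p] != EXCLUDED]
    _, frac = position_coverage_map(kept, len(sequence))
    return frac


def coverage_distribution(
    records: Sequence,
    enzymes: Sequence[EnzymeSpec],
    min_len: int = 4,
    max_len: int = 40,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> pd.DataFrame:
    """Per-(transcript, enzyme) total and uniquely-mappable coverage.

    ``records`` are objects with ``id`` and ``codes`` attributes (see
    :class:`ribodigest.io.TranscriptRecord`).
    """
    rows = []
    for rec in records:
        for enz in enzymes:
            rows.append(
                {
                    "transcript_id": rec.id,
                    "enzyme": enz.name,
                    "length_nt": len(rec.codes),
                    "total_coverage": predicted_coverage(
                        rec.codes, enz, min_len, max_len, False, monomers
                    ),
                    "unique_coverage": predicted_coverage(
                        rec.codes, enz, min_len, max_len, True, monomers
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "enzyme", "length_nt", "total_coverage", "unique_coverage"],
    )
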