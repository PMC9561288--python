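"""Identity-score mass fingerprinting against a transcript database.

Each candidate transcript is digested completely in silico; its retained
products (length window, one entry per distinct sequence, isomeric
products included) form the transcript's theoretical mass profile.  The
identity score is

    score = (fraction of theoretical products detected)
          x (fraction of total peak intensity explained),

so a transcript scores highly only when the observed masses cover its
digest *and* account for the bulk of the signal.  The target's
signal-to-noise is its score divided by the population standard
deviation of all other transcripts' scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chemistry import BUILTIN_MONOMERS, MonomerDef
from .digestion import CleavageProduct, EnzymeSpec, complete_digest, length_filter
from .ms1_match import DeconvolutedPeak, match_peaks


@dataclass(frozen=True)
class IdentityResult:
    transcript_id: str
    detected_fraction: float
    explained_intensity_fraction: float
    identity_score: float
    n_theoretical: int
    flag: str = ""


def theoretical_products(
    sequence: Sequence[str],
    enzyme: EnzymeSpec,
    min_len: int = 4,
    max_len: int = 40,
    transcript_id: str = "",
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[CleavageProduct]:
    """Fingerprint product set: complete digest, length window, one entry
    per distinct sequence (repeated fragments counted once; isomeric
    compositions kept)."""
    products = length_filter(
        complete_digest(sequence, enzyme, transcript_id, monomers=monomers),
        min_len,
        max_len,
    )
    seen: dict[tuple[str, ...], CleavageProduct] = {}
    for p in products:
        seen.setdefault(p.sequence, p)
    return list(seen.values())


def identity_score(
    peaks: Sequence[DeconvolutedPeak],
    products: Sequence[CleavageProduct],
    ppm_tol: float = 5.0,
) -> IdentityResult:
    """Score one transcript's theoretical product set against a peak list."""
    tid = products[0].transcript_id if products else ""
    total_intensity = sum(p.intensity for p in peaks)
    if not products:
        return IdentityResult(tid, 0.0, 0.0, 0.0, 0, flag="no_theoretical_products")
    if total_intensity == 0:
        return IdentityResult(tid, 0.0, 0.0, 0.0, len(products), flag="zero_total_intensity")
    matches = match_peaks(peaks, products, ppm_tol)
    detected_seqs = {m.product.sequence for m in matches}
    # keyed by object identity: value-equal peaks are still separate signals
    matched_peaks = {id(m.peak): m.peak for m in matches}
    detected = len(detected_seqs) / len(products)
    explained = sum(p.intensity for p in matched_peaks.values()) / total_intensity
    return IdentityResult(tid, detected, explained, detected * explained, len(products))


def database_search(
    peaks: Sequence[DeconvolutedPeak],
    database: Sequence,
    enzyme: EnzymeSpec,
    ppm_tol: float = 5.0,
    min_len: int = 4,
    max_len: int = 40,
    monomers: Mapping[str, MonomerDef] = BUILTIN_MONOMERS,
) -> list[IdentityResult]:
    """Score every transcript in ``database`` (objects with ``id`` and
    ``codes``); returns results sorted by descending score, ties broken
    by id for stability.  Peaks may explain several transcripts at once:
    matching is evaluated per transcript independently."""
    if not database:
        raise ValueError("empty transcript database")
    results = []
    for rec in database:
        prods = theoretical_products(rec.codes, enzyme, min_len, max_len, rec.id, monomers)
        results.append(identity_score(peaks, prods, ppm_tol))
    return sorted(results, key=lambda r: (-r.identity_score, r.transcript_id))


def signal_to_noise(
    results: Sequence[IdentityResult], target_id: str
) -> tuple[float, str]:
    """Target score / population SD of all non-target scores.

    Returns ``(value, flag)``; a zero SD among decoys is reported as
    ``inf`` with flag ``"zero_decoy_sd"`` rather than raising.
    """
    target = next((r for r in results if r.transcript_id == target_id), None)
    if target is None:
        raise KeyError(f"target {target_id!r} not in results")
    others = [r.identity_score for r in results if r.transcript_id != target_id]
    if len(others) < 3:
        raise ValueError("need at least 3 non-target transcripts for an SD")
    sd = float(np.std(others))  # population SD (n divisor)
    if sd == 0.0:
        if target.identity_score == 0.0:
            return 0.0, "zero_decoy_sd"
        return float("inf"), "zero_decoy_sd"
    return target.identity_score / sd, ""
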