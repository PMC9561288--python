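"""Matching deconvoluted MS1 neutral masses to theoretical digestion products.

Peaks are neutral monoisotopic masses with intensities, as produced by
upstream charge deconvolution of oligonucleotide MS1 spectra.  Matching
records every (peak, product) pair whose signed ppm error against the
*theoretical* mass is within tolerance; a peak matching more than one
distinct product sequence is flagged ambiguous and excluded from
unique-mapping coverage (but still counts for fingerprinting, which
evaluates transcripts independently).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemistry import ppm_error
from .coverage import position_coverage_map
from .digestion import CleavageProduct


@dataclass(frozen=True)
class DeconvolutedPeak:
    """One neutral monoisotopic mass with intensity from a deconvoluted run."""

    mass: float
    intensity: float
    run: str | None = None

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("peak mass must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class MassMatch:
    peak: DeconvolutedPeak
    product: CleavageProduct
    ppm: float
    ambiguous: bool = False


def match_peaks(
    peaks: Sequence[DeconvolutedPeak],
    products: Sequence[CleavageProduct],
    ppm_tol: float = 10.0,
) -> list[MassMatch]:
    """All (peak, product) pairs within ``ppm_tol``; order-independent.

    Products are binary-searched by mass.  Ambiguity is assessed at the
    sequence level: a peak that matches products with more than one
    distinct sequence string is flagged on every one of its matches.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    if not products or not peaks:
        return []
    prods = sorted(products, key=lambda p: p.mass)
    masses = np.array([p.mass for p in prods])
    raw: list[tuple[DeconvolutedPeak, CleavageProduct, float]] = []
    for peak in peaks:
        # |1e6 (m - t)/t| <= tol  <=>  m/(1+tol*1e-6) <= t <= m/(1-tol*1e-6)
        lo = peak.mass / (1 + ppm_tol * 1e-6)
        hi = peak.mass / (1 - ppm_tol * 1e-6)
        i0, i1 = np.searchsorted(masses, [lo, hi])
        for i in range(i0, i1):
            err = ppm_error(peak.mass, prods[i].mass)
            if abs(err) <= ppm_tol:
                raw.append((peak, prods[i], err))
    by_peak: dict[DeconvolutedPeak, set[tuple[str, ...]]] = defaultdict(set)
    for peak, prod, _ in raw:
        by_peak[peak].add(prod.sequence)
    return [
        MassMatch(peak, prod, err, ambiguous=len(by_peak[peak]) > 1)
        for peak, prod, err in raw
    ]


def aggregate_intensity(matches: Iterable[MassMatch]) -> dict[tuple[str, ...], float]:
    """Summed peak intensity per matched product sequence.

    Multiple peaks matching one sequence are summed; each peak counts
    once per sequence even if it matches that sequence at several loci
    or missed-cleavage states.
    """
    seen: set[tuple[DeconvolutedPeak, tuple[str, ...]]] = set()
    totals: dict[tuple[str, ...], float] = defaultdict(float)
    for m in matches:
        key = (m.peak, m.product.sequence)
        if key in seen:
            continue
        seen.add(key)
        totals[m.product.sequence] += m.peak.intensity
    return dict(totals)


def experimental_unique_coverage(
    matches: Sequence[MassMatch],
    transcript_length: int,
) -> tuple[np.ndarray, float]:
    """Coverage map over uniquely assigned peaks.

    Each peak is assigned to its closest product by |ppm error|
    (closest-match rule).  Exact ties — true isobars, i.e. products with
    identical elemental composition, or the same sequence at several
    loci — cannot be placed and contribute no coverage, except that a
    tie between otherwise identical products with different
    missed-cleavage counts resolves to the fewest missed cleavages.
    With noiseless peaks this reproduces the predicted uniquely-mappable
    coverage exactly.
    """
    by_peak: dict[DeconvolutedPeak, list[MassMatch]] = defaultdict(list)
    for m in matches:
        by_peak[m.peak].append(m)
    placed: list[CleavageProduct] = []
    for peak_matches in by_peak.values():
        best = min(abs(m.ppm) for m in peak_matches)
        ties = [m.product for m in peak_matches if abs(m.ppm) <= best + 1e-9]
        min_missed = min(p.missed_cleavages for p in ties)
        ties = [p for p in ties if p.missed_cleavages == min_missed]
        loci = {(p.start, p.end) for p in ties}
        if len(loci) == 1:
            placed.append(ties[0])
    return position_coverage_map(placed, transcript_length)


def missed_cleavage_stats(matches: Sequence[MassMatch]) -> pd.DataFrame:
    """Match counts and summed intensity by missed-cleavage count and by
    the canonical dinucleotide context of each skipped site.

    One row per (missed_cleavages, site_context); fully cleaved products
    appear under the empty context "".
    """
    rows: dict[tuple[int, str], dict[str, float]] = defaultdict(
        lambda: {"n_matches": 0, "intensity": 0.0}
    )
    for m in matches:
        contexts = m.product.missed_site_contexts or ("",)
        for ctx in contexts:
            cell = rows[(m.product.missed_cleavages, ctx)]
            cell["n_matches"] += 1
            cell["intensity"] += m.peak.intensity
    out = pd.DataFrame(
        [
            {"missed_cleavages": k, "site_context": ctx, **vals}
            for (k, ctx), vals in sorted(rows.items())
        ],
        columns=["missed_cleavages", "site_context", "n_matches", "intensity"],
    )
    return out


def pool_specificity_report(
    peaks_enzyme: Sequence[DeconvolutedPeak],
    peaks_control: Sequence[DeconvolutedPeak],
    pool: Sequence,
    enzyme,
    ppm_tol: float = 10.0,
) -> dict:
    """Multiplexed-pool specificity readout.

    For each intact pool oligo the log2 fold intensity change of the
    enzyme run relative to the no-enzyme control measures depletion
    (cleaved oligos drop).  Separately, every possible single-bond
    cleavage of every pool oligo is matched in the enzyme run, and
    product intensities are binned by the 3'-terminal nucleotide of 5'
    products and the 5'-terminal nucleotide of 3' products, normalised
    to the number of possible sites with that terminal base.

    ``pool`` contains objects with ``id`` and ``codes`` attributes.
    Returns ``{"oligo_log2fc": DataFrame, "five_prime_bins": Series,
    "three_prime_bins": Series}``.
    """
    from . import chemistry

    monomers = chemistry.BUILTIN_MONOMERS
    # --- intact-oligo depletion ---
    intact = []
    for rec in pool:
        intact.append(
            CleavageProduct(
                transcript_id=rec.id,
                start=0,
                end=len(rec.codes),
                sequence=tuple(rec.codes),
                missed_cleavages=0,
                five_prime=chemistry.five_prime("hydroxyl"),
                three_prime=chemistry.three_prime("hydroxyl"),
                mass=chemistry.oligo_mass(rec.codes),
            )
        )
    enz_int = aggregate_intensity(match_peaks(peaks_enzyme, intact, ppm_tol))
    ctl_int = aggregate_intensity(match_peaks(peaks_control, intact, ppm_tol))
    rows = []
    for rec, prod in zip(pool, intact):
        e = enz_int.get(prod.sequence, 0.0)
        c = ctl_int.get(prod.sequence, 0.0)
        if c == 0.0:
            log2fc, flag = (np.nan, "absent_in_control") if e == 0.0 else (np.inf, "zero_control")
        elif e == 0.0:
            log2fc, flag = -np.inf, "fully_depleted"
        else:
            log2fc, flag = float(np.log2(e / c)), ""
        rows.append({"oligo_id": rec.id, "log2_fold_change": log2fc, "flag": flag})
    oligo_df = pd.DataFrame(rows, columns=["oligo_id", "log2_fold_change", "flag"])

    # --- cleavage-product terminal binning ---
    p5_kind, p3_kind = enzyme.product_termini
    candidates_5: list[CleavageProduct] = []
    candidates_3: list[CleavageProduct] = []
    site_counts_3term: dict[str, int] = defaultdict(int)  # upstream base of each bond
    site_counts_5term: dict[str, int] = defaultdict(int)  # downstream base of each bond
    for rec in pool:
        codes = tuple(chemistry.resolve_code(c) for c in rec.codes)
        n = len(codes)
        for b in range(1, n):
            up = monomers[codes[b - 1]].base
            down = monomers[codes[b]].base
            site_counts_3term[up] += 1
            site_counts_5term[down] += 1
            if b >= 2:
                left = codes[:b]
                tp = chemistry.three_prime(p3_kind)
                candidates_5.append(
                    CleavageProduct(rec.id, 0, b, left, 0, chemistry.five_prime("hydroxyl"), tp,
                                    chemistry.oligo_mass(left, None, tp))
                )
            if n - b >= 2:
                right = codes[b:]
                fp = chemistry.five_prime(p5_kind)
                candidates_3.append(
                    CleavageProduct(rec.id, b, n, right, 0, fp, chemistry.three_prime("hydroxyl"),
                                    chemistry.oligo_mass(right, fp, None))
                )
    bins5: dict[str, float] = defaultdict(float)
    for seq, inten in aggregate_intensity(match_peaks(peaks_enzyme, candidates_5, ppm_tol)).items():
        bins5[monomers[seq[-1]].base] += inten
    bins3: dict[str, float] = defaultdict(float)
    for seq, inten in aggregate_intensity(match_peaks(peaks_enzyme, candidates_3, ppm_tol)).items():
        bins3[monomers[seq[0]].base] += inten
    five_series = pd.Series(
        {b: bins5.get(b, 0.0) / site_counts_3term[b] for b in site_counts_3term},
        name="intensity_per_site",
    ).sort_index()
    three_series = pd.Series(
        {b: bins3.get(b, 0.0) / site_counts_5term[b] for b in site_counts_5term},
        name="intensity_per_site",
    ).sort_index()
    return {
        "oligo_log2fc": oligo_df,
        "five_prime_bins": five_series,
        "three_prime_bins": three_series,
    }
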