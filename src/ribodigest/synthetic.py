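"""Synthetic inputs: random transcripts, decoy databases, benchmark
oligonucleotide pools, and simulated deconvoluted MS1 peak lists.

The peak-list simulator stands in for the instrument plus upstream
charge deconvolution: each theoretical product is detected independently
with probability ``detection_prob``; a detected mass is perturbed by a
Gaussian relative error of scale ``ppm_sigma`` (parts per million);
intensities are log-normal (deconvoluted oligonucleotide intensities
span orders of magnitude); and spurious contaminant peaks are sprinkled
uniformly over the observed mass range.  Defaults (1 ppm error, 90%
detection, 5 contaminants per 100 products) sit comfortably inside the
5-10 ppm matching tolerances used downstream; they are deliberately
unexceptional and documented as arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .digestion import CleavageProduct
from .io import TranscriptRecord
from .ms1_match import DeconvolutedPeak

CANONICAL = ("A", "C", "G", "U")


@dataclass(frozen=True)
class NoiseModel:
    """Instrument/deconvolution noise for simulated peak lists."""

    ppm_sigma: float = 1.0
    detection_prob: float = 0.9
    log_intensity_mean: float = np.log(1e6)
    log_intensity_sigma: float = 1.0
    contaminant_rate: float = 0.05  # contaminant peaks per theoretical product
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be non-negative")
        if self.contaminant_rate < 0:
            raise ValueError("contaminant_rate must be non-negative")


def random_transcript(
    length: int,
    frequencies: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | np.random.Generator = 0,
) -> tuple[str, ...]:
    """Random RNA sequence over A/C/G/U with the given base frequencies."""
    if length <= 0:
        raise ValueError("length must be positive")
    freqs = np.asarray(frequencies, dtype=float)
    if len(freqs) != 4 or (freqs < 0).any() or abs(freqs.sum() - 1) > 1e-9:
        raise ValueError("frequencies must be 4 non-negative values summing to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return tuple(rng.choice(CANONICAL, size=length, p=freqs))


def decoy_database(
    n: int,
    length_range: tuple[int, int] = (500, 2000),
    frequencies: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    id_prefix: str = "decoy",
) -> list[TranscriptRecord]:
    """``n`` random transcripts with unique ids, standing in for a
    reference transcript database in fingerprinting simulations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (0 < lo <= hi):
        raise ValueError("degenerate length range")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        codes = random_transcript(length, frequencies, rng)
        records.append(TranscriptRecord(id=f"{id_prefix}_{i:04d}", codes=codes))
    return records


def dinucleotide_pool(flank: int = 4) -> list[TranscriptRecord]:
    """Benchmark pool covering all 16 dinucleotides in a poly-A backbone.

    Oligo i carries dinucleotide XY between poly-A flanks; lengths are
    staggered (one extra 5' A per oligo) so every intact oligo has a
    distinct monoisotopic mass.  Deterministic.
    """
    oligos = []
    dinucs = [x + y for x in CANONICAL for y in CANONICAL]
    for i, xy in enumerate(dinucs):
        codes = tuple("A" * (flank + i)) + (xy[0], xy[1]) + tuple("A" * flank)
        oligos.append(TranscriptRecord(id=f"pool_{xy}", codes=codes))
    return oligos


MODIFIED_U_CODES = ("U", "Um", "psi", "m5U", "m5Um", "s4U", "D", "m1psi")


def modified_u_pool() -> list[TranscriptRecord]:
    """Pool probing uridine-modification sensitivity: one N*-A site per
    oligo (N* a uridine variant) in a U-free poly-AG backbone, with
    staggered lengths so intact masses are unique (psi is an isomer of U)."""
    oligos = []
    for i, code in enumerate(MODIFIED_U_CODES):
        left = ("A", "G") * (3 + i)
        right = ("G", "A") * 3
        codes = left + (code, "A") + right
        oligos.append(TranscriptRecord(id=f"poolU_{code}", codes=codes))
    return oligos


def simulate_peak_list(
    products: Sequence[CleavageProduct],
    noise: NoiseModel = NoiseModel(),
    run: str | None = None,
) -> list[DeconvolutedPeak]:
    """Simulated deconvoluted MS1 peak list for a set of theoretical
    products under ``noise``; reproducible given ``noise.seed``."""
    rng = np.random.default_rng(noise.seed)
    peaks: list[DeconvolutedPeak] = []
    masses = [p.mass for p in products]
    for mass in masses:
        if rng.random() > noise.detection_prob:
            continue
        eps = rng.normal(0.0, noise.ppm_sigma) if noise.ppm_sigma > 0 else 0.0
        obs = mass * (1 + eps * 1e-6)
        intensity = float(np.exp(rng.normal(noise.log_intensity_mean, noise.log_intensity_sigma)))
        peaks.append(DeconvolutedPeak(mass=obs, intensity=intensity, run=run))
    n_contam = rng.poisson(noise.contaminant_rate * len(products)) if products else 0
    if n_contam and masses:
        lo, hi = min(masses), max(masses) + 1.0
        for _ in range(n_contam):
            obs = float(rng.uniform(lo, hi))
            intensity = float(np.exp(rng.normal(noise.log_intensity_mean, noise.log_intensity_sigma)))
            peaks.append(DeconvolutedPeak(mass=obs, intensity=intensity, run=run))
    return sorted(peaks, key=lambda p: p.mass)
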