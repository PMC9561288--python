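"""Readers and writers: FASTA transcripts, delimited peak lists, and the
TSV/JSON/BED-like report files, plus the run configuration record.

Machine-readable outputs use 0-based, half-open coordinates; the JSON
run summary embeds the full configuration and seeds so any run can be
reproduced from the summary alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .chemistry import SubstitutionProfile
from .digestion import CleavageProduct
from .ms1_match import DeconvolutedPeak, MassMatch

logger = logging.getLogger("ribodigest")

_VALID_BASES = set("ACGU")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: identifier plus monomer codes (a substitution
    profile, e.g. all U -> m1psi, is applied at load time)."""

    id: str
    codes: tuple[str, ...]
    substitution: SubstitutionProfile = field(default_factory=SubstitutionProfile.identity)

    def __len__(self) -> int:
        return len(self.codes)


def _clean_sequence(raw: str, record_id: str) -> tuple[str, ...]:
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in _VALID_BASES:
            raise ValueError(
                f"record {record_id!r}: invalid residue {ch!r} at position {pos + 1} "
                "(IUPAC ambiguity codes are not accepted)"
            )
    return tuple(seq)


def read_fasta(
    path: str | Path,
    substitution: SubstitutionProfile | None = None,
) -> list[TranscriptRecord]:
    """Read transcripts from (optionally gzipped) FASTA.

    DNA alphabets are accepted (T is read as U); mixed case is
    uppercased; ids are taken up to the first whitespace.  An optional
    substitution profile is applied transcript-wide.
    """
    path = Path(path)
    if str(path).endswith(".gz"):
        import gzip

        handle = gzip.open(path, "rt")
    else:
        handle = open(path)
    profile = substitution or SubstitutionProfile.identity()
    records = []
    with handle:
        for rec in SeqIO.parse(handle, "fasta"):
            codes = profile.apply(_clean_sequence(str(rec.seq), rec.id))
            records.append(TranscriptRecord(id=rec.id, codes=codes, substitution=profile))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if any(len(c) > 1 for c in rec.codes):
                raise ValueError(
                    f"record {rec.id!r} contains multi-character monomer codes; "
                    "plain FASTA cannot represent it"
                )
            fh.write(f">{rec.id}\n")
            seq = "".join(rec.codes)
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_peaks(path: str | Path, run: str | None = None) -> list[DeconvolutedPeak]:
    """Read a deconvoluted peak list: delimited text with ``mass`` and
    ``intensity`` columns (header required, comma/tab/whitespace
    separated).  Output is sorted by mass; bad rows are reported with
    their (1-based, header-inclusive) line number."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("mass", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    peaks = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            mass = float(row["mass"])
            intensity = float(row["intensity"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: non-numeric value on line {line}") from None
        if mass != mass or mass <= 0:
            raise ValueError(f"{path}: non-positive mass on line {line}")
        if intensity < 0:
            raise ValueError(f"{path}: negative intensity on line {line}")
        peaks.append(DeconvolutedPeak(mass=mass, intensity=intensity, run=run))
    return sorted(peaks, key=lambda p: p.mass)


def write_peaks(peaks: Sequence[DeconvolutedPeak], path: str | Path) -> None:
    pd.DataFrame(
        {"mass": [p.mass for p in peaks], "intensity": [p.intensity for p in peaks]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Defaults mirror the package's standard analysis settings: 10 ppm
    for MS1 product matching, 5 ppm for fingerprint searches, a 4-40 nt
    product window, one missed cleavage for matching and two (from the
    5' end) for cap searches."""

    enzyme: str = "hRNase4"
    match_ppm: float = 10.0
    fingerprint_ppm: float = 5.0
    min_len: int = 4
    max_len: int = 40
    max_missed_match: int = 1
    max_missed_cap: int = 2
    substitution: dict = field(default_factory=dict)
    replicate_k: int = 1
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------

def products_frame(products: Iterable[CleavageProduct]) -> pd.DataFrame:
    """Product table; start/end are 0-based half-open."""
    rows = [
        {
            "transcript_id": p.transcript_id,
            "start": p.start,
            "end": p.end,
            "length_nt": len(p),
            "sequence": p.sequence_str,
            "missed_cleavages": p.missed_cleavages,
            "five_prime": getattr(p.five_prime, "kind", None) or getattr(p.five_prime, "name", ""),
            "three_prime": p.three_prime.kind,
            "mass_da": p.mass,
        }
        for p in products
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "end", "length_nt", "sequence",
            "missed_cleavages", "five_prime", "three_prime", "mass_da",
        ],
    )


def matches_frame(matches: Iterable[MassMatch]) -> pd.DataFrame:
    rows = [
        {
            "peak_mass_da": m.peak.mass,
            "peak_intensity": m.peak.intensity,
            "transcript_id": m.product.transcript_id,
            "start": m.product.start,
            "end": m.product.end,
            "sequence": m.product.sequence_str,
            "missed_cleavages": m.product.missed_cleavages,
            "theoretical_mass_da": m.product.mass,
            "ppm_error": m.ppm,
            "ambiguous": m.ambiguous,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "peak_mass_da", "peak_intensity", "transcript_id", "start", "end",
            "sequence", "missed_cleavages", "theoretical_mass_da", "ppm_error", "ambiguous",
        ],
    )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 0-based half-open intervals."""
    ordered = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def write_bed(
    intervals: Iterable[tuple[int, int]], chrom: str, path: str | Path
) -> None:
    """BED-like covered intervals (0-based half-open), merged."""
    with open(path, "w") as fh:
        for s, e in merge_intervals(intervals):
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_run_summary(
    path: str | Path, config: RunConfig, results: dict
) -> None:
    """JSON run summary embedding the full configuration (reproducibility
    contract: a run is re-creatable from this file alone)."""
    payload = {"config": dataclasses.asdict(config), "results": results}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
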