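"""Readers and writers for the package's external formats.

FASTQ (Phred+33, gzip-transparent, paired by record order), reference FASTA,
two-column lane-profile TSV (pixel_index, intensity), ladder band TSV
(length_nt, pixel), and report serialization to TSV/JSON with the package's
fixed numeric formatting (frequencies in 2-significant-digit scientific
notation, counts as integers; JSON keeps full precision).
"""

from __future__ import annotations

import gzip
import json
from collections import OrderedDict
from dataclasses import is_dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .processivity import LaneProfile


class FastqParseError(ValueError):
    """A malformed FASTQ record, annotated with its approximate line."""


class PairingError(ValueError):
    """R1/R2 record counts disagree."""


def _open_read(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _decode_quals(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33


def _iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality string); wrap malformed records."""
    n = 0
    with _open_read(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                item = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ record near line {4 * n + 1}: {exc}"
                ) from exc
            n += 1
            yield item


def read_fastq_pairs(r1_path, r2_path):
    """Stream read pairs from two FASTQ files, paired 1:1 by record order.

    Yields ``(read_id, seq1, qual1, seq2, qual2)`` with qualities decoded
    from Phred+33 to integer arrays.  Raises ``PairingError`` when the files
    hold different record counts and ``FastqParseError`` on malformed
    records.
    """
    it1 = _iter_fastq(r1_path)
    it2 = _iter_fastq(r2_path)
    n = 0
    sentinel = object()
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            longer = r2_path if a is sentinel else r1_path
            raise PairingError(
                f"unequal R1/R2 record counts: extra records in {longer} "
                f"after {n} pairs"
            )
        title1, seq1, q1 = a
        _, seq2, q2 = b
        n += 1
        read_id = title1.split()[0].removesuffix("/1")
        yield read_id, seq1.upper(), _decode_quals(q1), seq2.upper(), _decode_quals(q2)


def read_reference(reference) -> str:
    """Accept a sequence string or a FASTA path; return the sequence, upper."""
    if isinstance(reference, (str, Path)):
        p = Path(reference)
        try:
            exists = p.exists()
        except OSError:
            exists = False
        if exists and p.is_file():
            from Bio import SeqIO

            with _open_read(p) as handle:
                record = next(SeqIO.parse(handle, "fasta"), None)
            if record is None:
                raise ValueError(f"no FASTA record found in {reference}")
            return str(record.seq).upper()
        if isinstance(reference, Path):
            raise FileNotFoundError(f"reference FASTA not found: {reference}")
        return str(reference).upper()
    raise TypeError("reference must be a sequence string or a FASTA path")


def write_reference_fasta(sequence: str, path, name: str = "reference") -> None:
    with open(path, "w") as f:
        f.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            f.write(sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# lane-profile / ladder TSV
# ---------------------------------------------------------------------------


def read_lane_profile(path, pixel_pitch: float = 100.0) -> LaneProfile:
    """Two-column TSV (pixel_index, intensity) -> LaneProfile."""
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    order = np.argsort(data[:, 0])
    return LaneProfile(data[order, 1], pixel_pitch=pixel_pitch, label=str(path))


def write_lane_profile(profile: LaneProfile, path) -> None:
    with open(path, "w") as f:
        f.write("# pixel_index\tintensity\n")
        for i, v in enumerate(profile.intensities):
            f.write(f"{i}\t{v:.6g}\n")


def read_ladder_table(path) -> list[tuple[float, float]]:
    """TSV (length_nt, pixel) -> list of band rows."""
    data = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return [(float(L), float(px)) for L, px in data[:, :2]]


def write_ladder_table(bands, path) -> None:
    with open(path, "w") as f:
        f.write("# length_nt\tpixel\n")
        for L, px in bands:
            f.write(f"{L:.6g}\t{px:.6g}\n")


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------


def _report_rows(report) -> "OrderedDict[str, object]":
    if hasattr(report, "rows"):
        return OrderedDict(report.rows())
    if hasattr(report, "as_dict"):
        return OrderedDict(sorted(report.as_dict().items()))
    if isinstance(report, dict):
        return OrderedDict(sorted(report.items()))
    raise TypeError(f"cannot serialize report of type {type(report).__name__}")


def _format_value(value) -> str:
    """TSV cell formatting: counts as integers, frequencies as 2-sig-digit
    scientific notation, missing values as N.A."""
    if value is None:
        return "N.A."
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if value != value:  # nan
            return "N.A."
        if value == 0 or abs(value) < 1e-2 or abs(value) >= 1e6:
            return f"{value:.1e}" if value != 0 else "0"
        return f"{value:.6g}"
    return str(value)


def write_report(report, path, fmt: str = "tsv") -> None:
    """Serialize a report object to TSV or JSON.

    Output is byte-stable for identical inputs: row order is the report's own
    order (or sorted keys for plain mappings), numeric formatting is fixed.
    An empty report is an error, never an empty file.
    """
    rows = _report_rows(report)
    if not rows:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as f:
            for key, value in rows.items():
                f.write(f"{key}\t{_format_value(value)}\n")
    elif fmt == "json":
        def clean(v):
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            if isinstance(v, float) and v != v:
                return None
            return v

        with open(path, "w") as f:
            json.dump({k: clean(v) for k, v in rows.items()}, f, indent=2,
                      sort_keys=False)
            f.write("\n")
    else:
        raise ValueError(f"unknown report format {fmt!r} (expected tsv or json)")


def read_report_json(path) -> dict:
    with open(path) as f:
        return json.load(f)
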