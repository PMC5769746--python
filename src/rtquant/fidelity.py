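"""Single-molecule, dual-UMI consensus error calling.

The misincorporation frequency of a reverse transcriptase is estimated free
of PCR and sequencer bias by tagging every RT product with a 15-nt UMI at
each end, sequencing the PCR-amplified pool paired-end, and accepting a
change as an RT error only when the identical change (same position, type
and alternative allele) appears in *every* read sharing the combined 30-nt
UMI key.  Pipeline order follows the assay protocol: trim to the analysis
windows, discard any read pair with a base below Q20 in the retained span,
group by exact combined UMI, keep groups with >= 3 read pairs, align each
retained window to the reference, and intersect the per-read differences.

Frequencies:

* substitution frequency = substituted nucleotides / total nucleotides,
  where total nucleotides = qualifying products x nt per product;
* indel frequency = indel events / qualifying products, reported as
  not-determinable when no indel event was observed.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .align import DEFAULT_SCORES, SUB, AlignScores, Diff, read_diffs
from .io import FastqParseError, PairingError, read_fastq_pairs, read_reference

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass
class FidelityConfig:
    """Layout and filtering parameters of the consensus pipeline.

    Read layout (matching the library design): R1 starts with a 4-nt
    condition barcode then a 15-nt UMI then template-proximal sequence; R2
    starts with a 3-nt condition barcode then a 15-nt UMI then the reverse
    complement of the template's far end.  ``window_r1`` / ``window_r2`` are
    half-open reference intervals (0-based); R1 covers its window reading
    forward from reference position 0, R2 reading backward from the reference
    end.  Windows should be disjoint; nt per product is the sum of the two
    window lengths.
    """

    window_r1: tuple[int, int]
    window_r2: tuple[int, int]
    umi_length: int = 15
    bc_length_r1: int = 4
    bc_length_r2: int = 3
    bc_whitelist_r1: tuple[str, ...] | None = None
    bc_whitelist_r2: tuple[str, ...] | None = None
    min_reads: int = 3
    q_min: int = 20
    umi_collapse_hamming1: bool = False
    scores: AlignScores = field(default_factory=lambda: DEFAULT_SCORES)

    def __post_init__(self) -> None:
        if self.umi_length < 1:
            raise ValueError("a UMI is required: umi_length must be >= 1")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        for name in ("window_r1", "window_r2"):
            a, b = getattr(self, name)
            if not (0 <= a < b):
                raise ValueError(f"{name} must be a non-empty half-open interval")

    @property
    def nt_per_product(self) -> int:
        return (self.window_r1[1] - self.window_r1[0]) + (
            self.window_r2[1] - self.window_r2[0]
        )


@dataclass
class ReadRecord:
    """One mate after barcode/UMI extraction, trimming and orientation.

    ``sequence``/``qualities`` hold the retained analysis span oriented along
    the reference forward strand.
    """

    read_id: str
    mate: str  # "R1" | "R2"
    sequence: str
    qualities: np.ndarray
    barcode: str
    umi: str

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError("sequence/quality length mismatch")


@dataclass
class ReadPairWindows:
    """The two oriented window records of one read pair."""

    read_id: str
    umi5: str
    umi3: str
    r1: ReadRecord
    r2: ReadRecord

    @property
    def combined_umi(self) -> str:
        return self.umi5 + self.umi3


@dataclass
class UMIGroup:
    """All read pairs sharing one combined UMI — one original RT product."""

    combined_umi: str
    members: list[ReadPairWindows]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConsensusCall:
    """An error present identically in every read of a qualifying UMI group."""

    position: int  # 0-based reference coordinate
    kind: str      # substitution | insertion | deletion
    ref: str
    alt: str
    group_size: int
    combined_umi: str


_KIND_NAMES = {"sub": "substitution", "ins": "insertion", "del": "deletion"}


@dataclass
class FidelityReport:
    """Summary table of the consensus analysis (assay report schema)."""

    total_reads: int
    unique_products: int
    qualifying_products: int
    nt_per_product: int
    n_substituted_nt: int
    n_indel_events: int
    min_reads: int = 3

    @property
    def total_nucleotides(self) -> int:
        return self.qualifying_products * self.nt_per_product

    @property
    def substitution_frequency(self) -> float | None:
        if self.total_nucleotides == 0:
            return None
        return self.n_substituted_nt / self.total_nucleotides

    @property
    def indel_frequency(self) -> float | None:
        """Indel events per qualifying product; None when not determinable."""
        if self.qualifying_products == 0 or self.n_indel_events == 0:
            return None
        return self.n_indel_events / self.qualifying_products

    @property
    def insufficient_depth(self) -> bool:
        return self.qualifying_products == 0

    def rows(self) -> "OrderedDict[str, object]":
        """Report rows in the assay's table order."""
        return OrderedDict(
            [
                ("total reads", self.total_reads),
                ("unique products", self.unique_products),
                (f"products with >={self.min_reads} reads", self.qualifying_products),
                ("nucleotide/product", self.nt_per_product),
                ("total nucleotides", self.total_nucleotides),
                ("substitution frequency", self.substitution_frequency),
                ("indel frequency", self.indel_frequency),
            ]
        )


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def extract_barcodes(pair, config: FidelityConfig):
    """Split a raw pair into (barcode, UMI, insert) per mate.

    Returns ``None`` when a mate is shorter than its prefix or a condition
    barcode misses the whitelist (the pair is routed to the unmatched bin).
    """
    if config.umi_length < 1:
        raise ValueError("a UMI is required: umi_length must be >= 1")
    read_id, seq1, qual1, seq2, qual2 = pair
    p1 = config.bc_length_r1 + config.umi_length
    p2 = config.bc_length_r2 + config.umi_length
    if len(seq1) < p1 or len(seq2) < p2:
        return None
    bc1, umi1 = seq1[: config.bc_length_r1], seq1[config.bc_length_r1 : p1]
    bc2, umi2 = seq2[: config.bc_length_r2], seq2[config.bc_length_r2 : p2]
    if config.bc_whitelist_r1 is not None and bc1 not in config.bc_whitelist_r1:
        return None
    if config.bc_whitelist_r2 is not None and bc2 not in config.bc_whitelist_r2:
        return None
    r1 = ReadRecord(read_id, "R1", seq1[p1:], qual1[p1:], bc1, umi1)
    r2 = ReadRecord(read_id, "R2", seq2[p2:], qual2[p2:], bc2, umi2)
    return r1, r2


def trim_to_window(record: ReadRecord, window: tuple[int, int]) -> ReadRecord:
    """Slice a record to a read-coordinate window (sequence and qualities)."""
    a, b = window
    if not (0 <= a <= b <= len(record.sequence)):
        raise ValueError(
            f"window {window} outside read of length {len(record.sequence)}"
        )
    if a == b and (a, b) != (0, 0):
        raise ValueError("retained span has length 0")
    if (a, b) == (0, 0):
        return record
    return ReadRecord(
        record.read_id,
        record.mate,
        record.sequence[a:b],
        record.qualities[a:b],
        record.barcode,
        record.umi,
    )


def quality_filter(records: Iterable[ReadRecord], q_min: int = 20) -> list[ReadRecord]:
    """Keep only reads whose every retained base has Q >= q_min."""
    return [r for r in records if r.qualities.size and int(r.qualities.min()) >= q_min]


def passes_quality(record: ReadRecord, q_min: int = 20) -> bool:
    return record.qualities.size > 0 and int(record.qualities.min()) >= q_min


def group_by_umi(pairs: Iterable[ReadPairWindows]) -> list[UMIGroup]:
    """Partition read pairs by exact combined 30-nt UMI key."""
    groups: dict[str, list[ReadPairWindows]] = {}
    for pair in pairs:
        groups.setdefault(pair.combined_umi, []).append(pair)
    return [UMIGroup(k, v) for k, v in sorted(groups.items())]


def collapse_umi_groups_hamming1(groups: Sequence[UMIGroup]) -> list[UMIGroup]:
    """Merge each UMI group into a larger group within Hamming distance 1.

    Optional error-tolerant collapse for sequencer-miscalled UMIs: groups are
    visited largest-first and a smaller group is absorbed by the first
    accepted group whose key differs at a single position.  Exact-identity
    grouping remains the default.
    """

    def within_one(a: str, b: str) -> bool:
        mism = 0
        for x, y in zip(a, b):
            if x != y:
                mism += 1
                if mism > 1:
                    return False
        return True

    ordered = sorted(groups, key=lambda g: (-g.size, g.combined_umi))
    accepted: list[UMIGroup] = []
    for group in ordered:
        target = next(
            (a for a in accepted if within_one(a.combined_umi, group.combined_umi)),
            None,
        )
        if target is None:
            accepted.append(UMIGroup(group.combined_umi, list(group.members)))
        else:
            target.members.extend(group.members)
    return sorted(accepted, key=lambda g: g.combined_umi)


def filter_groups(groups: Sequence[UMIGroup], min_reads: int = 3) -> list[UMIGroup]:
    """Groups with at least ``min_reads`` member pairs."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [g for g in groups if g.size >= min_reads]


def align_to_reference(sequence: str, reference_window: str,
                       scores: AlignScores = DEFAULT_SCORES):
    """Global alignment of one read span against its reference window."""
    from .align import global_align

    return global_align(sequence, reference_window, scores)


def call_group_errors(
    group: UMIGroup,
    reference: str,
    config: FidelityConfig,
) -> list[ConsensusCall]:
    """Errors present identically in every member read of a qualifying group.

    Both mate windows are examined; a change seen in any strict subset of the
    members emits nothing.  If any member matches the reference window
    exactly, that window can produce no call (its difference set is empty).

    Indel calls touching a window's unanchored edge are suppressed: a true
    indel inside a fixed-length read slice shifts the slice content, which a
    global alignment must absorb as a spurious indel at the edge away from
    the read's anchored end (the window end for R1, read forward from the
    reference start; the window start for R2, read backward from the
    reference end).  Calls there are unresolvable edge artifacts.
    """
    calls: list[ConsensusCall] = []
    for mate, window in (("r1", config.window_r1), ("r2", config.window_r2)):
        a, b = window
        ref_win = reference[a:b]
        win_len = b - a
        consensus: set[Diff] | None = None
        for member in group.members:
            rec = getattr(member, mate)
            if rec.sequence == ref_win:
                consensus = set()
                break
            diffs = set(read_diffs(rec.sequence, ref_win, config.scores))
            consensus = diffs if consensus is None else (consensus & diffs)
            if not consensus:
                break
        for d in sorted(consensus or ()):
            if "N" in d.alt:
                continue
            if d.kind != SUB:
                if mate == "r1":
                    # unanchored edge = window end; calls are left-normalized,
                    # so test whether an equivalent right-shifted placement
                    # reaches the boundary
                    if _reaches_window_end(d, ref_win):
                        continue
                else:  # r2: unanchored edge = window start (leftmost already)
                    if d.pos == 0:
                        continue
            calls.append(
                ConsensusCall(
                    position=a + d.pos,
                    kind=_KIND_NAMES[d.kind],
                    ref=d.ref,
                    alt=d.alt,
                    group_size=group.size,
                    combined_umi=group.combined_umi,
                )
            )
    return calls


def _reaches_window_end(d: Diff, ref_win: str) -> bool:
    """True when an (left-normalized) indel has an equivalent placement
    touching the window end — i.e. it may be a trimming edge artifact."""
    n = len(ref_win)
    if d.kind == "ins":
        pos, bases = d.pos, d.alt
        while pos < n and ref_win[pos] == bases[0]:
            bases = bases[1:] + ref_win[pos]
            pos += 1
        return pos >= n
    if d.kind == "del":
        pos, L = d.pos, len(d.ref)
        while pos + L < n and ref_win[pos] == ref_win[pos + L]:
            pos += 1
        return pos + L >= n
    return False


def compute_fidelity_report(
    qualifying_groups: Sequence[UMIGroup],
    calls: Sequence[ConsensusCall],
    nt_per_product: int,
    *,
    total_reads: int = 0,
    unique_products: int = 0,
    min_reads: int = 3,
) -> FidelityReport:
    """Assemble the summary report from qualifying groups and their calls."""
    if nt_per_product <= 0:
        raise ValueError("nt_per_product must be > 0")
    n_sub = sum(len(c.alt) for c in calls if c.kind == "substitution")
    n_indel = sum(1 for c in calls if c.kind != "substitution")
    return FidelityReport(
        total_reads=total_reads,
        unique_products=unique_products,
        qualifying_products=len(qualifying_groups),
        nt_per_product=nt_per_product,
        n_substituted_nt=n_sub,
        n_indel_events=n_indel,
        min_reads=min_reads,
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class FidelityModel:
    """Dual-UMI consensus misincorporation analysis of one paired library.

    Parameters
    ----------
    r1_path, r2_path:
        Paired FASTQ files (Phred+33, gzip-transparent), records paired by
        order.
    reference:
        Reference sequence string, or a path to a FASTA file.
    config:
        A ``FidelityConfig`` with the read layout and filter settings.
    """

    def __init__(self, r1_path, r2_path, reference, config: FidelityConfig) -> None:
        self.r1_path = r1_path
        self.r2_path = r2_path
        self.reference = read_reference(reference)
        self.config = config
        for name in ("window_r1", "window_r2"):
            a, b = getattr(config, name)
            if b > len(self.reference):
                raise ValueError(
                    f"{name} {getattr(config, name)} exceeds reference length "
                    f"{len(self.reference)}"
                )

    # -- window extraction ---------------------------------------------------

    def _window_records(self, extracted) -> ReadPairWindows | None:
        """Trim both mates to their windows and orient them on the reference.

        R1 covers ``window_r1`` reading forward from reference position 0;
        R2 covers ``window_r2`` reading backward from the reference end (its
        retained span is reverse-complemented).  Returns None when a read is
        too short for its window.
        """
        cfg = self.config
        r1, r2 = extracted
        a1, b1 = cfg.window_r1
        if b1 > len(r1.sequence):
            return None
        t1 = trim_to_window(r1, (a1, b1))
        a2, b2 = cfg.window_r2
        L = len(self.reference)
        # R2 insert index 0 corresponds to reference position L - 1
        s2, e2 = L - b2, L - a2
        if e2 > len(r2.sequence):
            return None
        t2 = trim_to_window(r2, (s2, e2))
        t2 = ReadRecord(
            t2.read_id, "R2", _revcomp(t2.sequence), t2.qualities[::-1].copy(),
            t2.barcode, t2.umi,
        )
        return ReadPairWindows(r1.read_id, r1.umi, r2.umi, t1, t2)

    # -- fit -----------------------------------------------------------------

    def fit(self, *, compute_naive: bool = True) -> "FidelityResults":
        cfg = self.config
        counts: "OrderedDict[str, int]" = OrderedDict(
            pairs_total=0,
            pairs_unmatched_barcode=0,
            pairs_too_short=0,
            pairs_failed_quality=0,
            pairs_surviving=0,
        )
        surviving: list[ReadPairWindows] = []
        for pair in read_fastq_pairs(self.r1_path, self.r2_path):
            counts["pairs_total"] += 1
            extracted = extract_barcodes(pair, cfg)
            if extracted is None:
                counts["pairs_unmatched_barcode"] += 1
                continue
            windows = self._window_records(extracted)
            if windows is None:
                counts["pairs_too_short"] += 1
                continue
            if not (passes_quality(windows.r1, cfg.q_min)
                    and passes_quality(windows.r2, cfg.q_min)):
                counts["pairs_failed_quality"] += 1
                continue
            surviving.append(windows)
        counts["pairs_surviving"] = len(surviving)

        groups = group_by_umi(surviving)
        if cfg.umi_collapse_hamming1:
            groups = collapse_umi_groups_hamming1(groups)
        qualifying = filter_groups(groups, cfg.min_reads)
        counts["unique_products"] = len(groups)
        counts["qualifying_products"] = len(qualifying)

        calls: list[ConsensusCall] = []
        for group in qualifying:
            calls.extend(call_group_errors(group, self.reference, cfg))

        report = compute_fidelity_report(
            qualifying,
            calls,
            cfg.nt_per_product,
            total_reads=counts["pairs_total"],
            unique_products=len(groups),
            min_reads=cfg.min_reads,
        )

        naive = None
        if compute_naive:
            naive = self._naive_frequency(surviving)
        return FidelityResults(
            model=self,
            report=report,
            calls=calls,
            stage_counts=dict(counts),
            naive_substitution_frequency=naive,
        )

    def _naive_frequency(self, surviving: Sequence[ReadPairWindows]) -> float | None:
        """Bulk per-read mismatch frequency, no UMI collapsing.

        The classic estimator a UMI-free pipeline would report: positionally
        mismatched nucleotides across all surviving window reads divided by
        all window nucleotides.  It absorbs PCR and sequencer errors.
        """
        if not surviving:
            return None
        cfg = self.config
        total = 0
        mismatched = 0
        for mate, window in (("r1", cfg.window_r1), ("r2", cfg.window_r2)):
            a, b = window
            ref_win = self.reference[a:b]
            ref_arr = np.frombuffer(ref_win.encode(), dtype=np.uint8)
            seqs = [getattr(p, mate).sequence for p in surviving]
            block = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
            block = block.reshape(len(seqs), b - a)
            mismatched += int((block != ref_arr[None, :]).sum())
            total += block.size
        return mismatched / total if total else None


@dataclass
class FidelityResults:
    """Fitted consensus analysis: report, per-call table, stage counts."""

    model: FidelityModel
    report: FidelityReport
    calls: list[ConsensusCall]
    stage_counts: dict[str, int]
    naive_substitution_frequency: float | None

    def calls_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "position": c.position,
                    "type": c.kind,
                    "ref": c.ref,
                    "alt": c.alt,
                    "group_size": c.group_size,
                    "umi": c.combined_umi,
                }
                for c in self.calls
            ],
            columns=["position", "type", "ref", "alt", "group_size", "umi"],
        )

    def summary(self) -> str:
        rows = self.report.rows()
        width = max(len(k) for k in rows) + 2
        lines = ["Dual-UMI consensus misincorporation analysis", "=" * 46]
        for key, value in rows.items():
            if value is None:
                text = "N.A."
            elif isinstance(value, float):
                text = f"{value:.1e}"
            else:
                text = f"{value:,d}"
            lines.append(f"{key:<{width}}{text}")
        if self.naive_substitution_frequency is not None:
            lines.append(
                f"{'naive per-read frequency':<{width}}"
                f"{self.naive_substitution_frequency:.1e}"
            )
        lines.append("")
        lines.append("stage counts: " + ", ".join(
            f"{k}={v}" for k, v in self.stage_counts.items()
        ))
        return "\n".join(lines)


def run_fidelity_pipeline(
    r1_path,
    r2_path,
    reference,
    config: FidelityConfig,
    *,
    compute_naive: bool = True,
) -> FidelityResults:
    """One-call orchestration: trim -> Q-filter -> UMI sort -> >=min filter ->
    align -> consensus -> frequencies."""
    return FidelityModel(r1_path, r2_path, reference, config).fit(
        compute_naive=compute_naive
    )
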