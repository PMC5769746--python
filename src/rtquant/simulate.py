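"""Synthetic RT libraries, PCR pools, paired reads and gel lanes.

This module generates the ground-truth-bearing inputs that make both analysis
pipelines verifiable by parameter recovery:

* a reverse-transcription step that copies a reference with per-nucleotide
  substitution/indel errors and tags each product with a 15-nt unique
  molecular identifier (UMI) at each end;
* a PCR amplification step whose first ``explicit_tree_depth`` cycles are
  simulated as an explicit branching lineage tree (errors arising at cycle c
  are inherited by exactly that node's descendants — the subclonal structure
  the consensus caller must reject), with later cycles contributing
  read-private errors only;
* an Illumina-style paired-end sequencing step producing Phred+33 FASTQ plus
  a ground-truth manifest attributing every miscalled base to RT, PCR, or the
  sequencer;
* a single-cycle termination-length simulator (truncated geometric law under
  a uniform per-nucleotide dissociation probability) and a gel-lane renderer
  that turns a length distribution into a densitometry profile with a known
  log-linear mobility calibration.

All randomness flows from one seed; per-molecule sub-streams are derived
deterministically from (seed, molecule_id), so identical configurations give
byte-identical FASTQ output.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .processivity import LaneProfile

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

#: Avogadro constant (CODATA exact value), molecules per mole.
AVOGADRO = 6.02214076e23

#: Default ssDNA ladder band lengths (nt) used by the lane renderer.
DEFAULT_LADDER_LENGTHS = (25, 50, 100, 150, 200, 300, 400, 500, 650, 800)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def pmol_to_molecules(pmol: float) -> float:
    """Convert picomoles of template to molecule count (0.2 pmol -> 1.2e11)."""
    return pmol * 1e-12 * AVOGADRO


def umi_key_space(umi_length: int = 15, ends: int = 2) -> float:
    """Number of distinct combined UMI keys (4^(ends * umi_length))."""
    return float(4 ** (ends * umi_length))


def random_reference(length: int = 260, seed: int = 0) -> str:
    """Uniform random A/C/G/T reference sequence."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_BASES), size=length))


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for one synthetic sequencing library.

    Defaults mirror the library design used for the fidelity assay: 15-nt
    UMIs at both product ends, 4-nt / 3-nt condition barcodes, 10 + 13 PCR
    cycles (first 6 as an explicit lineage tree), PE250 paired-end reads with
    a two-level Q40/Q15 quality mixture (2% of reads low-quality).
    """

    reference_sequence: str
    n_molecules: int = 2000
    rt_sub_rate: float = 1e-4
    rt_indel_rate: float = 1e-5
    umi_length: int = 15
    condition_barcode_5: str = "ACTG"
    condition_barcode_3: str = "GTC"
    pcr_cycles: int = 23
    pcr_error_rate: float = 5e-7
    pcr_efficiency: float = 0.9
    explicit_tree_depth: int = 6
    reads_per_library: int = 60000
    seq_error_rate: float = 1e-3
    read_length_r1: int = 250
    read_length_r2: int = 250
    q_score_model: tuple[int, int, float] = (40, 15, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference_sequence:
            raise ValueError("reference_sequence must be non-empty")
        if set(self.reference_sequence) - set(_BASES):
            raise ValueError("reference_sequence must contain only A/C/G/T")
        for name in ("rt_sub_rate", "rt_indel_rate", "pcr_error_rate",
                     "pcr_efficiency", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if self.explicit_tree_depth > self.pcr_cycles:
            raise ValueError("explicit_tree_depth must be <= pcr_cycles")
        if self.explicit_tree_depth < 0:
            raise ValueError("explicit_tree_depth must be >= 0")
        qh, ql, frac = self.q_score_model
        if not 0.0 <= frac <= 1.0:
            raise ValueError("q_score_model low fraction must be in [0, 1]")


#: An RT/PCR error: (reference position, kind, base). For insertions the base
#: is inserted before the given reference position; for deletions base is "".
ErrorTuple = tuple[int, str, str]


@dataclass
class TaggedProduct:
    """One RT product: reference copy with RT errors, UMI-tagged at each end."""

    molecule_id: int
    umi5: str
    umi3: str
    sequence: str
    true_errors: tuple[ErrorTuple, ...]
    ref_coords: np.ndarray = field(repr=False, default=None)  # per-base ref position, -1 = inserted


@dataclass
class Amplicon:
    """A leaf of the explicit PCR lineage tree for one molecule.

    ``lineage`` records, per explicit cycle, which duplicate the amplicon
    descended from; ``pcr_errors`` carries (cycle, position, kind, base) for
    every error inherited along that path.
    """

    molecule_id: int
    umi5: str
    umi3: str
    lineage: tuple[int, ...]
    sequence: str
    pcr_errors: tuple[tuple[int, int, str, str], ...]
    ref_coords: np.ndarray = field(repr=False, default=None)


@dataclass
class SimulatedPair:
    """One sequenced read pair with full error provenance (reference coords)."""

    read_id: str
    molecule_id: int
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    rt_errors: tuple[ErrorTuple, ...]
    pcr_errors: tuple[ErrorTuple, ...]      # inherited (tree) + late read-private
    pcr_tree_errors: tuple[ErrorTuple, ...]  # inherited subset only
    seq_error_ref_positions: tuple[int, ...]  # -1 when outside the template


@dataclass
class SequencingRun:
    """In-memory result of ``simulate_sequencing`` plus FASTQ/manifest writers."""

    config: SimConfig
    pairs: list[SimulatedPair]

    def write(self, r1_path, r2_path, manifest_path=None) -> None:
        """Write Phred+33 FASTQ (gzip-transparent) and the truth manifest."""
        with _open_write(r1_path) as f1, _open_write(r2_path) as f2:
            for p in self.pairs:
                f1.write(f"@{p.read_id}/1\n{p.r1_seq}\n+\n{p.r1_qual}\n")
                f2.write(f"@{p.read_id}/2\n{p.r2_seq}\n+\n{p.r2_qual}\n")
        if manifest_path is not None:
            with _open_write(manifest_path) as fm:
                fm.write("read_id\tmolecule_id\tn_rt_errors\tn_pcr_errors\tn_seq_errors\n")
                for p in self.pairs:
                    fm.write(
                        f"{p.read_id}\t{p.molecule_id}\t{len(p.rt_errors)}"
                        f"\t{len(p.pcr_errors)}\t{len(p.seq_error_ref_positions)}\n"
                    )


def _open_write(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


# ---------------------------------------------------------------------------
# termination-length simulator (single-cycle processivity ground truth)
# ---------------------------------------------------------------------------


def simulate_termination_lengths(
    n_molecules: int,
    p_dissoc: float,
    full_length: int,
    primer_length: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Product lengths under a uniform per-nucleotide dissociation probability.

    Each initiated extension performs up to ``E = full_length - primer_length``
    incorporation steps and dissociates before each step with probability
    ``p_dissoc``, giving the truncated geometric law
    ``P(k = j) = p (1 - p)^j`` for ``j < E`` and ``P(k = E) = (1 - p)^E``.
    Returned lengths are ``primer_length + k``.
    """
    if not 0.0 <= p_dissoc <= 1.0:
        raise ValueError(f"p_dissoc must be in [0, 1], got {p_dissoc}")
    if primer_length >= full_length:
        raise ValueError("primer_length must be < full_length")
    if primer_length < 0 or n_molecules < 0:
        raise ValueError("primer_length and n_molecules must be >= 0")
    E = full_length - primer_length
    if p_dissoc == 0.0:
        return np.full(n_molecules, full_length, dtype=np.int64)
    rng = np.random.default_rng(seed)
    # geometric(p) counts trials to first success (support >= 1)
    k = np.minimum(rng.geometric(p_dissoc, size=n_molecules) - 1, E)
    return (primer_length + k).astype(np.int64)


# ---------------------------------------------------------------------------
# RT library
# ---------------------------------------------------------------------------


def apply_errors(reference: str, errors: Sequence[ErrorTuple]):
    """Materialize a sequence from the reference and an error list.

    Returns ``(sequence, ref_coords)`` where ``ref_coords[i]`` is the
    reference position of output base ``i`` (-1 for inserted bases).
    """
    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, list[str]] = {}
    for pos, kind, base in errors:
        if kind == "sub":
            subs[pos] = base
        elif kind == "del":
            dels.add(pos)
        elif kind == "ins":
            ins.setdefault(pos, []).append(base)
        else:  # pragma: no cover - guarded by generators
            raise ValueError(f"unknown error kind {kind!r}")
    out: list[str] = []
    coords: list[int] = []
    for pos in range(len(reference) + 1):
        for b in ins.get(pos, ()):
            out.append(b)
            coords.append(-1)
        if pos < len(reference) and pos not in dels:
            out.append(subs.get(pos, reference[pos]))
            coords.append(pos)
    return "".join(out), np.asarray(coords, dtype=np.int32)


def _random_other_base(rng: np.random.Generator, base: str) -> str:
    alts = _BASES.replace(base, "")
    return alts[rng.integers(3)]


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=length))


def simulate_rt_library(config: SimConfig) -> list[TaggedProduct]:
    """Reverse-transcribe ``n_molecules`` copies of the reference.

    Substitutions are per-position Bernoulli(``rt_sub_rate``) with the wrong
    base uniform over the three alternatives; indel events are per-position
    Bernoulli(``rt_indel_rate``), split evenly between a single-base insertion
    (inserted base uniform) and a single-base deletion.  Each product carries
    independent uniform UMIs at both ends.
    """
    ref = config.reference_sequence
    n = len(ref)
    products: list[TaggedProduct] = []
    for mol in range(config.n_molecules):
        rng = np.random.default_rng([config.seed, 1, mol])
        umi5 = _random_umi(rng, config.umi_length)
        umi3 = _random_umi(rng, config.umi_length)
        errors: list[ErrorTuple] = []
        if config.rt_sub_rate > 0:
            for pos in np.nonzero(rng.random(n) < config.rt_sub_rate)[0]:
                errors.append((int(pos), "sub", _random_other_base(rng, ref[pos])))
        if config.rt_indel_rate > 0:
            for pos in np.nonzero(rng.random(n) < config.rt_indel_rate)[0]:
                if rng.random() < 0.5:
                    errors.append((int(pos), "ins", _BASES[rng.integers(4)]))
                else:
                    errors.append((int(pos), "del", ""))
        errors.sort()
        if errors:
            seq, coords = apply_errors(ref, errors)
        else:
            seq, coords = ref, _IDENTITY_COORDS.setdefault(
                n, np.arange(n, dtype=np.int32)
            )
        products.append(
            TaggedProduct(mol, umi5, umi3, seq, tuple(errors), coords)
        )
    return products


_IDENTITY_COORDS: dict[int, np.ndarray] = {}


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------


def _draw_copy_errors(
    rng: np.random.Generator, reference: str, rate: float
) -> list[ErrorTuple]:
    """Substitution errors introduced while copying one strand once.

    Kept as a module-level hook so tests can force specific errors.
    """
    n = len(reference)
    k = rng.binomial(n, rate) if rate > 0 else 0
    out: list[ErrorTuple] = []
    if k:
        for pos in rng.choice(n, size=k, replace=False):
            out.append((int(pos), "sub", _random_other_base(rng, reference[pos])))
    return out


def simulate_pcr(products: Sequence[TaggedProduct], config: SimConfig) -> list[Amplicon]:
    """Amplify products through the explicit lineage tree.

    Each of the first ``explicit_tree_depth`` cycles duplicates every lineage
    member with probability ``pcr_efficiency``; the new copy acquires
    substitution errors at ``pcr_error_rate`` per base which are inherited by
    all of its descendants.  Cycles beyond the explicit depth are deferred to
    sequencing time as read-private errors (see ``simulate_sequencing``).

    With ``pcr_cycles == 0`` the output is the input products, unamplified.
    """
    if config.explicit_tree_depth > config.pcr_cycles:
        raise ValueError("explicit_tree_depth must be <= pcr_cycles")
    ref = config.reference_sequence
    depth = min(config.explicit_tree_depth, config.pcr_cycles)
    amplicons: list[Amplicon] = []
    for product in products:
        rng = np.random.default_rng([config.seed, 2, product.molecule_id])
        # (lineage, pcr_errors) per current pool member
        pool: list[tuple[tuple[int, ...], tuple[tuple[int, int, str, str], ...]]] = [
            ((), ())
        ]
        for cycle in range(1, depth + 1):
            new_pool = []
            for lineage, errs in pool:
                new_pool.append((lineage + (0,), errs))
                if rng.random() < config.pcr_efficiency:
                    new_errs = errs + tuple(
                        (cycle, pos, kind, base)
                        for pos, kind, base in _draw_copy_errors(
                            rng, ref, config.pcr_error_rate
                        )
                    )
                    new_pool.append((lineage + (1,), new_errs))
            pool = new_pool
        for lineage, errs in pool:
            if errs:
                combined = sorted(
                    list(product.true_errors)
                    + [(pos, kind, base) for _, pos, kind, base in errs]
                )
                seq, coords = apply_errors(ref, combined)
            else:
                seq, coords = product.sequence, product.ref_coords
            amplicons.append(
                Amplicon(
                    product.molecule_id,
                    product.umi5,
                    product.umi3,
                    lineage,
                    seq,
                    errs,
                    coords,
                )
            )
    return amplicons


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------


def _mutate_read(
    rng: np.random.Generator,
    seq: str,
    coords: np.ndarray,
    rate: float,
):
    """Apply per-base miscalls to a read; returns (seq, ref positions hit)."""
    n = len(seq)
    k = rng.binomial(n, rate) if rate > 0 else 0
    if not k:
        return seq, ()
    positions = rng.choice(n, size=k, replace=False)
    chars = list(seq)
    hit: list[int] = []
    for p in positions:
        chars[p] = _random_other_base(rng, chars[p]) if chars[p] in _BASES else "N"
        hit.append(int(coords[p]))
    return "".join(chars), tuple(hit)


def simulate_sequencing(
    amplicons: Sequence[TaggedProduct | Amplicon],
    config: SimConfig,
) -> SequencingRun:
    """Sample paired-end reads with replacement from the amplicon pool.

    R1 reads the top strand: 4-nt condition barcode, 15-nt UMI, then the
    template-proximal sequence.  R2 reads the bottom strand from the other
    end: 3-nt condition barcode, 15-nt UMI, then the reverse complement of the
    template's 3' side.  Late PCR cycles (beyond the explicit tree depth)
    contribute errors private to each sampled pair; sequencer miscalls are
    private to each mate.  Qualities follow the two-level mixture: with
    probability ``q_score_model[2]`` a read is low-quality (all bases at the
    low Q), otherwise all bases carry the high Q.
    """
    if not amplicons:
        raise ValueError("amplicon pool must be non-empty")
    ref = config.reference_sequence
    bc5, bc3 = config.condition_barcode_5, config.condition_barcode_3
    qh, ql, frac_low = config.q_score_model
    n_reads = config.reads_per_library
    late_cycles = config.pcr_cycles - min(config.explicit_tree_depth, config.pcr_cycles)
    late_rate = 1.0 - (1.0 - config.pcr_error_rate) ** late_cycles

    rng = np.random.default_rng([config.seed, 3])
    pick = rng.integers(len(amplicons), size=n_reads)
    low1 = rng.random(n_reads) < frac_low
    low2 = rng.random(n_reads) < frac_low

    qual_cache: dict[tuple[int, int], str] = {}

    def qual_string(q: int, n: int) -> str:
        key = (q, n)
        if key not in qual_cache:
            qual_cache[key] = chr(q + 33) * n
        return qual_cache[key]

    pairs: list[SimulatedPair] = []
    for i in range(n_reads):
        amp = amplicons[pick[i]]
        rt_errors = getattr(amp, "true_errors", None)
        if rt_errors is None:  # Amplicon: recover RT errors via tree errors
            tree = tuple((pos, kind, base) for _, pos, kind, base in amp.pcr_errors)
        else:
            tree = ()
        seq, coords = amp.sequence, amp.ref_coords
        # read-private late-PCR errors, shared by both mates of this pair
        late: tuple[ErrorTuple, ...] = ()
        if late_rate > 0:
            k = rng.binomial(len(seq), late_rate)
            if k:
                chars = list(seq)
                hits = []
                for p in rng.choice(len(seq), size=k, replace=False):
                    old = chars[p]
                    chars[p] = _random_other_base(rng, old)
                    hits.append((int(coords[p]), "sub", chars[p]))
                seq = "".join(chars)
                late = tuple(hits)

        top = bc5 + amp.umi5 + seq + revcomp(amp.umi3) + revcomp(bc3)
        top_coords = np.concatenate(
            [
                np.full(len(bc5) + len(amp.umi5), -1, dtype=np.int32),
                coords,
                np.full(len(amp.umi3) + len(bc3), -1, dtype=np.int32),
            ]
        )
        r1 = top[: config.read_length_r1]
        c1 = top_coords[: config.read_length_r1]
        bottom = revcomp(top)
        c_bottom = top_coords[::-1]
        r2 = bottom[: config.read_length_r2]
        c2 = c_bottom[: config.read_length_r2]

        r1, seq_hits1 = _mutate_read(rng, r1, c1, config.seq_error_rate)
        r2, seq_hits2 = _mutate_read(rng, r2, c2, config.seq_error_rate)
        q1 = qual_string(ql if low1[i] else qh, len(r1))
        q2 = qual_string(ql if low2[i] else qh, len(r2))

        # For Amplicon inputs the source product's RT errors are not carried
        # here; simulate_library patches them onto each pair afterwards.
        rt = rt_errors if rt_errors is not None else ()
        tree_errs = tree if rt_errors is None else ()
        pairs.append(
            SimulatedPair(
                read_id=f"sim{i:07d}",
                molecule_id=amp.molecule_id,
                r1_seq=r1,
                r1_qual=q1,
                r2_seq=r2,
                r2_qual=q2,
                rt_errors=rt,
                pcr_errors=tree_errs + late,
                pcr_tree_errors=tree_errs,
                seq_error_ref_positions=seq_hits1 + seq_hits2,
            )
        )
    return SequencingRun(config, pairs)


def simulate_library(config: SimConfig):
    """End-to-end convenience: RT -> PCR -> sequencing.

    Returns ``(products, amplicons, run)`` with full provenance: each pair's
    ``rt_errors`` come from its source product and ``pcr_tree_errors`` from
    its source amplicon.
    """
    products = simulate_rt_library(config)
    if config.pcr_cycles == 0:
        amplicons = [
            Amplicon(p.molecule_id, p.umi5, p.umi3, (), p.sequence, (), p.ref_coords)
            for p in products
        ]
    else:
        amplicons = simulate_pcr(products, config)
    run = simulate_sequencing(amplicons, config)
    by_mol = {p.molecule_id: p for p in products}
    for pair in run.pairs:
        pair.rt_errors = by_mol[pair.molecule_id].true_errors
    return products, amplicons, run


# ---------------------------------------------------------------------------
# gel lane rendering
# ---------------------------------------------------------------------------


@dataclass
class GelRenderSpec:
    """Parameters for rendering a densitometry lane from known band content.

    The mobility model is ``pixel = (log10(length) - intercept) / slope``,
    i.e. ``log10(length) = slope * pixel + intercept`` — the same log-linear
    law the ladder calibration fits.  Bands are Gaussians of ``band_sigma_px``
    standard deviation; the background is ``bg_const + bg_slope * pixel`` with
    additive Gaussian noise.
    """

    bands: Sequence[tuple[float, float]]  # (length nt, relative intensity)
    slope: float = -0.002
    intercept: float = 3.2
    n_pixels: int = 1200
    pixel_pitch: float = 100.0  # micrometres per pixel
    band_sigma_px: float = 2.0
    bg_const: float = 30.0
    bg_slope: float = 0.02
    noise_sigma: float = 0.5
    seed: int = 0
    ladder_lengths: Sequence[float] = DEFAULT_LADDER_LENGTHS

    def __post_init__(self) -> None:
        if self.band_sigma_px <= 0:
            raise ValueError("band_sigma_px must be > 0")
        if self.n_pixels < 2:
            raise ValueError("n_pixels must be >= 2")
        if self.slope == 0:
            raise ValueError("slope must be non-zero")
        for length, intensity in self.bands:
            if length <= 0:
                raise ValueError(f"band length must be > 0, got {length}")
            if intensity < 0:
                raise ValueError("band intensities must be >= 0")

    def length_to_pixel(self, length) -> np.ndarray:
        return (np.log10(np.asarray(length, dtype=float)) - self.intercept) / self.slope


def lengths_to_bands(lengths: Iterable[int]) -> list[tuple[float, float]]:
    """Collapse simulated product lengths into (length, count) bands.

    Zero-length products (dissociation before the first incorporation when
    ``primer_length`` is 0) have no gel mobility and are dropped.
    """
    values, counts = np.unique(np.asarray(list(lengths)), return_counts=True)
    return [(float(v), float(c)) for v, c in zip(values, counts) if v > 0]


def _render_profile(
    spec: GelRenderSpec,
    bands: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    x = np.arange(spec.n_pixels, dtype=float)
    y = spec.bg_const + spec.bg_slope * x
    if bands:
        lengths = np.array([b[0] for b in bands], dtype=float)
        weights = np.array([b[1] for b in bands], dtype=float)
        centers = spec.length_to_pixel(lengths)
        y = y + (
            weights[:, None]
            * np.exp(-0.5 * ((x[None, :] - centers[:, None]) / spec.band_sigma_px) ** 2)
        ).sum(axis=0)
    if spec.noise_sigma > 0:
        y = y + rng.normal(0.0, spec.noise_sigma, size=spec.n_pixels)
    return y


def render_gel_lane(spec: GelRenderSpec):
    """Render sample and ladder lanes plus the ladder band table.

    Returns ``(sample, ladder, band_table)`` where the band table is a list
    of (length nt, pixel position) rows — the input the calibration fit takes.
    """
    rng = np.random.default_rng(spec.seed)
    sample = _render_profile(spec, list(spec.bands), rng)
    ladder_bands = [(float(L), 1000.0) for L in spec.ladder_lengths]
    ladder = _render_profile(spec, ladder_bands, rng)
    table = [
        (float(L), float(spec.length_to_pixel(L))) for L in spec.ladder_lengths
    ]
    return (
        LaneProfile(sample, pixel_pitch=spec.pixel_pitch, label="sample"),
        LaneProfile(ladder, pixel_pitch=spec.pixel_pitch, label="ladder"),
        table,
    )
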