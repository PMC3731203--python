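"""Footprint processing: read anatomy, P-site calibration, pooled tracks.

Raw footprint reads end in an in-vitro poly-A tail.  The footprint length is
the number of leading nucleotides matching the reference before the tail
begins; when the reference base at the inferred boundary is itself an A the
length is AMBIGUOUS and the read is excluded from length-specific analyses
(this exclusion is what produces the documented density dip ~10 nt upstream
of A-rich codons in queuing metaplots).

P-site offsets per read length are calibrated from the start-codon metagene:
the modal upstream 5'-end peak marks ribosomes with the start codon in their
P site.  Frame shifts are expressed relative to the 28-mer frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference import OrfModel

log = logging.getLogger(__name__)

#: sentinel length for reads whose poly-A boundary coincides with a genomic A
AMBIGUOUS = -1

MIN_LENGTH, MAX_LENGTH = 25, 31

#: the fixed frame-shift table (nt into the 28-mer frame; negative = 3' shift)
FIXED_FRAME_SHIFTS: dict[int, int] = {25: 0, 26: 0, 27: 0, 28: 0, 29: -1, 30: -1, 31: -2}

#: equivalent fixed 5'-end -> P-site offsets (28-mer offset is 12 nt)
FIXED_PSITE_OFFSETS: dict[int, int] = {L: 12 - s for L, s in FIXED_FRAME_SHIFTS.items()}

ANCHOR_NT = 21  # reads are placed by their 5' 21-mer


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# read anatomy


def determine_footprint_length(read_sequence: str, orf: OrfModel, candidate_fiveprime: int) -> int:
    """Footprint length of a poly-A-tailed read placed at ``candidate_fiveprime``.

    Returns the length in nt, or :data:`AMBIGUOUS` when the reference base at
    the first tail position is an A (the tail boundary cannot be located).
    Raises ValueError for reads shorter than the 21-nt anchor or mismatching
    the reference.
    """
    read = read_sequence.upper()
    if len(read) < ANCHOR_NT:
        raise ValueError(f"read shorter than {ANCHOR_NT} nt")
    ref = orf.sequence(candidate_fiveprime, candidate_fiveprime + len(read) + 1)
    if read[:ANCHOR_NT] != ref[:ANCHOR_NT]:
        raise ValueError("5' 21-mer does not match the reference at the candidate position")
    core = read.rstrip("A")
    m = len(core)
    if m == len(read):  # no tail: must match the reference to its end
        if read != ref[: len(read)]:
            raise ValueError("untailed read mismatches the reference")
        return len(read)
    if read[:m] != ref[:m]:
        raise ValueError("footprint portion mismatches the reference")
    if ref[m] == "A":
        return AMBIGUOUS
    return m


def map_fastq(
    fastq_path,
    orfs: dict[str, OrfModel],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Place FASTQ reads by exact 5' 21-mer match and size them.

    Returns (sized count table with columns orf_id/fiveprime/length/count,
    stats dict).  Reads whose 21-mer is absent or non-unique across the
    reference are dropped and counted.  Genome-scale mismatch-tolerant
    alignment is out of scope; this placer serves synthetic references.
    """
    index: dict[str, tuple[str, int] | None] = {}
    for orf_id, orf in orfs.items():
        up = len(orf.upstream_flank)
        ext = orf.upstream_flank + orf.coding_seq + orf.downstream_flank
        for i in range(0, len(ext) - ANCHOR_NT + 1):
            kmer = ext[i : i + ANCHOR_NT]
            pos = i - up
            if kmer in index and index[kmer] != (orf_id, pos):
                index[kmer] = None  # non-unique
            else:
                index[kmer] = (orf_id, pos)

    stats = {"total": 0, "placed": 0, "unplaced": 0, "multimapped": 0, "mismatch": 0}
    cache: dict[str, tuple[str, int, int] | str] = {}
    rows: dict[tuple[str, int, int], int] = {}
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        seq = str(rec.seq).upper()
        stats["total"] += 1
        hit = cache.get(seq)
        if hit is None:
            placed = index.get(seq[:ANCHOR_NT], "absent")
            if placed == "absent":
                hit = "unplaced"
            elif placed is None:
                hit = "multimapped"
            else:
                orf_id, pos = placed
                try:
                    L = determine_footprint_length(seq, orfs[orf_id], pos)
                except (ValueError, IndexError):
                    hit = "mismatch"
                else:
                    hit = (orf_id, pos, L)
            cache[seq] = hit
        if isinstance(hit, str):
            stats[hit] += 1
            continue
        stats["placed"] += 1
        rows[hit] = rows.get(hit, 0) + 1

    sized = pd.DataFrame(
        [(o, p, L, c) for (o, p, L), c in sorted(rows.items())],
        columns=["orf_id", "fiveprime", "length", "count"],
    )
    return sized, stats


# ---------------------------------------------------------------------------
# P-site calibration


@dataclass
class PsiteCalibration:
    """Per-length 5'->P-site offsets and frame shifts into the 28-mer frame."""

    psite_offset_by_length: dict[int, int]
    frame_shift_by_length: dict[int, int]
    source: str = "calibrated"  # or "fixed-table"
    warnings: tuple[str, ...] = ()
    metagenes: dict[int, pd.DataFrame] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for L, off in self.psite_offset_by_length.items():
            if not 0 <= off <= L:
                raise ValueError(f"offset for {L}-mers out of range: {off}")
        if self.frame_shift_by_length.get(28, 0) != 0:
            raise ValueError("28-mers define the frame; their shift must be 0")

    def to_frame(self) -> pd.DataFrame:
        Ls = sorted(self.psite_offset_by_length)
        return pd.DataFrame(
            {
                "length": Ls,
                "psite_offset": [self.psite_offset_by_length[L] for L in Ls],
                "frame_shift": [self.frame_shift_by_length[L] for L in Ls],
                "source": self.source,
            }
        )


def fixed_calibration() -> PsiteCalibration:
    """The published fixed offset table, for use when data are insufficient."""
    return PsiteCalibration(
        dict(FIXED_PSITE_OFFSETS), dict(FIXED_FRAME_SHIFTS), source="fixed-table"
    )


def calibrate_psite(
    sized: pd.DataFrame,
    orfs: dict[str, OrfModel],
    min_reads: int = 200,
    peak_factor: float = 3.0,
    window: tuple[int, int] = (-40, 20),
    fallback_to_fixed: bool = False,
) -> PsiteCalibration:
    """Estimate per-length P-site offsets from the start-codon metagene.

    For each read length, 5' ends are binned by position relative to the
    start codon over ``window``; the modal upstream peak at distance d gives
    the offset, provided it exceeds ``peak_factor`` times the mean upstream
    background and at least ``min_reads`` start-proximal reads exist.  Ties
    are broken toward the published 28-mer-consistent distance.  On failure,
    either falls back to the fixed table (with a warning) or raises
    :class:`CalibrationError`.
    """
    lo, hi = window
    offsets: dict[int, int] = {}
    warns: list[str] = []
    metagenes: dict[int, pd.DataFrame] = {}
    lengths = sorted(
        int(L) for L in sized["length"].unique() if MIN_LENGTH <= int(L) <= MAX_LENGTH
    )
    for L in lengths:
        sub = sized[sized["length"] == L]
        inwin = sub[(sub["fiveprime"] >= lo) & (sub["fiveprime"] < hi)]
        hist = (
            inwin.groupby("fiveprime")["count"].sum().reindex(range(lo, hi), fill_value=0)
        )
        metagenes[L] = hist.rename("count").reset_index()
        total = int(hist.sum())
        upstream = hist[hist.index < 0]
        if total < min_reads or upstream.sum() == 0:
            warns.append(f"length {L}: insufficient start-proximal reads ({total})")
            continue
        peak_count = upstream.max()
        peaks = upstream[upstream == peak_count].index.to_numpy()
        expected = -FIXED_PSITE_OFFSETS.get(L, 12)
        peak_pos = int(peaks[np.argmin(np.abs(peaks - expected))])
        background = upstream.drop(index=peak_pos).mean()
        if background > 0 and peak_count < peak_factor * background:
            warns.append(
                f"length {L}: no upstream peak exceeding {peak_factor}x background"
            )
            continue
        offsets[L] = -peak_pos

    missing = [L for L in lengths if L not in offsets]
    if missing or 28 not in offsets:
        if fallback_to_fixed:
            for L in set(missing) | ({28} - set(offsets)):
                offsets[L] = FIXED_PSITE_OFFSETS[L]
                warns.append(f"length {L}: fixed-table offset used")
            source = "fixed-table" if len(missing) == len(lengths) else "calibrated"
        else:
            raise CalibrationError(
                "calibration failed for lengths "
                + ", ".join(map(str, missing or [28]))
                + ("; " + "; ".join(warns) if warns else "")
            )
    else:
        source = "calibrated"
    for w in warns:
        log.warning("calibrate_psite: %s", w)
    anchor = offsets[28]
    shifts = {L: anchor - off for L, off in offsets.items()}
    return PsiteCalibration(offsets, shifts, source=source, warnings=tuple(warns), metagenes=metagenes)


# ---------------------------------------------------------------------------
# pooled tracks


class PooledFiveprimeTrack:
    """Per-ORF 5'-end count vectors over [-upstream, L + downstream).

    Two layers: ``shifted`` (length-split reads moved into the 28-mer frame;
    ambiguous-length reads excluded) and ``unsplit`` (all retained reads at
    their raw 5' positions, ambiguous included) -- the latter is what RPKM
    counting uses.
    """

    def __init__(self, orfs: dict[str, OrfModel], upstream: int = 60, downstream: int = 30):
        self.orfs = orfs
        self.upstream = upstream
        self.downstream = downstream
        self.shifted: dict[str, np.ndarray] = {}
        self.unsplit: dict[str, np.ndarray] = {}
        for orf_id, orf in orfs.items():
            n = upstream + len(orf.coding_seq) + downstream
            self.shifted[orf_id] = np.zeros(n, dtype=np.int64)
            self.unsplit[orf_id] = np.zeros(n, dtype=np.int64)
        self.dropped: dict[str, int] = {}
        self.total_orf_reads = 0  # shifted-layer total
        self.unsplit_total = 0

    def _drop(self, reason: str, n: int) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + int(n)

    def shifted_array(self, orf_id: str) -> np.ndarray:
        return self.shifted[orf_id]

    def unsplit_array(self, orf_id: str) -> np.ndarray:
        return self.unsplit[orf_id]

    def count_at(self, orf_id: str, position: int, layer: str = "shifted") -> int:
        arr = self.shifted if layer == "shifted" else self.unsplit
        return int(arr[orf_id][position + self.upstream])

    def add(self, other: "PooledFiveprimeTrack") -> "PooledFiveprimeTrack":
        """Positionwise sum (replicate pooling); references must match."""
        if set(self.orfs) != set(other.orfs) or self.upstream != other.upstream:
            raise ValueError("cannot pool tracks built on different references")
        for orf_id in self.orfs:
            if len(self.shifted[orf_id]) != len(other.shifted[orf_id]):
                raise ValueError("cannot pool tracks built on different references")
        out = PooledFiveprimeTrack(self.orfs, self.upstream, self.downstream)
        for orf_id in self.orfs:
            out.shifted[orf_id] = self.shifted[orf_id] + other.shifted[orf_id]
            out.unsplit[orf_id] = self.unsplit[orf_id] + other.unsplit[orf_id]
        out.total_orf_reads = self.total_orf_reads + other.total_orf_reads
        out.unsplit_total = self.unsplit_total + other.unsplit_total
        for d in (self.dropped, other.dropped):
            for k, v in d.items():
                out.dropped[k] = out.dropped.get(k, 0) + v
        return out


def pool_and_frameshift(
    sized: pd.DataFrame,
    orfs: dict[str, OrfModel],
    calibration: PsiteCalibration,
    upstream: int = 60,
    downstream: int = 30,
) -> PooledFiveprimeTrack:
    """Pool sized 5' ends into per-ORF tracks, shifting into the 28-mer frame.

    A length-L record at position p lands at p - frame_shift(L) in the
    shifted layer (negative shifts move 3'-ward) and at p in the unsplit
    layer.  Ambiguous-length records enter the unsplit layer only; lengths
    outside 25-31 are dropped with a counted warning.
    """
    track = PooledFiveprimeTrack(orfs, upstream, downstream)
    for orf_id, fp, L, count in zip(
        sized["orf_id"], sized["fiveprime"], sized["length"], sized["count"]
    ):
        fp, L, count = int(fp), int(L), int(count)
        if orf_id not in track.orfs:
            track._drop("unknown_orf", count)
            continue
        n = len(track.unsplit[orf_id])
        uidx = fp + upstream
        if L == AMBIGUOUS:
            if 0 <= uidx < n:
                track.unsplit[orf_id][uidx] += count
                track.unsplit_total += count
            else:
                track._drop("out_of_track", count)
            continue
        if not MIN_LENGTH <= L <= MAX_LENGTH:
            track._drop("length_out_of_range", count)
            continue
        if L not in calibration.frame_shift_by_length:
            raise CalibrationError(f"no calibration for length {L}")
        sidx = fp - calibration.frame_shift_by_length[L] + upstream
        if 0 <= uidx < n:
            track.unsplit[orf_id][uidx] += count
            track.unsplit_total += count
        else:
            track._drop("out_of_track", count)
        if 0 <= sidx < n:
            track.shifted[orf_id][sidx] += count
            track.total_orf_reads += count
        else:
            track._drop("shifted_out_of_track", count)
    if track.dropped:
        log.warning("pool_and_frameshift dropped records: %s", track.dropped)
    return track
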