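"""Reference loading: ORF models and the ORF-relative coordinate frame.

An :class:`OrfModel` is the universe every other module's positions refer to.
Coordinates are 0-based, half-open, on the coding strand, with position 0 at
the first nucleotide of the start codon; all genomic projection (splicing,
strand flips, flank clipping) happens once, at load time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codons import SENSE_CODONS, STOP_CODONS, is_codon, revcomp

log = logging.getLogger(__name__)

FLANK_NT = 60


@dataclass(frozen=True)
class GenomicPlacement:
    chrom: str
    strand: str  # "+" or "-"
    blocks: tuple[tuple[int, int], ...]  # ordered, non-overlapping, genomic half-open


@dataclass
class OrfModel:
    """One ORF: spliced coding sequence, flanks and coordinate frame.

    ``coding_seq`` runs from the first nt of the start codon through the last
    nt of the stop codon.  ``upstream_flank`` is the sequence 5' of position 0
    on the coding strand (its last character sits at position -1).
    """

    orf_id: str
    coding_seq: str
    upstream_flank: str
    downstream_flank: str
    genomic_placement: GenomicPlacement | None = None
    flags: tuple[str, ...] = ()
    _codons: tuple[str, ...] | None = field(default=None, repr=False, compare=False)
    _codon_arr: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_codons(self) -> int:
        return len(self.coding_seq) // 3

    @property
    def codons(self) -> tuple[str, ...]:
        if self._codons is None:
            s = self.coding_seq
            object.__setattr__(
                self, "_codons", tuple(s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3))
            )
        return self._codons

    @property
    def codon_array(self) -> np.ndarray:
        if self._codon_arr is None:
            object.__setattr__(self, "_codon_arr", np.array(self.codons, dtype=object))
        return self._codon_arr

    def sequence(self, start: int, end: int) -> str:
        """ORF-relative slice over [start, end); may extend into the flanks."""
        up = len(self.upstream_flank)
        ext_len = up + len(self.coding_seq) + len(self.downstream_flank)
        if start + up < 0 or end + up > ext_len:
            raise IndexError(
                f"{self.orf_id}: slice [{start}, {end}) outside available sequence "
                f"[{-up}, {ext_len - up})"
            )
        ext = self.upstream_flank + self.coding_seq + self.downstream_flank
        return ext[start + up : end + up]

    def validate(self, strict: bool = False) -> tuple[str, ...]:
        """Return (and store) structural flags; raise only in strict mode."""
        flags = []
        if len(self.coding_seq) == 0 or len(self.coding_seq) % 3 != 0:
            flags.append("length_not_multiple_of_3")
        if not self.coding_seq.startswith("ATG"):
            flags.append("no_atg_start")
        if self.coding_seq[-3:] not in STOP_CODONS:
            flags.append("no_stop_end")
        if strict and flags:
            raise ValueError(f"{self.orf_id}: invalid ORF: {', '.join(flags)}")
        self.flags = tuple(flags)
        return self.flags


@dataclass(frozen=True)
class CodonInstance:
    orf_id: str
    codon_index: int
    codon: str

    @property
    def start_nt(self) -> int:
        return 3 * self.codon_index


# ---------------------------------------------------------------------------
# loading / writing

_ANNOT_COLS = ["orf_id", "chrom", "strand", "block_starts", "block_ends", "frame"]


def _parse_blocks(starts: str, ends: str, orf_id: str) -> tuple[tuple[int, int], ...]:
    s = [int(x) for x in str(starts).rstrip(",").split(",")]
    e = [int(x) for x in str(ends).rstrip(",").split(",")]
    if len(s) != len(e):
        raise ValueError(f"{orf_id}: block_starts/block_ends length mismatch")
    blocks = tuple(zip(s, e))
    for (a, b) in blocks:
        if b <= a:
            raise ValueError(f"{orf_id}: empty or inverted block [{a}, {b})")
    for (_, b1), (a2, _) in zip(blocks, blocks[1:]):
        if a2 < b1:
            raise ValueError(f"{orf_id}: overlapping or unordered blocks")
    return blocks


def _read_annotation_tab(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_ANNOT_COLS, dtype=str)
    return df


def _read_annotation_bed12(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if bed.shape[1] < 12:
        raise ValueError("BED12 annotation requires 12 columns")
    rows = []
    for _, r in bed.iterrows():
        chrom, start = r[0], int(r[1])
        name, strand = r[3], r[5]
        sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
        offs = [int(x) for x in str(r[11]).rstrip(",").split(",")]
        starts = [start + o for o in offs]
        ends = [a + s for a, s in zip(starts, sizes)]
        rows.append(
            {
                "orf_id": name,
                "chrom": chrom,
                "strand": strand,
                "block_starts": ",".join(map(str, starts)),
                "block_ends": ",".join(map(str, ends)),
                "frame": "0",
            }
        )
    return pd.DataFrame(rows, columns=_ANNOT_COLS)


def load_reference(fasta_path, annotation_path, fmt: str = "tab", flank: int = FLANK_NT) -> dict[str, OrfModel]:
    """Load contigs + ORF annotation into a dict of OrfModel keyed by orf_id.

    Minus-strand ORFs are reverse-complemented; flanks are taken on the coding
    strand and clipped at contig ends.  Ordering is deterministic (by orf_id).
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if fmt == "tab":
        annot = _read_annotation_tab(annotation_path)
    elif fmt == "bed12":
        annot = _read_annotation_bed12(annotation_path)
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")

    orfs: dict[str, OrfModel] = {}
    for _, row in annot.iterrows():
        orf_id = row["orf_id"]
        chrom = row["chrom"]
        if chrom not in contigs:
            raise KeyError(f"annotation for {orf_id!r} names absent contig {chrom!r}")
        seq = contigs[chrom]
        strand = row["strand"]
        blocks = _parse_blocks(row["block_starts"], row["block_ends"], orf_id)
        spliced = "".join(seq[a:b] for a, b in blocks)
        gstart, gend = blocks[0][0], blocks[-1][1]
        left = seq[max(0, gstart - flank) : gstart]
        right = seq[gend : gend + flank]
        if strand == "+":
            coding, up, down = spliced, left, right
        elif strand == "-":
            coding, up, down = revcomp(spliced), revcomp(right), revcomp(left)
        else:
            raise ValueError(f"{orf_id}: strand must be '+' or '-', got {strand!r}")
        model = OrfModel(orf_id, coding, up, down, GenomicPlacement(chrom, strand, blocks))
        model.validate(strict=False)
        if "length_not_multiple_of_3" in model.flags:
            warnings.warn(f"{orf_id}: coding length not a multiple of 3; flagged", stacklevel=2)
        orfs[orf_id] = model
    return dict(sorted(orfs.items()))


def write_reference(orfs: dict[str, OrfModel], fasta_path, annotation_path) -> None:
    """Write one contig per ORF (flanks included) plus a tab annotation.

    The projection is normalized to the plus strand; reloading reproduces
    identical coding sequences, flanks and ORF-relative coordinates.
    """
    with open(fasta_path, "w") as fa, open(annotation_path, "w") as an:
        an.write("#" + "\t".join(_ANNOT_COLS) + "\n")
        for orf_id in sorted(orfs):
            o = orfs[orf_id]
            contig = o.upstream_flank + o.coding_seq + o.downstream_flank
            fa.write(f">{orf_id}_contig\n{contig}\n")
            a = len(o.upstream_flank)
            b = a + len(o.coding_seq)
            an.write(f"{orf_id}\t{orf_id}_contig\t+\t{a}\t{b}\t0\n")


# ---------------------------------------------------------------------------
# codon instances


def enumerate_codon_instances(orfs: dict[str, OrfModel], codon: str) -> list[CodonInstance]:
    """All in-frame instances of ``codon`` across the ORF collection.

    Only codon-aligned (in-frame) occurrences count; an AAA spanning two
    codon slots is not an instance of AAA.
    """
    if not is_codon(codon):
        raise ValueError(f"not an ACGT codon: {codon!r}")
    out: list[CodonInstance] = []
    for orf_id in orfs:
        o = orfs[orf_id]
        for i, c in enumerate(o.codons):
            if c == codon:
                out.append(CodonInstance(orf_id, i, codon))
    return out


def instance_positions(orf: OrfModel, codon: str) -> np.ndarray:
    """First-nt ORF-relative positions of in-frame instances (vectorized)."""
    if not is_codon(codon):
        raise ValueError(f"not an ACGT codon: {codon!r}")
    idx = np.flatnonzero(orf.codon_array == codon)
    return 3 * idx


def count_sense_instances(orfs: dict[str, OrfModel]) -> dict[str, int]:
    """Instance counts for every sense codon (stop codons not included)."""
    counts = dict.fromkeys(SENSE_CODONS, 0)
    for o in orfs.values():
        for c in o.codons:
            if c in counts:
                counts[c] += 1
    return counts
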