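"""Synthetic Ribo-seq / RNA-seq library generator with known ground truth.

The generative model is the inverse of the analysis: a ribosome's P-site
codon position is drawn with probability proportional to the host gene's
initiation flux times the product of dwell multipliers over the seven codons
it covers (sites -2..+2).  Dwell effects are multiplicative across sites,
the regime is initiation-limited (positions are sampled independently; no
explicit ribosome traffic), and footprint 5' ends are deterministic given
read length.  Reads carry in-vitro poly-A tails, reproducing the length
ambiguity that arises when a footprint boundary coincides with a genomic A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, SITE_CODON_DELTA, SITES, STOP_CODONS
from .reference import OrfModel

#: 5'-end -> P-site first-nt distance for the standard footprint anatomy.
#: Consistent with frame shifts (25:0, 26:0, 27:0, 28:0, 29:-1, 30:-1, 31:-2)
#: relative to the 12-nt 28-mer offset.
STANDARD_PSITE_OFFSETS: dict[int, int] = {25: 12, 26: 12, 27: 12, 28: 12, 29: 13, 30: 13, 31: 14}

#: a realistic footprint length distribution (28-mers dominate)
STANDARD_LENGTH_DISTRIBUTION: dict[int, float] = {
    25: 0.02, 26: 0.06, 27: 0.15, 28: 0.45, 29: 0.20, 30: 0.08, 31: 0.04,
}

#: poly-A tail lengths (>= 4 nt survive trimming in real libraries)
STANDARD_TAIL_DISTRIBUTION: dict[int, float] = {
    4: 0.25, 5: 0.20, 6: 0.17, 7: 0.13, 8: 0.10, 9: 0.07, 10: 0.05, 11: 0.02, 12: 0.01,
}

#: codon-context half-width: sites -2..+2 cover P-site codon +/- 3 codons
CONTEXT_CODONS = 3


@dataclass
class SimulationTruth:
    """Everything needed to regenerate a library, and to check recovery.

    dwell_multiplier keys are (site, codon) pairs, e.g. ("A", "AAA"); any
    absent pair has multiplier 1.0.  start_peak_fraction is the fraction of
    reads from initiating ribosomes (start codon in the P site) -- the peak
    the P-site calibration reads out.
    """

    gene_flux: dict[str, float]
    dwell_multiplier: dict[tuple[str, str], float] = field(default_factory=dict)
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(STANDARD_LENGTH_DISTRIBUTION)
    )
    psite_offset_by_length: dict[int, int] = field(
        default_factory=lambda: dict(STANDARD_PSITE_OFFSETS)
    )
    tail_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(STANDARD_TAIL_DISTRIBUTION)
    )
    queue_probability: float = 0.0
    start_peak_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.dwell_multiplier.values()):
            raise ValueError("dwell multipliers must be positive")
        if any(s not in SITES for s, _ in self.dwell_multiplier):
            raise ValueError("dwell multiplier site must be one of " + ",".join(SITES))
        tot = sum(self.length_distribution.values())
        if not np.isclose(tot, 1.0):
            raise ValueError(f"length_distribution sums to {tot}, not 1")
        for L, p in self.length_distribution.items():
            if p > 0 and L not in self.psite_offset_by_length:
                raise ValueError(f"no P-site offset for length {L}")
        if any(t < 4 for t in self.tail_length_distribution):
            raise ValueError("poly-A tails shorter than 4 nt are not modelled")

    def multiplier(self, site: str, codon: str) -> float:
        return self.dwell_multiplier.get((site, codon), 1.0)

    def with_dwell(self, dwell: dict[tuple[str, str], float], **kw) -> "SimulationTruth":
        return replace(self, dwell_multiplier=dict(dwell), **kw)


def uniform_flux(orfs: dict[str, OrfModel]) -> dict[str, float]:
    return {orf_id: 1.0 for orf_id in orfs}


# ---------------------------------------------------------------------------
# reference construction


def build_synthetic_reference(
    n_orfs: int,
    length_range_codons: tuple[int, int],
    codon_usage_weights: dict[str, float] | None = None,
    flank_composition: dict[str, float] | None = None,
    seed: int = 0,
    flank_nt: int = 60,
) -> dict[str, OrfModel]:
    """Random ORFs: ATG + usage-weighted sense codons + a stop, with flanks.

    ``flank_composition`` controls flank base frequencies (an A-free flank
    makes footprints ending at the ORF/flank boundary unambiguous by
    construction).  Reproducible given the seed.
    """
    lo, hi = length_range_codons
    if lo < 20:
        raise ValueError("ORFs must be at least 20 codons")
    rng = np.random.default_rng(seed)
    if codon_usage_weights is None:
        usage = {c: 1.0 for c in SENSE_CODONS}
    else:
        usage = {c: float(codon_usage_weights.get(c, 0.0)) for c in SENSE_CODONS}
    w = np.array([usage[c] for c in SENSE_CODONS], dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise ValueError("codon usage weights must be non-negative with a positive sum")
    # the start codon is fixed; avoid spurious interior ATG weight distortion is
    # not attempted -- interior codons follow the stated usage exactly
    pw = w / w.sum()
    if flank_composition is None:
        comp = {b: 0.25 for b in "ACGT"}
    else:
        comp = {b: float(flank_composition.get(b, 0.0)) for b in "ACGT"}
    cw = np.array([comp[b] for b in "ACGT"], dtype=float)
    if cw.sum() <= 0:
        raise ValueError("flank composition weights must have a positive sum")
    cw = cw / cw.sum()
    bases = np.array(list("ACGT"))
    sense = np.array(SENSE_CODONS, dtype=object)
    stops = np.array(STOP_CODONS, dtype=object)

    orfs: dict[str, OrfModel] = {}
    for i in range(n_orfs):
        n_codons = int(rng.integers(lo, hi + 1))
        interior = rng.choice(sense, size=n_codons - 2, p=pw)
        stop = rng.choice(stops)
        coding = "ATG" + "".join(interior) + str(stop)
        up = "".join(rng.choice(bases, size=flank_nt, p=cw))
        down = "".join(rng.choice(bases, size=flank_nt, p=cw))
        orf_id = f"synth{i:04d}"
        model = OrfModel(orf_id, coding, up, down)
        model.validate(strict=True)
        orfs[orf_id] = model
    return dict(sorted(orfs.items()))


# ---------------------------------------------------------------------------
# footprint simulation

READ_COLUMNS = ["read_id", "orf_id", "true_fiveprime", "true_length", "tail_length", "origin"]


def _position_weights(orf: OrfModel, truth: SimulationTruth) -> np.ndarray:
    """Sampling weight for the P site at each codon index (0 where excluded).

    Codon indices whose 7-codon context (P-site codon +/- 3) leaves the ORF
    are excluded from elongation sampling.
    """
    n = orf.n_codons
    w = np.zeros(n, dtype=float)
    k0, k1 = CONTEXT_CODONS, n - CONTEXT_CODONS  # valid P-site codon indices
    if k1 <= k0:
        return w
    w[k0:k1] = 1.0
    if truth.dwell_multiplier:
        codon_arr = orf.codon_array
        for (site, codon), m in truth.dwell_multiplier.items():
            delta = SITE_CODON_DELTA[site]
            # P at k places `codon` in `site` iff codon_arr[k + delta] == codon
            hits = np.flatnonzero(codon_arr == codon) - delta
            hits = hits[(hits >= k0) & (hits < k1)]
            w[hits] *= m
    return w


def simulate_footprints(
    orfs: dict[str, OrfModel],
    truth: SimulationTruth,
    n_reads: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw footprints; returns a read table (one row per read).

    Columns: read_id, orf_id, true_fiveprime, true_length, tail_length,
    origin ("elongation" | "initiation").  true_fiveprime is the ORF-relative
    5'-end position (P-site position minus the length's P-site offset).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    orf_ids: list[str] = []
    pos_orf: list[np.ndarray] = []
    pos_k: list[np.ndarray] = []
    pos_w: list[np.ndarray] = []
    flux_ids, flux_w = [], []
    for j, (orf_id, orf) in enumerate(orfs.items()):
        flux = float(truth.gene_flux.get(orf_id, 0.0))
        if flux < 0:
            raise ValueError(f"{orf_id}: negative flux")
        if orf.n_codons < 2 * CONTEXT_CODONS + 1:
            warnings.warn(f"{orf_id}: shorter than the 7-codon context window; skipped")
            continue
        if flux == 0.0:
            continue
        w = _position_weights(orf, truth) * flux
        keep = np.flatnonzero(w > 0)
        orf_ids.append(orf_id)
        pos_orf.append(np.full(len(keep), len(orf_ids) - 1, dtype=np.int32))
        pos_k.append(keep.astype(np.int32))
        pos_w.append(w[keep])
        flux_ids.append(orf_id)
        flux_w.append(flux)
    if not pos_w:
        raise ValueError("no ORF is long enough to sample from")

    flat_orf = np.concatenate(pos_orf)
    flat_k = np.concatenate(pos_k)
    flat_w = np.concatenate(pos_w)
    flat_p = flat_w / flat_w.sum()

    n_init = rng.binomial(n_reads, truth.start_peak_fraction)
    n_elong = n_reads - n_init

    idx = rng.choice(len(flat_p), size=n_elong, p=flat_p)
    e_orf = flat_orf[idx]
    e_psite = 3 * flat_k[idx].astype(np.int64)

    fw = np.array(flux_w, dtype=float)
    gi = rng.choice(len(fw), size=n_init, p=fw / fw.sum())
    i_orf = gi.astype(np.int32)
    i_psite = np.zeros(n_init, dtype=np.int64)

    all_orf = np.concatenate([e_orf, i_orf])
    all_psite = np.concatenate([e_psite, i_psite])
    origin = np.array(["elongation"] * n_elong + ["initiation"] * n_init, dtype=object)

    lengths_av = np.array(sorted(truth.length_distribution), dtype=np.int64)
    lp = np.array([truth.length_distribution[int(L)] for L in lengths_av], dtype=float)
    lens = lengths_av[rng.choice(len(lengths_av), size=n_reads, p=lp / lp.sum())]
    offs = np.array([truth.psite_offset_by_length[int(L)] for L in lengths_av], dtype=np.int64)
    off_of = dict(zip(lengths_av.tolist(), offs.tolist()))
    fiveprime = all_psite - np.array([off_of[int(L)] for L in lens], dtype=np.int64)

    tails_av = np.array(sorted(truth.tail_length_distribution), dtype=np.int64)
    tp = np.array([truth.tail_length_distribution[int(t)] for t in tails_av], dtype=float)
    tails = tails_av[rng.choice(len(tails_av), size=n_reads, p=tp / tp.sum())]

    id_arr = np.array(orf_ids, dtype=object)
    df = pd.DataFrame(
        {
            "read_id": np.arange(n_reads, dtype=np.int64),
            "orf_id": id_arr[all_orf],
            "true_fiveprime": fiveprime,
            "true_length": lens.astype(np.int64),
            "tail_length": tails.astype(np.int64),
            "origin": origin,
        }
    )
    return df


def inject_queue(
    reads: pd.DataFrame,
    orfs: dict[str, OrfModel],
    truth: SimulationTruth,
    stall_positions: list[tuple[str, int]],
    spacing_nt: int = 28,
    seed: int | None = None,
) -> pd.DataFrame:
    """Add stacked trailing ribosomes behind stalled A-site codons.

    For each read whose A-site codon is a stall position, with probability
    ``truth.queue_probability`` an extra read is emitted whose 5' end lies
    ``spacing_nt`` upstream (5'-end to 5'-end), length drawn from the same
    length model.
    """
    for orf_id, k in stall_positions:
        if orf_id not in orfs:
            raise ValueError(f"stall position ({orf_id!r}, {k}) has no host ORF")
        if not 0 <= k < orfs[orf_id].n_codons:
            raise ValueError(f"stall codon index {k} outside {orf_id!r}")
    if truth.queue_probability == 0.0 or len(stall_positions) == 0:
        return reads.copy()
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)

    offs = reads["true_length"].map(truth.psite_offset_by_length).to_numpy()
    a_first_nt = reads["true_fiveprime"].to_numpy() + offs + 3
    a_index = a_first_nt // 3
    stall_keys = set(stall_positions)
    keys = list(zip(reads["orf_id"], a_index.tolist()))
    is_lead = np.array([key in stall_keys for key in keys], dtype=bool)
    lead = reads[is_lead]
    pick = rng.random(len(lead)) < truth.queue_probability
    lead = lead[pick]
    n = len(lead)
    if n == 0:
        return reads.copy()

    lengths_av = np.array(sorted(truth.length_distribution), dtype=np.int64)
    lp = np.array([truth.length_distribution[int(L)] for L in lengths_av], dtype=float)
    lens = lengths_av[rng.choice(len(lengths_av), size=n, p=lp / lp.sum())]
    tails_av = np.array(sorted(truth.tail_length_distribution), dtype=np.int64)
    tp = np.array([truth.tail_length_distribution[int(t)] for t in tails_av], dtype=float)
    tails = tails_av[rng.choice(len(tails_av), size=n, p=tp / tp.sum())]

    extra = pd.DataFrame(
        {
            "read_id": np.arange(len(reads), len(reads) + n, dtype=np.int64),
            "orf_id": lead["orf_id"].to_numpy(),
            "true_fiveprime": lead["true_fiveprime"].to_numpy() - spacing_nt,
            "true_length": lens.astype(np.int64),
            "tail_length": tails.astype(np.int64),
            "origin": "queue",
        }
    )
    return pd.concat([reads, extra], ignore_index=True)


def simulate_rnaseq(
    orfs: dict[str, OrfModel],
    abundances: dict[str, float],
    n_reads: int,
    read_length: int = 28,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform-coverage RNA-seq control: 5' ends uniform over each ORF.

    Gene weight is abundance x number of start positions, so coverage per nt
    is proportional to abundance.  Reads carry no poly-A tail.
    """
    if not abundances or all(v == 0 for v in abundances.values()):
        raise ValueError("empty or all-zero abundance table")
    rng = np.random.default_rng(seed)
    ids, weights, npos = [], [], []
    for orf_id, orf in orfs.items():
        a = float(abundances.get(orf_id, 0.0))
        if a < 0:
            raise ValueError(f"{orf_id}: negative abundance")
        span = len(orf.coding_seq) - read_length + 1
        if a == 0 or span <= 0:
            continue
        ids.append(orf_id)
        weights.append(a * span)
        npos.append(span)
    w = np.array(weights, dtype=float)
    gi = rng.choice(len(w), size=n_reads, p=w / w.sum())
    spans = np.array(npos, dtype=np.int64)[gi]
    pos = (rng.random(n_reads) * spans).astype(np.int64)
    id_arr = np.array(ids, dtype=object)
    return pd.DataFrame(
        {
            "read_id": np.arange(n_reads, dtype=np.int64),
            "orf_id": id_arr[gi],
            "true_fiveprime": pos,
            "true_length": np.full(n_reads, read_length, dtype=np.int64),
            "tail_length": np.zeros(n_reads, dtype=np.int64),
            "origin": "rnaseq",
        }
    )


# ---------------------------------------------------------------------------
# emission


def read_sequence(row_orf: OrfModel, fiveprime: int, length: int, tail: int) -> str:
    return row_orf.sequence(fiveprime, fiveprime + length) + "A" * tail


def write_fastq(reads: pd.DataFrame, orfs: dict[str, OrfModel], path) -> int:
    """Emit reads as FASTQ (footprint slice + poly-A tail); returns count."""
    n = 0
    with open(path, "w") as fh:
        for rid, orf_id, fp, L, tail in zip(
            reads["read_id"], reads["orf_id"], reads["true_fiveprime"],
            reads["true_length"], reads["tail_length"],
        ):
            seq = read_sequence(orfs[orf_id], int(fp), int(L), int(tail))
            fh.write(f"@read{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def reads_to_sized_counts(reads: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a read table into a sized 5'-end count table (truth lengths).

    This is the simulator acting as its own (perfect) mapper; the honest
    route through FASTQ and length determination lives in footprints.map_fastq.
    """
    g = (
        reads.groupby(["orf_id", "true_fiveprime", "true_length"], sort=True)
        .size()
        .reset_index(name="count")
        .rename(columns={"true_fiveprime": "fiveprime", "true_length": "length"})
    )
    return g


def write_truth_tables(truth: SimulationTruth, orfs: dict[str, OrfModel], outdir) -> None:
    """Dump dwell multipliers and fluxes as plain TSVs."""
    import os

    rows = [
        {"site": s, "codon": c, "multiplier": m}
        for (s, c), m in sorted(truth.dwell_multiplier.items())
    ]
    pd.DataFrame(rows, columns=["site", "codon", "multiplier"]).to_csv(
        os.path.join(outdir, "truth_dwell.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {"orf_id": list(truth.gene_flux), "flux": list(truth.gene_flux.values())}
    ).to_csv(os.path.join(outdir, "truth_flux.tsv"), sep="\t", index=False)
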